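"""Reference checks that exercise the full pipeline against independent oracles.

Each function here regenerates its own synthetic inputs from a seed, runs
the relevant pipeline stage(s), and measures agreement with either an
exhaustive brute-force oracle or the designed ground truth.  They are the
package's self-validation battery: the test suite asserts on their
outputs, and the reproduction script reports them.

The problem sizes (numbers of stacks, spots, cells, curves) are chosen so
the full battery runs in a couple of minutes on one CPU while still
exercising every code path at realistic scale.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.spatial import cKDTree

from .biophysics import fit_on_rate, melting_temperature
from .cellquant import (
    CellQuant,
    correlate_copy_number,
    fit_autofluorescence,
    integrated_density,
    quantify_cells,
)
from .coloc import ColocParams, colocalize, find_pairs
from .detect import DetectionParams, detect_transcripts, find_maxima_stack, maxima_3d
from .preprocess import ImageStack
from .roi import rectangle_roi
from .synthetic import (
    CellFieldTruth,
    RenderParams,
    make_scene,
    render_cell_field,
    render_stack,
    simulate_kinetics,
    simulate_melt_curve,
)

# ---------------------------------------------------------------------------
# brute-force oracles (kept deliberately naive and separate from the pipeline)


def _oracle_spots_3d(voxels: np.ndarray) -> set[tuple[int, int, int]]:
    """Exhaustive 26-neighborhood scan over candidate 2D maxima."""
    nz, ny, nx = voxels.shape
    survivors = []
    for z in range(nz):
        for y in range(1, ny - 1):
            for x in range(1, nx - 1):
                v = voxels[z, y, x]
                in_slice = [
                    voxels[z, yy, xx]
                    for yy in (y - 1, y, y + 1)
                    for xx in (x - 1, x, x + 1)
                    if (yy, xx) != (y, x)
                ]
                if not all(v > w for w in in_slice):
                    continue
                cube = [
                    voxels[zz, yy, xx]
                    for zz in range(max(z - 1, 0), min(z + 2, nz))
                    for yy in (y - 1, y, y + 1)
                    for xx in (x - 1, x, x + 1)
                    if (zz, yy, xx) != (z, y, x)
                ]
                if all(v >= w for w in cube) and any(v > w for w in cube):
                    survivors.append((z, y, x, v))
    survivors.sort()
    kept: list[tuple[int, int, int, float]] = []
    for z, y, x, v in survivors:
        if not any(
            kv == v and abs(kz - z) <= 1 and abs(ky - y) <= 1 and abs(kx - x) <= 1
            for kz, ky, kx, kv in kept
        ):
            kept.append((z, y, x, v))
    return {(z, y, x) for z, y, x, _ in kept}


def _oracle_pairs(A: np.ndarray, B: np.ndarray, z_reach: float, radius: float) -> set:
    """All-pairs cylinder test via dense distance matrices."""
    dz = np.abs(A[:, 0:1] - B[:, 0].T)
    lat2 = (A[:, 1:2] - B[:, 1].T) ** 2 + (A[:, 2:3] - B[:, 2].T) ** 2
    ii, jj = np.nonzero((dz <= z_reach) & (lat2 <= radius**2))
    return {(int(i), int(j)) for i, j in zip(ii, jj)}


# ---------------------------------------------------------------------------
# checks


def spot_oracle_check(seed: int, n_stacks: int = 100, shape=(9, 16, 16)) -> dict:
    """Pipeline 3D maxima vs the exhaustive cube oracle on random stacks."""
    rng = np.random.default_rng([seed, 1])
    discrepancies = 0
    total = 0
    for _ in range(n_stacks):
        voxels = np.round(rng.uniform(0, 30, shape), 0)  # coarse values force ties
        stack = ImageStack(voxels)
        maxima = find_maxima_stack(stack)
        got = {(s.z, s.y, s.x) for s in maxima_3d(maxima, stack)}
        want = _oracle_spots_3d(stack.voxels)
        discrepancies += len(got ^ want)
        total += len(want)
    return {"n_stacks": n_stacks, "n_oracle_spots": total, "discrepancies": discrepancies}


def coloc_oracle_check(seed: int, n_scenes: int = 20, n_spots: int = 500) -> dict:
    """find_pairs vs the all-pairs oracle, plus cylinder boundary cases."""
    rng = np.random.default_rng([seed, 2])
    params = ColocParams()
    discrepancies = 0
    total = 0
    for _ in range(n_scenes):
        A = rng.uniform(0, [30, 100, 100], (n_spots, 3))
        B = rng.uniform(0, [30, 100, 100], (n_spots, 3))
        got = find_pairs(A, B, params)
        want = _oracle_pairs(A, B, params.z_reach, params.radius)
        discrepancies += len(got ^ want)
        total += len(want)
    a = [(10.0, 50.0, 50.0)]
    boundary_ok = (
        find_pairs(a, [(14.0, 53.0, 54.0)], params) == {(0, 0)}  # dz=4, lat=5.0
        and find_pairs(a, [(15.0, 50.0, 50.0)], params) == set()  # dz=5
        and find_pairs(a, [(10.0, 50.0, 55.01)], params) == set()  # lat=5.01
    )
    return {
        "n_scenes": n_scenes,
        "n_oracle_pairs": total,
        "discrepancies": discrepancies,
        "boundary_ok": bool(boundary_ok),
    }


def _match_f1(truth: np.ndarray, spots, tol: float = 3.0) -> float:
    if len(spots) == 0:
        return 0.0
    det = np.array([[s.z, s.y, s.x] for s in spots], dtype=float)
    d, idx = cKDTree(truth).query(det)
    tp = len(set(idx[d < tol]))
    precision = tp / len(det)
    recall = tp / len(truth)
    return 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)


def fraction_recovery_check(seed: int, fractions=(0.2, 0.5, 0.75), n_spots: int = 40) -> dict:
    """Designed colocalized fraction: exact at ground truth, close after imaging.

    Truth-level percentages are computed on the designed coordinates; the
    end-to-end percentages re-detect both channels from rendered stacks
    (amplitude 200 against ~4 units of combined shot + read noise, i.e.
    SNR far above 10) and colocalize the detections.
    """
    out: dict = {"fractions": list(fractions)}
    truth_pcts, e2e_pcts = [], []
    roi = rectangle_roi(8, 8, 140, 140)
    for k, f in enumerate(fractions):
        scene = make_scene(
            n_spots, n_spots, f, roi, stack_shape=(56, 150, 150),
            seed=int(np.random.default_rng([seed, 3, k]).integers(2**31)),
            min_separation=4 * 1.3, separation_z_scale=1.3 / 2.0,
        )
        truth_pcts.append(colocalize(scene.spots_a, scene.spots_b).pct_a)
        params = RenderParams(seed=seed + k)
        spots_a = detect_transcripts(render_stack(scene, params, channel="a"), roi, DetectionParams())
        spots_b = detect_transcripts(render_stack(scene, params, channel="b"), roi, DetectionParams())
        e2e_pcts.append(colocalize(spots_a, spots_b).pct_a)
    designed = [100.0 * round(f * n_spots) / n_spots for f in fractions]
    out["truth_pct_a"] = truth_pcts
    out["end_to_end_pct_a"] = e2e_pcts
    out["truth_exact"] = bool(
        all(abs(t - d) < 1e-9 for t, d in zip(truth_pcts, designed))
    )
    out["max_end_to_end_error_pp"] = float(
        max(abs(e - d) for e, d in zip(e2e_pcts, designed))
    )
    return out


def detection_recovery_check(seed: int, n_spots: int = 50, n_thresholds: int = 10) -> dict:
    """F1 on well-separated bright spots plus the threshold monotonicity sweep."""
    roi = rectangle_roi(8, 8, 120, 120)
    scene = make_scene(
        n_spots, 0, 0.0, roi, stack_shape=(56, 128, 128), seed=seed + 17,
        min_separation=4 * 1.3, separation_z_scale=1.3 / 2.0,
    )
    stack = render_stack(scene, RenderParams(seed=seed + 18))
    spots = detect_transcripts(stack, roi, DetectionParams())
    f1 = _match_f1(scene.spots_a, spots)
    counts = []
    for thr in np.linspace(0.0, 400.0, n_thresholds):
        counts.append(
            len(detect_transcripts(stack, roi, DetectionParams(min_intensity=float(thr))))
        )
    return {
        "n_true": n_spots,
        "n_detected": len(spots),
        "f1": float(f1),
        "threshold_counts": counts,
        "threshold_monotone": bool(counts == sorted(counts, reverse=True)),
    }


def _cell_grid(n_cells: int, cell: int = 18, gap: int = 6, ncol: int = 8):
    rois = []
    for k in range(n_cells):
        r, c = divmod(k, ncol)
        y0 = gap + r * (cell + gap)
        x0 = gap + c * (cell + gap)
        rois.append(rectangle_roi(y0, x0, y0 + cell - 1, x0 + cell - 1))
    nrow = (n_cells + ncol - 1) // ncol
    shape = (gap + nrow * (cell + gap), gap + ncol * (cell + gap))
    return rois, shape


def _fit_negative_af_model(seed: int, n_cells: int = 8):
    """Autofluorescence model from rendered probe-negative cells."""
    rois, shape = _cell_grid(n_cells)
    rng = np.random.default_rng([seed, 4])
    cells = [
        CellFieldTruth(r, tmr_density=float(rng.uniform(1.0, 4.0)),
                       ref_density=0.0, enhancement_density=0.0)
        for r in rois
    ]
    params = RenderParams(noise_model="gaussian", read_noise_sd=1.0, background_level=0.0,
                          autofluorescence_ratio=0.3, seed=seed + 41)
    rep, _, tmr = render_cell_field(cells, params, r_closed=0.2, shape=shape)
    pairs = [(integrated_density(rep, r), integrated_density(tmr, r)) for r in rois]
    return fit_autofluorescence(pairs)


def enhancement_check(seed: int, n_cells: int = 8) -> dict:
    """Closure at designed zero, exact linearity, full-chain slope recovery."""
    af_model = _fit_negative_af_model(seed)
    rois, shape = _cell_grid(n_cells)
    rng = np.random.default_rng([seed, 5])
    read_noise = 1.0

    # designed-zero field
    zero_cells = [
        CellFieldTruth(r, tmr_density=float(rng.uniform(1.0, 4.0)),
                       ref_density=8.0, enhancement_density=0.0)
        for r in rois
    ]
    params = RenderParams(noise_model="gaussian", read_noise_sd=read_noise,
                          background_level=0.0, autofluorescence_ratio=0.3, seed=seed + 51)
    rep, ref, tmr = render_cell_field(zero_cells, params, r_closed=0.2, shape=shape)
    quant = quantify_cells(rep, ref, tmr, rois, af_model, r_closed=0.2)
    n_pixels = rois[0].mask(shape).sum()
    # an enhancement combines three integrated densities, each with
    # read_noise * sqrt(n_pixels) of measurement noise
    noise_sd = read_noise * math.sqrt(n_pixels) * math.sqrt(3)
    mean_zero = float(np.mean([c.enhancement for c in quant]))
    sem = noise_sd / math.sqrt(n_cells)

    # exact linearity of the formula
    from .cellquant import enhancement as enh

    def e(rep_id, ref_id):
        return enh(CellQuant(rep_id=rep_id, ref_id=ref_id, tmr_id=0.0,
                             af_rep=30.0, r_closed=0.2))

    linear_ok = (
        abs((e(500.0, 100.0) - e(400.0, 100.0)) - 100.0) < 1e-9
        and abs((e(500.0, 200.0) - e(500.0, 100.0)) + 0.2 * 100.0) < 1e-9
    )

    # full chain: designed enhancement proportional to transcript count
    counts = [20, 60, 120, 240, 40, 160, 80, 200][:n_cells]
    per_count = 0.02
    chain_cells = [
        CellFieldTruth(r, tmr_density=float(rng.uniform(1.0, 4.0)),
                       ref_density=8.0, enhancement_density=per_count * n)
        for r, n in zip(rois, counts)
    ]
    params2 = RenderParams(noise_model="gaussian", read_noise_sd=read_noise,
                           background_level=0.0, autofluorescence_ratio=0.3, seed=seed + 52)
    rep, ref, tmr = render_cell_field(chain_cells, params2, r_closed=0.2, shape=shape)
    quant2 = quantify_cells(rep, ref, tmr, rois, af_model, r_closed=0.2, n_transcripts=counts)
    fit = correlate_copy_number(quant2)
    designed_slope = per_count * n_pixels
    return {
        "mean_zero_enhancement": mean_zero,
        "noise_sd": float(noise_sd),
        "zero_within_2sd": bool(abs(mean_zero) < 2 * noise_sd),
        "mean_zero_in_sem": float(abs(mean_zero) / sem),
        "linearity_exact": bool(linear_ok),
        "chain_slope": float(fit.slope),
        "designed_slope": float(designed_slope),
        "chain_slope_rel_error": float(abs(fit.slope - designed_slope) / designed_slope),
    }


def copy_number_check(seed: int, n_cells: int = 48) -> dict:
    """Pearson correlation of recovered enhancement vs true transcript count.

    Cells span 0-300 transcripts with 10% multiplicative noise on the
    designed enhancement signal, mirroring a linear
    fluorescence-per-transcript relation.
    """
    af_model = _fit_negative_af_model(seed + 1)
    rois, shape = _cell_grid(n_cells)
    rng = np.random.default_rng([seed, 6])
    counts = rng.integers(0, 301, n_cells)
    per_count = 0.02
    cells = [
        CellFieldTruth(
            r,
            tmr_density=float(rng.uniform(1.0, 4.0)),
            ref_density=8.0,
            enhancement_density=float(per_count * n * (1 + 0.10 * rng.standard_normal())),
        )
        for r, n in zip(rois, counts)
    ]
    params = RenderParams(noise_model="gaussian", read_noise_sd=1.0, background_level=0.0,
                          autofluorescence_ratio=0.3, seed=seed + 61)
    rep, ref, tmr = render_cell_field(cells, params, r_closed=0.2, shape=shape)
    quant = quantify_cells(rep, ref, tmr, rois, af_model, r_closed=0.2,
                           n_transcripts=[int(n) for n in counts])
    fit = correlate_copy_number(quant)
    return {"n_cells": n_cells, "pearson_r": float(fit.r), "slope": float(fit.slope)}


def biophysics_check(seed: int, n_curves: int = 100, n_traces: int = 100) -> dict:
    """Tm and k_obs recovery statistics over many noisy simulations.

    Melting curves: Tm 61.3 degC, amplitude 900, noise 1% of amplitude.
    Kinetics: k_obs 0.01 /s, amplitude 900, noise 2% of amplitude.
    """
    rng = np.random.default_rng([seed, 7])
    tm_true = 61.3
    errors = []
    for _ in range(n_curves):
        c = simulate_melt_curve(tm_true, 2.5, 100.0, 1000.0, noise_sd=9.0,
                                seed=int(rng.integers(2**31)))
        res = melting_temperature(c)
        if res.tm is not None:
            errors.append(res.tm - tm_true)
    errors = np.array(errors)

    k_true = 0.01
    rel_sq = []
    for _ in range(n_traces):
        tr = simulate_kinetics(k_true, 100.0, 1000.0, noise_sd=18.0,
                               times=np.arange(0.0, 600.0),
                               seed=int(rng.integers(2**31)))
        fit = fit_on_rate(tr)
        rel_sq.append(((fit.k_obs - k_true) / k_true) ** 2)
    return {
        "n_curves": int(len(errors)),
        "tm_bias_c": float(errors.mean()),
        "tm_sd_c": float(errors.std()),
        "n_traces": n_traces,
        "k_obs_rel_rmse": float(math.sqrt(np.mean(rel_sq))),
    }


def determinism_check(seed: int) -> dict:
    """Identical seeds and configs must give bit-identical results everywhere."""
    roi = rectangle_roi(8, 8, 90, 90)

    def run():
        scene = make_scene(15, 15, 0.4, roi, stack_shape=(20, 100, 100), seed=seed + 71,
                           min_separation=5.0, separation_z_scale=0.65)
        params = RenderParams(seed=seed + 72)
        stack = render_stack(scene, params)
        spots = detect_transcripts(stack, roi, DetectionParams())
        melt = simulate_melt_curve(60.0, 2.5, 100.0, 1000.0, noise_sd=9.0, seed=seed + 73)
        kin = simulate_kinetics(0.01, 100.0, 1000.0, noise_sd=18.0, seed=seed + 74)
        return scene, stack, spots, melt, kin

    s1, st1, sp1, m1, k1 = run()
    s2, st2, sp2, m2, k2 = run()
    identical = (
        np.array_equal(s1.spots_a, s2.spots_a)
        and np.array_equal(s1.spots_b, s2.spots_b)
        and np.array_equal(st1.voxels, st2.voxels)
        and sp1 == sp2
        and np.array_equal(m1.fluorescence, m2.fluorescence)
        and np.array_equal(k1.fluorescence, k2.fluorescence)
    )
    return {"identical": bool(identical), "n_spots": len(sp1)}
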