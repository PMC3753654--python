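"""Synthetic microscopy: ground-truth scenes, renderers and biophysics curves.

Every downstream stage of the pipeline is testable without real data
through this module.  It emulates the imaging setting of
single-transcript experiments: 56-slice z-stacks at 0.2 um z-spacing in
which each transcript — tagged by up to ~96 hybridized probes — appears
as one bright diffraction-limited punctum, two spectrally distinct
channels with a *designed* colocalized fraction, cell-shaped polygon
ROIs, autofluorescent background, and shot/read noise.

Ground truth is exact by construction: designed-colocalized partner
spots are sampled inside the colocalization cylinder (shrunk by a safety
margin), and every other cross-channel pair is kept outside all
cylinders by rejection sampling with an explicit failure — never silent
clutter.  Spot centers are continuous (sub-voxel); voxelization happens
only at render time, so cylinder boundary cases can be probed precisely.

The point-spread function is an anisotropic 3D Gaussian (peak amplitude
= the spot's amplitude); optics-accurate PSF models, photobleaching and
spot motion are out of scope.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .cellquant import CellQuant  # noqa: F401  (ground-truth fields mirror CellQuant)
from .coloc import ColocParams
from .preprocess import ImageStack
from .roi import PolygonROI


class SceneGeometryError(RuntimeError):
    """The ROI/cylinder geometry left no room to place a spot as designed."""


@dataclass
class RenderParams:
    """Optics and noise of the virtual microscope.

    psf_sigma_xy / psf_sigma_z:
        Gaussian PSF widths in lateral voxels and z-slices.  Defaults
        (1.3, 2.0) approximate a high-NA oil objective sampled near
        Nyquist with 0.2 um z-steps.
    background_level / background_gradient:
        Flat background plus a linear ramp along x (intensity units /
        pixel), emulating uneven illumination.
    autofluorescence_ratio:
        Reporter-channel autofluorescence per unit of TMR-channel
        autofluorescence (used by :func:`render_cell_field`).
    noise_model:
        "poisson", "gaussian" or "poisson+gaussian" (default — shot noise
        plus EMCCD-like read noise).
    read_noise_sd:
        SD of the additive Gaussian read noise, intensity units.
    """

    psf_sigma_xy: float = 1.3
    psf_sigma_z: float = 2.0
    background_level: float = 10.0
    background_gradient: float = 0.0
    autofluorescence_ratio: float = 0.3
    noise_model: str = "poisson+gaussian"
    read_noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.psf_sigma_xy <= 0 or self.psf_sigma_z <= 0:
            raise ValueError("PSF sigmas must be positive")
        if self.background_level < 0 or self.read_noise_sd < 0:
            raise ValueError("background_level and read_noise_sd must be >= 0")
        if self.noise_model not in ("poisson", "gaussian", "poisson+gaussian", "none"):
            raise ValueError("noise_model must be poisson, gaussian, poisson+gaussian or none")


@dataclass
class Scene:
    """Exact ground truth for a two-channel field.

    ``spots_a``/``spots_b`` are ``(n, 3)`` float arrays of ``(z, y, x)``
    centers in voxel units (sub-voxel allowed) with per-spot peak
    amplitudes.  ``coloc_flags[i]`` marks channel-A spot ``i`` as having
    a designed partner; by construction the designed pairs are
    ``(i, i)`` for the flagged (first) indices.
    """

    spots_a: np.ndarray
    amps_a: np.ndarray
    spots_b: np.ndarray
    amps_b: np.ndarray
    coloc_flags: np.ndarray
    cell_roi: PolygonROI
    stack_shape: tuple[int, int, int]
    seed: int

    @property
    def n_designed_pairs(self) -> int:
        return int(self.coloc_flags.sum())

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "spots_a": self.spots_a.tolist(),
                    "amps_a": self.amps_a.tolist(),
                    "spots_b": self.spots_b.tolist(),
                    "amps_b": self.amps_b.tolist(),
                    "coloc_flags": self.coloc_flags.astype(int).tolist(),
                    "cell_roi": self.cell_roi.to_dict(),
                    "stack_shape": list(self.stack_shape),
                    "seed": self.seed,
                },
                fh,
            )

    @classmethod
    def from_json(cls, path) -> "Scene":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            spots_a=np.array(d["spots_a"], dtype=float).reshape(-1, 3),
            amps_a=np.array(d["amps_a"], dtype=float),
            spots_b=np.array(d["spots_b"], dtype=float).reshape(-1, 3),
            amps_b=np.array(d["amps_b"], dtype=float),
            coloc_flags=np.array(d["coloc_flags"], dtype=bool),
            cell_roi=PolygonROI.from_dict(d["cell_roi"]),
            stack_shape=tuple(d["stack_shape"]),
            seed=int(d["seed"]),
        )


# ---------------------------------------------------------------------------
# scene design


def _inside_cylinder(p: np.ndarray, q: np.ndarray, z_reach: float, radius: float) -> bool:
    return abs(p[0] - q[0]) <= z_reach and math.hypot(p[1] - q[1], p[2] - q[2]) <= radius


def _separated(p: np.ndarray, others: list[np.ndarray], min_sep: float, z_scale: float) -> bool:
    if min_sep <= 0:
        return True
    for q in others:
        d2 = (p[1] - q[1]) ** 2 + (p[2] - q[2]) ** 2 + (z_scale * (p[0] - q[0])) ** 2
        if d2 < min_sep**2:
            return False
    return True


def make_scene(
    n_spots_a: int,
    n_spots_b: int,
    coloc_fraction: float,
    cell_roi: PolygonROI,
    stack_shape: tuple[int, int, int] = (56, 128, 128),
    coloc_params: ColocParams | None = None,
    seed: int = 0,
    amplitude: float = 200.0,
    amplitude_cv: float = 0.1,
    min_separation: float = 0.0,
    separation_z_scale: float = 1.0,
    cylinder_margin: float = 1.0,
    max_attempts: int = 10_000,
) -> Scene:
    """Design a two-channel ground-truth scene with an exact colocalized fraction.

    Exactly ``round(coloc_fraction * n_spots_a)`` channel-A spots receive
    a channel-B partner placed uniformly inside the colocalization
    cylinder (shrunk laterally by ``cylinder_margin`` pixels and axially
    by one slice so designed pairs survive voxelization); all remaining
    cross-channel pairs are kept strictly outside every cylinder (grown
    by the same margin), so the designed fraction is exact at ground
    truth.  Deterministic per seed.

    Parameters
    ----------
    min_separation:
        Optional minimum pairwise separation between same-channel spots,
        measured as sqrt(dy^2 + dx^2 + (separation_z_scale * dz)^2) —
        set ``separation_z_scale = psf_sigma_xy / psf_sigma_z`` to make
        the constraint uniform in PSF widths.
    amplitude / amplitude_cv:
        Per-spot peak amplitudes are lognormal with this median and
        coefficient of variation, mimicking the brightness spread of
        multi-probe puncta.

    Raises
    ------
    SceneGeometryError
        When ``max_attempts`` rejections cannot place a spot (ROI too
        small or too cluttered).
    """
    if not 0.0 <= coloc_fraction <= 1.0:
        raise ValueError("coloc_fraction must be in [0, 1]")
    n_pairs = int(round(coloc_fraction * n_spots_a))
    if n_pairs > n_spots_b:
        raise ValueError("round(coloc_fraction * n_spots_a) exceeds n_spots_b")
    params = coloc_params or ColocParams()
    nz, ny, nx = stack_shape
    rng = np.random.default_rng(seed)
    ymin, xmin, ymax, xmax = cell_roi.bounds
    # spots must be renderable: restrict to the ROI's intersection with the stack
    ymin, xmin = max(ymin, 0.0), max(xmin, 0.0)
    ymax, xmax = min(ymax, ny - 1.0), min(xmax, nx - 1.0)
    if ymax <= ymin or xmax <= xmin:
        raise SceneGeometryError("cell ROI lies outside the stack's lateral bounds")
    z_pad = max(min(float(params.z_reach), (nz - 1) / 2 - 0.5), 0.0)
    z_lo, z_hi = z_pad, nz - 1 - z_pad
    if z_hi < z_lo:
        raise SceneGeometryError("stack too shallow to place spots")

    inner_r = max(params.radius - cylinder_margin, 0.0)
    inner_z = max(params.z_reach - 1.0, 0.0)
    outer_r = params.radius + cylinder_margin
    outer_z = params.z_reach + 1.0

    def sample_in_roi(z_range: tuple[float, float]) -> np.ndarray:
        for _ in range(max_attempts):
            y = rng.uniform(ymin, ymax)
            x = rng.uniform(xmin, xmax)
            if cell_roi.contains_point(y, x):
                z = rng.uniform(*z_range)
                return np.array([z, y, x])
        raise SceneGeometryError("could not place a spot inside the ROI")

    # channel A.  When partners will be designed, A spots additionally keep
    # two cylinder-widths of clearance from each other, so every flagged
    # spot's (shrunken) cylinder stays clear of all other (grown) cylinders
    # and partner placement is always feasible.
    spots_a: list[np.ndarray] = []
    for _ in range(n_spots_a):
        for _ in range(max_attempts):
            p = sample_in_roi((z_lo, z_hi))
            if not _separated(p, spots_a, min_separation, separation_z_scale):
                continue
            if n_pairs > 0 and any(
                _inside_cylinder(p, q, 2 * outer_z, 2 * outer_r) for q in spots_a
            ):
                continue
            spots_a.append(p)
            break
        else:
            raise SceneGeometryError("could not place channel-A spots at the requested separation")

    # channel B: designed partners for the first n_pairs A spots
    spots_b: list[np.ndarray] = []
    for i in range(n_pairs):
        a = spots_a[i]
        for _ in range(max_attempts):
            r = inner_r * math.sqrt(rng.uniform())
            theta = rng.uniform(0, 2 * math.pi)
            dz = rng.uniform(-inner_z, inner_z)
            p = a + np.array([dz, r * math.sin(theta), r * math.cos(theta)])
            if not (
                1.0 <= p[0] <= nz - 2.0
                and ymin <= p[1] <= ymax
                and xmin <= p[2] <= xmax
                and cell_roi.contains_point(p[1], p[2])
            ):
                continue
            # a partner may not stray into any *other* A spot's cylinder
            if any(
                _inside_cylinder(p, spots_a[j], outer_z, outer_r)
                for j in range(n_spots_a)
                if j != i
            ):
                continue
            if _separated(p, spots_b, min_separation, separation_z_scale):
                spots_b.append(p)
                break
        else:
            raise SceneGeometryError("could not place a designed colocalized partner")

    # channel B clutter: outside every A cylinder
    for _ in range(n_spots_b - n_pairs):
        for _ in range(max_attempts):
            p = sample_in_roi((z_lo, z_hi))
            if any(_inside_cylinder(p, a, outer_z, outer_r) for a in spots_a):
                continue
            if _separated(p, spots_b, min_separation, separation_z_scale):
                spots_b.append(p)
                break
        else:
            raise SceneGeometryError(
                "could not place non-colocalized spots outside all cylinders"
            )

    def amps(n: int) -> np.ndarray:
        if n == 0:
            return np.empty(0)
        if amplitude_cv <= 0:
            return np.full(n, amplitude)
        sig = math.sqrt(math.log(1 + amplitude_cv**2))
        return rng.lognormal(mean=math.log(amplitude), sigma=sig, size=n)

    flags = np.zeros(n_spots_a, dtype=bool)
    flags[:n_pairs] = True
    return Scene(
        spots_a=np.array(spots_a).reshape(-1, 3),
        amps_a=amps(n_spots_a),
        spots_b=np.array(spots_b).reshape(-1, 3),
        amps_b=amps(len(spots_b)),
        coloc_flags=flags,
        cell_roi=cell_roi,
        stack_shape=(nz, ny, nx),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# rendering


def _apply_noise(img: np.ndarray, params: RenderParams, rng: np.random.Generator) -> np.ndarray:
    if params.noise_model == "none":
        return img
    if params.noise_model == "poisson":
        return rng.poisson(img).astype(float)
    if params.noise_model == "gaussian":
        return img + rng.normal(0.0, params.read_noise_sd, img.shape)
    return rng.poisson(img).astype(float) + rng.normal(0.0, params.read_noise_sd, img.shape)


def _add_gaussian_spots(
    img: np.ndarray,
    spots: np.ndarray,
    amps: np.ndarray,
    sigma_z: float,
    sigma_xy: float,
) -> None:
    nz, ny, nx = img.shape
    hz = int(math.ceil(4.5 * sigma_z))
    hxy = int(math.ceil(4.5 * sigma_xy))
    for (z0, y0, x0), amp in zip(spots, amps):
        zi = np.arange(max(int(z0) - hz, 0), min(int(z0) + hz + 1, nz))
        yi = np.arange(max(int(y0) - hxy, 0), min(int(y0) + hxy + 1, ny))
        xi = np.arange(max(int(x0) - hxy, 0), min(int(x0) + hxy + 1, nx))
        gz = np.exp(-((zi - z0) ** 2) / (2 * sigma_z**2))
        gy = np.exp(-((yi - y0) ** 2) / (2 * sigma_xy**2))
        gx = np.exp(-((xi - x0) ** 2) / (2 * sigma_xy**2))
        img[np.ix_(zi, yi, xi)] += amp * gz[:, None, None] * gy[None, :, None] * gx[None, None, :]


def render_stack(
    scene: Scene,
    params: RenderParams,
    channel: str = "a",
    z_step: float = 0.2,
    pixel_size_xy: float = 0.16,
) -> ImageStack:
    """Render one channel of a scene into a z-stack.

    Each spot contributes an anisotropic 3D Gaussian with the scene's
    per-spot peak amplitude; background (flat level + x-gradient) is
    added, then noise per ``params.noise_model``.  Bit-reproducible for a
    given (scene, params) because the noise generator is seeded from
    ``params.seed`` and the channel label.
    """
    if channel not in ("a", "b"):
        raise ValueError("channel must be 'a' or 'b'")
    spots = scene.spots_a if channel == "a" else scene.spots_b
    amps = scene.amps_a if channel == "a" else scene.amps_b
    nz, ny, nx = scene.stack_shape
    if len(spots) and (
        spots[:, 0].min() < 0
        or spots[:, 0].max() > nz - 1
        or spots[:, 1].min() < 0
        or spots[:, 1].max() > ny - 1
        or spots[:, 2].min() < 0
        or spots[:, 2].max() > nx - 1
    ):
        raise ValueError("scene contains spots outside the stack bounds")
    img = np.full((nz, ny, nx), float(params.background_level))
    if params.background_gradient:
        img += params.background_gradient * np.arange(nx)[None, None, :]
    _add_gaussian_spots(img, np.asarray(spots, dtype=float), np.asarray(amps, dtype=float),
                        params.psf_sigma_z, params.psf_sigma_xy)
    rng = np.random.default_rng([params.seed, ord(channel)])
    noisy = _apply_noise(img, params, rng)
    return ImageStack(noisy, pixel_size_xy=pixel_size_xy, z_step=z_step, channel=channel)


# ---------------------------------------------------------------------------
# cell fields


@dataclass
class CellFieldTruth:
    """Designed per-cell signal densities (intensity per pixel) for a field image.

    Integrated density inside the ROI is density x (number of mask
    pixels), so the designed values are exactly recoverable at zero
    noise.
    """

    roi: PolygonROI
    tmr_density: float
    ref_density: float
    enhancement_density: float


def render_cell_field(
    cells: Sequence[CellFieldTruth],
    params: RenderParams,
    r_closed: float = 0.2,
    shape: tuple[int, int] = (256, 256),
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Render single-plane (reporter, reference, TMR) images of a cell field.

    Inside each cell's ROI: the TMR image carries the cell's
    autofluorescence density; the reference image its probe reference
    density; the reporter image ``autofluorescence_ratio x TMR density +
    r_closed x reference density + enhancement density``.  Background and
    noise are applied per ``params``.  Overlapping ROIs are rejected.
    """
    for i in range(len(cells)):
        for j in range(i + 1, len(cells)):
            if cells[i].roi.overlaps(cells[j].roi):
                raise ValueError(f"cell ROIs {i} and {j} overlap")
    reporter = np.full(shape, float(params.background_level))
    reference = np.full(shape, float(params.background_level))
    tmr = np.full(shape, float(params.background_level))
    for cell in cells:
        mask = cell.roi.mask(shape)
        tmr[mask] += cell.tmr_density
        reference[mask] += cell.ref_density
        reporter[mask] += (
            params.autofluorescence_ratio * cell.tmr_density
            + r_closed * cell.ref_density
            + cell.enhancement_density
        )
    rng = np.random.default_rng([params.seed, 101])
    return (
        _apply_noise(reporter, params, rng),
        _apply_noise(reference, params, rng),
        _apply_noise(tmr, params, rng),
    )


# ---------------------------------------------------------------------------
# probe biophysics curves


def simulate_melt_curve(
    tm: float,
    transition_width: float,
    f_folded: float,
    f_unfolded: float,
    drift_slope: float = 0.0,
    noise_sd: float = 0.0,
    temps: Sequence[float] | None = None,
    seed: int = 0,
    target_conc: float = 500.0,
):
    """Two-state melting profile: sigmoid + linear drift + Gaussian noise.

    ``F(T) = f_folded + (f_unfolded - f_folded) / (1 + exp(-(T - tm)/w))
    + drift_slope * (T - T_first) + noise``.  The default temperature
    grid descends from 95 to 25 degC in 1 degC steps, the standard
    thermal-scan protocol for hairpin probes.
    """
    from .biophysics import MeltCurve

    if transition_width <= 0:
        raise ValueError("transition_width must be positive")
    T = np.arange(95.0, 24.0, -1.0) if temps is None else np.asarray(temps, dtype=float)
    F = f_folded + (f_unfolded - f_folded) / (1.0 + np.exp(-(T - tm) / transition_width))
    F = F + drift_slope * (T - T[0])
    if noise_sd > 0:
        F = F + np.random.default_rng(seed).normal(0.0, noise_sd, len(T))
    return MeltCurve(T, F, target_conc=target_conc)


def simulate_kinetics(
    k_obs: float,
    f0: float,
    f_inf: float,
    noise_sd: float = 0.0,
    times: Sequence[float] | None = None,
    seed: int = 0,
    probe_conc: float = 50.0,
    target_conc: float = 500.0,
):
    """Pseudo-first-order hybridization trace:
    ``F(t) = f_inf - (f_inf - f0) exp(-k_obs t) + noise``."""
    from .biophysics import KineticsTrace

    if k_obs <= 0:
        raise ValueError("k_obs must be positive")
    t = np.arange(0.0, 600.0, 1.0) if times is None else np.asarray(times, dtype=float)
    F = f_inf - (f_inf - f0) * np.exp(-k_obs * t)
    if noise_sd > 0:
        F = F + np.random.default_rng(seed).normal(0.0, noise_sd, len(t))
    return KineticsTrace(t, F, probe_conc=probe_conc, target_conc=target_conc)
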