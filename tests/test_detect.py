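"""Spot detection: 2D maxima, ROI gating, thresholding, 3D cube promotion."""

import numpy as np
import pytest

from puncta import (
    DetectionParams,
    ImageStack,
    Maximum2D,
    RenderParams,
    Spot,
    count_transcripts,
    detect_transcripts,
    find_maxima_2d,
    find_maxima_stack,
    gate_by_roi,
    make_scene,
    maxima_3d,
    otsu_min_intensity,
    rectangle_roi,
    render_stack,
    threshold_filter,
)


# ---------------------------------------------------------------------------
# independent oracles


def brute_maxima_2d(img, exclude_edges=True):
    """Exhaustive 8-neighborhood scan: strictly greater than every neighbor."""
    ny, nx = img.shape
    out = []
    for y in range(ny):
        for x in range(nx):
            if exclude_edges and (y in (0, ny - 1) or x in (0, nx - 1)):
                continue
            nbrs = [
                img[yy, xx]
                for yy in range(max(y - 1, 0), min(y + 2, ny))
                for xx in range(max(x - 1, 0), min(x + 2, nx))
                if (yy, xx) != (y, x)
            ]
            if all(img[y, x] > w for w in nbrs):
                out.append((y, x))
    return set(out)


def brute_spots_3d(maxima, voxels):
    """Exhaustive 26-neighborhood cube test + lexicographic tie-break."""
    nz, ny, nx = voxels.shape
    survivors = []
    for m in maxima:
        z, y, x = m.z, m.y, m.x
        nbrs = [
            voxels[zz, yy, xx]
            for zz in range(max(z - 1, 0), min(z + 2, nz))
            for yy in range(max(y - 1, 0), min(y + 2, ny))
            for xx in range(max(x - 1, 0), min(x + 2, nx))
            if (zz, yy, xx) != (z, y, x)
        ]
        v = voxels[z, y, x]
        if nbrs and all(v >= w for w in nbrs) and any(v > w for w in nbrs):
            survivors.append((z, y, x, v))
    survivors.sort()
    kept = []
    for z, y, x, v in survivors:
        if not any(
            kv == v and abs(kz - z) <= 1 and abs(ky - y) <= 1 and abs(kx - x) <= 1
            for kz, ky, kx, kv in kept
        ):
            kept.append((z, y, x, v))
    return {(z, y, x) for z, y, x, _ in kept}


# ---------------------------------------------------------------------------
# 2D maxima


class TestFindMaxima2D:
    def test_single_peak(self):
        img = np.zeros((5, 5))
        img[2, 2] = 10.0
        maxima = find_maxima_2d(img)
        assert [(m.y, m.x, m.intensity) for m in maxima] == [(2, 2, 10.0)]

    def test_constant_slice_has_no_maxima(self):
        assert find_maxima_2d(np.full((6, 6), 3.0)) == []

    def test_plateau_wider_than_one_pixel_yields_nothing(self):
        img = np.zeros((7, 7))
        img[3, 3] = img[3, 4] = 5.0
        assert find_maxima_2d(img) == []

    def test_matches_brute_force_on_random_slices(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            img = np.round(rng.uniform(0, 20, (16, 16)), 0)  # ties likely
            got = {(m.y, m.x) for m in find_maxima_2d(img)}
            assert got == brute_maxima_2d(img)

    def test_edge_maxima_kept_when_exclusion_off(self):
        img = np.zeros((5, 5))
        img[0, 2] = 9.0
        params = DetectionParams(exclude_edge_maxima=False)
        assert {(m.y, m.x) for m in find_maxima_2d(img, params)} == {(0, 2)}
        assert find_maxima_2d(img) == []  # default excludes edges

    def test_noise_tolerance_suppresses_shallow_maxima(self):
        # a ridge with two peaks and a saddle between them: the lower
        # peak (11) stands only 1 unit above the saddle (10)
        img = np.zeros((5, 7))
        img[2, 1], img[2, 2], img[2, 3] = 20.0, 10.0, 11.0
        lax = find_maxima_2d(img, DetectionParams(noise_tolerance=0.5,
                                                  exclude_edge_maxima=False))
        strict = find_maxima_2d(img, DetectionParams(noise_tolerance=5.0,
                                                     exclude_edge_maxima=False))
        assert {(m.y, m.x) for m in lax} == {(2, 1), (2, 3)}
        assert {(m.y, m.x) for m in strict} == {(2, 1)}

    def test_noise_tolerance_monotone(self):
        rng = np.random.default_rng(8)
        img = rng.uniform(0, 50, (24, 24))
        counts = [
            len(find_maxima_2d(img, DetectionParams(noise_tolerance=t)))
            for t in (0.0, 2.0, 5.0, 10.0, 20.0)
        ]
        assert counts == sorted(counts, reverse=True)


# ---------------------------------------------------------------------------
# gating and thresholding


def mk(z, y, x, v):
    return Maximum2D(z=z, y=y, x=x, intensity=v)


class TestGateAndThreshold:
    def test_centroid_kept_outside_removed(self):
        roi = rectangle_roi(10, 10, 20, 20)
        inside = mk(0, 15, 15, 5.0)
        outside = mk(0, 50, 50, 5.0)
        assert gate_by_roi([inside, outside], roi) == [inside]

    def test_gate_matches_raycasting_on_random_maxima(self):
        from test_roi import raycast_inside

        # off-lattice vertices so no integer pixel sits exactly on an edge
        # (the oracle tests the open interior, the gate includes the boundary)
        roi_verts = [(5.3, 10.7), (2.1, 30.3), (10.7, 48.1), (30.9, 52.3),
                     (48.3, 40.9), (50.1, 15.3), (30.7, 2.9)]
        from puncta import PolygonROI

        roi = PolygonROI(roi_verts)
        rng = np.random.default_rng(9)
        maxima = [mk(0, int(y), int(x), 1.0) for y, x in rng.uniform(0, 55, (1000, 2))]
        kept = {(m.y, m.x) for m in gate_by_roi(maxima, roi)}
        expected = {(m.y, m.x) for m in maxima if raycast_inside(roi_verts, m.y, m.x)}
        assert kept == expected

    def test_threshold_semantics(self):
        maxima = [mk(0, 0, i, v) for i, v in enumerate([1.0, 5.0, 10.0, 20.0])]
        assert threshold_filter(maxima, 0.0) == maxima
        assert threshold_filter(maxima, 100.0) == []
        assert [m.intensity for m in threshold_filter(maxima, 7.0)] == [10.0, 20.0]
        # boundary is inclusive
        assert [m.intensity for m in threshold_filter(maxima, 5.0)] == [5.0, 10.0, 20.0]

    def test_otsu_default_splits_bimodal_intensities(self):
        low = [mk(0, 0, i, v) for i, v in enumerate([1.0, 2.0, 1.5, 2.5])]
        high = [mk(0, 1, i, v) for i, v in enumerate([100.0, 110.0, 105.0])]
        thr = otsu_min_intensity(low + high)
        assert 2.5 < thr < 100.0
        assert otsu_min_intensity([]) == 0.0
        assert otsu_min_intensity([mk(0, 0, 0, 5.0)] * 3) == 0.0


# ---------------------------------------------------------------------------
# 3D promotion


class TestMaxima3D:
    def stack(self, voxels):
        return ImageStack(np.asarray(voxels, dtype=float))

    def test_single_bright_voxel(self):
        v = np.zeros((3, 5, 5))
        v[1, 2, 2] = 10.0
        st = self.stack(v)
        maxima = find_maxima_stack(st)
        spots = maxima_3d(maxima, st)
        assert [(s.z, s.y, s.x) for s in spots] == [(1, 2, 2)]

    def test_stacked_maxima_lower_one_loses(self):
        # same (y, x) in adjacent slices, values 10 (z=3) and 8 (z=4):
        # the 8 has a greater cube neighbor directly above -> not a spot
        v = np.zeros((9, 7, 7))
        v[3, 3, 3] = 10.0
        v[4, 3, 3] = 8.0
        st = self.stack(v)
        maxima = find_maxima_stack(st)
        assert {(m.z, m.y, m.x) for m in maxima} >= {(3, 3, 3), (4, 3, 3)}
        spots = maxima_3d(maxima, st)
        assert [(s.z, s.y, s.x) for s in spots] == [(3, 3, 3)]

    def test_exact_tie_in_adjacent_slices_keeps_lower_z(self):
        v = np.zeros((5, 7, 7))
        v[2, 3, 3] = 10.0
        v[3, 3, 3] = 10.0
        st = self.stack(v)
        maxima = [mk(2, 3, 3, 10.0), mk(3, 3, 3, 10.0)]
        spots = maxima_3d(maxima, st)
        assert [(s.z, s.y, s.x) for s in spots] == [(2, 3, 3)]

    def test_gt_rule_rejects_any_tie(self):
        v = np.zeros((5, 7, 7))
        v[2, 3, 3] = 10.0
        v[3, 3, 3] = 10.0
        st = self.stack(v)
        maxima = [mk(2, 3, 3, 10.0), mk(3, 3, 3, 10.0)]
        assert maxima_3d(maxima, st, cube_rule="gt") == []

    def test_matches_brute_force_on_random_stacks(self):
        rng = np.random.default_rng(10)
        for _ in range(100):
            v = np.round(rng.uniform(0, 30, (9, 16, 16)), 0)
            st = self.stack(v)
            maxima = find_maxima_stack(st)
            got = {(s.z, s.y, s.x) for s in maxima_3d(maxima, st)}
            assert got == brute_spots_3d(maxima, st.voxels)

    def test_out_of_bounds_maximum_rejected(self):
        st = self.stack(np.zeros((3, 5, 5)))
        with pytest.raises(ValueError):
            maxima_3d([mk(5, 2, 2, 1.0)], st)


# ---------------------------------------------------------------------------
# counting and the full pipeline


class TestPipeline:
    def test_count_transcripts(self):
        assert count_transcripts([]) == 0
        spots = [Spot(z=1, y=2, x=3, intensity=5.0), Spot(z=1, y=8, x=9, intensity=4.0)]
        assert count_transcripts(spots) == 2
        roi = rectangle_roi(0, 0, 5, 5)
        assert count_transcripts(spots, roi) == 1

    def test_recovers_well_separated_spots(self):
        roi = rectangle_roi(8, 8, 120, 120)
        scene = make_scene(
            50, 0, 0.0, roi, stack_shape=(56, 128, 128), seed=3,
            min_separation=4 * 1.3, separation_z_scale=1.3 / 2.0,
        )
        stack = render_stack(scene, RenderParams(seed=4))
        spots = detect_transcripts(stack, roi, DetectionParams())
        assert count_transcripts(spots) == 50
        det = np.array([[s.z, s.y, s.x] for s in spots], dtype=float)
        from scipy.spatial import cKDTree

        d, idx = cKDTree(scene.spots_a).query(det)
        assert (d < 3.0).all()
        assert len(set(idx)) == 50

    def test_raising_threshold_never_increases_count(self):
        roi = rectangle_roi(8, 8, 120, 120)
        scene = make_scene(30, 0, 0.0, roi, stack_shape=(20, 128, 128), seed=5,
                           min_separation=5.0, separation_z_scale=0.65)
        stack = render_stack(scene, RenderParams(seed=6))
        counts = []
        for thr in np.linspace(0, 400, 10):
            spots = detect_transcripts(stack, roi, DetectionParams(min_intensity=thr))
            counts.append(len(spots))
        assert counts == sorted(counts, reverse=True)

    def test_amplitudes_below_threshold_kill_recall(self):
        """Dim spots below the user threshold go undetected."""
        roi = rectangle_roi(8, 8, 120, 120)
        scene = make_scene(30, 0, 0.0, roi, stack_shape=(20, 128, 128), seed=5,
                           min_separation=5.0, separation_z_scale=0.65,
                           amplitude=2.0, amplitude_cv=0.0)  # ~noise level
        stack = render_stack(scene, RenderParams(seed=6))
        spots = detect_transcripts(stack, roi, DetectionParams(min_intensity=50.0))
        assert len(spots) == 0

    def test_filtering_improves_f1_at_low_snr(self):
        """rolling-ball + LoG beats raw-maxima detection on a dim noisy stack."""
        from scipy.spatial import cKDTree

        roi = rectangle_roi(8, 8, 120, 120)
        scene = make_scene(30, 0, 0.0, roi, stack_shape=(20, 128, 128), seed=11,
                           min_separation=6.0, separation_z_scale=0.65,
                           amplitude=18.0, amplitude_cv=0.0)
        params = RenderParams(seed=12, background_level=50.0,
                              background_gradient=0.3, read_noise_sd=3.0)
        stack = render_stack(scene, params)
        tree = cKDTree(scene.spots_a)

        def f1(spots):
            if not spots:
                return 0.0
            det = np.array([[s.z, s.y, s.x] for s in spots], dtype=float)
            d, idx = tree.query(det)
            tp = len(set(idx[d < 3.0]))
            prec, rec = tp / len(det), tp / len(scene.spots_a)
            return 0.0 if prec + rec == 0 else 2 * prec * rec / (prec + rec)

        filtered = detect_transcripts(stack, roi, DetectionParams())
        raw = detect_transcripts(stack, roi, DetectionParams(),
                                 rolling_ball_radius=None, log_sigma=None)
        assert f1(filtered) > f1(raw)
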