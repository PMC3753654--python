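"""Cylindrical two-channel 3D colocalization of detected spots.

Two spots detected in different channels of the same registered stack are
considered colocalized when the second lies within a cylinder centered on
the first: within ``z_reach`` slices axially and ``radius`` pixels
laterally (both bounds inclusive).  Distances are deliberately
anisotropic — lateral in pixels, axial in slice counts — matching how
such analyses are specified on the instrument rather than converting to
micrometers.

Two directional percentages summarize a pair set: the percentage of
channel-A spots with at least one partner, and likewise for channel B.
Percentages count distinct matched spots, never pair multiplicity, so
both are always in [0, 100].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .detect import Spot
from .roi import PolygonROI


@dataclass
class ColocParams:
    """Geometry and matching mode of the colocalization test.

    z_reach:
        Axial half-height of the cylinder in slices (4 by default: four
        slices above and four below count as colocalized).
    radius:
        Lateral radius in pixels (5 by default).
    mode:
        ``"any-partner"`` (default): a spot is colocalized if at least one
        spot of the other channel lies in its cylinder.  ``"one-to-one"``:
        a greedy nearest-first matching subset of those pairs.
    offset:
        Optional constant chromatic-shift correction ``(dz, dy, dx)``
        added to channel-B coordinates before comparison.
    """

    z_reach: int = 4
    radius: float = 5.0
    mode: str = "any-partner"
    offset: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.z_reach < 0 or self.radius < 0:
            raise ValueError("z_reach and radius must be >= 0")
        if self.mode not in ("any-partner", "one-to-one"):
            raise ValueError("mode must be 'any-partner' or 'one-to-one'")


@dataclass(frozen=True)
class ColocResult:
    """Pair set plus the two directional colocalization percentages."""

    pairs: frozenset
    n_a: int
    n_b: int
    pct_a: float
    pct_b: float

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


def _coords(spots) -> np.ndarray:
    """(n, 3) float array of (z, y, x) from Spot lists or array-likes."""
    if len(spots) == 0:
        return np.empty((0, 3), dtype=float)
    if isinstance(spots[0], Spot):
        return np.array([[s.z, s.y, s.x] for s in spots], dtype=float)
    arr = np.asarray(spots, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ValueError("spot coordinates must be (n, 3) (z, y, x)")
    return arr


def in_cylinder(dz, dy, dx, params: ColocParams) -> np.ndarray:
    """Boundary-inclusive cylinder membership for displacement(s) (dz, dy, dx)."""
    dz = np.abs(np.asarray(dz, dtype=float))
    lat2 = np.asarray(dy, dtype=float) ** 2 + np.asarray(dx, dtype=float) ** 2
    return (dz <= params.z_reach) & (lat2 <= params.radius**2)


def find_pairs(spots_a, spots_b, params: ColocParams | None = None) -> set[tuple[int, int]]:
    """All colocalized index pairs ``(i_a, i_b)``.

    A pair qualifies iff ``|z_a - z_b| <= z_reach`` and the lateral
    Euclidean distance is ``<= radius`` (both inclusive).  In one-to-one
    mode a greedy matching is returned instead: candidate pairs sorted by
    (lateral distance, |dz|, indices), each spot used at most once.
    """
    params = params or ColocParams()
    A = _coords(spots_a)
    B = _coords(spots_b) + np.asarray(params.offset, dtype=float)
    if len(A) == 0 or len(B) == 0:
        return set()
    tree = cKDTree(B[:, 1:])  # lateral (y, x) only
    candidates: list[tuple[float, float, int, int]] = []
    pairs: set[tuple[int, int]] = set()
    for i, a in enumerate(A):
        for j in tree.query_ball_point(a[1:], r=params.radius):
            if abs(a[0] - B[j, 0]) <= params.z_reach:
                if params.mode == "one-to-one":
                    lat = math.hypot(a[1] - B[j, 1], a[2] - B[j, 2])
                    candidates.append((lat, abs(a[0] - B[j, 0]), i, j))
                else:
                    pairs.add((i, int(j)))
    if params.mode == "one-to-one":
        used_a: set[int] = set()
        used_b: set[int] = set()
        for _, _, i, j in sorted(candidates):
            if i not in used_a and j not in used_b:
                pairs.add((i, j))
                used_a.add(i)
                used_b.add(j)
    return pairs


def coloc_percentages(pairs, n_a: int, n_b: int) -> ColocResult:
    """Directional percentages over distinct matched spots.

    ``pct_a`` is 100 x (number of distinct A spots appearing in a pair)
    / ``n_a``; ``pct_b`` analogously.  Undefined (raises) when either
    channel has no spots.
    """
    if n_a < 1 or n_b < 1:
        raise ValueError("colocalization percentages are undefined when a channel has no spots")
    matched_a = {i for i, _ in pairs}
    matched_b = {j for _, j in pairs}
    return ColocResult(
        pairs=frozenset(pairs),
        n_a=n_a,
        n_b=n_b,
        pct_a=100.0 * len(matched_a) / n_a,
        pct_b=100.0 * len(matched_b) / n_b,
    )


def colocalize(spots_a, spots_b, params: ColocParams | None = None) -> ColocResult:
    """find_pairs + coloc_percentages in one call."""
    A = _coords(spots_a)
    B = _coords(spots_b)
    return coloc_percentages(find_pairs(A, B, params), len(A), len(B))


def coloc_per_cell(
    spots_a: Sequence[Spot],
    spots_b: Sequence[Spot],
    rois: Sequence[PolygonROI],
    params: ColocParams | None = None,
) -> tuple[list[ColocResult | None], dict]:
    """Colocalization computed independently within each cell ROI.

    Spots are gated by each ROI (boundary inclusive, on (y, x)); cells
    with zero spots in either channel yield ``None`` and are excluded
    from the summary.  Returns per-cell results (aligned with ``rois``)
    and a summary dict with the mean and SD (ddof=1) of both percentages
    across defined cells.
    """
    params = params or ColocParams()
    results: list[ColocResult | None] = []
    for roi in rois:
        a_in = [s for s in spots_a if roi.contains_point(s.y, s.x)]
        b_in = [s for s in spots_b if roi.contains_point(s.y, s.x)]
        if len(a_in) == 0 or len(b_in) == 0:
            results.append(None)
            continue
        results.append(colocalize(a_in, b_in, params))
    defined = [r for r in results if r is not None]
    summary: dict = {"n_cells": len(rois), "n_defined": len(defined)}
    for key in ("pct_a", "pct_b"):
        vals = np.array([getattr(r, key) for r in defined], dtype=float)
        summary[f"mean_{key}"] = float(vals.mean()) if len(vals) else float("nan")
        summary[f"sd_{key}"] = float(vals.std(ddof=1)) if len(vals) > 1 else float("nan")
    return results, summary
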