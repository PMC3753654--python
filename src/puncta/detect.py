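"""Single-transcript spot detection in filtered z-stacks.

The procedure mirrors the ImageJ/MATLAB workflow used for counting single
RNA transcripts tagged by dozens of hybridized probes:

1. find all 2D local maxima in every slice of the (filtered) stack
   ("Find Maxima" semantics: noise tolerance, edge-maxima exclusion);
2. gate the maxima by a hand-drawn cell ROI taken from the
   maximum-intensity projection;
3. keep maxima above a user-specified minimum intensity threshold;
4. promote a 2D maximum to a 3D maximum iff its intensity dominates the
   3x3x3 cube centered on it (9 voxels in the slice above, the 8 in-slice
   neighbors, and 9 in the slice below).

Each surviving 3D local maximum is counted as one RNA transcript.

Plateau rule: a pixel is a 2D maximum iff it is strictly greater than
every in-bounds 8-neighbor, so flat plateaus (of any size, including a
constant slice) yield no maxima at noise tolerance 0 — deterministic and
directly oracle-checkable.  The cube test instead uses a
>=-all/at-least-one-strict rule by default
(``cube_rule="ge"``); a strictly-greater-than-all variant is available as
``cube_rule="gt"``.  When two cube-test survivors in adjacent slices tie
exactly in intensity within each other's cube, only the one with the
lexicographically smallest ``(z, y, x)`` is kept, so a single transcript
is never counted twice.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .preprocess import ImageStack, log_filter, max_project, rolling_ball_subtract
from .roi import PolygonROI

_RING = np.ones((3, 3), dtype=bool)
_RING[1, 1] = False


@dataclass(frozen=True)
class Maximum2D:
    """An in-slice local maximum: 0-based ``(z, y, x)`` plus intensity."""

    z: int
    y: int
    x: int
    intensity: float


@dataclass(frozen=True)
class Spot:
    """A confirmed 3D local maximum — one RNA transcript."""

    z: int
    y: int
    x: int
    intensity: float
    channel: str = ""


@dataclass
class DetectionParams:
    """Knobs of the maxima-finding step.

    noise_tolerance:
        A 2D maximum is suppressed when its prominence — height above the
        highest saddle connecting it to a higher maximum — is below this
        value.  At the default of 0 this is a no-op beyond the strict
        plateau rule.
    exclude_edge_maxima:
        Drop maxima on the image border (on by default).
    min_intensity:
        User-specified minimum intensity for a maximum to be considered.
        ``None`` selects an automatic Otsu threshold over the detected
        maxima intensities of the stack.
    cube_rule:
        ``"ge"`` (default): promoted iff >= all present cube neighbors and
        > at least one.  ``"gt"``: strictly greater than all present
        neighbors.
    """

    noise_tolerance: float = 0.0
    exclude_edge_maxima: bool = True
    min_intensity: float | None = None
    cube_rule: str = "ge"

    def __post_init__(self) -> None:
        if self.noise_tolerance < 0:
            raise ValueError("noise_tolerance must be >= 0")
        if self.min_intensity is not None and self.min_intensity < 0:
            raise ValueError("min_intensity must be >= 0")
        if self.cube_rule not in ("ge", "gt"):
            raise ValueError("cube_rule must be 'ge' or 'gt'")


# ---------------------------------------------------------------------------
# 2D maxima


def _suppress_by_prominence(img: np.ndarray, ys, xs, tol: float):
    """Drop maxima whose prominence is below ``tol``.

    From each candidate, flood through pixels with value > v - tol
    (8-connectivity); reaching any strictly higher pixel means the
    candidate sits less than ``tol`` above a saddle to a greater maximum.
    """
    ny, nx = img.shape
    keep_y, keep_x = [], []
    for y0, x0 in zip(ys, xs):
        v = img[y0, x0]
        lo = v - tol
        seen = {(y0, x0)}
        queue = deque([(y0, x0)])
        prominent = True
        while queue and prominent:
            y, x = queue.popleft()
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    if dy == 0 and dx == 0:
                        continue
                    yy, xx = y + dy, x + dx
                    if not (0 <= yy < ny and 0 <= xx < nx) or (yy, xx) in seen:
                        continue
                    w = img[yy, xx]
                    if w > v:
                        prominent = False
                        break
                    if w > lo:
                        seen.add((yy, xx))
                        queue.append((yy, xx))
                if not prominent:
                    break
        if prominent:
            keep_y.append(y0)
            keep_x.append(x0)
    return np.array(keep_y, dtype=int), np.array(keep_x, dtype=int)


def find_maxima_2d(
    slice_image: np.ndarray,
    params: DetectionParams | None = None,
    z: int = 0,
) -> list[Maximum2D]:
    """Find in-slice local maxima with "Find Maxima"-style semantics.

    A pixel qualifies when it is strictly greater than each of its
    (in-bounds) 8 neighbors; flat plateaus produce no maxima.  Border
    pixels are excluded when ``params.exclude_edge_maxima`` is set.
    ``params.min_intensity`` is *not* applied here — thresholding is a
    separate step.
    """
    params = params or DetectionParams()
    img = np.asarray(slice_image, dtype=float)
    if img.ndim != 2:
        raise ValueError("slice_image must be 2D")
    nbr_max = ndimage.maximum_filter(img, footprint=_RING, mode="constant", cval=-np.inf)
    cand = img > nbr_max
    if params.exclude_edge_maxima:
        cand[0, :] = cand[-1, :] = False
        cand[:, 0] = cand[:, -1] = False
    ys, xs = np.nonzero(cand)
    if params.noise_tolerance > 0 and len(ys):
        ys, xs = _suppress_by_prominence(img, ys, xs, params.noise_tolerance)
    return [Maximum2D(z=z, y=int(y), x=int(x), intensity=float(img[y, x])) for y, x in zip(ys, xs)]


def find_maxima_stack(stack: ImageStack, params: DetectionParams | None = None) -> list[Maximum2D]:
    """Run :func:`find_maxima_2d` on every slice of a stack."""
    out: list[Maximum2D] = []
    for z in range(stack.shape[0]):
        out.extend(find_maxima_2d(stack.voxels[z], params, z=z))
    return out


# ---------------------------------------------------------------------------
# gating and thresholding


def gate_by_roi(maxima: Sequence[Maximum2D], roi: PolygonROI) -> list[Maximum2D]:
    """Keep maxima whose (y, x) lies inside the ROI (boundary inclusive)."""
    if not maxima:
        return []
    ys = np.array([m.y for m in maxima], dtype=float)
    xs = np.array([m.x for m in maxima], dtype=float)
    inside = roi.contains_points(ys, xs)
    return [m for m, ok in zip(maxima, inside) if ok]


def threshold_filter(maxima: Sequence[Maximum2D], min_intensity: float) -> list[Maximum2D]:
    """Keep maxima with intensity >= ``min_intensity``."""
    return [m for m in maxima if m.intensity >= min_intensity]


def otsu_min_intensity(maxima: Sequence[Maximum2D]) -> float:
    """Automatic default intensity threshold: exact Otsu on the maxima intensities.

    The between-class variance is evaluated at every split of the sorted
    intensities (no histogram binning) and the threshold is placed midway
    between the two classes.  Falls back to 0 when there are too few
    distinct intensities for a bimodal split.
    """
    vals = np.sort(np.array([m.intensity for m in maxima], dtype=float))
    n = len(vals)
    if n < 2 or np.ptp(vals) == 0:
        return 0.0
    w1 = np.arange(1, n, dtype=float)
    cum = np.cumsum(vals)
    mu1 = cum[:-1] / w1
    mu2 = (cum[-1] - cum[:-1]) / (n - w1)
    between = w1 * (n - w1) * (mu1 - mu2) ** 2
    k = int(np.argmax(between))
    return float(0.5 * (vals[k] + vals[k + 1]))


# ---------------------------------------------------------------------------
# 3D promotion


def maxima_3d(
    maxima: Sequence[Maximum2D],
    stack: ImageStack,
    cube_rule: str = "ge",
    channel: str | None = None,
) -> list[Spot]:
    """Promote 2D maxima to 3D local maxima via the 3x3x3 cube test.

    A 2D maximum at ``(z, y, x)`` becomes a :class:`Spot` iff its voxel
    intensity dominates every one of the up-to-26 cube neighbors present
    in the stack (slices missing above the top or below the bottom simply
    contribute no comparisons).  Under the default ``"ge"`` rule it must
    be >= all neighbors and strictly greater than at least one; under
    ``"gt"`` it must exceed them all strictly.  Exact-intensity ties
    between surviving candidates lying within each other's cube are
    resolved by keeping the lexicographically smallest ``(z, y, x)``.
    """
    if cube_rule not in ("ge", "gt"):
        raise ValueError("cube_rule must be 'ge' or 'gt'")
    V = stack.voxels
    nz, ny, nx = V.shape
    chan = channel if channel is not None else stack.channel
    survivors: list[Maximum2D] = []
    for m in maxima:
        z, y, x = m.z, m.y, m.x
        if not (0 <= z < nz and 0 <= y < ny and 0 <= x < nx):
            raise ValueError(f"maximum {(z, y, x)} outside stack of shape {V.shape}")
        cube = V[max(z - 1, 0) : z + 2, max(y - 1, 0) : y + 2, max(x - 1, 0) : x + 2]
        v = V[z, y, x]
        # neighbors = cube minus the center voxel
        total = cube.size
        if total <= 1:
            continue
        cmax = cube.max()
        if cube_rule == "gt":
            # strict: center must be the unique maximum of the cube
            ok = v >= cmax and np.count_nonzero(cube == v) == 1
        else:
            ok = v >= cmax and cube.min() < v
        if ok:
            survivors.append(m)
    # tie-break: equal-intensity survivors within each other's cube
    survivors.sort(key=lambda m: (m.z, m.y, m.x))
    kept: list[Maximum2D] = []
    for m in survivors:
        dup = any(
            k.intensity == m.intensity
            and abs(k.z - m.z) <= 1
            and abs(k.y - m.y) <= 1
            and abs(k.x - m.x) <= 1
            for k in kept
        )
        if not dup:
            kept.append(m)
    return [Spot(z=m.z, y=m.y, x=m.x, intensity=float(V[m.z, m.y, m.x]), channel=chan) for m in kept]


def count_transcripts(spots: Sequence[Spot], roi: PolygonROI | None = None) -> int:
    """Number of detected transcripts (= number of 3D maxima).

    ``roi`` may be passed for a final safety gate; spots are normally
    ROI-gated upstream, in which case it is redundant.
    """
    if roi is not None:
        spots = [s for s in spots if roi.contains_point(s.y, s.x)]
    return len(spots)


# ---------------------------------------------------------------------------
# full pipeline


def detect_transcripts(
    stack: ImageStack,
    roi: PolygonROI | None = None,
    params: DetectionParams | None = None,
    rolling_ball_radius: int | None = 5,
    log_sigma: float | None = 1.5,
    log_mode: str = "2d",
) -> list[Spot]:
    """Full transcript identification chain on a raw stack.

    rolling-ball subtraction -> LoG filter -> per-slice 2D maxima -> ROI
    gate -> intensity threshold -> 3x3x3 cube promotion.  Set
    ``rolling_ball_radius`` or ``log_sigma`` to ``None`` to skip that
    stage (e.g. for pre-filtered input).
    """
    params = params or DetectionParams()
    filtered = stack
    if rolling_ball_radius is not None:
        filtered = rolling_ball_subtract(filtered, rolling_ball_radius)
    if log_sigma is not None:
        filtered = log_filter(filtered, log_sigma, mode=log_mode)
    maxima = find_maxima_stack(filtered, params)
    if roi is not None:
        maxima = gate_by_roi(maxima, roi)
    thr = params.min_intensity if params.min_intensity is not None else otsu_min_intensity(maxima)
    maxima = threshold_filter(maxima, thr)
    return maxima_3d(maxima, filtered, cube_rule=params.cube_rule)


# ---------------------------------------------------------------------------
# spot tables


def spots_to_frame(spots: Sequence[Spot], cell_id: int | str = 0) -> pd.DataFrame:
    """Tabulate spots with columns cell_id, channel, z, y, x, intensity."""
    return pd.DataFrame(
        {
            "cell_id": [cell_id] * len(spots),
            "channel": [s.channel for s in spots],
            "z": [s.z for s in spots],
            "y": [s.y for s in spots],
            "x": [s.x for s in spots],
            "intensity": [s.intensity for s in spots],
        }
    )


def frame_to_spots(df: pd.DataFrame) -> list[Spot]:
    # coordinates are integral for detected spots but kept as written, so
    # ground-truth (sub-voxel) tables round-trip losslessly too
    return [
        Spot(z=r.z, y=r.y, x=r.x, intensity=float(r.intensity), channel=str(r.channel))
        for r in df.itertuples()
    ]
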