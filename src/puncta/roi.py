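"""Polygonal cell regions of interest.

Cell outlines are hand-drawn-style simple polygons in pixel coordinates.
Vertices are stored ``(y, x)`` (row, column), matching array indexing; the
polygon boundary counts as *inside* everywhere in this package, because
hand-drawn outlines are generous and consistency matters more than the
choice of convention.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import shapely
from shapely.geometry import Polygon


@dataclass(frozen=True)
class PolygonROI:
    """A simple (non-self-intersecting) polygon in ``(y, x)`` pixel coordinates.

    Parameters
    ----------
    vertices:
        Ordered sequence of ``(y, x)`` vertex coordinates; at least three,
        forming a simple polygon with positive area.

    Raises
    ------
    ValueError
        If fewer than three vertices are given, or the polygon is
        degenerate (zero area) or self-intersecting.
    """

    vertices: tuple[tuple[float, float], ...]
    _poly: Polygon = field(init=False, repr=False, compare=False)

    def __init__(self, vertices: Iterable[Sequence[float]]):
        verts = tuple((float(y), float(x)) for y, x in vertices)
        if len(verts) < 3:
            raise ValueError("a polygon ROI needs at least 3 vertices")
        # shapely works in (x, y); swap on the way in.
        poly = Polygon([(x, y) for y, x in verts])
        if not poly.is_valid or poly.area <= 0.0:
            raise ValueError("degenerate or self-intersecting polygon ROI")
        object.__setattr__(self, "vertices", verts)
        object.__setattr__(self, "_poly", poly)

    # ------------------------------------------------------------------ geometry

    @property
    def area(self) -> float:
        return float(self._poly.area)

    @property
    def centroid(self) -> tuple[float, float]:
        c = self._poly.centroid
        return (float(c.y), float(c.x))

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(ymin, xmin, ymax, xmax)."""
        xmin, ymin, xmax, ymax = self._poly.bounds
        return (float(ymin), float(xmin), float(ymax), float(xmax))

    def contains_points(self, ys, xs) -> np.ndarray:
        """Boundary-inclusive membership test for points ``(ys, xs)``.

        Returns a boolean array of the broadcast shape of ``ys``/``xs``.
        """
        ys = np.asarray(ys, dtype=float)
        xs = np.asarray(xs, dtype=float)
        ys_b, xs_b = np.broadcast_arrays(ys, xs)
        # intersects == point in the closure of the polygon (boundary inclusive)
        return shapely.intersects_xy(self._poly, xs_b.ravel(), ys_b.ravel()).reshape(
            ys_b.shape
        )

    def contains_point(self, y: float, x: float) -> bool:
        return bool(self.contains_points(np.array([y]), np.array([x]))[0])

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        """Rasterize to a boolean mask over pixel centers of an image of ``shape``.

        A pixel ``(i, j)`` is in the mask iff its center ``(y=i, x=j)`` lies
        inside or on the boundary of the polygon.
        """
        ny, nx = shape
        ymin, xmin, ymax, xmax = self.bounds
        i0 = max(int(np.floor(ymin)), 0)
        i1 = min(int(np.ceil(ymax)) + 1, ny)
        j0 = max(int(np.floor(xmin)), 0)
        j1 = min(int(np.ceil(xmax)) + 1, nx)
        out = np.zeros(shape, dtype=bool)
        if i0 >= i1 or j0 >= j1:
            return out
        ys, xs = np.mgrid[i0:i1, j0:j1]
        out[i0:i1, j0:j1] = self.contains_points(ys, xs)
        return out

    def overlaps(self, other: "PolygonROI", tol: float = 1e-9) -> bool:
        """True if the two polygon interiors overlap by more than ``tol`` area."""
        return self._poly.intersection(other._poly).area > tol

    # ------------------------------------------------------------------ serialization

    def to_dict(self) -> dict:
        return {"vertices": [[y, x] for y, x in self.vertices]}

    @classmethod
    def from_dict(cls, d: dict) -> "PolygonROI":
        return cls(d["vertices"])

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_json(cls, path) -> "PolygonROI":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def rectangle_roi(ymin: float, xmin: float, ymax: float, xmax: float) -> PolygonROI:
    """Convenience axis-aligned rectangular ROI."""
    return PolygonROI(
        [(ymin, xmin), (ymin, xmax), (ymax, xmax), (ymax, xmin)]
    )


def load_rois(path) -> list[PolygonROI]:
    """Read one or many ROIs from JSON.

    Accepts ``{"vertices": [...]}``, ``[{"vertices": ...}, ...]`` or
    ``{"cells": [{"vertices": ...}, ...]}``.
    """
    with open(path) as fh:
        data = json.load(fh)
    if isinstance(data, dict) and "vertices" in data:
        return [PolygonROI.from_dict(data)]
    if isinstance(data, dict) and "cells" in data:
        data = data["cells"]
    return [PolygonROI.from_dict(d) for d in data]


def save_rois(rois: Sequence[PolygonROI], path) -> None:
    with open(path, "w") as fh:
        json.dump({"cells": [r.to_dict() for r in rois]}, fh)
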