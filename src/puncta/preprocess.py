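"""Z-stack container and pre-detection filtering.

The operations here mirror the classical ImageJ-style preparation of
fluorescence z-stacks before single-molecule spot detection: per-slice
rolling-ball background subtraction, a (negated) Laplacian-of-Gaussian
spot-enhancing filter, and maximum-intensity projection for drawing cell
outlines.

All filter responses are clamped at zero so downstream intensity
thresholds operate on a non-negative scale.  The absolute normalization of
the LoG response is arbitrary; only the relative heights of its maxima
matter for detection.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import tifffile
from scipy import ndimage
from skimage.restoration import rolling_ball as _sk_rolling_ball


@dataclass
class ImageStack:
    """A 3D fluorescence volume indexed ``(z, y, x)``.

    ``z = 0`` is the first acquired slice.  Negative voxel values are
    clamped to zero on construction; non-finite values are rejected.

    Parameters
    ----------
    voxels:
        3D array of intensities, shape ``(nz, ny, nx)``.
    pixel_size_xy:
        Lateral pixel size in micrometers.
    z_step:
        Axial spacing between slices in micrometers (0.2 by default, a
        typical fine z-sampling for single-transcript stacks).
    channel:
        Free-form channel label (e.g. ``"CF640R"``, ``"TMR"``).
    """

    voxels: np.ndarray
    pixel_size_xy: float = 0.16
    z_step: float = 0.2
    channel: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.voxels, dtype=float)
        if v.ndim != 3 or min(v.shape) < 1:
            raise ValueError("voxels must be a 3D (z, y, x) array")
        if not np.all(np.isfinite(v)):
            raise ValueError("voxel intensities must be finite")
        self.voxels = np.clip(v, 0.0, None)
        if self.pixel_size_xy <= 0 or self.z_step <= 0:
            raise ValueError("pixel_size_xy and z_step must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    def with_voxels(self, voxels: np.ndarray) -> "ImageStack":
        return replace(self, voxels=voxels)

    # ------------------------------------------------------------------ I/O

    def to_tiff(self, path) -> None:
        """Write as a multi-page grayscale TIFF (float32)."""
        tifffile.imwrite(path, self.voxels.astype(np.float32))

    @classmethod
    def from_tiff(
        cls,
        path,
        pixel_size_xy: float = 0.16,
        z_step: float = 0.2,
        channel: str = "",
    ) -> "ImageStack":
        v = tifffile.imread(path)
        if v.ndim == 2:
            v = v[None]
        return cls(v.astype(float), pixel_size_xy=pixel_size_xy, z_step=z_step, channel=channel)


def rolling_ball_subtract(stack: ImageStack, radius: int = 5) -> ImageStack:
    """Rolling-ball background subtraction, applied independently per z-slice.

    The smooth background under each slice is estimated by rolling a ball
    of the given radius beneath the intensity surface (grayscale opening
    with a ball structuring element) and subtracted; the result is clamped
    at zero, so the output never exceeds the input anywhere.

    Parameters
    ----------
    radius:
        Ball radius in pixels (>= 1).  Must fit inside a slice.
    """
    if radius < 1:
        raise ValueError("rolling-ball radius must be >= 1")
    nz, ny, nx = stack.shape
    if 2 * radius + 1 > min(ny, nx):
        raise ValueError(
            f"rolling-ball radius {radius} too large for slice of shape {(ny, nx)}"
        )
    out = np.empty_like(stack.voxels)
    for z in range(nz):
        bg = _sk_rolling_ball(stack.voxels[z], radius=radius)
        out[z] = stack.voxels[z] - bg
    return stack.with_voxels(np.clip(out, 0.0, None))


def log_filter(stack: ImageStack, sigma: float, mode: str = "2d") -> ImageStack:
    """Spot-enhancing (negated) Laplacian-of-Gaussian filter.

    Bright blob-like structures of scale ~``sigma`` become positive peaks
    centered on the blob; the response is scale-normalized (multiplied by
    ``sigma**2``) and clamped at zero.

    Parameters
    ----------
    sigma:
        Gaussian scale in lateral voxels (> 0).
    mode:
        ``"2d"`` (default) filters each slice independently with an
        isotropic 2D LoG; ``"3d"`` applies a true 3D LoG whose axial sigma
        is scaled by ``pixel_size_xy / z_step`` so the physical scale is
        isotropic in micrometers.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    # truncate=8 keeps the discrete kernel's DC leakage negligible, so a
    # flat region maps to (numerically) zero response
    if mode == "2d":
        out = np.empty_like(stack.voxels)
        for z in range(stack.shape[0]):
            out[z] = -ndimage.gaussian_laplace(stack.voxels[z], sigma=sigma, truncate=8.0)
    elif mode == "3d":
        sigma_z = sigma * stack.pixel_size_xy / stack.z_step
        out = -ndimage.gaussian_laplace(
            stack.voxels, sigma=(sigma_z, sigma, sigma), truncate=8.0
        )
    else:
        raise ValueError(f"unknown LoG mode {mode!r}; use '2d' or '3d'")
    return stack.with_voxels(np.clip(out * sigma**2, 0.0, None))


def max_project(stack: ImageStack) -> np.ndarray:
    """Maximum-intensity projection over z: per-(y, x) maximum."""
    return stack.voxels.max(axis=0)
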