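"""Per-cell fluorescence quantification for ratiometric hairpin probes.

A ratiometric bimolecular beacon (RBMB) carries a quenched reporter dye
and an always-on reference dye.  In a cell the reporter channel sums
three contributions: cellular autofluorescence, residual fluorescence of
unopened (target-free) probe, and the hybridization-driven enhancement
that actually reports RNA.  This module isolates the enhancement:

* autofluorescence in the reporter channel is predicted from the TMR
  channel via a linear model fitted on probe-negative cells;
* unopened-probe background is the reference-channel integrated density
  scaled by ``R_CLOSED``, the reporter:reference ratio of the probe
  without target (measured on emulsion droplets of free probe);
* enhancement = (reporter ID - autofluorescence) - R_CLOSED x reference ID,

where ID is integrated density, the sum of pixel intensities inside a
cell ROI.  Enhancement per cell can then be regressed against the
transcript count from high-magnification z-stacks; a linear relation
with high Pearson correlation indicates the probe signal scales with RNA
copy number.

The autofluorescence subtraction happens *inside* the enhancement
formula by default; ``af_mode="none"`` reproduces the raw variant
(reporter ID - R_CLOSED x reference ID) for data whose reporter images
were autofluorescence-corrected beforehand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .roi import PolygonROI


@dataclass
class CellQuant:
    """Per-cell quantities; integrated densities are raw unless noted."""

    rep_id: float
    ref_id: float
    tmr_id: float
    af_rep: float | None = None
    r_closed: float | None = None
    enhancement: float | None = None
    n_transcripts: int | None = None
    cell_id: int | str = 0

    def __post_init__(self) -> None:
        for name in ("rep_id", "ref_id", "tmr_id"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.r_closed is not None and self.r_closed < 0:
            raise ValueError("r_closed must be >= 0")


@dataclass(frozen=True)
class AutofluorModel:
    """Linear reporter-vs-TMR autofluorescence model from probe-negative cells."""

    slope: float
    intercept: float
    residual_sd: float
    n_cells: int

    def predict(self, tmr_id) -> np.ndarray | float:
        return self.slope * np.asarray(tmr_id, dtype=float) + self.intercept


def integrated_density(image: np.ndarray, roi: PolygonROI) -> float:
    """Sum of pixel intensities inside the ROI (boundary inclusive).

    The image should already be background-subtracted.  Raises if the ROI
    covers no pixel of the image.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("image must be 2D")
    mask = roi.mask(image.shape)
    if not mask.any():
        raise ValueError("ROI lies outside the image (empty pixel mask)")
    return float(image[mask].sum())


def fit_autofluorescence(negative_cells: Sequence[tuple[float, float]]) -> AutofluorModel:
    """Least-squares line rep_id = slope * tmr_id + intercept on probe-negative cells.

    ``negative_cells`` is a sequence of ``(rep_id, tmr_id)`` pairs from
    cells without probe, so their reporter signal is pure
    autofluorescence.  Requires >= 3 cells and non-degenerate TMR values.
    """
    arr = np.asarray(negative_cells, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValueError("need >= 3 (rep_id, tmr_id) pairs")
    rep, tmr = arr[:, 0], arr[:, 1]
    if np.ptp(tmr) == 0:
        raise ValueError("degenerate fit: all TMR integrated densities identical")
    slope, intercept = np.polyfit(tmr, rep, 1)
    resid = rep - (slope * tmr + intercept)
    dof = max(len(rep) - 2, 1)
    return AutofluorModel(
        slope=float(slope),
        intercept=float(intercept),
        residual_sd=float(np.sqrt((resid**2).sum() / dof)),
        n_cells=len(rep),
    )


def estimate_r_closed(
    droplets: Sequence[tuple[np.ndarray, np.ndarray, PolygonROI]],
    rep_background: float = 0.0,
    ref_background: float = 0.0,
) -> float:
    """R_CLOSED from emulsion-droplet image pairs of target-free probe.

    For each droplet, the background-subtracted *mean* reporter intensity
    inside the droplet ROI is divided by the mean reference intensity
    (means, not integrated densities, so droplet size cancels); the
    per-droplet ratios are averaged.
    """
    if len(droplets) < 1:
        raise ValueError("need at least one droplet")
    ratios = []
    for rep_img, ref_img, roi in droplets:
        mask = roi.mask(np.asarray(rep_img).shape)
        if not mask.any():
            raise ValueError("droplet ROI lies outside the image")
        rep_mean = float(np.asarray(rep_img, dtype=float)[mask].mean()) - rep_background
        ref_mean = float(np.asarray(ref_img, dtype=float)[mask].mean()) - ref_background
        if ref_mean == 0:
            raise ValueError("zero reference intensity in droplet")
        ratios.append(rep_mean / ref_mean)
    return float(np.mean(ratios))


def enhancement(cell: CellQuant, af_mode: str = "subtract") -> float:
    """Hybridization-attributable reporter signal of one cell.

    ``subtract`` (default): (rep_id - af_rep) - r_closed * ref_id.
    ``none``: rep_id - r_closed * ref_id (for pre-corrected reporter images).
    """
    if cell.r_closed is None:
        raise ValueError("cell.r_closed is required")
    if af_mode == "subtract":
        if cell.af_rep is None:
            raise ValueError("cell.af_rep is required in af_mode='subtract'")
        return (cell.rep_id - cell.af_rep) - cell.r_closed * cell.ref_id
    if af_mode == "none":
        return cell.rep_id - cell.r_closed * cell.ref_id
    raise ValueError("af_mode must be 'subtract' or 'none'")


@dataclass(frozen=True)
class CopyNumberFit:
    slope: float
    intercept: float
    r: float
    n_cells: int


def correlate_copy_number(cells: Sequence[CellQuant]) -> CopyNumberFit:
    """Least-squares line and Pearson r of enhancement vs transcript count."""
    usable = [c for c in cells if c.enhancement is not None and c.n_transcripts is not None]
    if len(usable) < 3:
        raise ValueError("need >= 3 cells with enhancement and transcript count")
    counts = np.array([c.n_transcripts for c in usable], dtype=float)
    enh = np.array([c.enhancement for c in usable], dtype=float)
    if np.ptp(counts) == 0:
        raise ValueError("zero variance in transcript counts")
    fit = stats.linregress(counts, enh)
    return CopyNumberFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r=float(fit.rvalue),
        n_cells=len(usable),
    )


def quantify_cells(
    rep_image: np.ndarray,
    ref_image: np.ndarray,
    tmr_image: np.ndarray,
    rois: Sequence[PolygonROI],
    af_model: AutofluorModel,
    r_closed: float,
    n_transcripts: Sequence[int] | None = None,
    af_mode: str = "subtract",
) -> list[CellQuant]:
    """Measure and correct every cell of a field in one pass."""
    cells: list[CellQuant] = []
    for k, roi in enumerate(rois):
        rep = integrated_density(rep_image, roi)
        ref = integrated_density(ref_image, roi)
        tmr = integrated_density(tmr_image, roi)
        cell = CellQuant(
            rep_id=rep,
            ref_id=ref,
            tmr_id=tmr,
            af_rep=float(af_model.predict(tmr)),
            r_closed=r_closed,
            n_transcripts=None if n_transcripts is None else int(n_transcripts[k]),
            cell_id=k,
        )
        cell.enhancement = enhancement(cell, af_mode=af_mode)
        cells.append(cell)
    return cells


def cells_to_frame(cells: Sequence[CellQuant]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cell_id": [c.cell_id for c in cells],
            "rep_id": [c.rep_id for c in cells],
            "ref_id": [c.ref_id for c in cells],
            "tmr_id": [c.tmr_id for c in cells],
            "af_rep": [c.af_rep for c in cells],
            "enhancement": [c.enhancement for c in cells],
            "n_transcripts": [c.n_transcripts for c in cells],
        }
    )
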