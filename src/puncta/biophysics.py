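"""Melting-curve and hybridization-kinetics analysis for hairpin probes.

Melting profiles (fluorescence vs temperature, typically recorded from
95 down to 25 degC in 1 degC steps at 50 nM probe with or without 500 nM
target) are corrected for the intrinsic temperature dependence of dye
fluorescence, then reduced to a melting temperature Tm by either of two
standard routes:

* **derivative** — the temperature of maximal |dF/dT| on a lightly
  smoothed curve, refined by quadratic interpolation around the grid
  peak;
* **two-state fit** — a two-state sigmoid with linear folded/unfolded
  baselines,

  F(T) = (a_f + b_f*T) + [(a_u + b_u*T) - (a_f + b_f*T)] / (1 + exp(-(T - Tm)/w)),

  whose fitted midpoint is Tm.

Hybridization kinetics at excess target (pseudo-first-order regime;
target >= 5-fold over probe) follow

  F(t) = F_inf - (F_inf - F0) * exp(-k_obs * t),

fitted by least squares; the second-order on-rate is
k_on = k_obs / [target] in 1/(M*s).

These closed forms are the standard beacon-hybridization models; the
module fits them, it does not derive thermodynamic parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit


class FitError(RuntimeError):
    """A model fit failed to converge or produced a non-physical rate."""


# ---------------------------------------------------------------------------
# containers


def _validate_xy(x: np.ndarray, y: np.ndarray, xname: str) -> None:
    if x.ndim != 1 or y.ndim != 1 or len(x) != len(y):
        raise ValueError(f"{xname} and fluorescence must be equal-length 1D arrays")
    if len(x) < 2:
        raise ValueError("need at least 2 samples")


@dataclass
class MeltCurve:
    """Fluorescence vs temperature; temperatures strictly monotonic (either direction)."""

    temps: np.ndarray
    fluorescence: np.ndarray
    probe_conc: float = 50.0   # nM
    target_conc: float = 500.0  # nM, 0 for probe-only scans

    def __post_init__(self) -> None:
        self.temps = np.asarray(self.temps, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        _validate_xy(self.temps, self.fluorescence, "temps")
        d = np.diff(self.temps)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("temperatures must be strictly monotonic")

    def ascending(self) -> "MeltCurve":
        if self.temps[0] > self.temps[-1]:
            return replace(self, temps=self.temps[::-1].copy(), fluorescence=self.fluorescence[::-1].copy())
        return self

    def to_csv(self, path) -> None:
        pd.DataFrame({"temperature_C": self.temps, "fluorescence": self.fluorescence}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path, probe_conc: float = 50.0, target_conc: float = 500.0) -> "MeltCurve":
        df = pd.read_csv(path, comment="#")
        t, f = df.iloc[:, 0].to_numpy(float), df.iloc[:, 1].to_numpy(float)
        return cls(t, f, probe_conc=probe_conc, target_conc=target_conc)


@dataclass
class KineticsTrace:
    """Fluorescence vs time after target addition; times strictly increasing."""

    times: np.ndarray
    fluorescence: np.ndarray
    probe_conc: float = 50.0   # nM
    target_conc: float = 500.0  # nM
    temperature: float = 37.0  # degC

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        _validate_xy(self.times, self.fluorescence, "times")
        if np.any(self.times < 0) or not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be non-negative and strictly increasing")

    def to_csv(self, path) -> None:
        pd.DataFrame({"time_s": self.times, "fluorescence": self.fluorescence}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path, probe_conc: float = 50.0, target_conc: float = 500.0,
                 temperature: float = 37.0) -> "KineticsTrace":
        df = pd.read_csv(path, comment="#")
        t, f = df.iloc[:, 0].to_numpy(float), df.iloc[:, 1].to_numpy(float)
        return cls(t, f, probe_conc=probe_conc, target_conc=target_conc, temperature=temperature)


# ---------------------------------------------------------------------------
# drift correction


@dataclass(frozen=True)
class LinearDrift:
    """Linear temperature response of dye fluorescence: f(T) = slope*T + intercept."""

    slope: float
    intercept: float

    def __call__(self, temps) -> np.ndarray:
        return self.slope * np.asarray(temps, dtype=float) + self.intercept


def correct_temperature_drift(
    curve: MeltCurve,
    reference: MeltCurve | LinearDrift | None = None,
    baseline_fraction: float = 0.1,
) -> MeltCurve:
    """Remove the intrinsic temperature dependence of dye fluorescence.

    With a reference (a free-dye melt scan, or a :class:`LinearDrift`
    model), the curve is divided pointwise by the reference evaluated at
    the curve's temperatures (a reference curve is interpolated onto
    them; it must cover the same range and contain no zeros).  Dividing a
    curve by itself therefore yields the constant 1.

    Without a reference, the drift slope is estimated as the mean of the
    slopes of two lines fitted separately to the first and last
    ``baseline_fraction`` of samples (at least 3 points each end) — the
    intrinsic dye drift tilts both baselines equally, while the
    transition step between them does not enter either local fit.  The
    zero-mean drift component is subtracted, preserving the curve's
    overall level.
    """
    c = curve.ascending()
    if reference is not None:
        if isinstance(reference, LinearDrift):
            ref_vals = reference(c.temps)
        else:
            r = reference.ascending()
            if c.temps[0] < r.temps[0] - 1e-9 or c.temps[-1] > r.temps[-1] + 1e-9:
                raise ValueError("reference does not cover the curve's temperature range")
            ref_vals = np.interp(c.temps, r.temps, r.fluorescence)
        if np.any(ref_vals == 0):
            raise ValueError("reference contains zeros; cannot divide")
        return replace(c, fluorescence=c.fluorescence / ref_vals)
    n = len(c.temps)
    k = max(int(round(baseline_fraction * n)), 3)
    lo_slope = np.polyfit(c.temps[:k], c.fluorescence[:k], 1)[0]
    hi_slope = np.polyfit(c.temps[-k:], c.fluorescence[-k:], 1)[0]
    slope = 0.5 * (lo_slope + hi_slope)
    drift = slope * c.temps
    return replace(c, fluorescence=c.fluorescence - (drift - drift.mean()))


# ---------------------------------------------------------------------------
# melting temperature


@dataclass(frozen=True)
class TmResult:
    """Melting-temperature estimate with diagnostics.

    ``tm`` is the estimate from the requested method (None when no
    transition was detected); both methods' values are always reported.
    """

    tm: float | None
    method: str
    tm_derivative: float | None
    tm_fit: float | None
    fit_params: dict | None
    message: str = ""


def _two_state(T, tm, width, a_f, b_f, a_u, b_u):
    base_f = a_f + b_f * T
    base_u = a_u + b_u * T
    return base_f + (base_u - base_f) / (1.0 + np.exp(-(T - tm) / width))


def _smooth(y: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return y
    kernel = np.ones(window) / window
    pad = window // 2
    ypad = np.pad(y, pad, mode="edge")
    return np.convolve(ypad, kernel, mode="valid")[: len(y)]


def _tm_derivative(temps: np.ndarray, fluor: np.ndarray, window: int) -> float | None:
    ys = _smooth(fluor, window)
    dF = np.gradient(ys, temps)
    mag = np.abs(dF)
    i = int(np.argmax(mag))
    if i == 0 or i == len(temps) - 1:
        return float(temps[i])
    # quadratic refinement around the grid peak
    y0, y1, y2 = mag[i - 1], mag[i], mag[i + 1]
    denom = y0 - 2 * y1 + y2
    if denom == 0:
        return float(temps[i])
    shift = 0.5 * (y0 - y2) / denom
    shift = float(np.clip(shift, -1.0, 1.0))
    step = temps[min(i + 1, len(temps) - 1)] - temps[i] if shift >= 0 else temps[i] - temps[i - 1]
    return float(temps[i] + shift * abs(step))


def melting_temperature(
    curve: MeltCurve,
    method: str = "two-state-fit",
    smooth_window: int = 3,
) -> TmResult:
    """Estimate Tm from a (corrected) melting profile.

    Both the derivative estimate and the two-state fit are computed and
    reported; ``method`` ({"derivative", "two-state-fit"}) selects which
    populates ``tm``.  A curve with no discernible transition (total
    amplitude below ~5x the point-to-point noise) yields ``tm=None``
    with an explanatory message rather than a spurious number.
    """
    if method not in ("derivative", "two-state-fit"):
        raise ValueError("method must be 'derivative' or 'two-state-fit'")
    c = curve.ascending()
    T, F = c.temps, c.fluorescence
    # transition detectability: amplitude vs successive-difference noise proxy
    noise = np.median(np.abs(np.diff(F))) / np.sqrt(2)
    amplitude = np.ptp(_smooth(F, smooth_window))
    if amplitude == 0 or (noise > 0 and amplitude < 5 * noise):
        return TmResult(None, method, None, None, None, message="no transition detected (flat curve)")

    tm_der = _tm_derivative(T, F, smooth_window)

    tm_fit = None
    fit_params = None
    n = len(T)
    k = max(n // 10, 2)
    f0, f1 = float(F[:k].mean()), float(F[-k:].mean())
    p0 = [tm_der if tm_der is not None else float(T[n // 2]), 2.0, f0, 0.0, f1, 0.0]
    try:
        popt, _ = curve_fit(_two_state, T, F, p0=p0, maxfev=20000)
        if T[0] <= popt[0] <= T[-1] and popt[1] > 0:
            tm_fit = float(popt[0])
            fit_params = {
                "tm": float(popt[0]),
                "width": float(popt[1]),
                "baseline_folded": (float(popt[2]), float(popt[3])),
                "baseline_unfolded": (float(popt[4]), float(popt[5])),
            }
    except RuntimeError:
        pass

    tm = tm_der if method == "derivative" else tm_fit
    msg = "" if tm is not None else "two-state fit did not converge inside the scanned range"
    return TmResult(tm, method, tm_der, tm_fit, fit_params, message=msg)


# ---------------------------------------------------------------------------
# kinetics


@dataclass(frozen=True)
class OnRateFit:
    """Pseudo-first-order fit: observed rate plus derived second-order on-rate."""

    k_obs: float       # 1/s
    k_on: float        # 1/(M*s)
    f0: float
    f_inf: float
    residual_sd: float


def _exp_rise(t, f_inf, f0, k):
    return f_inf - (f_inf - f0) * np.exp(-k * t)


def fit_on_rate(trace: KineticsTrace) -> OnRateFit:
    """Fit F(t) = F_inf - (F_inf - F0) exp(-k_obs t) and derive k_on.

    Requires the pseudo-first-order regime: target at >= 5-fold excess
    over probe.  Initial estimates: F0/F_inf from the first/last 10% of
    samples, k_obs from a log-linear fit of the normalized approach to
    plateau.  Raises :class:`FitError` on non-convergence or a
    non-positive fitted rate.
    """
    if trace.target_conc < 5 * trace.probe_conc:
        raise ValueError("pseudo-first-order fit requires target >= 5-fold excess over probe")
    t, F = trace.times, trace.fluorescence
    n = len(t)
    k = max(n // 10, 2)
    f0_init, finf_init = float(F[:k].mean()), float(F[-k:].mean())
    # log-linear initialization of the rate from the normalized approach
    k_init = None
    amp = finf_init - f0_init
    if amp != 0:
        frac = (finf_init - F) / amp
        good = (frac > 1e-3) & (frac < 1.0) & (t > t[0])
        if good.sum() >= 2:
            slope = np.polyfit(t[good], np.log(frac[good]), 1)[0]
            if slope < 0:
                k_init = -slope
    if k_init is None:
        k_init = 1.0 / max(t[-1] - t[0], 1e-9)
    try:
        popt, _ = curve_fit(_exp_rise, t, F, p0=[finf_init, f0_init, k_init], maxfev=20000)
    except RuntimeError as exc:
        raise FitError(f"kinetics fit did not converge: {exc}") from exc
    f_inf, f0, k_obs = (float(v) for v in popt)
    if k_obs <= 0:
        raise FitError(f"fitted k_obs = {k_obs:.3g} is non-positive")
    resid = F - _exp_rise(t, *popt)
    resid_sd = float(np.sqrt((resid**2).mean()))
    if abs(f_inf - f0) < 5 * resid_sd:
        raise FitError("no resolvable fluorescence change (flat trace)")
    target_molar = trace.target_conc * 1e-9
    return OnRateFit(
        k_obs=k_obs,
        k_on=k_obs / target_molar,
        f0=f0,
        f_inf=f_inf,
        residual_sd=resid_sd,
    )
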