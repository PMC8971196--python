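"""Dual-emission ratiometric dye calibration.

Ratiometric pH dyes (cSNARF1 for cytoplasm, Hoechst 34580 for the DNA
nanodomain) report pH through the ratio of two emission bands.  Under a
nigericin/high-K+ clamp the intracellular pH equals the superfusate pH, so a
titration series of (pH, ratio) pairs can be fitted to a single-site
protonation curve with an optional Hill slope:

    R(pH) = r_min + (r_max - r_min) / (1 + 10**(hill * (pKa - pH)))

``r_min`` is the acid asymptote and ``r_max`` the base asymptote; either may
be the larger value, so the same equation covers dyes whose ratio rises or
falls with pH.  At pH = pKa the ratio is the midpoint (r_min + r_max) / 2.
The curve is strictly monotone, hence invertible between its asymptotes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "CalibrationCurve",
    "PHInsensitiveDyeError",
    "fit_calibration",
    "pH_to_ratio",
    "ratio_to_pH",
]


class PHInsensitiveDyeError(ValueError):
    """Raised when a titration series shows no usable pH dependence.

    Mirrors the behaviour of SYTO-family DNA dyes, whose emission ratio is
    flat across the physiological pH range and which therefore cannot be
    calibrated.
    """


@dataclass(frozen=True)
class CalibrationCurve:
    """Fitted (or specified) titration curve for one dye.

    Parameters
    ----------
    dye:
        Dye label, e.g. ``"cSNARF1"`` or ``"H34580"``.
    r_min, r_max:
        Acid and base asymptotes of the emission ratio.  ``r_min != r_max``.
    pKa:
        pH of half-transition; the ratio there is ``(r_min + r_max) / 2``.
    hill:
        Hill slope (> 0); 1 for a single protonation site.
    numerator_band, denominator_band:
        Emission-band labels forming the ratio (e.g. "580", "640").
    fit_rms:
        Residual RMS of the least-squares fit, if the curve was fitted.
    """

    dye: str
    r_min: float
    r_max: float
    pKa: float
    hill: float = 1.0
    numerator_band: str = ""
    denominator_band: str = ""
    fit_rms: Optional[float] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.r_min == self.r_max:
            raise ValueError("r_min must differ from r_max")
        if not self.hill > 0:
            raise ValueError("hill slope must be > 0")

    @property
    def dynamic_range(self) -> float:
        return abs(self.r_max - self.r_min)

    def __call__(self, pH):
        return pH_to_ratio(self, pH)


def pH_to_ratio(curve: CalibrationCurve, pH):
    """Evaluate the forward titration equation at ``pH`` (scalar or array)."""
    pH = np.asarray(pH, dtype=float)
    r = curve.r_min + (curve.r_max - curve.r_min) / (
        1.0 + 10.0 ** (curve.hill * (curve.pKa - pH))
    )
    return r if r.ndim else float(r)


def ratio_to_pH(curve: CalibrationCurve, ratio, *, clamp_tol: float = 0.01):
    """Invert the titration curve: emission ratio -> pH.

    Ratios must lie strictly between the asymptotes.  Values outside the open
    interval by at most ``clamp_tol`` (as a fraction of the dynamic range) are
    clamped to just inside the interval; values further out are undefined and
    returned as NaN so callers can flag the pixel or cell.

    Returns a float for scalar input, else an ndarray with NaN marking
    out-of-range ratios.
    """
    ratio = np.asarray(ratio, dtype=float)
    scalar = ratio.ndim == 0
    r = np.atleast_1d(ratio).astype(float).copy()

    lo, hi = sorted((curve.r_min, curve.r_max))
    rng = hi - lo
    tol = clamp_tol * rng
    out_of_range = (r <= lo - tol) | (r >= hi + tol)
    # clamp near-miss values to just inside the open interval
    eps = 1e-12 * rng
    r = np.clip(r, lo + eps, hi - eps)
    with np.errstate(divide="ignore", invalid="ignore"):
        pH = curve.pKa + (1.0 / curve.hill) * np.log10(
            (r - curve.r_min) / (curve.r_max - r)
        )
    pH[out_of_range] = np.nan
    return float(pH[0]) if scalar else pH


def _model(pH, r_min, r_max, pKa, hill):
    return r_min + (r_max - r_min) / (1.0 + 10.0 ** (hill * (pKa - pH)))


def fit_calibration(
    series: pd.DataFrame,
    dye: str = "",
    hill_fixed: Optional[float] = None,
    *,
    numerator_band: str = "",
    denominator_band: str = "",
    flat_tol: float = 1e-6,
    min_dynamic_range: float = 0.05,
) -> CalibrationCurve:
    """Least-squares fit of the titration curve to a (pH, ratio) series.

    Parameters
    ----------
    series:
        DataFrame with columns ``pH`` and ``ratio`` (one row per ROI
        measurement; replicate rows per pH level are expected).
    hill_fixed:
        If given, the Hill slope is fixed at this value and only the three
        remaining parameters are fitted.
    flat_tol, min_dynamic_range:
        A series whose observed ratio spread is below ``flat_tol``, or whose
        fitted dynamic range falls below ``min_dynamic_range``, is rejected as
        pH-insensitive (the SYTO-dye behaviour).

    The fit is deterministic (no random initialisation) and invariant to row
    order: initial values come from order statistics of the data.
    """
    if not {"pH", "ratio"}.issubset(series.columns):
        raise ValueError("series must have 'pH' and 'ratio' columns")
    pH = np.asarray(series["pH"], dtype=float)
    ratio = np.asarray(series["ratio"], dtype=float)
    n_levels = np.unique(pH).size
    n_params = 3 if hill_fixed is not None else 4
    if n_levels < n_params:
        raise ValueError(
            f"need at least {n_params} distinct pH levels, got {n_levels}"
        )
    if np.ptp(ratio) < flat_tol:
        raise PHInsensitiveDyeError(
            f"ratio spread {np.ptp(ratio):.3g} below {flat_tol}: "
            "dye appears pH-insensitive"
        )

    # orientation from data: does the ratio rise or fall with pH?
    level_means = pd.Series(ratio).groupby(pd.Series(pH)).mean()
    rising = level_means.iloc[-1] >= level_means.iloc[0]
    r_lo, r_hi = float(np.min(ratio)), float(np.max(ratio))
    r_min0, r_max0 = (r_lo, r_hi) if rising else (r_hi, r_lo)
    mid = 0.5 * (r_lo + r_hi)
    pKa0 = float(pH[np.argmin(np.abs(ratio - mid))])

    if hill_fixed is not None:
        def f(x, r_min, r_max, pKa):
            return _model(x, r_min, r_max, pKa, hill_fixed)
        p0 = [r_min0, r_max0, pKa0]
    else:
        f = _model
        p0 = [r_min0, r_max0, pKa0, 1.0]

    bounds_lo = [-np.inf, -np.inf, np.min(pH) - 5.0]
    bounds_hi = [np.inf, np.inf, np.max(pH) + 5.0]
    if hill_fixed is None:
        bounds_lo.append(1e-3)
        bounds_hi.append(20.0)

    try:
        popt, _ = curve_fit(
            f, pH, ratio, p0=p0, bounds=(bounds_lo, bounds_hi), maxfev=20000
        )
    except RuntimeError as exc:  # pragma: no cover - optimizer pathology
        raise PHInsensitiveDyeError(f"calibration fit failed: {exc}") from exc

    if hill_fixed is not None:
        r_min, r_max, pKa = popt
        hill = float(hill_fixed)
    else:
        r_min, r_max, pKa, hill = popt
    if abs(r_max - r_min) < min_dynamic_range:
        raise PHInsensitiveDyeError(
            f"fitted dynamic range {abs(r_max - r_min):.3g} below "
            f"{min_dynamic_range}: dye appears pH-insensitive"
        )
    resid = ratio - _model(pH, r_min, r_max, pKa, hill)
    rms = float(np.sqrt(np.mean(resid**2)))
    return CalibrationCurve(
        dye=dye,
        r_min=float(r_min),
        r_max=float(r_max),
        pKa=float(pKa),
        hill=float(hill),
        numerator_band=numerator_band,
        denominator_band=denominator_band,
        fit_rms=rms,
    )
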