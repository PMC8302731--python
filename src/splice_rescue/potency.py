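"""Dose-response potency estimation and the two-sample t test.

Reporter fluorescence (%GFP) and viability readouts are modelled with a
four-parameter logistic (4PL),

    response(d) = bottom + (top - bottom) / (1 + (ec50 / d)^hill),

fitted by least squares on log10 dose with multi-start initialisation.
Effective concentrations are read off the fitted curve: EC25 is the dose
at which the normalized response reaches 25% (with the reference
treatment set to 100%), and CT50 the dose at 50% viability on a falling
curve normalized to vehicle = 100%.  A level the curve never attains
within the admissible range (tested concentrations x [1/10, 10]) is
reported as "not reached".

Group comparisons use Student's unpaired pooled-variance t test
(df = n_a + n_b - 2), one- or two-tailed; Welch's correction is
available behind a flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .simulate import four_pl

__all__ = [
    "DoseResponseFit",
    "TTestResult",
    "normalize_reporter",
    "fit_4pl",
    "ec_at",
    "ct50",
    "t_test",
    "NOT_REACHED",
]

NOT_REACHED = "not reached"


@dataclass
class DoseResponseFit:
    bottom: float
    top: float
    ec50: float
    hill: float
    converged: bool
    residual_norm: float
    dose_range: tuple[float, float]
    n_points: int = 0
    compound: str = ""
    ec25: float | str | None = None
    ct50: float | str | None = None
    diagnostics: dict = field(default_factory=dict)

    def predict(self, dose):
        return four_pl(dose, self.bottom, self.top, self.ec50, self.hill)


def normalize_reporter(
    table: pd.DataFrame,
    reference: tuple[str, float],
    response_col: str = "response",
) -> pd.DataFrame:
    """Rescale responses so the mean at the reference (compound, dose) is 100%."""
    compound, dose = reference
    mask = (table["compound"] == compound) & np.isclose(table["dose_uM"], dose)
    if not mask.any():
        raise ValueError(f"reference rows ({compound}, {dose} uM) not found")
    ref_mean = table.loc[mask, response_col].mean()
    if ref_mean == 0:
        raise ValueError("reference mean response is zero")
    out = table.copy()
    out[response_col] = table[response_col] * (100.0 / ref_mean)
    return out


def _fit_once(logd, y, p0, bounds):
    popt, _ = optimize.curve_fit(
        lambda ld, bottom, top, log_ec50, hill: four_pl(
            10.0**ld, bottom, top, 10.0**log_ec50, hill
        ),
        logd,
        y,
        p0=p0,
        bounds=bounds,
        maxfev=20000,
    )
    resid = y - four_pl(10.0**logd, popt[0], popt[1], 10.0 ** popt[2], popt[3])
    return popt, float(np.sqrt(np.sum(resid**2)))


def fit_4pl(
    table: pd.DataFrame,
    response_col: str = "response",
    compound: str | None = None,
) -> DoseResponseFit:
    """Least-squares 4PL fit on log10 dose with multi-start initialisation.

    Vehicle rows (dose 0) are excluded from the fit.  Initial guesses
    sweep hill in {+-0.5, +-1, +-2} and ec50 over dose quantiles; the
    start with the smallest residual norm wins.  Requires >= 4 distinct
    positive doses.
    """
    if compound is not None:
        table = table[table["compound"] == compound]
    table = table[table["dose_uM"] > 0]
    doses = table["dose_uM"].to_numpy(dtype=float)
    y = table[response_col].to_numpy(dtype=float)
    distinct = np.unique(doses)
    if distinct.size < 4:
        raise ValueError(f"need >= 4 distinct positive doses, got {distinct.size}")
    logd = np.log10(doses)
    span = y.max() - y.min() or 1.0
    bounds = (
        [y.min() - 2 * span, y.min() - 2 * span, logd.min() - 2, -10.0],
        [y.max() + 2 * span, y.max() + 2 * span, logd.max() + 2, 10.0],
    )
    best = None
    quantiles = np.quantile(distinct, [0.25, 0.5, 0.75])
    for hill0 in (0.5, 1.0, 2.0, -0.5, -1.0, -2.0):
        for ec0 in quantiles:
            lo, hi = (y.min(), y.max()) if hill0 > 0 else (y.max(), y.min())
            p0 = [lo, hi, math.log10(ec0), hill0]
            try:
                popt, rnorm = _fit_once(logd, y, p0, bounds)
            except (RuntimeError, ValueError):
                continue
            if best is None or rnorm < best[1]:
                best = (popt, rnorm)
    if best is None:
        return DoseResponseFit(
            math.nan, math.nan, math.nan, math.nan,
            converged=False, residual_norm=math.inf,
            dose_range=(float(distinct.min()), float(distinct.max())),
            n_points=len(y), compound=compound or "",
        )
    (bottom, top, log_ec50, hill), rnorm = best
    return DoseResponseFit(
        float(bottom), float(top), float(10.0**log_ec50), float(hill),
        converged=True, residual_norm=rnorm,
        dose_range=(float(distinct.min()), float(distinct.max())),
        n_points=len(y), compound=compound or "",
        diagnostics={"n_distinct_doses": int(distinct.size)},
    )


def ec_at(fit: DoseResponseFit, level: float) -> float | str:
    """Dose at which the fitted curve crosses ``level`` x 100% response.

    The response scale is the normalized one (reference = 100%), so
    ``level=0.25`` inverts the curve at 25%.  Returns ``"not reached"``
    if the crossing lies outside tested-range x [1/10, 10] or the curve
    never attains the level.
    """
    if not fit.converged:
        raise ValueError("cannot invert an unconverged fit")
    if not 0.0 < level < 1.0:
        raise ValueError("level must be inside (0, 1)")
    target = level * 100.0
    lo, hi = sorted((fit.bottom, fit.top))
    if not lo < target < hi:
        return NOT_REACHED
    # invert: target = bottom + (top-bottom)/(1+(ec50/d)^hill)
    ratio = (fit.top - fit.bottom) / (target - fit.bottom) - 1.0
    if ratio <= 0:
        return NOT_REACHED
    dose = fit.ec50 / ratio ** (1.0 / fit.hill)
    dmin, dmax = fit.dose_range
    if not dmin / 10.0 <= dose <= dmax * 10.0:
        return NOT_REACHED
    return float(dose)


def ct50(fit: DoseResponseFit) -> float | str:
    """50% cytotoxic concentration of a falling viability curve."""
    return ec_at(fit, 0.5)


@dataclass(frozen=True)
class TTestResult:
    statistic: float
    df: float
    p_value: float
    tails: int
    flagged: str = ""


def t_test(
    group_a,
    group_b,
    tails: int = 2,
    welch: bool = False,
) -> TTestResult:
    """Student's unpaired t test (pooled variance unless ``welch``).

    The one-tailed p value is for the observed direction of the
    difference (half the two-tailed p).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    if tails not in (1, 2):
        raise ValueError("tails must be 1 or 2")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0 and a.mean() == b.mean():
        df = a.size + b.size - 2
        return TTestResult(0.0, df, 1.0, tails, flagged="zero variance, equal means")
    res = stats.ttest_ind(a, b, equal_var=not welch)
    df = float(res.df)
    p = float(res.pvalue)
    if tails == 1:
        p /= 2.0
    return TTestResult(float(res.statistic), df, p, tails)
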