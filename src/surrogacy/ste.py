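"""Surrogate threshold effect (STE) from the 95% prediction band.

The STE is the least extreme PFS-HR that predicts a statistically
significant OS benefit in a *future* trial: on the log scale it is the root
of

    upper 95% prediction limit for ln OS-HR at ln PFS-HR = x  ==  0.

The band around the weighted regression line at x0 for a future comparison
with relative weight w_f is

    yhat(x0) +/- t_{df, 0.975} * sqrt( s^2 * ( 1/w_f + x0' (X'WX)^{-1} x0 ) )

with s^2 the residual variance on the mean-1 weight scale and w_f =
future_trial_n / mean(randomized N of the fitted comparisons). By default
the future trial is average-sized (w_f = 1), mirroring how the threshold is
read off a published band. For an adjusted fit the band is evaluated with
the treatment-class indicator at its weighted mean (a marginal band).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.optimize import brentq

from .regression import SurrogacyFit
from .trial_data import ValidationError

__all__ = ["STEResult", "prediction_band", "compute_ste", "band_grid"]

#: Log-scale search interval floor: HR = 0.05, far below any plausible effect.
SEARCH_FLOOR = math.log(0.05)
ROOT_TOL = 1e-8


@dataclass(frozen=True)
class STEResult:
    """STE on the HR scale, or an explicit non-estimable marker."""

    ste_hr: float | None
    estimable: bool
    future_trial_n: float
    band_upper_at_null_x: float  # upper limit of predicted ln OS-HR at ln PFS-HR = 0
    search_interval: tuple[float, float]
    model_spec: str = ""

    def __post_init__(self) -> None:
        if self.estimable != (self.ste_hr is not None):
            raise ValueError("estimable flag must mirror presence of ste_hr")


def _band_halfwidth(fit: SurrogacyFit, x0: float, w_future: float, treat0: float | None) -> float:
    v = [1.0, x0]
    if fit.adjusted and fit.treat is not None:
        v.append(fit.treat_mean_weighted if treat0 is None else treat0)
    v = np.asarray(v)
    t_q = stats.t.ppf(0.975, fit.df_residual)
    var = fit.residual_variance * (1.0 / w_future + float(v @ fit.cov_unscaled @ v))
    return float(t_q * math.sqrt(var))


def prediction_band(
    fit: SurrogacyFit,
    x0: float,
    future_weight: float = 1.0,
    treat0: float | None = None,
) -> tuple[float, float]:
    """95% prediction limits for a future trial's ln OS-HR at ln PFS-HR = x0.

    ``future_weight`` is on the mean-1 scale of the fitted weights (1 = a
    trial of average size). With zero residual variance the band collapses to
    the fitted line.
    """
    if not (future_weight > 0):
        raise ValidationError(f"future_weight must be positive, got {future_weight}")
    if fit.df_residual < 1:
        raise ValueError("prediction band requires df_residual >= 1")
    yhat = fit.predict(x0, treat0)
    h = _band_halfwidth(fit, x0, future_weight, treat0)
    return (yhat - h, yhat + h)


def compute_ste(
    fit: SurrogacyFit,
    future_trial_n: float | None = None,
    treat0: float | None = None,
) -> STEResult:
    """Surrogate threshold effect for a future trial of given size.

    ``future_trial_n`` defaults to the mean randomized N of the fitted
    comparisons (an average-sized future trial). The root of the upper
    prediction limit is searched by bisection over ln HR in
    [ln 0.05, 0]; if the upper limit stays >= 0 over the whole interval the
    STE is reported as non-estimable. With several sign changes the root
    closest to HR = 1 is reported with a warning.
    """
    if future_trial_n is None:
        future_trial_n = fit.mean_n
    if not (future_trial_n > 0):
        raise ValidationError(f"future_trial_n must be positive, got {future_trial_n}")
    w_future = future_trial_n / fit.mean_n

    def upper(x0: float) -> float:
        return prediction_band(fit, x0, w_future, treat0)[1]

    a, b = SEARCH_FLOOR, 0.0
    spec = f"{fit.subgroup}/{fit.treatment_class}/{'adjusted' if fit.adjusted else 'unadjusted'}"
    # locate sign changes on a grid, then refine by bisection
    grid = np.linspace(a, b, 513)
    vals = np.array([upper(g) for g in grid])
    sign_changes = [
        (grid[i], grid[i + 1])
        for i in range(len(grid) - 1)
        if vals[i] < 0.0 <= vals[i + 1] or vals[i] >= 0.0 > vals[i + 1]
    ]
    if not sign_changes:
        if np.all(vals >= 0):
            # band never dips below the null: no PFS effect in the search
            # range predicts a significant OS benefit
            return STEResult(
                ste_hr=None,
                estimable=False,
                future_trial_n=float(future_trial_n),
                band_upper_at_null_x=float(upper(0.0)),
                search_interval=(a, b),
                model_spec=spec,
            )
        return _degenerate_all_negative(fit, future_trial_n, a, b, spec, upper)
    if len(sign_changes) > 1:
        warnings.warn(
            f"{spec}: upper prediction limit crosses zero {len(sign_changes)} times; "
            "reporting the root closest to HR = 1",
            RuntimeWarning,
            stacklevel=2,
        )
    lo_br, hi_br = sign_changes[-1]  # largest root (closest to 1)
    root = brentq(upper, lo_br, hi_br, xtol=ROOT_TOL)
    return STEResult(
        ste_hr=float(math.exp(root)),
        estimable=True,
        future_trial_n=float(future_trial_n),
        band_upper_at_null_x=float(upper(0.0)),
        search_interval=(a, b),
        model_spec=spec,
    )


def _degenerate_all_negative(fit, future_trial_n, a, b, spec, upper):
    # upper limit below zero over the whole interval: any PFS-HR up to 1
    # predicts a significant OS benefit; report the boundary.
    warnings.warn(
        f"{spec}: upper prediction limit is negative over the whole search "
        "interval; STE reported at the HR = 1 boundary",
        RuntimeWarning,
        stacklevel=3,
    )
    return STEResult(
        ste_hr=1.0,
        estimable=True,
        future_trial_n=float(future_trial_n),
        band_upper_at_null_x=float(upper(0.0)),
        search_interval=(a, b),
        model_spec=spec,
    )


def band_grid(
    fit: SurrogacyFit,
    n_points: int = 101,
    future_trial_n: float | None = None,
    pad: float = 0.05,
):
    """Fitted line and prediction band on an x-grid, for plotting.

    Returns a DataFrame with columns ln_pfs_hr, fit, band_lo, band_hi spanning
    the observed ln PFS-HR range (padded by ``pad`` on each side).
    """
    import pandas as pd

    if future_trial_n is None:
        future_trial_n = fit.mean_n
    w_future = future_trial_n / fit.mean_n
    xs = np.linspace(fit.x.min() - pad, fit.x.max() + pad, n_points)
    rows = []
    for x0 in xs:
        lo, hi = prediction_band(fit, float(x0), w_future)
        rows.append(
            {"ln_pfs_hr": float(x0), "fit": fit.predict(float(x0)), "band_lo": lo, "band_hi": hi}
        )
    return pd.DataFrame(rows)
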