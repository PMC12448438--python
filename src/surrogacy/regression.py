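"""Trial-level surrogacy regression of log OS-HR on log PFS-HR.

The surrogacy model is a weighted least-squares regression across randomized
comparisons,

    ln OS-HR_i = a + b * ln PFS-HR_i + e_i,      weight_i = N_i,

with N_i the number of randomized patients in comparison i. The weighted
coefficient of determination R^2 quantifies trial-level surrogacy; the slope
is the alternative measure and must differ significantly from zero for the
effects to be considered associated. A treatment-class-adjusted variant adds
an indicator for the experimental-arm regimen (ICI alone vs ICI+chemo) and
summarizes surrogacy as the squared partial correlation of the two log
effects given that indicator.

Weights are used as *relative* precision weights: they are rescaled to mean 1
before fitting, which leaves coefficients, R^2 and p-values unchanged but
makes the residual variance scale interpretable (and the prediction band for
a future trial well-defined; see :mod:`surrogacy.ste`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .trial_data import Dataset, ValidationError

__all__ = [
    "SurrogacyFit",
    "CrossValidationResult",
    "InsufficientComparisonsError",
    "DegenerateDesignError",
    "fit_surrogacy",
    "bootstrap_r2_ci",
    "loocv_r2",
    "slope_test",
]


class InsufficientComparisonsError(ValueError):
    """Stratum holds fewer comparisons than the model requires."""


class DegenerateDesignError(ValueError):
    """Design matrix is rank deficient (e.g. all PFS effects identical)."""


def _stratum_arrays(ds: Dataset, subgroup: str, treatment_class: str):
    sub = ds.filter(subgroup, treatment_class)
    x = np.array([r.effect("pfs").log_hr for r in sub])
    y = np.array([r.effect("os").log_hr for r in sub])
    n = np.array([float(r.n_randomized) for r in sub])
    t = np.array([1.0 if r.treatment_class == "ici_chemo" else 0.0 for r in sub])
    ids = [r.comparison_id for r in sub]
    return x, y, n, t, ids


def _design(x: np.ndarray, t: np.ndarray | None) -> np.ndarray:
    cols = [np.ones_like(x), x]
    if t is not None:
        cols.append(t)
    return np.column_stack(cols)


def _wls_core(x, y, w, t):
    """Closed-form WLS fit; returns (beta, r2, ss_res, partial_r2 or None).

    ``w`` must already be on the mean-1 scale. ``t`` is the treatment
    indicator column or None for the simple model. Raises
    DegenerateDesignError when the design is rank deficient.
    """
    adjusted = t is not None
    if adjusted and np.unique(t).size < 2:
        # constant covariate carries no information: the adjusted model
        # reduces exactly to the simple fit, and the partial correlation
        # given a constant equals the marginal one
        t = None
    X = _design(x, t)
    XtW = X.T * w
    xtwx = XtW @ X
    if np.linalg.matrix_rank(xtwx) < X.shape[1]:
        raise DegenerateDesignError("rank-deficient weighted design matrix")
    beta = np.linalg.solve(xtwx, XtW @ y)
    resid = y - X @ beta
    ss_res = float(np.sum(w * resid**2))
    ybar = float(np.sum(w * y) / np.sum(w))
    ss_tot = float(np.sum(w * (y - ybar) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    partial = None
    if adjusted:
        if t is None:
            partial = r2
        else:
            # reduced model: y ~ 1 + indicator
            Xr = np.column_stack([np.ones_like(x), t])
            br = np.linalg.solve((Xr.T * w) @ Xr, (Xr.T * w) @ y)
            ss_red = float(np.sum(w * (y - Xr @ br) ** 2))
            partial = (ss_red - ss_res) / ss_red if ss_red > 0 else 1.0
    return beta, r2, ss_res, partial


@dataclass(frozen=True)
class SurrogacyFit:
    """A fitted weighted surrogacy regression for one stratum."""

    slope: float
    intercept: float
    slope_se: float
    slope_pvalue: float
    r2: float
    adjusted: bool
    partial_r2: float | None
    n_comparisons: int
    residual_variance: float
    df_residual: int
    subgroup: str
    treatment_class: str
    r2_ci_lo: float | None = None
    r2_ci_hi: float | None = None
    # fitted-data internals used by prediction bands and reports
    x: np.ndarray = field(repr=False, default=None)
    y: np.ndarray = field(repr=False, default=None)
    weights_used: np.ndarray = field(repr=False, default=None)  # mean-1 scale
    treat: np.ndarray | None = field(repr=False, default=None)
    beta: np.ndarray = field(repr=False, default=None)
    cov_unscaled: np.ndarray = field(repr=False, default=None)  # (X' W X)^-1
    mean_n: float = float("nan")
    comparison_ids: tuple[str, ...] = ()

    @property
    def headline_r2(self) -> float:
        """Partial R^2 when adjusted, plain weighted R^2 otherwise."""
        return self.partial_r2 if self.adjusted else self.r2

    @property
    def treat_mean_weighted(self) -> float | None:
        if self.treat is None:
            return None
        return float(np.sum(self.weights_used * self.treat) / np.sum(self.weights_used))

    def predict(self, x0: float, treat0: float | None = None) -> float:
        """Point prediction of ln OS-HR at ln PFS-HR = x0.

        For an adjusted fit, ``treat0`` defaults to the weighted mean of the
        indicator (a marginal prediction).
        """
        v = [1.0, x0]
        if self.adjusted and self.treat is not None:
            v.append(self.treat_mean_weighted if treat0 is None else treat0)
        return float(np.asarray(v) @ self.beta)

    def to_dict(self) -> dict:
        return {
            "subgroup": self.subgroup,
            "treatment_class": self.treatment_class,
            "adjusted": self.adjusted,
            "n_comparisons": self.n_comparisons,
            "slope": self.slope,
            "intercept": self.intercept,
            "slope_se": self.slope_se,
            "slope_pvalue": self.slope_pvalue,
            "r2": self.r2,
            "partial_r2": self.partial_r2,
            "r2_ci_lo": self.r2_ci_lo,
            "r2_ci_hi": self.r2_ci_hi,
            "residual_variance": self.residual_variance,
            "df_residual": self.df_residual,
        }


def fit_surrogacy(
    ds: Dataset,
    subgroup: str,
    treatment_class: str = "all",
    adjust_for_treatment: bool = False,
) -> SurrogacyFit:
    """Fit the weighted surrogacy regression for one stratum.

    y = ln OS-HR, x = ln PFS-HR, weights = randomized N (rescaled to mean 1).
    With ``adjust_for_treatment`` the model adds the ICI+chemo indicator and
    additionally reports the squared partial correlation of y with x given
    the indicator (``partial_r2``).
    """
    x, y, n, t, ids = _stratum_arrays(ds, subgroup, treatment_class)
    k_min = 4 if adjust_for_treatment else 3
    if len(x) < k_min:
        raise InsufficientComparisonsError(
            f"stratum {subgroup}/{treatment_class} has {len(x)} comparisons; "
            f"need >={k_min}{' for the adjusted model' if adjust_for_treatment else ''}"
        )
    if np.unique(x).size < 2:
        raise DegenerateDesignError("all ln PFS-HR values identical")
    w = n / n.mean()
    # constant indicator: the adjusted model reduces exactly to the simple
    # fit with partial R^2 = R^2 (the covariate carries no information)
    tcol = t if (adjust_for_treatment and np.unique(t).size > 1) else None

    X = _design(x, tcol)
    res = sm.WLS(y, X, weights=w).fit()
    _, r2_manual, ss_res, partial = _wls_core(x, y, w, tcol)
    if adjust_for_treatment and tcol is None:
        partial = r2_manual

    return SurrogacyFit(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        slope_se=float(res.bse[1]),
        slope_pvalue=float(res.pvalues[1]),
        r2=float(r2_manual),
        adjusted=adjust_for_treatment,
        partial_r2=partial,
        n_comparisons=len(x),
        residual_variance=float(res.mse_resid),
        df_residual=int(res.df_resid),
        subgroup=subgroup,
        treatment_class=treatment_class,
        x=x,
        y=y,
        weights_used=w,
        treat=tcol,
        beta=np.asarray(res.params, dtype=float),
        cov_unscaled=np.asarray(res.normalized_cov_params, dtype=float),
        mean_n=float(n.mean()),
        comparison_ids=tuple(ids),
    )


def bootstrap_r2_ci(
    ds: Dataset,
    subgroup: str,
    treatment_class: str = "all",
    adjust_for_treatment: bool = False,
    n_boot: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile bootstrap 95% CI for the stratum's headline R^2.

    Comparisons — (x, y, weight) triples, plus the treatment indicator when
    adjusting — are resampled with replacement and the model refitted; the
    2.5 and 97.5 percentiles of the resampled R^2 (partial R^2 when adjusted)
    form the interval. Rank-deficient resamples are redrawn; more than
    10 * n_boot redraws aborts with ``RuntimeError``. Reproducible for a
    fixed ``seed``.
    """
    x, y, n, t, _ = _stratum_arrays(ds, subgroup, treatment_class)
    k_min = 4 if adjust_for_treatment else 3
    if len(x) < k_min:
        raise InsufficientComparisonsError(
            f"stratum {subgroup}/{treatment_class} has {len(x)} comparisons; need >={k_min}"
        )
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    w_all = n / n.mean()
    tcol = t if adjust_for_treatment else None
    rng = np.random.default_rng(seed)
    stats_out = np.empty(n_boot)
    redraws = 0
    b = 0
    while b < n_boot:
        idx = rng.integers(0, len(x), size=len(x))
        try:
            _, r2, _, partial = _wls_core(
                x[idx], y[idx], w_all[idx] / w_all[idx].mean(),
                tcol[idx] if tcol is not None else None,
            )
        except DegenerateDesignError:
            redraws += 1
            if redraws > 10 * n_boot:
                raise RuntimeError(
                    f"bootstrap exceeded {10 * n_boot} degenerate redraws"
                )
            continue
        stats_out[b] = partial if adjust_for_treatment else r2
        b += 1
    lo, hi = np.percentile(stats_out, [2.5, 97.5])
    return float(lo), float(hi)


@dataclass(frozen=True)
class CrossValidationResult:
    """Leave-one-out predictions of ln OS-HR and the cross-validated R^2."""

    predictions: np.ndarray
    observed: np.ndarray
    cv_r2: float
    model_spec: str
    comparison_ids: tuple[str, ...] = ()
    weights: np.ndarray | None = None


def _weighted_corr(a: np.ndarray, b: np.ndarray, w: np.ndarray) -> float:
    w = w / w.sum()
    am, bm = np.sum(w * a), np.sum(w * b)
    cov = np.sum(w * (a - am) * (b - bm))
    return float(cov / math.sqrt(np.sum(w * (a - am) ** 2) * np.sum(w * (b - bm) ** 2)))


def loocv_r2(
    ds: Dataset,
    subgroup: str,
    treatment_class: str = "all",
    adjust_for_treatment: bool = False,
    weighted_correlation: bool = True,
) -> CrossValidationResult:
    """Leave-one-out cross-validation of the surrogacy model.

    Each comparison is left out once; the model refitted on the rest predicts
    its ln OS-HR. ``cv_r2`` is the squared correlation between the held-out
    predictions and the observed values — weighted by randomized N by
    default (``weighted_correlation=False`` gives the plain Pearson version).
    """
    x, y, n, t, ids = _stratum_arrays(ds, subgroup, treatment_class)
    k_min = 5 if adjust_for_treatment else 4  # >=4 comparisons in every training fold
    if len(x) < k_min:
        raise InsufficientComparisonsError(
            f"stratum {subgroup}/{treatment_class} has {len(x)} comparisons; need >={k_min}"
        )
    # constant indicator: adjusted model reduces to the simple one
    tcol = t if (adjust_for_treatment and np.unique(t).size > 1) else None
    preds = np.empty(len(x))
    for i in range(len(x)):
        m = np.ones(len(x), dtype=bool)
        m[i] = False
        try:
            beta, _, _, _ = _wls_core(
                x[m], y[m], n[m] / n[m].mean(), tcol[m] if tcol is not None else None
            )
        except DegenerateDesignError as exc:
            raise DegenerateDesignError(
                f"leave-one-out fit excluding comparison {ids[i]!r} is degenerate"
            ) from exc
        v = [1.0, x[i]] + ([t[i]] if tcol is not None else [])
        preds[i] = np.asarray(v) @ beta
    r = (
        _weighted_corr(preds, y, n)
        if weighted_correlation
        else float(np.corrcoef(preds, y)[0, 1])
    )
    spec = (
        f"{subgroup}/{treatment_class}/"
        f"{'adjusted' if adjust_for_treatment else 'unadjusted'}/"
        f"{'weighted' if weighted_correlation else 'unweighted'}-corr"
    )
    return CrossValidationResult(
        predictions=preds,
        observed=y,
        cv_r2=r**2,
        model_spec=spec,
        comparison_ids=tuple(ids),
        weights=n,
    )


def slope_test(fit: SurrogacyFit, alpha: float = 0.05) -> tuple[float, float, bool]:
    """Two-sided t-test of slope = 0; returns (t, p, significant at alpha)."""
    if fit.df_residual < 1:
        raise ValueError("slope test requires df_residual >= 1")
    if fit.slope_se == 0.0:
        t_stat = math.inf if fit.slope != 0 else 0.0
        p = 0.0 if fit.slope != 0 else 1.0
    else:
        t_stat = fit.slope / fit.slope_se
        p = 2.0 * stats.t.sf(abs(t_stat), fit.df_residual)
    return float(t_stat), float(p), bool(p < alpha)
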