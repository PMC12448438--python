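"""Random-effects pooling of log-HR estimates (DerSimonian-Laird).

Provides the meta-analytic summary columns of a forest plot: pooled effect
with 95% CI, the between-trial variance tau^2, Cochran's Q with its p-value,
and the I^2 heterogeneity statistic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .trial_data import Dataset, EffectEstimate, ValidationError, Z95

__all__ = ["PooledEffect", "InsufficientDataError", "pool_random_effects", "pool_by_stratum", "pooled_table"]


class InsufficientDataError(ValueError):
    """Fewer estimates than the pooling method requires."""


@dataclass(frozen=True)
class PooledEffect:
    """DerSimonian-Laird random-effects summary of k log-HR estimates."""

    pooled_log_hr: float
    se: float
    ci_lo: float
    ci_hi: float
    tau2: float
    q_stat: float
    q_df: int
    q_pvalue: float
    i2_percent: float
    k: int

    @property
    def pooled_hr(self) -> float:
        return math.exp(self.pooled_log_hr)

    @property
    def hr_ci(self) -> tuple[float, float]:
        return (math.exp(self.ci_lo), math.exp(self.ci_hi))


def pool_random_effects(estimates: Sequence[EffectEstimate]) -> PooledEffect:
    """Pool log-HR estimates with the DerSimonian-Laird moment estimator.

    Fixed-effect weights w_i = 1/se_i^2 give Q = sum w_i (y_i - yhat_FE)^2;
    tau^2 = max(0, (Q - df) / (sum w - sum w^2 / sum w)); random-effects
    weights 1/(se_i^2 + tau^2) give the pooled effect, its SE, and a
    normal-quantile 95% CI. Q's p-value is chi-square with df = k - 1.
    """
    if len(estimates) < 2:
        raise InsufficientDataError(f"need >=2 estimates to pool, got {len(estimates)}")
    y = np.array([e.log_hr for e in estimates], dtype=float)
    se = np.array([e.se for e in estimates], dtype=float)
    if np.any(se <= 0):
        raise ValidationError("all estimates must have se > 0 for pooling")

    w = 1.0 / se**2
    y_fe = np.sum(w * y) / np.sum(w)
    q = float(np.sum(w * (y - y_fe) ** 2))
    df = len(y) - 1
    denom = np.sum(w) - np.sum(w**2) / np.sum(w)
    tau2 = max(0.0, (q - df) / denom) if denom > 0 else 0.0

    w_re = 1.0 / (se**2 + tau2)
    pooled = float(np.sum(w_re * y) / np.sum(w_re))
    se_pooled = float(1.0 / math.sqrt(np.sum(w_re)))
    i2 = max(0.0, (q - df) / q) * 100.0 if q > 0 else 0.0
    return PooledEffect(
        pooled_log_hr=pooled,
        se=se_pooled,
        ci_lo=pooled - Z95 * se_pooled,
        ci_hi=pooled + Z95 * se_pooled,
        tau2=float(tau2),
        q_stat=q,
        q_df=df,
        q_pvalue=float(stats.chi2.sf(q, df)),
        i2_percent=float(i2),
        k=len(y),
    )


def pool_by_stratum(
    ds: Dataset,
    endpoint: str,
    subgroup: str,
    treatment_class: str = "all",
) -> PooledEffect:
    """Pool one endpoint's log-HRs over the comparisons of a stratum."""
    sub = ds.filter(subgroup, treatment_class)
    if len(sub) < 2:
        raise InsufficientDataError(
            f"stratum {subgroup}/{treatment_class} has {len(sub)} comparison(s); need >=2"
        )
    return pool_random_effects([r.effect(endpoint) for r in sub])


def pooled_table(ds: Dataset):
    """Tidy per-stratum pooled-effect table (both endpoints, HR scale).

    One row per (subgroup, treatment class incl. "all", endpoint); the
    forest-plot summary panels in tabular form.
    """
    import pandas as pd

    rows = []
    for subgroup in ("overall", "male", "female"):
        for tclass in ("all", "ici_alone", "ici_chemo"):
            for endpoint in ("os", "pfs"):
                p = pool_by_stratum(ds, endpoint, subgroup, tclass)
                rows.append(
                    {
                        "subgroup": subgroup,
                        "treatment_class": tclass,
                        "endpoint": endpoint,
                        "k": p.k,
                        "pooled_hr": p.pooled_hr,
                        "hr_ci_lo": p.hr_ci[0],
                        "hr_ci_hi": p.hr_ci[1],
                        "tau2": p.tau2,
                        "q_stat": p.q_stat,
                        "q_pvalue": p.q_pvalue,
                        "i2_percent": p.i2_percent,
                    }
                )
    return pd.DataFrame(rows)
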