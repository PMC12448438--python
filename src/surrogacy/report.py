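"""End-to-end reproduction pipeline: every stratum-level result in one report.

The default report mirrors the published analysis set: ten surrogacy rows —
ITT and each sex with and without treatment-class adjustment, plus the four
sex x treatment-type strata — each carrying the weighted fit, bootstrap R^2
CI, leave-one-out cross-validated R^2, slope test, and surrogate threshold
effect, alongside a pooled-effects table for the forest-plot panels.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .pooling import pooled_table
from .regression import (
    InsufficientComparisonsError,
    bootstrap_r2_ci,
    fit_surrogacy,
    loocv_r2,
    slope_test,
)
from .ste import band_grid, compute_ste
from .trial_data import Dataset, fixture_table1, load_comparisons

__all__ = ["AnalysisConfig", "DEFAULT_STRATA", "run_full_analysis", "export_plot_data"]

logger = logging.getLogger("surrogacy")

#: (subgroup, treatment_class, adjust_for_treatment) for the ten headline rows.
DEFAULT_STRATA: tuple[tuple[str, str, bool], ...] = (
    ("overall", "all", False),
    ("overall", "all", True),
    ("male", "all", False),
    ("male", "all", True),
    ("female", "all", False),
    ("female", "all", True),
    ("male", "ici_alone", False),
    ("female", "ici_alone", False),
    ("male", "ici_chemo", False),
    ("female", "ici_chemo", False),
)

SCHEMA_VERSION = "1"


@dataclass(frozen=True)
class AnalysisConfig:
    """Configuration of a full analysis run."""

    input: str = "fixture"  # "fixture" or a comparison-CSV path
    strata: tuple[tuple[str, str, bool], ...] = DEFAULT_STRATA
    n_boot: int = 1000
    seed: int = 20250820
    future_n: float | None = None  # None -> mean N of each stratum
    out_dir: str | None = None

    def load(self) -> Dataset:
        if self.input == "fixture":
            return fixture_table1()
        return load_comparisons(self.input)


def _stratum_seed(seed: int, index: int) -> int:
    return int(np.random.SeedSequence([seed, index]).generate_state(1)[0] % (2**31))


def _analyze_stratum(ds: Dataset, subgroup: str, tclass: str, adjust: bool, cfg: AnalysisConfig, index: int) -> dict:
    fit = fit_surrogacy(ds, subgroup, tclass, adjust_for_treatment=adjust)
    row = fit.to_dict()
    row["headline_r2"] = fit.headline_r2

    t_stat, p, sig = slope_test(fit)
    row["slope_t"] = t_stat
    row["slope_significant"] = sig

    if cfg.n_boot > 0:
        lo, hi = bootstrap_r2_ci(
            ds, subgroup, tclass, adjust_for_treatment=adjust,
            n_boot=cfg.n_boot, seed=_stratum_seed(cfg.seed, index),
        )
        row["r2_ci_lo"], row["r2_ci_hi"] = lo, hi
    else:
        row["r2_ci_lo"] = row["r2_ci_hi"] = None

    try:
        cv = loocv_r2(ds, subgroup, tclass, adjust_for_treatment=adjust)
        row["cv_r2"] = cv.cv_r2
        row["cv_model_spec"] = cv.model_spec
    except InsufficientComparisonsError as exc:
        row["cv_r2"] = None
        row["cv_model_spec"] = f"unavailable: {exc}"

    ste = compute_ste(fit, future_trial_n=cfg.future_n)
    row["ste_hr"] = ste.ste_hr
    row["ste_estimable"] = ste.estimable
    row["ste_future_trial_n"] = ste.future_trial_n
    return row


def run_full_analysis(config: AnalysisConfig) -> dict:
    """Run every configured stratum and return (and optionally write) a report.

    Stratum failures are recorded per stratum without aborting the others;
    the report's ``n_failed`` counts them. With ``out_dir`` set, writes
    ``report.json`` plus tidy CSVs (surrogacy_table.csv, pooled_effects.csv,
    ste_table.csv). Output is byte-stable for identical configs.
    """
    ds = config.load()
    rows: list[dict] = []
    n_failed = 0
    for i, (subgroup, tclass, adjust) in enumerate(config.strata):
        try:
            row = _analyze_stratum(ds, subgroup, tclass, adjust, config, i)
        except Exception as exc:  # per-stratum isolation
            logger.warning("stratum %s/%s failed: %s", subgroup, tclass, exc)
            row = {
                "subgroup": subgroup,
                "treatment_class": tclass,
                "adjusted": adjust,
                "error": str(exc),
            }
            n_failed += 1
        rows.append(row)

    pooled = pooled_table(ds)
    report = {
        "schema_version": SCHEMA_VERSION,
        "package_version": __version__,
        "seed": config.seed,
        "n_boot": config.n_boot,
        "input": config.input,
        "n_records": len(ds),
        "n_failed": n_failed,
        "strata": rows,
        "pooled_effects": pooled.to_dict(orient="records"),
    }

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        pd.DataFrame(rows).to_csv(out / "surrogacy_table.csv", index=False, float_format="%.4f")
        pooled.to_csv(out / "pooled_effects.csv", index=False, float_format="%.4f")
        ste_rows = [
            {
                "subgroup": r.get("subgroup"),
                "treatment_class": r.get("treatment_class"),
                "adjusted": r.get("adjusted"),
                "future_trial_n": r.get("ste_future_trial_n"),
                "ste_hr": (
                    "n.e." if r.get("ste_estimable") is False else r.get("ste_hr")
                ),
            }
            for r in rows
        ]
        pd.DataFrame(ste_rows).to_csv(out / "ste_table.csv", index=False, float_format="%.4f")
    return report


def export_plot_data(
    config: AnalysisConfig,
    strata: tuple[tuple[str, str, bool], ...] | None = None,
    n_grid: int = 101,
) -> dict:
    """Scatter points, fitted line, band bounds and STE marker per stratum.

    Defaults to the four sex x treatment panels of the published correlation
    figure. Returns {label: {"points": DataFrame, "band": DataFrame,
    "ste_hr": float | None}}; with ``out_dir`` set in the config the tables
    are written as CSVs.
    """
    if strata is None:
        strata = (
            ("male", "ici_alone", False),
            ("female", "ici_alone", False),
            ("male", "ici_chemo", False),
            ("female", "ici_chemo", False),
        )
    ds = config.load()
    out: dict = {}
    for subgroup, tclass, adjust in strata:
        fit = fit_surrogacy(ds, subgroup, tclass, adjust_for_treatment=adjust)
        points = pd.DataFrame(
            {
                "comparison_id": list(fit.comparison_ids),
                "ln_pfs_hr": fit.x,
                "ln_os_hr": fit.y,
                "weight": fit.weights_used,
            }
        )
        band = band_grid(fit, n_points=n_grid, future_trial_n=config.future_n)
        ste = compute_ste(fit, future_trial_n=config.future_n)
        label = f"{subgroup}_{tclass}_{'adj' if adjust else 'unadj'}"
        out[label] = {"points": points, "band": band, "ste_hr": ste.ste_hr}
        if config.out_dir is not None:
            d = Path(config.out_dir)
            d.mkdir(parents=True, exist_ok=True)
            points.to_csv(d / f"points_{label}.csv", index=False)
            band.to_csv(d / f"band_{label}.csv", index=False)
    return out
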