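"""Aggregate comparison-level trial data: records, CSV I/O, and the packaged dataset.

The unit of analysis throughout the package is the *pairwise comparison*
(experimental vs control arm) within a subgroup, not the trial: a three-arm
trial contributes two comparisons whose shared control arm is recorded as
metadata (``shares_control_with``) but not otherwise adjusted for.

Each comparison carries hazard ratios (HR) with 95% confidence intervals for
two time-to-event endpoints — overall survival (OS) and progression-free
survival (PFS) — plus the number of randomized patients, which downstream
regression uses as a precision weight.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd

__all__ = [
    "SUBGROUPS",
    "TREATMENT_CLASSES",
    "CSV_COLUMNS",
    "Z95",
    "ComparisonRecord",
    "EffectEstimate",
    "Dataset",
    "SchemaError",
    "ValidationError",
    "effect_from_ci",
    "load_comparisons",
    "write_comparisons",
    "fixture_table1",
]

SUBGROUPS = ("overall", "male", "female")
TREATMENT_CLASSES = ("ici_alone", "ici_chemo")

#: Exact required CSV header, in order.
CSV_COLUMNS = (
    "trial_id",
    "comparison_id",
    "subgroup",
    "treatment_class",
    "n_randomized",
    "hr_os",
    "hr_os_lo",
    "hr_os_hi",
    "hr_pfs",
    "hr_pfs_lo",
    "hr_pfs_hi",
    "shares_control_with",
)

#: 97.5% normal quantile used for every CI <-> SE conversion.
Z95 = 1.959964


class SchemaError(ValueError):
    """The input file does not match the required comparison CSV schema."""


class ValidationError(ValueError):
    """A record violates a domain invariant (non-positive HR, inverted CI, ...)."""


@dataclass(frozen=True)
class EffectEstimate:
    """A log hazard ratio with its standard error.

    ``se`` is reconstructed from the reported 95% CI assuming normality of the
    log-HR; it is zero only for a degenerate (point) interval.
    """

    log_hr: float
    se: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.log_hr):
            raise ValidationError(f"log_hr must be finite, got {self.log_hr}")
        if not (self.se >= 0.0):
            raise ValidationError(f"se must be >= 0, got {self.se}")


def effect_from_ci(hr: float, lo: float, hi: float) -> EffectEstimate:
    """Convert a hazard ratio and its 95% CI to a log-scale estimate with SE.

    se = (ln hi - ln lo) / (2 * 1.959964), the standard reconstruction for a
    symmetric normal interval on the log scale.

    Raises :class:`ValidationError` unless 0 < lo <= hr <= hi.
    """
    if not (0.0 < lo <= hr <= hi):
        raise ValidationError(
            f"require 0 < lo <= hr <= hi, got hr={hr}, lo={lo}, hi={hi}"
        )
    return EffectEstimate(log_hr=math.log(hr), se=(math.log(hi) - math.log(lo)) / (2.0 * Z95))


@dataclass(frozen=True)
class ComparisonRecord:
    """One randomized pairwise comparison in one subgroup (overall/male/female)."""

    trial_id: str
    comparison_id: str
    subgroup: str
    treatment_class: str
    n_randomized: int
    hr_os: float
    hr_os_lo: float
    hr_os_hi: float
    hr_pfs: float
    hr_pfs_lo: float
    hr_pfs_hi: float
    shares_control_with: str | None = None

    def __post_init__(self) -> None:
        if self.subgroup not in SUBGROUPS:
            raise ValidationError(
                f"{self.comparison_id}: subgroup {self.subgroup!r} not in {SUBGROUPS}"
            )
        if self.treatment_class not in TREATMENT_CLASSES:
            raise ValidationError(
                f"{self.comparison_id}: treatment_class {self.treatment_class!r} "
                f"not in {TREATMENT_CLASSES}"
            )
        if not (isinstance(self.n_randomized, int) and self.n_randomized >= 1):
            raise ValidationError(
                f"{self.comparison_id}: n_randomized must be a positive integer, "
                f"got {self.n_randomized!r}"
            )
        for endpoint in ("os", "pfs"):
            hr = getattr(self, f"hr_{endpoint}")
            lo = getattr(self, f"hr_{endpoint}_lo")
            hi = getattr(self, f"hr_{endpoint}_hi")
            if not (0.0 < lo <= hr <= hi):
                raise ValidationError(
                    f"{self.comparison_id}/{self.subgroup}: {endpoint.upper()}-HR CI "
                    f"must satisfy 0 < lo <= hr <= hi, got {hr} ({lo} to {hi})"
                )

    def effect(self, endpoint: str) -> EffectEstimate:
        """Log-HR effect estimate for ``endpoint`` in {"os", "pfs"}."""
        if endpoint not in ("os", "pfs"):
            raise ValueError(f"endpoint must be 'os' or 'pfs', got {endpoint!r}")
        return effect_from_ci(
            getattr(self, f"hr_{endpoint}"),
            getattr(self, f"hr_{endpoint}_lo"),
            getattr(self, f"hr_{endpoint}_hi"),
        )


@dataclass(frozen=True)
class Dataset:
    """An ordered collection of :class:`ComparisonRecord` with a provenance label."""

    records: tuple[ComparisonRecord, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        keys = [(r.trial_id, r.comparison_id, r.subgroup) for r in self.records]
        if len(set(keys)) != len(keys):
            dupes = sorted({k for k in keys if keys.count(k) > 1})
            raise ValidationError(f"duplicate (trial, comparison, subgroup) keys: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ComparisonRecord]:
        return iter(self.records)

    def filter(self, subgroup: str, treatment_class: str = "all") -> "Dataset":
        """Records for one subgroup, optionally restricted to one treatment class."""
        if subgroup not in SUBGROUPS:
            raise ValueError(f"subgroup must be one of {SUBGROUPS}, got {subgroup!r}")
        if treatment_class != "all" and treatment_class not in TREATMENT_CLASSES:
            raise ValueError(
                f"treatment_class must be 'all' or one of {TREATMENT_CLASSES}, "
                f"got {treatment_class!r}"
            )
        recs = tuple(
            r
            for r in self.records
            if r.subgroup == subgroup
            and (treatment_class == "all" or r.treatment_class == treatment_class)
        )
        label = f"{self.provenance}[{subgroup}/{treatment_class}]"
        return Dataset(records=recs, provenance=label)

    def to_frame(self) -> pd.DataFrame:
        """Tidy DataFrame with one row per record, in the CSV column order."""
        rows = [
            {c: getattr(r, c) if c != "shares_control_with" else (r.shares_control_with or "")
             for c in CSV_COLUMNS}
            for r in self.records
        ]
        return pd.DataFrame(rows, columns=list(CSV_COLUMNS))


def _record_from_row(row: pd.Series, line_no: int) -> ComparisonRecord:
    try:
        shares = row["shares_control_with"]
        shares = None if (pd.isna(shares) or str(shares).strip() == "") else str(shares)
        return ComparisonRecord(
            trial_id=str(row["trial_id"]),
            comparison_id=str(row["comparison_id"]),
            subgroup=str(row["subgroup"]),
            treatment_class=str(row["treatment_class"]),
            n_randomized=int(row["n_randomized"]),
            hr_os=float(row["hr_os"]),
            hr_os_lo=float(row["hr_os_lo"]),
            hr_os_hi=float(row["hr_os_hi"]),
            hr_pfs=float(row["hr_pfs"]),
            hr_pfs_lo=float(row["hr_pfs_lo"]),
            hr_pfs_hi=float(row["hr_pfs_hi"]),
            shares_control_with=shares,
        )
    except (ValidationError, ValueError, TypeError) as exc:
        raise ValidationError(f"row {line_no}: {exc}") from exc


def load_comparisons(path: str | Path, provenance: str | None = None) -> Dataset:
    """Read a comparison CSV into a :class:`Dataset`.

    The header must contain exactly the columns of :data:`CSV_COLUMNS`.
    Loading is atomic: any invalid row aborts the whole load with a
    :class:`ValidationError` naming the offending row.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False, na_values=[""])
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    extra = [c for c in df.columns if c not in CSV_COLUMNS]
    if extra:
        raise SchemaError(f"{path}: unexpected column(s) {extra}")
    records = [
        _record_from_row(row, line_no=i + 2)  # header is line 1
        for i, (_, row) in enumerate(df.iterrows())
    ]
    return Dataset(records=tuple(records), provenance=provenance or str(path))


def write_comparisons(ds: Dataset, path: str | Path) -> None:
    """Write a Dataset to CSV in the canonical schema (UTF-8, full precision)."""
    df = ds.to_frame()
    # repr-roundtrip precision for the HR columns
    df.to_csv(path, index=False, float_format="%.17g")


def fixture_table1() -> Dataset:
    """The packaged analysis dataset: 21 randomized comparisons x 3 subgroups.

    Twenty phase 2/3 trials of PD-(L)1 inhibitors (alone or with chemotherapy)
    in advanced NSCLC; one three-arm trial (JAVELIN Lung 100) contributes two
    comparisons sharing a control arm. HRs are stored exactly as published
    (two decimals); 11 comparisons test ICI alone and 10 ICI plus chemotherapy.
    """
    with resources.as_file(
        resources.files("surrogacy.data").joinpath("table1_comparisons.csv")
    ) as p:
        return load_comparisons(p, provenance="table1")
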