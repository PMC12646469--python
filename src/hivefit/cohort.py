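"""Patient cohort container, delimited-text I/O, schema validation, and the
active-ingredient binarization operator.

The cohort schema mirrors the modified clinical dataset used throughout the
package: 20 binary supplement/lifestyle/clinical indicators, an integer oocyte
count, integer age, and a binary embryo-transfer outcome. Column order is part
of the on-disk contract because feature masks downstream are index-based.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical predictor order. Masks produced by the selection stages index
#: into this list, so the order is frozen.
FEATURE_ORDER: tuple[str, ...] = (
    "working_status",
    "diagnosed_illness",
    "dha",
    "omega3",
    "folic_acid",
    "coq10",
    "vit_b12",
    "ferritin",
    "vit_c",
    "vit_b6",
    "vit_b5",
    "vit_d",
    "phytoalexin",
    "magnesium",
    "selenium",
    "zinc",
    "melatonin",
    "exercise",
    "oocyte_count",
    "embryo_quality",
    "dietician_support",
    "age",
)

OUTCOME_NAME = "transfer_state"

#: Predictors constrained to {0, 1}. The outcome is binary as well.
BINARY_FEATURES: tuple[str, ...] = tuple(
    f for f in FEATURE_ORDER if f not in ("oocyte_count", "age")
)

DEFAULT_AGE_RANGE = (18, 60)


class SchemaError(ValueError):
    """A cohort file does not match the expected column schema."""


class CohortValidationError(ValueError):
    """A cohort value violates a patient-record invariant."""


@dataclass
class RDIEntry:
    """Daily requirement for one active ingredient."""

    ingredient: str
    daily_requirement: float
    unit: str

    def __post_init__(self) -> None:
        if self.daily_requirement <= 0:
            raise ValueError(
                f"daily_requirement must be positive for {self.ingredient!r}"
            )


@dataclass
class IntakeRecord:
    """One product taken daily by one patient, with per-ingredient amounts."""

    patient_id: str
    product: str
    ingredient_amounts: dict[str, float]
    unit: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for ing, amt in self.ingredient_amounts.items():
            if amt < 0:
                raise ValueError(
                    f"negative intake amount for {ing!r} (patient {self.patient_id})"
                )


@dataclass
class ValidationReport:
    violations: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations


class CohortTable:
    """Validated patient-by-feature matrix with a binary outcome column.

    Parameters
    ----------
    frame : DataFrame with columns ``FEATURE_ORDER + (OUTCOME_NAME,)``.
    provenance : free-text note recording where the cohort came from.
    """

    def __init__(self, frame: pd.DataFrame, provenance: str = "") -> None:
        missing = [c for c in FEATURE_ORDER + (OUTCOME_NAME,) if c not in frame.columns]
        if missing:
            raise SchemaError(f"cohort frame missing columns: {missing}")
        self.frame = frame.loc[:, list(FEATURE_ORDER) + [OUTCOME_NAME]].reset_index(
            drop=True
        )
        self.provenance = provenance

    # ------------------------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.frame)

    @property
    def p(self) -> int:
        return len(FEATURE_ORDER)

    @property
    def feature_names(self) -> tuple[str, ...]:
        return FEATURE_ORDER

    @property
    def X(self) -> np.ndarray:
        return self.frame.loc[:, list(FEATURE_ORDER)].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return self.frame[OUTCOME_NAME].to_numpy(dtype=int)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        prev = float(self.frame[OUTCOME_NAME].mean()) if self.n else float("nan")
        return f"CohortTable(n={self.n}, p={self.p}, outcome_prevalence={prev:.3f})"


# ----------------------------------------------------------------------
# I/O
# ----------------------------------------------------------------------

def _normalize(name: str) -> str:
    return name.strip().lower().replace(" ", "_").replace("-", "_")


def read_cohort(path, schema: tuple[str, ...] | None = None) -> CohortTable:
    """Read a cohort CSV (UTF-8, header row) into a validated :class:`CohortTable`.

    Header names are matched case/space-insensitively against ``schema``
    (default: the canonical feature order plus the outcome). Row order is
    preserved. Binary columns are checked strictly for {0, 1}.
    """
    expected = list(schema) if schema is not None else list(FEATURE_ORDER) + [
        OUTCOME_NAME
    ]
    df = pd.read_csv(path)
    rename = {}
    normalized = {_normalize(c): c for c in df.columns}
    for col in expected:
        key = _normalize(col)
        if key not in normalized:
            raise SchemaError(f"missing column {col!r} in {path}")
        rename[normalized[key]] = col
    df = df.rename(columns=rename).loc[:, expected]

    for col in BINARY_FEATURES + (OUTCOME_NAME,):
        if col not in df.columns:
            continue
        vals = df[col]
        bad = ~vals.isin([0, 1])
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise CohortValidationError(
                f"non-binary value {vals.iloc[row]!r} in binary column {col!r} "
                f"at row {row}"
            )
    if df.isna().any().any():
        col = df.columns[df.isna().any().to_numpy()][0]
        row = int(df[col].isna().to_numpy().argmax())
        raise CohortValidationError(f"missing value in column {col!r} at row {row}")

    cohort = CohortTable(df, provenance=f"read from {path}")
    prev = float(cohort.frame[OUTCOME_NAME].mean()) if cohort.n else float("nan")
    logger.info(
        "read cohort: n=%d p=%d outcome prevalence=%.3f", cohort.n, cohort.p, prev
    )
    return cohort


def write_cohort(cohort: CohortTable, path) -> None:
    """Write the cohort to CSV in the canonical column order."""
    out = cohort.frame.copy()
    for col in BINARY_FEATURES + (OUTCOME_NAME, "oocyte_count", "age"):
        out[col] = out[col].astype(int)
    out.to_csv(path, index=False)


# ----------------------------------------------------------------------
# Validation and summaries
# ----------------------------------------------------------------------

def validate_cohort(
    cohort: CohortTable, age_range: tuple[int, int] = DEFAULT_AGE_RANGE
) -> ValidationReport:
    """Report-only check of patient-record invariants.

    Binary fields must lie in {0, 1}; oocyte counts must be non-negative;
    age must fall in ``age_range``. A single-class outcome is flagged as a
    warning because descriptive use is still legal, but no model can be fit.
    """
    report = ValidationReport()
    df = cohort.frame
    for col in BINARY_FEATURES + (OUTCOME_NAME,):
        bad = ~df[col].isin([0, 1])
        for row in np.flatnonzero(bad.to_numpy()):
            report.violations.append(
                f"row {row}: {col} = {df[col].iloc[row]!r} not in {{0,1}}"
            )
    for row in np.flatnonzero((df["oocyte_count"] < 0).to_numpy()):
        report.violations.append(
            f"row {row}: oocyte_count = {df['oocyte_count'].iloc[row]} < 0"
        )
    lo, hi = age_range
    out_of_range = (df["age"] < lo) | (df["age"] > hi)
    for row in np.flatnonzero(out_of_range.to_numpy()):
        report.violations.append(
            f"row {row}: age = {df['age'].iloc[row]} outside [{lo}, {hi}]"
        )
    if cohort.n and df[OUTCOME_NAME].nunique() < 2:
        report.warnings.append("single-class outcome: modelling operations will fail")
    return report


def summarize_cohort(cohort: CohortTable) -> pd.DataFrame:
    """Per-feature mean, SD, min, max (one row per feature plus the outcome).

    SD uses the sample (n-1) convention, reported as 0 for n = 1.
    For binary columns the mean is exactly the class proportion.
    """
    if cohort.n == 0:
        raise ValueError("cannot summarize an empty cohort")
    df = cohort.frame
    rows = []
    for col in list(FEATURE_ORDER) + [OUTCOME_NAME]:
        vals = df[col].to_numpy(dtype=float)
        sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
        rows.append(
            {
                "parameter": col,
                "mean": float(vals.mean()),
                "sd": sd,
                "min": float(vals.min()),
                "max": float(vals.max()),
            }
        )
    return pd.DataFrame(rows).set_index("parameter")


# ----------------------------------------------------------------------
# Active-ingredient binarization
# ----------------------------------------------------------------------

def read_rdi_table(path) -> list[RDIEntry]:
    df = pd.read_csv(path)
    entries = [
        RDIEntry(str(r.ingredient), float(r.daily_requirement), str(r.unit))
        for r in df.itertuples()
    ]
    names = [e.ingredient for e in entries]
    if len(set(names)) != len(names):
        raise ValueError("duplicate ingredient identifiers in RDI table")
    return entries


def read_intake_records(path) -> list[IntakeRecord]:
    """Read long-format intake CSV (patient_id, product, ingredient, amount, unit)."""
    df = pd.read_csv(path)
    records: dict[tuple[str, str], IntakeRecord] = {}
    for r in df.itertuples():
        key = (str(r.patient_id), str(r.product))
        rec = records.setdefault(
            key, IntakeRecord(str(r.patient_id), str(r.product), {}, {})
        )
        rec.ingredient_amounts[str(r.ingredient)] = float(r.amount)
        rec.unit[str(r.ingredient)] = str(r.unit)
    return list(records.values())


def binarize_intakes(
    intakes: list[IntakeRecord],
    rdi: list[RDIEntry],
    policy: str = "sum_across_products",
) -> dict[str, dict[str, int]]:
    """Map per-patient product intakes to per-ingredient binary flags.

    A flag is 1 iff the patient's total daily amount of the ingredient reaches
    100% of the daily requirement. Under the default ``sum_across_products``
    policy amounts are summed over all of the patient's products before
    thresholding (monotone: adding a record can only turn flags on); under
    ``per_product`` at least one single product must meet the requirement on
    its own.

    Unknown ingredients are excluded with a warning; a unit mismatch against
    the requirement table is an error.
    """
    if policy not in ("sum_across_products", "per_product"):
        raise ValueError(f"unknown policy {policy!r}")
    rdi_map = {e.ingredient: e for e in rdi}

    patients = sorted({rec.patient_id for rec in intakes})
    flags: dict[str, dict[str, int]] = {
        pid: {ing: 0 for ing in rdi_map} for pid in patients
    }
    totals: dict[str, dict[str, float]] = {
        pid: {ing: 0.0 for ing in rdi_map} for pid in patients
    }

    for rec in intakes:
        for ing, amount in rec.ingredient_amounts.items():
            if ing not in rdi_map:
                warnings.warn(
                    f"unknown ingredient {ing!r} in product {rec.product!r} "
                    f"(patient {rec.patient_id}); excluded",
                    stacklevel=2,
                )
                continue
            entry = rdi_map[ing]
            unit = rec.unit.get(ing, entry.unit)
            if unit != entry.unit:
                raise ValueError(
                    f"unit mismatch for ingredient {ing!r}: intake in {unit!r}, "
                    f"requirement in {entry.unit!r}"
                )
            if policy == "per_product":
                if amount >= entry.daily_requirement:
                    flags[rec.patient_id][ing] = 1
            else:
                totals[rec.patient_id][ing] += amount

    if policy == "sum_across_products":
        for pid in patients:
            for ing, entry in rdi_map.items():
                if totals[pid][ing] >= entry.daily_requirement:
                    flags[pid][ing] = 1
    return flags
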