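"""Patient-level data schema for EIP audit cohorts.

One row per audited patient: demographics (gender, age, broad ONS ethnicity
category), the uptake status of each audited treatment or physical-health
intervention, and HoNOS item 6 ("problems associated with hallucinations and
delusions", scored 0-4) at an initial and a follow-up assessment.  Outcome
change is follow-up minus initial; negative change is an improvement.

The module owns the CSV schema, the category encoders, the two-stage
exclusion pipeline (adults only; both assessments recorded) and the post-
exclusion chi-square demographic balance check.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml
from scipy import stats

logger = logging.getLogger("equity_audit")

__all__ = [
    "Gender",
    "Ethnicity",
    "UptakeStatus",
    "AgeGroup",
    "DEFAULT_TREATMENTS",
    "PatientRecord",
    "ExclusionStage",
    "CohortTable",
    "ChiSquareResult",
    "SchemaConfig",
    "SchemaError",
    "RowParseError",
    "DegenerateTableError",
    "SUPPRESSION_THRESHOLD",
    "encode_age_group",
    "encode_age_groups",
    "binarise_uptake",
    "read_cohort",
    "write_cohort",
    "apply_exclusions",
    "balance_check",
    "exclusion_log_frame",
]

#: Reported cells with fewer members than this are masked (statistical
#: disclosure floor; the low-count suppression rule for summary tables).
SUPPRESSION_THRESHOLD = 10


class Gender(str, Enum):
    FEMALE = "Female"
    MALE = "Male"
    NON_BINARY_OTHER = "Non-binary/other"


class Ethnicity(str, Enum):
    """Broad ONS ethnic groups plus the two non-response codes."""

    ASIAN = "Asian or Asian British"
    BLACK = "Black or Black British"
    MIXED = "Mixed"
    OTHER = "Other"
    WHITE = "White"
    REFUSED = "Refused"
    UNKNOWN = "Unknown/undocumented"


class UptakeStatus(str, Enum):
    TAKEN_UP = "taken_up"
    REFUSED = "refused"
    WAITING = "waiting"
    NOT_OFFERED = "not_offered"
    NOT_ELIGIBLE = "not_eligible"
    UNKNOWN = "unknown"


class AgeGroup(str, Enum):
    A18_24 = "18-24"
    A25_34 = "25-34"
    A35_44 = "35-44"
    A45_54 = "45-54"
    A55_69 = "55-69"


#: Audited treatments and physical-health interventions.  Closed enumeration;
#: extensible only through SchemaConfig / GeneratorConfig.
DEFAULT_TREATMENTS: tuple[str, ...] = (
    "CBTp",
    "FamilyIntervention",
    "Antipsychotic",
    "Clozapine",
    "SupportedEmployment",
    "CarerIntervention",
    "Smoking",
    "Alcohol",
    "SubstanceMisuse",
    "WeightGain",
    "Hypertension",
    "Diabetes",
    "Dyslipidaemia",
)

DEMOGRAPHIC_VARIABLES: tuple[str, ...] = ("gender", "ethnicity", "age_group")

_GENDER_VALUES = {g.value for g in Gender}
_ETHNICITY_VALUES = {e.value for e in Ethnicity}
_UPTAKE_VALUES = {u.value for u in UptakeStatus}

# Fallback level for unparseable category labels, per variable.  Gender has no
# unknown-style level, so unparseable genders join the (suppressed-from-
# reports) Non-binary/other group.
_CATEGORY_FALLBACK = {
    "gender": Gender.NON_BINARY_OTHER.value,
    "ethnicity": Ethnicity.UNKNOWN.value,
    "uptake": UptakeStatus.UNKNOWN.value,
}


class SchemaError(ValueError):
    """A mandatory column is missing or the schema config is malformed."""


class RowParseError(ValueError):
    """A data row holds a token that cannot be parsed (row number reported)."""


class DegenerateTableError(ValueError):
    """Fewer than two retained categories in a contingency table."""


def encode_age_group(age: int) -> AgeGroup:
    """Map an adult age in years onto the audit age bands.

    Bands are 18-24, 25-34, 35-44, 45-54 and 55-69 with the top band open
    ended (patients older than 69 are grouped with the 55-and-over band, the
    same way the audit groups its few over-64s).
    """
    if age < 18:
        raise ValueError(f"age {age} is below 18; under-18s must be excluded first")
    if age <= 24:
        return AgeGroup.A18_24
    if age <= 34:
        return AgeGroup.A25_34
    if age <= 44:
        return AgeGroup.A35_44
    if age <= 54:
        return AgeGroup.A45_54
    return AgeGroup.A55_69


def encode_age_groups(ages: Iterable[int]) -> pd.Series:
    """Vectorised :func:`encode_age_group`; returns band labels as strings."""
    arr = np.asarray(list(ages) if not isinstance(ages, (pd.Series, np.ndarray)) else ages)
    if (arr < 18).any():
        bad = int(arr[arr < 18][0])
        raise ValueError(f"age {bad} is below 18; under-18s must be excluded first")
    bins = [18, 25, 35, 45, 55, np.inf]
    labels = [g.value for g in AgeGroup]
    out = pd.cut(arr, bins=bins, labels=labels, right=False)
    return pd.Series(out.astype(str), name="age_group")


def binarise_uptake(status: UptakeStatus | str) -> int:
    """Dichotomise an uptake status: taken up -> 1, everything else -> 0.

    'Everything else' covers refused, waiting, not offered, not eligible and
    unknown; waiting sits in the 0 class (configurable nowhere else in the
    analysis, see docs/methods.md).
    """
    status = UptakeStatus(status)
    return 1 if status is UptakeStatus.TAKEN_UP else 0


@dataclass(frozen=True)
class PatientRecord:
    """A single audited patient."""

    patient_id: str
    age: int
    gender: str
    ethnicity: str
    uptake: Mapping[str, str]
    honos6_initial: int | None
    honos6_followup: int | None

    def __post_init__(self) -> None:
        if self.age < 0:
            raise ValueError("age must be non-negative")
        for score in (self.honos6_initial, self.honos6_followup):
            if score is not None and score not in (0, 1, 2, 3, 4):
                raise ValueError(f"HoNOS item 6 score {score!r} outside 0-4")
        Gender(self.gender)
        Ethnicity(self.ethnicity)
        for status in self.uptake.values():
            UptakeStatus(status)


@dataclass(frozen=True)
class ExclusionStage:
    stage_name: str
    n_before: int
    n_excluded: int
    n_after: int

    def __post_init__(self) -> None:
        if self.n_after != self.n_before - self.n_excluded:
            raise ValueError("inconsistent exclusion stage counts")


@dataclass
class CohortTable:
    """An ordered cohort of patients plus the provenance of applied exclusions.

    Backed by a DataFrame with columns ``patient_id, age, gender, ethnicity,
    honos6_initial, honos6_followup`` and one ``uptake_<treatment>`` column of
    fine uptake-status labels per configured treatment.
    """

    df: pd.DataFrame
    treatments: tuple[str, ...] = DEFAULT_TREATMENTS
    exclusion_log: list[ExclusionStage] = field(default_factory=list)

    def __post_init__(self) -> None:
        required = ["patient_id", "age", "gender", "ethnicity", "honos6_initial", "honos6_followup"]
        required += [f"uptake_{t}" for t in self.treatments]
        missing = [c for c in required if c not in self.df.columns]
        if missing:
            raise SchemaError(f"cohort frame missing columns: {missing}")
        # chained stages must agree
        for prev, nxt in zip(self.exclusion_log, self.exclusion_log[1:]):
            if nxt.n_before != prev.n_after:
                raise ValueError("exclusion log stages do not chain")

    @property
    def n(self) -> int:
        return len(self.df)

    def outcome_change(self) -> pd.Series:
        """Follow-up minus initial HoNOS item 6 score (NaN when either missing)."""
        return (
            self.df["honos6_followup"].astype("float64")
            - self.df["honos6_initial"].astype("float64")
        )

    def uptake_binary(self) -> pd.DataFrame:
        """Binary taken-up indicators, one column per treatment."""
        data = {
            t: (self.df[f"uptake_{t}"] == UptakeStatus.TAKEN_UP.value).astype(np.int8)
            for t in self.treatments
        }
        return pd.DataFrame(data, index=self.df.index)

    def age_groups(self) -> pd.Series:
        out = encode_age_groups(self.df["age"].to_numpy())
        out.index = self.df.index
        return out

    def demographic_series(self, variable: str) -> pd.Series:
        if variable == "age_group":
            return self.age_groups()
        if variable in ("gender", "ethnicity"):
            return self.df[variable]
        raise ValueError(f"unknown demographic variable {variable!r}")

    def records(self) -> Iterable[PatientRecord]:
        for _, row in self.df.iterrows():
            yield PatientRecord(
                patient_id=row["patient_id"],
                age=int(row["age"]),
                gender=row["gender"],
                ethnicity=row["ethnicity"],
                uptake={t: row[f"uptake_{t}"] for t in self.treatments},
                honos6_initial=None if pd.isna(row["honos6_initial"]) else int(row["honos6_initial"]),
                honos6_followup=None if pd.isna(row["honos6_followup"]) else int(row["honos6_followup"]),
            )

    def subset(self, mask: np.ndarray | pd.Series) -> "CohortTable":
        return CohortTable(self.df.loc[mask].copy(), self.treatments, list(self.exclusion_log))


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float


@dataclass
class SchemaConfig:
    """Maps CSV columns and raw labels onto the canonical schema.

    ``columns`` maps record fields to CSV column names; ``uptake_prefix`` plus
    the treatment name gives each uptake column; the ``*_labels`` dicts map
    raw file labels (case-insensitive) to canonical enum values on top of the
    identity mapping for canonical labels themselves.
    """

    columns: dict[str, str] = field(
        default_factory=lambda: {
            "patient_id": "patient_id",
            "age": "age",
            "gender": "gender",
            "ethnicity": "ethnicity",
            "honos6_initial": "honos6_initial",
            "honos6_followup": "honos6_followup",
        }
    )
    uptake_prefix: str = "uptake_"
    treatments: tuple[str, ...] = DEFAULT_TREATMENTS
    gender_labels: dict[str, str] = field(default_factory=dict)
    ethnicity_labels: dict[str, str] = field(default_factory=dict)
    uptake_labels: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_dict(cls, d: Mapping) -> "SchemaConfig":
        cfg = cls()
        if "columns" in d:
            cfg.columns.update(d["columns"])
        if "uptake_prefix" in d:
            cfg.uptake_prefix = d["uptake_prefix"]
        if "treatments" in d:
            cfg.treatments = tuple(d["treatments"])
        for key in ("gender_labels", "ethnicity_labels", "uptake_labels"):
            if key in d:
                getattr(cfg, key).update(d[key])
        return cfg

    @classmethod
    def from_yaml(cls, path_or_stream) -> "SchemaConfig":
        if hasattr(path_or_stream, "read"):
            d = yaml.safe_load(path_or_stream)
        else:
            with open(path_or_stream) as fh:
                d = yaml.safe_load(fh)
        return cls.from_dict(d or {})


def _canonicalise(series: pd.Series, canonical: set[str], extra: Mapping[str, str],
                  kind: str, column: str) -> pd.Series:
    lut = {v.lower(): v for v in canonical}
    lut.update({k.lower(): v for k, v in extra.items()})
    raw = series.str.strip()
    mapped = raw.str.lower().map(lut)
    bad = mapped.isna()
    if bad.any():
        fallback = _CATEGORY_FALLBACK[kind]
        for label in sorted(raw[bad].unique()):
            logger.warning(
                "column %r: unparseable %s label %r mapped to %r",
                column, kind, label, fallback,
            )
        mapped = mapped.where(~bad, fallback)
    return mapped


def _parse_int_column(series: pd.Series, column: str, allow_missing: bool,
                      valid_range: tuple[int, int] | None) -> pd.Series:
    raw = series.str.strip()
    missing = raw == ""
    if missing.any() and not allow_missing:
        row = int(series.index[missing][0]) + 2  # 1-based + header
        raise RowParseError(f"row {row}: column {column!r} is empty")
    values = pd.to_numeric(raw.where(~missing, None), errors="coerce")
    bad = values.isna() & ~missing
    if bad.any():
        row = int(series.index[bad][0]) + 2
        token = raw[bad].iloc[0]
        raise RowParseError(f"row {row}: column {column!r} has non-integer token {token!r}")
    nonint = (~values.isna()) & (values != values.round())
    if nonint.any():
        row = int(series.index[nonint][0]) + 2
        raise RowParseError(f"row {row}: column {column!r} has non-integer token {raw[nonint].iloc[0]!r}")
    if valid_range is not None:
        lo, hi = valid_range
        out_of_range = (~values.isna()) & ((values < lo) | (values > hi))
        if out_of_range.any():
            row = int(series.index[out_of_range][0]) + 2
            raise RowParseError(
                f"row {row}: column {column!r} value {int(values[out_of_range].iloc[0])} outside {lo}-{hi}"
            )
    return values.astype("Int64")


def read_cohort(source, schema: SchemaConfig | None = None) -> CohortTable:
    """Read a patient-level audit table from CSV (RFC 4180, header required).

    Missing HoNOS scores are retained as missing (exclusion is a separate,
    logged step); unparseable category labels fall back to the variable's
    unknown-style level with a warning.
    """
    schema = schema or SchemaConfig()
    raw = pd.read_csv(source, dtype=str, keep_default_na=False, skipinitialspace=True)
    needed = dict(schema.columns)
    uptake_cols = {t: f"{schema.uptake_prefix}{t}" for t in schema.treatments}
    for t, col in uptake_cols.items():
        needed[f"uptake:{t}"] = col
    missing_cols = [col for col in needed.values() if col not in raw.columns]
    if missing_cols:
        raise SchemaError(f"missing mandatory column(s): {missing_cols}")

    df = pd.DataFrame(index=raw.index)
    df["patient_id"] = raw[schema.columns["patient_id"]].str.strip()
    df["age"] = _parse_int_column(raw[schema.columns["age"]], schema.columns["age"],
                                  allow_missing=False, valid_range=(0, 130)).astype("int64")
    df["gender"] = _canonicalise(raw[schema.columns["gender"]], _GENDER_VALUES,
                                 schema.gender_labels, "gender", schema.columns["gender"])
    df["ethnicity"] = _canonicalise(raw[schema.columns["ethnicity"]], _ETHNICITY_VALUES,
                                    schema.ethnicity_labels, "ethnicity", schema.columns["ethnicity"])
    for name in ("honos6_initial", "honos6_followup"):
        df[name] = _parse_int_column(raw[schema.columns[name]], schema.columns[name],
                                     allow_missing=True, valid_range=(0, 4))
    for t, col in uptake_cols.items():
        df[f"uptake_{t}"] = _canonicalise(raw[col], _UPTAKE_VALUES,
                                          schema.uptake_labels, "uptake", col)
    return CohortTable(df, tuple(schema.treatments))


def write_cohort(cohort: CohortTable, path_or_buf) -> None:
    """Write a cohort back to canonical CSV (round-trips with read_cohort)."""
    out = cohort.df.copy()
    for name in ("honos6_initial", "honos6_followup"):
        out[name] = out[name].astype("Int64").astype(str).replace("<NA>", "")
    out.to_csv(path_or_buf, index=False)


def apply_exclusions(cohort: CohortTable) -> CohortTable:
    """Apply the two study-inclusion stages, logging counts per stage.

    Stage 1 drops patients under 18; stage 2 drops patients missing either
    HoNOS item 6 assessment.  Input order is preserved, and the pipeline is
    idempotent.  A record failing both rules is excluded (and counted) at
    stage 1 only.
    """
    df = cohort.df
    log = list(cohort.exclusion_log)

    adult = df["age"] >= 18
    n0 = len(df)
    df1 = df.loc[adult]
    log.append(ExclusionStage("age>=18", n0, n0 - len(df1), len(df1)))

    complete = df1["honos6_initial"].notna() & df1["honos6_followup"].notna()
    df2 = df1.loc[complete]
    log.append(ExclusionStage("honos6_both_recorded", len(df1), len(df1) - len(df2), len(df2)))

    if len(df2) == 0:
        logger.warning("exclusion pipeline removed every record")
    return CohortTable(df2.copy(), cohort.treatments, log)


def exclusion_log_frame(cohort: CohortTable) -> pd.DataFrame:
    """Exclusion log as a table (stage, n_before, n_excluded, n_after)."""
    return pd.DataFrame(
        [(s.stage_name, s.n_before, s.n_excluded, s.n_after) for s in cohort.exclusion_log],
        columns=["stage", "n_before", "n_excluded", "n_after"],
    )


def balance_check(before: CohortTable, after: CohortTable, variable: str) -> ChiSquareResult:
    """Pearson chi-square comparison of a demographic distribution pre/post exclusion.

    Builds the categories-by-(before/after) contingency table, dropping
    categories with zero total count; df = k-1 for k retained categories.
    No continuity correction.  For ``age_group`` only patients aged 18+ enter
    (the band encoder is undefined below 18), mirroring the audit's comparison
    of the adult data-set with the filtered one.
    """
    if variable not in DEMOGRAPHIC_VARIABLES:
        raise ValueError(f"variable must be one of {DEMOGRAPHIC_VARIABLES}, got {variable!r}")
    if before.n == 0 or after.n == 0:
        raise ValueError("both cohorts must be non-empty")

    def counts(c: CohortTable) -> pd.Series:
        if variable == "age_group":
            adults = c.df["age"] >= 18
            return encode_age_groups(c.df.loc[adults, "age"].to_numpy()).value_counts()
        return c.df[variable].value_counts()

    cb, ca = counts(before), counts(after)
    cats = sorted(set(cb.index) | set(ca.index))
    table = np.array([[cb.get(k, 0), ca.get(k, 0)] for k in cats], dtype=float)
    keep = table.sum(axis=1) > 0
    table = table[keep]
    k = table.shape[0]
    if k < 2:
        raise DegenerateTableError("fewer than 2 categories with non-zero counts")
    statistic, p_value, dof, _ = stats.chi2_contingency(table, correction=False)
    return ChiSquareResult(float(statistic), int(dof), float(p_value))
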