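"""Participant-level data model: records, cohorts, CSV round-trip.

A cohort is one row per participant: two blood-pressure readings (mmHg), a
self-reported physician-diagnosed hypertension flag, 25 further self-reported
disease flags, and socio-demographic / lifestyle / anthropometric covariates.
Final hypertension status is *derived* later (diagnosis module); the flag
stored here is self-report only.

The in-memory container is a validated :class:`pandas.DataFrame` wrapped by
:class:`Cohort`; :class:`ParticipantRecord` offers a per-row dataclass view
for record-oriented code and tests.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from ._utils import SchemaError, ValidationError, logger
from .registry import DEFAULT_REGISTRY, DiseaseRegistry

#: Allowed levels for each categorical covariate.  `wealth_tertile` is
#: integer-coded; all other categoricals are lower-case strings.
CATEGORICAL_LEVELS: dict[str, tuple[str, ...]] = {
    "sex": ("male", "female"),
    "urbanicity": ("rural", "urban"),
    "ethnicity": ("han", "uygur", "kazak", "hui", "tibetan", "other"),
    "education": ("no_formal", "primary", "middle", "college"),
    "occupation": ("unemployed", "agriculture", "employed"),
    "marital": ("married", "widowed", "separated_divorced", "never_married"),
    "smoking": ("never", "former", "current"),
    "drinking": ("never", "occasional", "usual"),
    "pa_tertile": ("low", "moderate", "high"),
}

#: Covariates that may be missing (NaN / empty cell).  Sex and age are
#: mandatory; disease flags and blood pressure are always mandatory.
OPTIONAL_COVARIATES = (
    "province",
    "urbanicity",
    "ethnicity",
    "education",
    "occupation",
    "marital",
    "wealth_tertile",
    "smoking",
    "drinking",
    "pa_tertile",
    "sleep_hours",
    "height_cm",
    "weight_kg",
    "waist_cm",
)

MANDATORY_COLUMNS = (
    "participant_id",
    "sbp",
    "dbp",
    "self_reported_hypertension",
    "sex",
    "age",
)

_TRUE = {"1", "true", "yes"}
_FALSE = {"0", "false", "no"}


def _coerce_bool(series: pd.Series, column: str) -> pd.Series:
    """Coerce {0,1,true,false,yes,no} (case-insensitive) to numpy bool."""
    s = series.astype(str).str.strip().str.lower()
    bad = ~(s.isin(_TRUE) | s.isin(_FALSE))
    if bad.any():
        rows = list(series.index[bad][:5])
        raise ValidationError(
            f"column {column!r}: non-boolean values at rows {rows}"
        )
    return s.isin(_TRUE)


@dataclass
class ParticipantRecord:
    """One survey row.  ``disease_flags`` covers the 25 non-hypertension codes."""

    participant_id: str
    sbp: float
    dbp: float
    self_reported_hypertension: bool
    disease_flags: dict[str, bool]
    sex: str
    age: float
    province: str | None = None
    urbanicity: str | None = None
    ethnicity: str | None = None
    education: str | None = None
    occupation: str | None = None
    marital: str | None = None
    wealth_tertile: int | None = None
    smoking: str | None = None
    drinking: str | None = None
    pa_tertile: str | None = None
    sleep_hours: float | None = None
    height_cm: float | None = None
    weight_kg: float | None = None
    waist_cm: float | None = None


@dataclass
class RowIssue:
    """Diagnostic for a rejected input row (0-based data row index)."""

    row: int
    participant_id: str
    reason: str


def expected_columns(registry: DiseaseRegistry = DEFAULT_REGISTRY) -> list[str]:
    """Full column set of the cohort CSV, in canonical order."""
    return (
        list(MANDATORY_COLUMNS)
        + list(registry.self_report_codes)
        + list(OPTIONAL_COVARIATES)
    )


def cohort_schema(registry: DiseaseRegistry = DEFAULT_REGISTRY) -> dict:
    """Machine-readable description of the cohort CSV columns and levels."""
    props: dict[str, dict] = {
        "participant_id": {"type": "string", "unique": True},
        "sbp": {"type": "number", "unit": "mmHg", "minimum_exclusive": 0},
        "dbp": {"type": "number", "unit": "mmHg", "minimum_exclusive": 0,
                "constraint": "dbp < sbp"},
        "self_reported_hypertension": {"type": "boolean"},
        "sex": {"type": "string", "enum": list(CATEGORICAL_LEVELS["sex"])},
        "age": {"type": "number", "unit": "years"},
    }
    for code in registry.self_report_codes:
        props[code] = {"type": "boolean", "label": registry.labels[code]}
    for cov in OPTIONAL_COVARIATES:
        if cov in CATEGORICAL_LEVELS:
            props[cov] = {"type": "string", "nullable": True,
                          "enum": list(CATEGORICAL_LEVELS[cov])}
        elif cov == "wealth_tertile":
            props[cov] = {"type": "integer", "nullable": True, "enum": [1, 2, 3]}
        elif cov == "province":
            props[cov] = {"type": "string", "nullable": True}
        else:
            props[cov] = {"type": "number", "nullable": True,
                          "minimum_exclusive": 0}
    return {
        "format": "CSV, comma-separated, UTF-8, '.' decimal separator",
        "boolean_encoding": "0/1 on write; {0,1,true,false,yes,no} on read",
        "columns": props,
    }


def write_schema(path: str | Path,
                 registry: DiseaseRegistry = DEFAULT_REGISTRY) -> Path:
    path = Path(path)
    path.write_text(json.dumps(cohort_schema(registry), indent=2))
    return path


class Cohort:
    """A validated cohort backed by a DataFrame in canonical column order.

    Parameters
    ----------
    data
        One row per participant with the columns of :func:`expected_columns`.
        Disease flags and ``self_reported_hypertension`` must be boolean-like;
        optional covariates may contain NaN (missing stays missing — no
        imputation anywhere in the pipeline).
    registry
        Disease registry fixing codes and column order.
    """

    def __init__(self, data: pd.DataFrame,
                 registry: DiseaseRegistry = DEFAULT_REGISTRY) -> None:
        self.registry = registry
        self.data = self._validate(data.copy())

    # -- construction -----------------------------------------------------
    def _validate(self, df: pd.DataFrame) -> pd.DataFrame:
        missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
        missing += [c for c in self.registry.self_report_codes
                    if c not in df.columns]
        if missing:
            raise SchemaError(f"missing mandatory columns: {missing}")
        for cov in OPTIONAL_COVARIATES:
            if cov not in df.columns:
                df[cov] = np.nan
        df = df[expected_columns(self.registry)].reset_index(drop=True)

        df["participant_id"] = df["participant_id"].astype(str)
        if df["participant_id"].duplicated().any():
            dupes = df.loc[df["participant_id"].duplicated(), "participant_id"]
            raise ValidationError(
                f"duplicate participant_id: {sorted(set(dupes))[:5]}"
            )
        for col in ("sbp", "dbp", "age"):
            df[col] = pd.to_numeric(df[col], errors="raise")
        if (df["sbp"] <= 0).any() or (df["dbp"] <= 0).any():
            raise ValidationError("blood pressure must be positive")
        if (df["dbp"] >= df["sbp"]).any():
            bad = list(df.index[df["dbp"] >= df["sbp"]][:5])
            raise ValidationError(f"dbp >= sbp at rows {bad}")

        bool_cols = ["self_reported_hypertension",
                     *self.registry.self_report_codes]
        for col in bool_cols:
            if df[col].dtype != bool:
                df[col] = _coerce_bool(df[col], col)

        bad_sex = ~df["sex"].isin(CATEGORICAL_LEVELS["sex"])
        if bad_sex.any():
            raise ValidationError(
                f"unknown sex level at rows {list(df.index[bad_sex][:5])}"
            )
        for cov, levels in CATEGORICAL_LEVELS.items():
            if cov == "sex":
                continue
            vals = df[cov]
            bad = vals.notna() & ~vals.isin(levels)
            if bad.any():
                raise ValidationError(
                    f"column {cov!r}: unknown level "
                    f"{sorted(set(vals[bad]))[:5]}"
                )
        for col in ("sleep_hours", "height_cm", "weight_kg", "waist_cm"):
            df[col] = pd.to_numeric(df[col], errors="raise")
            if (df[col].dropna() <= 0).any() and col != "sleep_hours":
                raise ValidationError(f"column {col!r} must be positive")
        df["wealth_tertile"] = pd.to_numeric(df["wealth_tertile"],
                                             errors="raise")
        wt = df["wealth_tertile"].dropna()
        if (~wt.isin([1, 2, 3])).any():
            raise ValidationError("wealth_tertile must be in {1,2,3}")
        return df

    # -- basic protocol ---------------------------------------------------
    def __len__(self) -> int:
        return len(self.data)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Cohort):
            return NotImplemented
        if self.registry.codes != other.registry.codes:
            return False
        a, b = self.data, other.data
        if list(a.columns) != list(b.columns) or len(a) != len(b):
            return False
        for col in a.columns:
            x, y = a[col], b[col]
            if x.dtype.kind == "f" or y.dtype.kind == "f":
                if not ((x.isna() == y.isna()).all()
                        and np.allclose(x.dropna(), y.dropna())):
                    return False
            else:
                if not (x.fillna("<NA>") == y.fillna("<NA>")).all():
                    return False
        return True

    @property
    def participant_ids(self) -> np.ndarray:
        return self.data["participant_id"].to_numpy()

    @property
    def records(self) -> list[ParticipantRecord]:
        """Row-wise dataclass view (convenience; O(N) Python objects)."""
        codes = self.registry.self_report_codes
        out = []
        for row in self.data.itertuples(index=False):
            d = row._asdict()
            flags = {c: bool(d.pop(c)) for c in codes}
            d = {k: (None if isinstance(v, float) and math.isnan(v) else v)
                 for k, v in d.items()}
            wt = d.get("wealth_tertile")
            d["wealth_tertile"] = None if wt is None else int(wt)
            out.append(ParticipantRecord(disease_flags=flags, **d))
        return out

    @classmethod
    def from_records(cls, records: Iterable[ParticipantRecord],
                     registry: DiseaseRegistry = DEFAULT_REGISTRY) -> "Cohort":
        rows = []
        for r in records:
            if set(r.disease_flags) != set(registry.self_report_codes):
                raise ValidationError(
                    f"record {r.participant_id}: disease_flags must cover "
                    "exactly the 25 non-hypertension codes"
                )
            d = {k: v for k, v in r.__dict__.items() if k != "disease_flags"}
            d.update(r.disease_flags)
            rows.append(d)
        df = pd.DataFrame(rows)
        return cls(df, registry)

    def subset(self, mask: np.ndarray) -> "Cohort":
        """Row subset as a new validated cohort."""
        return Cohort(self.data.loc[np.asarray(mask)], self.registry)


def read_cohort(path: str | Path,
                schema: Mapping[str, str] | None = None,
                registry: DiseaseRegistry = DEFAULT_REGISTRY,
                ) -> tuple[Cohort, list[RowIssue]]:
    """Read a cohort CSV, rejecting invalid rows with row-indexed diagnostics.

    Parameters
    ----------
    path
        CSV file with a header row.
    schema
        Optional mapping from the file's column names to canonical names,
        for sources with different headers.

    Returns
    -------
    cohort, issues
        The validated cohort of accepted rows, and one :class:`RowIssue`
        per rejected row (empty when all rows pass).

    Raises
    ------
    SchemaError
        If a mandatory column is absent from the file.
    """
    df = pd.read_csv(path, dtype={"participant_id": str})
    if schema:
        df = df.rename(columns=dict(schema))
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    missing += [c for c in registry.self_report_codes if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory columns: {missing}")

    issues: list[RowIssue] = []
    keep = np.ones(len(df), dtype=bool)

    def reject(mask: pd.Series, reason: str) -> None:
        for i in df.index[mask & keep]:
            pid = str(df.at[i, "participant_id"])
            issues.append(RowIssue(int(i), pid, reason))
        keep[np.asarray(mask)] = False

    for col in ("sbp", "dbp", "age"):
        numeric = pd.to_numeric(df[col], errors="coerce")
        reject(numeric.isna(), f"non-numeric or missing {col}")
        df[col] = numeric
    reject((df["sbp"] <= 0) | (df["dbp"] <= 0),
           "non-positive blood pressure")
    reject(df["dbp"] >= df["sbp"], "dbp >= sbp")
    for col in ("self_reported_hypertension", *registry.self_report_codes):
        s = df[col].astype(str).str.strip().str.lower()
        reject(~(s.isin(_TRUE) | s.isin(_FALSE)),
               f"non-boolean value in {col}")
        df[col] = s.isin(_TRUE)
    reject(~df["sex"].astype(str).isin(CATEGORICAL_LEVELS["sex"]),
           "unknown sex level")
    for cov, levels in CATEGORICAL_LEVELS.items():
        if cov == "sex" or cov not in df.columns:
            continue
        vals = df[cov]
        reject(vals.notna() & ~vals.astype(str).isin(levels),
               f"unknown level in {cov}")

    if issues:
        logger.warning("read_cohort: rejected %d of %d rows (%s)",
                       len(issues), len(df), path)
    cohort = Cohort(df.loc[keep], registry)
    return cohort, issues


def write_cohort(cohort: Cohort, path: str | Path) -> Path:
    """Write a cohort to CSV (booleans as 0/1), readable by read_cohort."""
    path = Path(path)
    df = cohort.data.copy()
    for col in ("self_reported_hypertension", *cohort.registry.self_report_codes):
        df[col] = df[col].astype(int)
    df.to_csv(path, index=False)
    return path
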