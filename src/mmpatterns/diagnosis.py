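"""Hypertension criteria, final disease status, and covariate categorization.

Hypertension status combines a measured blood-pressure exceedance with the
self-reported physician diagnosis: a participant is hypertensive under a
criterion iff they self-report a diagnosis OR their SBP/DBP reaches the
criterion's threshold (inclusive, the guideline convention).  Two criteria
ship as built-ins:

* ``CHL_2018`` — 140/90 mmHg (2018 Chinese Hypertension League guideline)
* ``ACC_AHA_2017`` — 130/80 mmHg (2017 ACC/AHA guideline)

Every other condition is self-report only, so switching criteria changes
exactly one column of the disease matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._utils import ConfigError, ValidationError
from .cohort import Cohort, ParticipantRecord
from .registry import DEFAULT_REGISTRY, DiseaseRegistry


@dataclass(frozen=True)
class CriterionSpec:
    """A named hypertension diagnostic threshold (SBP/DBP in mmHg)."""

    name: str
    sbp_threshold: float
    dbp_threshold: float

    def __post_init__(self) -> None:
        if self.sbp_threshold <= 0 or self.dbp_threshold <= 0:
            raise ConfigError("thresholds must be positive")
        if self.sbp_threshold <= self.dbp_threshold:
            raise ConfigError("sbp_threshold must exceed dbp_threshold")


CHL_2018 = CriterionSpec("CHL2018", 140.0, 90.0)
ACC_AHA_2017 = CriterionSpec("ACCAHA2017", 130.0, 80.0)

BUILTIN_CRITERIA: dict[str, CriterionSpec] = {
    "CHL2018": CHL_2018,
    "ACCAHA2017": ACC_AHA_2017,
}


def get_criterion(name: str) -> CriterionSpec:
    """Look up a built-in criterion by (case-insensitive) name."""
    key = name.replace("/", "").replace("-", "").replace("_", "").upper()
    aliases = {"14090": "CHL2018", "13080": "ACCAHA2017"}
    key = aliases.get(key, key)
    if key not in BUILTIN_CRITERIA:
        raise ConfigError(
            f"unknown criterion {name!r}; built-ins: {sorted(BUILTIN_CRITERIA)}"
        )
    return BUILTIN_CRITERIA[key]


def diagnose_hypertension(record: ParticipantRecord,
                          criterion: CriterionSpec) -> bool:
    """Hypertension status for one participant under a criterion.

    True iff the participant self-reports a physician diagnosis or either
    measured pressure reaches its threshold (>=).
    """
    return bool(
        record.self_reported_hypertension
        or record.sbp >= criterion.sbp_threshold
        or record.dbp >= criterion.dbp_threshold
    )


@dataclass
class DiseaseMatrix:
    """N x 26 binary indicator matrix in registry column order."""

    values: np.ndarray
    row_ids: np.ndarray
    criterion: CriterionSpec
    registry: DiseaseRegistry

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.registry):
            raise ValidationError(
                f"disease matrix must have {len(self.registry)} columns"
            )
        if not np.isin(self.values, (0, 1)).all():
            raise ValidationError("disease matrix entries must be 0/1")
        if len(self.row_ids) != self.values.shape[0]:
            raise ValidationError("row_ids length mismatch")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def column(self, code: str) -> np.ndarray:
        return self.values[:, self.registry.index(code)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_ids,
                            columns=list(self.registry.codes))


def build_disease_matrix(cohort: Cohort,
                         criterion: CriterionSpec) -> DiseaseMatrix:
    """Derive the N x 26 disease matrix for a cohort under one criterion.

    The hypertension column applies the criterion to measured BP plus the
    self-report flag; the 25 remaining columns are the survey flags verbatim.
    """
    if len(cohort) == 0:
        raise ValidationError("cannot build a disease matrix from an "
                              "empty cohort")
    df = cohort.data
    registry = cohort.registry
    values = np.zeros((len(df), len(registry)), dtype=np.int8)
    htn = (
        df["self_reported_hypertension"].to_numpy()
        | (df["sbp"].to_numpy() >= criterion.sbp_threshold)
        | (df["dbp"].to_numpy() >= criterion.dbp_threshold)
    )
    values[:, registry.index("hypertension")] = htn
    for code in registry.self_report_codes:
        values[:, registry.index(code)] = df[code].to_numpy()
    return DiseaseMatrix(values=values, row_ids=cohort.participant_ids,
                         criterion=criterion, registry=registry)


# -- covariate categorization ---------------------------------------------

#: BMI classes (Chinese criteria), half-open bins so every value maps to
#: exactly one class: [0,18) underweight, [18,24) normal, [24,28) overweight,
#: [28,inf) obese.
_BMI_EDGES = (18.0, 24.0, 28.0)
_BMI_LABELS = ("underweight", "normal", "overweight", "obese")

#: Central-obesity waist cutoffs, inclusive: >=85 cm men, >=80 cm women.
_WAIST_CUTOFF = {"male": 85.0, "female": 80.0}

#: Banding schemes: (edges, labels); bins are [e_{i-1}, e_i).
BAND_SCHEMES: dict[str, tuple[tuple[float, ...], tuple[str, ...]]] = {
    # descriptive-table age bands
    "age_table1": ((45.0, 65.0), ("<45", "45-64", ">=65")),
    # subgroup-analysis age split
    "age_subgroup": ((60.0,), ("<60", ">=60")),
    # sleep duration: [0,7), [7,8], (8,inf)
    "sleep": ((7.0, 8.0), ("<7h", "7-8h", ">8h")),
}


def bmi_class(height_cm: float | None, weight_kg: float | None) -> str | None:
    """BMI class from height and weight; None when either is missing."""
    if height_cm is None or weight_kg is None:
        return None
    if isinstance(height_cm, float) and np.isnan(height_cm):
        return None
    if isinstance(weight_kg, float) and np.isnan(weight_kg):
        return None
    if height_cm <= 0 or weight_kg <= 0:
        raise ValidationError("height and weight must be positive")
    bmi = weight_kg / (height_cm / 100.0) ** 2
    for edge, label in zip(_BMI_EDGES, _BMI_LABELS):
        if bmi < edge:
            return label
    return _BMI_LABELS[-1]


def central_obesity(waist_cm: float | None, sex: str) -> str | None:
    """Central-obesity class from waist circumference; None when missing."""
    if sex not in _WAIST_CUTOFF:
        raise ValidationError(f"unknown sex level: {sex!r}")
    if waist_cm is None or (isinstance(waist_cm, float) and np.isnan(waist_cm)):
        return None
    if waist_cm <= 0:
        raise ValidationError("waist circumference must be positive")
    return "central_obesity" if waist_cm >= _WAIST_CUTOFF[sex] else "normal"


def band(value: float, scheme: str) -> str:
    """Deterministic band label for a numeric value under a named scheme.

    The sleep scheme treats its middle band as closed, [7, 8]; age bands use
    half-open [lo, hi) intervals.
    """
    if scheme not in BAND_SCHEMES:
        raise ConfigError(
            f"unknown band scheme {scheme!r}; known: {sorted(BAND_SCHEMES)}"
        )
    if scheme == "sleep":
        if value < 7.0:
            return "<7h"
        if value <= 8.0:
            return "7-8h"
        return ">8h"
    edges, labels = BAND_SCHEMES[scheme]
    for edge, label in zip(edges, labels):
        if value < edge:
            return label
    return labels[-1]


def derived_covariates(cohort: Cohort) -> pd.DataFrame:
    """Categorical covariates derived from continuous measurements.

    Returns a DataFrame aligned to the cohort with columns ``bmi_class``,
    ``central_obesity``, ``age_band``, ``age_group`` (subgroup split) and
    ``sleep_band``; missing inputs yield missing categories.
    """
    df = cohort.data
    height = df["height_cm"].to_numpy(dtype=float)
    weight = df["weight_kg"].to_numpy(dtype=float)
    bmi = np.full(len(df), np.nan)
    ok = ~(np.isnan(height) | np.isnan(weight))
    bmi[ok] = weight[ok] / (height[ok] / 100.0) ** 2

    out = pd.DataFrame(index=df.index)
    out["bmi_class"] = pd.cut(
        bmi, bins=[0, *_BMI_EDGES, np.inf], labels=_BMI_LABELS, right=False
    ).astype(object)
    cutoff = df["sex"].map(_WAIST_CUTOFF).to_numpy(dtype=float)
    waist = df["waist_cm"].to_numpy(dtype=float)
    co = np.where(waist >= cutoff, "central_obesity", "normal")
    out["central_obesity"] = np.where(np.isnan(waist), None, co)
    out["age_band"] = [band(a, "age_table1") for a in df["age"]]
    out["age_group"] = [band(a, "age_subgroup") for a in df["age"]]
    sleep = df["sleep_hours"]
    out["sleep_band"] = [None if pd.isna(s) else band(s, "sleep")
                         for s in sleep]
    return out
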