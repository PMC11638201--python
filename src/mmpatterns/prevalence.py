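"""Multimorbidity flags and stratified prevalence tables.

Multimorbidity is the presence of at least two of the 26 registered
conditions in one individual.  Prevalence tables report, per covariate level,
the number and percentage of flagged participants among that level
(row-wise percentages, the convention of descriptive cohort tables);
participants missing a covariate are excluded from that covariate's rows
only, never from the overall row or the disease analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._utils import ValidationError, percentage
from .cohort import Cohort
from .diagnosis import DiseaseMatrix, derived_covariates

#: Covariates selectable for stratification: raw cohort columns plus the
#: derived categoricals (BMI class, central obesity, age/sleep bands).
DERIVED_COVARIATES = ("bmi_class", "central_obesity", "age_band",
                      "age_group", "sleep_band")


@dataclass
class PrevalenceTable:
    """Stratified counts and percentages for one binary outcome.

    ``table`` holds one row per (covariate, level) plus an overall row
    (covariate ``"overall"``); ``pct`` is 100 * n_positive / n_total rounded
    half away from zero to one decimal.
    """

    outcome_name: str
    table: pd.DataFrame  # columns: covariate, level, n_total, n_positive, pct

    def row(self, covariate: str, level: str) -> pd.Series:
        t = self.table
        hit = t[(t["covariate"] == covariate) & (t["level"] == level)]
        if hit.empty:
            raise KeyError(f"no stratum ({covariate!r}, {level!r})")
        return hit.iloc[0]

    @property
    def overall(self) -> pd.Series:
        return self.row("overall", "overall")

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def multimorbid_flags(matrix: DiseaseMatrix) -> np.ndarray:
    """1 where a participant has >= 2 of the 26 conditions, else 0."""
    return (matrix.values.sum(axis=1) >= 2).astype(np.int8)


def condition_count_distribution(matrix: DiseaseMatrix) -> pd.Series:
    """Histogram of per-participant condition counts (QC summary).

    Index k = exact number of conditions; values sum to N.
    """
    counts = matrix.values.sum(axis=1)
    hist = np.bincount(counts, minlength=len(matrix.registry) + 1)
    return pd.Series(hist, index=range(len(hist)), name="participants")


def _covariate_series(cohort: Cohort, name: str) -> pd.Series:
    if name in cohort.data.columns:
        return cohort.data[name]
    if name in DERIVED_COVARIATES:
        return derived_covariates(cohort)[name]
    raise ValidationError(f"unknown covariate {name!r}")


def _level_order(series: pd.Series) -> list:
    from .cohort import CATEGORICAL_LEVELS

    name = series.name
    if name in CATEGORICAL_LEVELS:
        return [lv for lv in CATEGORICAL_LEVELS[name] if lv in set(series)]
    ordered = {
        "bmi_class": ["underweight", "normal", "overweight", "obese"],
        "central_obesity": ["normal", "central_obesity"],
        "age_band": ["<45", "45-64", ">=65"],
        "age_group": ["<60", ">=60"],
        "sleep_band": ["<7h", "7-8h", ">8h"],
    }
    if name in ordered:
        return [lv for lv in ordered[name] if lv in set(series.dropna())]
    return sorted(series.dropna().unique())


def prevalence_table(flags: np.ndarray, cohort: Cohort,
                     covariates: list[str],
                     outcome_name: str = "multimorbidity") -> PrevalenceTable:
    """Tabulate a binary outcome overall and within covariate levels.

    Parameters
    ----------
    flags
        0/1 vector aligned to the cohort rows.
    covariates
        Cohort columns or derived covariate names to stratify by.
    """
    flags = np.asarray(flags).astype(int)
    if flags.shape != (len(cohort),):
        raise ValidationError("flags must align with cohort rows")
    rows = [{
        "covariate": "overall", "level": "overall",
        "n_total": len(cohort), "n_positive": int(flags.sum()),
        "pct": percentage(int(flags.sum()), len(cohort)),
    }]
    for cov in covariates:
        series = _covariate_series(cohort, cov)
        for level in _level_order(series):
            in_level = (series == level).to_numpy()
            n_total = int(in_level.sum())
            n_pos = int(flags[in_level].sum())
            rows.append({
                "covariate": cov, "level": str(level),
                "n_total": n_total, "n_positive": n_pos,
                "pct": percentage(n_pos, n_total) if n_total else float("nan"),
            })
    return PrevalenceTable(outcome_name=outcome_name,
                           table=pd.DataFrame(rows))
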