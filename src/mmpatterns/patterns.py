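"""Pattern-level analytics for a named multimorbidity pattern.

A pattern (e.g. the cardiometabolic cluster: hypertension, diabetes, acute
myocardial infarction, angina, stroke/TIA) defines pattern multimorbidity as
carrying at least two of its member conditions.  This module computes pattern
flags, the component-disease mix among flagged participants, exact
combination frequencies, and — across all 26 diseases — the share of each
disease's carriers who are pattern-multimorbid.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._utils import ValidationError, logger, percentage
from .clustering import DEFAULT_PATTERN_SEEDS
from .diagnosis import DiseaseMatrix


@dataclass(frozen=True)
class PatternDefinition:
    """A named multimorbidity pattern: a set of >= 2 member disease codes."""

    name: str
    members: frozenset[str]

    def __init__(self, name: str, members) -> None:
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "members", frozenset(members))
        if len(self.members) < 2:
            raise ValidationError("a pattern needs at least two members")


#: The hypertension-containing pattern analysed in depth.
CARDIOMETABOLIC = PatternDefinition(
    "cardiometabolic", DEFAULT_PATTERN_SEEDS["cardiometabolic"]
)


def _member_submatrix(matrix: DiseaseMatrix,
                      pattern: PatternDefinition) -> tuple[list[str], np.ndarray]:
    unknown = pattern.members - set(matrix.registry.codes)
    if unknown:
        raise ValidationError(f"pattern members not in registry: "
                              f"{sorted(unknown)}")
    codes = [c for c in matrix.registry.codes if c in pattern.members]
    cols = np.column_stack([matrix.column(c) for c in codes])
    return codes, cols


def pattern_flags(matrix: DiseaseMatrix,
                  pattern: PatternDefinition) -> np.ndarray:
    """1 where a participant carries >= 2 pattern members, else 0."""
    _, cols = _member_submatrix(matrix, pattern)
    return (cols.sum(axis=1) >= 2).astype(np.int8)


def component_disease_shares(matrix: DiseaseMatrix,
                             pattern: PatternDefinition,
                             exclude: str) -> pd.DataFrame:
    """Mix of component diseases among pattern-multimorbid participants.

    For each member other than ``exclude`` (typically hypertension, present
    in nearly all flagged participants), the count and percentage of
    pattern-flagged participants carrying that disease.
    """
    if exclude not in pattern.members:
        raise ValidationError(f"{exclude!r} is not a pattern member")
    codes, cols = _member_submatrix(matrix, pattern)
    flagged = cols.sum(axis=1) >= 2
    n_flagged = int(flagged.sum())
    if n_flagged == 0:
        raise ValidationError("no pattern-multimorbid participants: "
                              "shares have an empty denominator")
    rows = []
    for idx, code in enumerate(codes):
        if code == exclude:
            continue
        n = int(cols[flagged, idx].sum())
        rows.append({"code": code, "n": n,
                     "pct": percentage(n, n_flagged)})
    out = pd.DataFrame(rows).sort_values("n", ascending=False,
                                         kind="stable").reset_index(drop=True)
    return out


@dataclass
class CombinationTable:
    """Frequencies of member-disease combinations within a pattern.

    ``table`` rows: combination (``+``-joined codes), size, n, pct of the
    full cohort (two decimals — combination percentages are conventionally
    printed finer than prevalence tables).
    """

    pattern: PatternDefinition
    convention: str  # "exact" or "at_least"
    table: pd.DataFrame


def combination_frequencies(matrix: DiseaseMatrix,
                            pattern: PatternDefinition,
                            max_size: int | None = None, *,
                            convention: str = "exact") -> CombinationTable:
    """Count member-disease combinations of size 2..max_size.

    With the default ``exact`` convention each participant is counted once,
    under the precise member subset they carry; ``at_least`` counts a
    participant under every subset of their profile (superset-inclusive),
    for sensitivity analyses.  Percentages use the full cohort as base.
    """
    codes, cols = _member_submatrix(matrix, pattern)
    m = len(codes)
    max_size = m if max_size is None else max_size
    if not 2 <= max_size <= m:
        raise ValidationError(f"max_size must be in [2, {m}]")
    if convention not in ("exact", "at_least"):
        raise ValidationError("convention must be 'exact' or 'at_least'")
    if m > 20:  # 2^m profile table
        raise ValidationError("combination enumeration supports patterns "
                              "of at most 20 members")

    # integer profile per participant (bit i = carries codes[i])
    weights = 1 << np.arange(m)
    profiles = cols.astype(np.int64) @ weights
    profile_counts = np.bincount(profiles, minlength=1 << m)

    rows = []
    for size in range(2, max_size + 1):
        for combo in itertools.combinations(range(m), size):
            bits = int(sum(1 << i for i in combo))
            if convention == "exact":
                n = int(profile_counts[bits])
            else:
                sel = (np.arange(1 << m) & bits) == bits
                n = int(profile_counts[sel].sum())
            if n == 0:
                continue
            rows.append({
                "combination": "+".join(codes[i] for i in combo),
                "size": size, "n": n,
                "pct": percentage(n, matrix.n, ndigits=2),
            })
    table = pd.DataFrame(rows, columns=["combination", "size", "n", "pct"])
    table = table.sort_values(["n", "combination"],
                              ascending=[False, True],
                              kind="stable").reset_index(drop=True)
    return CombinationTable(pattern=pattern, convention=convention,
                            table=table)


def pattern_share_by_disease(matrix: DiseaseMatrix,
                             pattern: PatternDefinition) -> pd.DataFrame:
    """Among carriers of each disease, the share who are pattern-multimorbid.

    One row per registry disease: carriers, n pattern-flagged, pct.  A
    disease with zero carriers gets a missing share (logged).
    """
    flags = pattern_flags(matrix, pattern)
    rows = []
    for code in matrix.registry.codes:
        carriers = matrix.column(code).astype(bool)
        n_car = int(carriers.sum())
        if n_car == 0:
            logger.warning("pattern_share_by_disease: no carriers of %s; "
                           "share reported missing", code)
            rows.append({"code": code, "n_carriers": 0, "n_pattern": 0,
                         "pct": float("nan")})
            continue
        n_pat = int(flags[carriers].sum())
        rows.append({"code": code, "n_carriers": n_car, "n_pattern": n_pat,
                     "pct": percentage(n_pat, n_car)})
    return pd.DataFrame(rows)
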