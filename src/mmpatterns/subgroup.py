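"""Stratified replication of the association/clustering stack.

Re-runs Yule's Q + Ward clustering within strata (sex; age <60 / >=60;
the five named ethnic groups) and under both hypertension criteria, and
summarizes pattern stability as the adjusted Rand index between the
assignments obtained under the two criteria within each stratum.

Small or sparse strata are the numerically fragile case: a disease nobody
(or everybody) in a stratum carries has an undefined Yule's Q, so such
diseases are dropped from that stratum's clustering (listed in the result);
strata below a configurable minimum size are skipped outright.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._utils import ValidationError, logger
from .clustering import (ClusterAssignment, Dendrogram, adjusted_rand_index,
                         agglomerate_ward, association_matrix, cut,
                         name_clusters, to_dissimilarity)
from .cohort import Cohort
from .diagnosis import (CriterionSpec, DiseaseMatrix, band,
                        build_disease_matrix)

#: Ethnic groups retained for ethnicity stratification.
NAMED_ETHNIC_GROUPS = ("han", "uygur", "kazak", "hui", "tibetan")


def stratify(cohort: Cohort, by: str,
             scheme: str | None = None) -> dict[str, Cohort]:
    """Split a cohort into disjoint sub-cohorts by a covariate.

    Participants with a missing stratifier are dropped (count logged);
    ethnicity stratification keeps only the five named groups.  ``scheme``
    applies a banding scheme to a numeric covariate (e.g. ``age_subgroup``).
    """
    if by not in cohort.data.columns:
        raise ValidationError(f"unknown covariate {by!r}")
    series = cohort.data[by]
    if scheme is not None:
        series = pd.Series([band(v, scheme) if pd.notna(v) else None
                            for v in series], index=series.index, name=by)
    missing = series.isna()
    if missing.any():
        logger.info("stratify(%s): dropped %d participants with missing "
                    "stratifier", by, int(missing.sum()))
    if by == "ethnicity":
        keep_levels = [lv for lv in NAMED_ETHNIC_GROUPS
                       if lv in set(series.dropna())]
    else:
        keep_levels = sorted(series.dropna().astype(str).unique())
    out: dict[str, Cohort] = {}
    for level in keep_levels:
        mask = (series.astype(str) == level).to_numpy()
        out[str(level)] = cohort.subset(mask)
    return out


@dataclass
class StratumResult:
    """Clustering output for one (stratum, criterion) cell."""

    stratum: str
    criterion: str
    n: int
    dendrogram: Dendrogram | None
    assignment: ClusterAssignment | None
    excluded: list[str] = field(default_factory=list)
    skipped: bool = False
    skip_reason: str | None = None


@dataclass
class ReplicationResult:
    """All (stratum, criterion) cells plus the cross-criterion stability."""

    cells: dict[tuple[str, str], StratumResult]
    stability: pd.DataFrame  # stratum, criterion_a, criterion_b, ari


def _drop_constant(matrix: DiseaseMatrix) -> tuple[DiseaseMatrix, list[str]]:
    sums = matrix.values.sum(axis=0)
    keep = [i for i, s in enumerate(sums) if 0 < s < matrix.n]
    dropped = [matrix.registry.codes[i] for i in range(len(sums))
               if i not in keep]
    if not dropped:
        return matrix, []
    from .registry import DiseaseRegistry

    codes = tuple(matrix.registry.codes[i] for i in keep)
    sub = DiseaseRegistry(codes=codes,
                          labels={c: matrix.registry.labels[c] for c in codes})
    reduced = DiseaseMatrix(values=matrix.values[:, keep],
                            row_ids=matrix.row_ids,
                            criterion=matrix.criterion, registry=sub)
    return reduced, dropped


def cluster_stratum(cohort: Cohort, criterion: CriterionSpec, k: int, *,
                    square_dissimilarity: bool = False,
                    ) -> tuple[Dendrogram, ClusterAssignment, list[str]]:
    """Association + Ward + k-cut for one stratum under one criterion.

    Constant disease columns are dropped first; the returned list names
    the exclusions.
    """
    matrix = build_disease_matrix(cohort, criterion)
    matrix, dropped = _drop_constant(matrix)
    if dropped:
        logger.warning("stratum clustering: excluded constant diseases %s",
                       dropped)
    assoc = association_matrix(matrix)
    dend = agglomerate_ward(to_dissimilarity(assoc),
                            square_dissimilarity=square_dissimilarity)
    k_eff = min(k, dend.n_leaves)
    assignment = name_clusters(cut(dend, k_eff))
    return dend, assignment, dropped


def replicate_clustering(cohort: Cohort,
                         criteria: list[CriterionSpec],
                         strata: dict[str, Cohort] | None = None,
                         k: int = 4, *,
                         min_stratum_size: int = 100,
                         square_dissimilarity: bool = False,
                         ) -> ReplicationResult:
    """Run the clustering stack per (stratum, criterion) and score stability.

    Parameters
    ----------
    strata
        Mapping level -> sub-cohort (e.g. from :func:`stratify`); ``None``
        runs on the whole cohort only (stratum label ``"all"``).
    min_stratum_size
        Strata smaller than this are skipped with a warning: pairwise
        Yule's Q on rare diseases in tiny strata is numerically meaningless.

    Returns
    -------
    ReplicationResult
        Per-cell dendrograms/assignments and a stability table with the
        adjusted Rand index between each pair of criteria within each
        stratum (computed on the diseases clustered under both).
    """
    if strata is None:
        strata = {"all": cohort}
    cells: dict[tuple[str, str], StratumResult] = {}
    for level, sub in strata.items():
        for crit in criteria:
            key = (level, crit.name)
            if len(sub) < min_stratum_size:
                logger.warning("stratum %s (n=%d) below minimum size %d: "
                               "skipped", level, len(sub), min_stratum_size)
                cells[key] = StratumResult(
                    stratum=level, criterion=crit.name, n=len(sub),
                    dendrogram=None, assignment=None, skipped=True,
                    skip_reason=f"n={len(sub)} < {min_stratum_size}")
                continue
            dend, assignment, dropped = cluster_stratum(
                sub, crit, k, square_dissimilarity=square_dissimilarity)
            cells[key] = StratumResult(
                stratum=level, criterion=crit.name, n=len(sub),
                dendrogram=dend, assignment=assignment, excluded=dropped)

    rows = []
    for level in strata:
        for i in range(len(criteria)):
            for j in range(i + 1, len(criteria)):
                ca = cells[(level, criteria[i].name)]
                cb = cells[(level, criteria[j].name)]
                if ca.skipped or cb.skipped:
                    ari = float("nan")
                else:
                    shared = [c for c in ca.assignment.mapping
                              if c in cb.assignment.mapping]
                    ari = adjusted_rand_index(
                        np.array([ca.assignment.mapping[c] for c in shared]),
                        np.array([cb.assignment.mapping[c] for c in shared]))
                rows.append({"stratum": level,
                             "criterion_a": criteria[i].name,
                             "criterion_b": criteria[j].name,
                             "ari": ari})
    stability = pd.DataFrame(rows,
                             columns=["stratum", "criterion_a",
                                      "criterion_b", "ari"])
    return ReplicationResult(cells=cells, stability=stability)
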