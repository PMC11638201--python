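"""Model/Results front end for the multimorbidity-pattern analysis.

:class:`MultimorbidityModel` bundles a cohort with the analysis settings
(diagnostic criteria, number of patterns k, the pattern analysed in depth);
:meth:`~MultimorbidityModel.fit` runs the full stack — disease matrices
under every criterion, Yule's Q association, Ward clustering, k-cut pattern
assignment, multimorbidity and pattern prevalence, combination frequencies —
and returns a :class:`MultimorbidityResults` carrying the estimates, the
cross-criterion stability diagnostics and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._utils import ValidationError, percentage
from .clustering import (AssociationMatrix, ClusterAssignment, Dendrogram,
                         DissimilarityMatrix, adjusted_rand_index,
                         agglomerate_ward, association_matrix, cut,
                         export_newick, name_clusters, to_dissimilarity)
from .cohort import Cohort, read_cohort
from .diagnosis import (ACC_AHA_2017, CHL_2018, CriterionSpec, DiseaseMatrix,
                        build_disease_matrix)
from .patterns import (CARDIOMETABOLIC, CombinationTable, PatternDefinition,
                       combination_frequencies, component_disease_shares,
                       pattern_flags, pattern_share_by_disease)
from .prevalence import (PrevalenceTable, condition_count_distribution,
                         multimorbid_flags, prevalence_table)
from .registry import DEFAULT_REGISTRY
from .subgroup import ReplicationResult, replicate_clustering, stratify

#: Default covariates for the descriptive prevalence table.
DEFAULT_TABLE_COVARIATES = (
    "sex", "age_band", "province", "urbanicity", "ethnicity", "education",
    "occupation", "marital", "wealth_tertile", "smoking", "drinking",
    "pa_tertile", "sleep_band", "bmi_class", "central_obesity",
)


@dataclass
class CriterionResult:
    """Everything derived from one hypertension criterion."""

    criterion: CriterionSpec
    disease_matrix: DiseaseMatrix
    association: AssociationMatrix
    dissimilarity: DissimilarityMatrix
    dendrogram: Dendrogram
    assignment: ClusterAssignment
    multimorbid: np.ndarray
    pattern: np.ndarray
    combinations: CombinationTable
    component_shares: pd.DataFrame
    pattern_by_disease: pd.DataFrame

    @property
    def hypertension_prevalence(self) -> float:
        return float(self.disease_matrix.column("hypertension").mean())

    @property
    def multimorbidity_prevalence(self) -> float:
        return float(self.multimorbid.mean())

    @property
    def pattern_prevalence(self) -> float:
        return float(self.pattern.mean())


class MultimorbidityModel:
    """Multimorbidity pattern analysis of a cohort.

    Parameters
    ----------
    cohort
        A validated :class:`~mmpatterns.cohort.Cohort`.
    criteria
        Hypertension criteria to replicate the analysis under; default the
        140/90 mmHg and 130/80 mmHg guideline thresholds.
    k
        Number of patterns to cut the dendrogram into (default 4).
    pattern
        The pattern analysed in depth (default cardiometabolic).
    square_dissimilarity
        Ward dialect switch; see :func:`~mmpatterns.clustering.agglomerate_ward`.
    combination_convention
        ``"exact"`` (default) or ``"at_least"`` combination counting.

    Examples
    --------
    >>> from mmpatterns import MultimorbidityModel, simulate
    >>> cohort = simulate.generate(simulate.SyntheticConfig(n=5000, seed=7))
    >>> res = MultimorbidityModel(cohort).fit()
    >>> print(res.summary())            # doctest: +SKIP
    """

    def __init__(self, cohort: Cohort,
                 criteria: Sequence[CriterionSpec] = (CHL_2018, ACC_AHA_2017),
                 k: int = 4,
                 pattern: PatternDefinition = CARDIOMETABOLIC,
                 *,
                 square_dissimilarity: bool = False,
                 combination_convention: str = "exact",
                 pattern_seeds: Mapping[str, tuple[str, ...]] | None = None,
                 ) -> None:
        if len(criteria) == 0:
            raise ValidationError("need at least one criterion")
        unknown = pattern.members - set(cohort.registry.codes)
        if unknown:
            raise ValidationError(
                f"pattern {pattern.name!r} members not in registry: "
                f"{sorted(unknown)}")
        self.cohort = cohort
        self.criteria = list(criteria)
        self.k = int(k)
        self.pattern = pattern
        self.square_dissimilarity = bool(square_dissimilarity)
        self.combination_convention = combination_convention
        self.pattern_seeds = dict(pattern_seeds) if pattern_seeds else None

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, *,
                       registry=DEFAULT_REGISTRY, **kwargs
                       ) -> "MultimorbidityModel":
        """Build the model from a raw participant DataFrame."""
        return cls(Cohort(data, registry), **kwargs)

    @classmethod
    def from_csv(cls, path, *, schema=None, registry=DEFAULT_REGISTRY,
                 **kwargs) -> "MultimorbidityModel":
        """Build the model from a cohort CSV (invalid rows dropped, logged)."""
        cohort, _ = read_cohort(path, schema=schema, registry=registry)
        return cls(cohort, **kwargs)

    def fit(self) -> "MultimorbidityResults":
        """Run the full analysis under every criterion."""
        per: dict[str, CriterionResult] = {}
        for crit in self.criteria:
            matrix = build_disease_matrix(self.cohort, crit)
            assoc = association_matrix(matrix)
            dissim = to_dissimilarity(assoc)
            dend = agglomerate_ward(
                dissim, square_dissimilarity=self.square_dissimilarity)
            assignment = name_clusters(cut(dend, self.k), self.pattern_seeds)
            per[crit.name] = CriterionResult(
                criterion=crit,
                disease_matrix=matrix,
                association=assoc,
                dissimilarity=dissim,
                dendrogram=dend,
                assignment=assignment,
                multimorbid=multimorbid_flags(matrix),
                pattern=pattern_flags(matrix, self.pattern),
                combinations=combination_frequencies(
                    matrix, self.pattern,
                    convention=self.combination_convention),
                component_shares=component_disease_shares(
                    matrix, self.pattern, exclude="hypertension")
                if "hypertension" in self.pattern.members else pd.DataFrame(),
                pattern_by_disease=pattern_share_by_disease(
                    matrix, self.pattern),
            )
        return MultimorbidityResults(model=self, per_criterion=per)


@dataclass
class MultimorbidityResults:
    """Fitted estimates, diagnostics and export helpers."""

    model: MultimorbidityModel
    per_criterion: dict[str, CriterionResult]
    _stability: pd.DataFrame | None = field(default=None, repr=False)

    def __getitem__(self, criterion_name: str) -> CriterionResult:
        return self.per_criterion[criterion_name]

    @property
    def n(self) -> int:
        return len(self.model.cohort)

    @property
    def stability(self) -> pd.DataFrame:
        """Pairwise cross-criterion ARI of the pattern assignments."""
        if self._stability is None:
            names = list(self.per_criterion)
            codes = tuple(self.model.cohort.registry.codes)
            rows = []
            for i in range(len(names)):
                for j in range(i + 1, len(names)):
                    la = self.per_criterion[names[i]].assignment.labels(codes)
                    lb = self.per_criterion[names[j]].assignment.labels(codes)
                    rows.append({"criterion_a": names[i],
                                 "criterion_b": names[j],
                                 "ari": adjusted_rand_index(la, lb)})
            self._stability = pd.DataFrame(
                rows, columns=["criterion_a", "criterion_b", "ari"])
        return self._stability

    def prevalence_table(self, covariates: Sequence[str] | None = None,
                         criterion: str | None = None,
                         outcome: str = "multimorbidity") -> PrevalenceTable:
        """Stratified prevalence of multimorbidity or the focal pattern."""
        covariates = list(covariates if covariates is not None
                          else DEFAULT_TABLE_COVARIATES)
        crit = criterion or next(iter(self.per_criterion))
        res = self.per_criterion[crit]
        flags = {"multimorbidity": res.multimorbid,
                 "pattern": res.pattern}[outcome]
        name = (outcome if outcome == "multimorbidity"
                else self.model.pattern.name)
        return prevalence_table(flags, self.model.cohort, covariates,
                                outcome_name=f"{name} ({crit})")

    def condition_counts(self, criterion: str | None = None) -> pd.Series:
        crit = criterion or next(iter(self.per_criterion))
        return condition_count_distribution(
            self.per_criterion[crit].disease_matrix)

    def replicate(self, by: str, scheme: str | None = None, *,
                  min_stratum_size: int = 100) -> ReplicationResult:
        """Re-run the clustering stack within strata of a covariate."""
        strata = stratify(self.model.cohort, by, scheme)
        return replicate_clustering(
            self.model.cohort, self.model.criteria, strata,
            k=self.model.k, min_stratum_size=min_stratum_size,
            square_dissimilarity=self.model.square_dissimilarity)

    def summary(self) -> str:
        """Plain-text summary in the spirit of statsmodels results."""
        lines = []
        width = 72
        lines.append("Multimorbidity Pattern Analysis".center(width))
        lines.append("=" * width)
        lines.append(f"Participants: {self.n:>10,d}    "
                     f"Diseases: {len(self.model.cohort.registry)}    "
                     f"k: {self.model.k}")
        lines.append(f"Focal pattern: {self.model.pattern.name} "
                     f"({', '.join(sorted(self.model.pattern.members))})")
        lines.append("-" * width)
        header = (f"{'criterion':<12}{'threshold':>10}{'htn %':>9}"
                  f"{'multimorb %':>13}{'pattern %':>11}")
        lines.append(header)
        for name, res in self.per_criterion.items():
            c = res.criterion
            lines.append(
                f"{name:<12}{f'{c.sbp_threshold:.0f}/{c.dbp_threshold:.0f}':>10}"
                f"{percentage(int(res.disease_matrix.column('hypertension').sum()), self.n):>9.1f}"
                f"{percentage(int(res.multimorbid.sum()), self.n):>13.1f}"
                f"{percentage(int(res.pattern.sum()), self.n):>11.1f}")
        lines.append("-" * width)
        first = next(iter(self.per_criterion.values()))
        for cid in sorted(set(first.assignment.mapping.values())):
            nm = first.assignment.names.get(cid, f"cluster_{cid}")
            members = ", ".join(first.assignment.members(cid))
            lines.append(f"  [{cid}] {nm}: {members}")
        if len(self.per_criterion) > 1:
            lines.append("-" * width)
            for row in self.stability.itertuples(index=False):
                lines.append(f"  pattern stability ARI "
                             f"{row.criterion_a} vs {row.criterion_b}: "
                             f"{row.ari:.3f}")
        lines.append("=" * width)
        return "\n".join(lines)

    def save(self, outdir) -> Path:
        """Write all per-criterion artifacts as plain-text files."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, res in self.per_criterion.items():
            sub = outdir / name
            sub.mkdir(exist_ok=True)
            res.association.to_frame().to_csv(sub / "association.csv")
            res.dissimilarity.to_frame().to_csv(sub / "dissimilarity.csv")
            res.dendrogram.to_merge_table().to_csv(sub / "merges.csv",
                                                   index=False)
            (sub / "dendrogram.newick").write_text(
                export_newick(res.dendrogram) + "\n")
            res.assignment.to_frame().to_csv(sub / "assignment.csv",
                                             index=False)
            res.combinations.table.to_csv(sub / "combinations.csv",
                                          index=False)
            if not res.component_shares.empty:
                res.component_shares.to_csv(sub / "component_shares.csv",
                                            index=False)
            res.pattern_by_disease.to_csv(sub / "pattern_share_by_disease.csv",
                                          index=False)
            self.prevalence_table(criterion=name).to_csv(
                sub / "prevalence.csv")
            self.prevalence_table(criterion=name, outcome="pattern").to_csv(
                sub / "pattern_prevalence.csv")
            self.condition_counts(name).to_csv(sub / "condition_counts.csv")
        self.stability.to_csv(outdir / "stability.csv", index=False)
        return outdir
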