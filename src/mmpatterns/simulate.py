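"""Synthetic multi-ethnic cohort generator with planted disease structure.

Stands in for the undeposited survey data: a Gaussian latent-threshold
(probit/copula-style) construction plants positive within-block association
among four disease blocks mirroring the four multimorbidity patterns
(cardiometabolic, respiratory, digestive-bone-kidney, mental-cancer), with
near-zero association between blocks and for unassigned "noise" diseases.

Per participant, each block contributes one standard-normal factor F_b; the
liability of disease j in block b is

    L_j = sqrt(rho_b) * F_b + gamma * A + sqrt(1 - rho_b - gamma^2) * eps_j

with A the standardized age (an age gradient on all diseases) and eps_j
independent noise.  The disease flag thresholds L_j at the standard-normal
quantile of its target marginal prevalence, so marginals are controlled
directly while within-block association is tuned by rho.

Blood pressure is bivariate normal shifted by the hypertension liability,
with mass across the 130/80-140/90 band, so switching the diagnostic
criterion moves participants; the self-reported hypertension flag fires for
a configurable fraction of participants whose liability exceeds the
reporting threshold (diagnosed-but-aware participants).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import ConfigError
from .clustering import ClusterAssignment
from .cohort import CATEGORICAL_LEVELS, Cohort
from .registry import DEFAULT_REGISTRY, DiseaseRegistry


@dataclass(frozen=True)
class Block:
    """A planted disease block: correlated liabilities within, none between."""

    name: str
    members: tuple[str, ...]
    rho: float  # within-block liability correlation, in [0, 1)

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho < 1.0:
            raise ConfigError(f"block {self.name}: rho must be in [0, 1)")


@dataclass(frozen=True)
class BPModel:
    """Bivariate-normal blood pressure linked to the hypertension liability.

    ``liability_corr`` is the correlation of each pressure with the
    hypertension liability; ``resid_corr`` the residual SBP-DBP correlation.
    Defaults put substantial mass in the 130-139 / 80-89 mmHg band.
    """

    sbp_mean: float = 122.0
    sbp_sd: float = 16.0
    dbp_mean: float = 76.0
    dbp_sd: float = 10.0
    liability_corr: float = 0.5
    resid_corr: float = 0.6

    def __post_init__(self) -> None:
        if not 0.0 <= self.liability_corr < 1.0:
            raise ConfigError("liability_corr must be in [0, 1)")
        if not -1.0 < self.resid_corr < 1.0:
            raise ConfigError("resid_corr must be in (-1, 1)")


#: Marginal target prevalences: chronic conditions in the few-percent range
#: typical of a middle-aged survey population (hypertension is handled by
#: the BP + self-report machinery and is far more common).
DEFAULT_MARGINALS: dict[str, float] = {
    "diabetes": 0.060, "acute_mi": 0.010, "angina": 0.020,
    "other_ihd": 0.015, "stroke_tia": 0.025,
    "pulmonary_heart_disease": 0.008, "rheumatic_heart_disease": 0.006,
    "pulmonary_tb": 0.010, "emphysema": 0.012, "chronic_bronchitis": 0.040,
    "copd": 0.020, "asthma": 0.012, "chronic_hepatitis_cirrhosis": 0.015,
    "peptic_ulcer": 0.030, "gallstones_cholecystitis": 0.050,
    "chronic_kidney_disease": 0.012, "osteoporosis": 0.030,
    "fracture": 0.040, "rheumatoid_arthritis": 0.025, "depression": 0.012,
    "anxiety": 0.015, "neurasthenia": 0.010, "other_mental": 0.006,
    "traumatic_brain_injury": 0.008, "cancer": 0.007,
}

#: Default planted blocks mirroring the four observed patterns; the four
#: diseases left unassigned (other IHD, pulmonary/rheumatic heart disease,
#: traumatic brain injury) are noise diseases with zero cross-correlation.
DEFAULT_BLOCKS: tuple[Block, ...] = (
    Block("cardiometabolic",
          ("hypertension", "diabetes", "acute_mi", "angina", "stroke_tia"),
          0.5),
    Block("respiratory",
          ("pulmonary_tb", "emphysema", "chronic_bronchitis", "copd",
           "asthma"), 0.5),
    Block("digestive_bone_kidney",
          ("chronic_hepatitis_cirrhosis", "peptic_ulcer",
           "gallstones_cholecystitis", "chronic_kidney_disease",
           "osteoporosis", "fracture", "rheumatoid_arthritis"), 0.5),
    Block("mental_cancer",
          ("depression", "anxiety", "neurasthenia", "other_mental",
           "cancer"), 0.5),
)

_PROVINCES = ("shaanxi", "xinjiang", "ningxia", "gansu", "qinghai")

#: Categorical covariate distributions, roughly matching a rural-majority
#: multi-ethnic Northwest-China survey population.
DEFAULT_COVARIATES: dict[str, tuple[tuple, tuple[float, ...]]] = {
    "sex": (("male", "female"), (0.405, 0.595)),
    "province": (_PROVINCES, (0.391, 0.268, 0.137, 0.180, 0.024)),
    "urbanicity": (("rural", "urban"), (0.722, 0.278)),
    "ethnicity": (("han", "uygur", "kazak", "hui", "tibetan", "other"),
                  (0.748, 0.134, 0.018, 0.082, 0.013, 0.005)),
    "education": (("no_formal", "primary", "middle", "college"),
                  (0.187, 0.297, 0.361, 0.155)),
    "occupation": (("unemployed", "agriculture", "employed"),
                   (0.267, 0.483, 0.250)),
    "marital": (("married", "widowed", "separated_divorced", "never_married"),
                (0.887, 0.063, 0.020, 0.030)),
    "wealth_tertile": ((1, 2, 3), (0.319, 0.342, 0.339)),
    "smoking": (("never", "former", "current"), (0.814, 0.028, 0.158)),
    "drinking": (("never", "occasional", "usual"), (0.735, 0.188, 0.077)),
    "pa_tertile": (("low", "moderate", "high"), (0.348, 0.322, 0.330)),
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Everything needed to generate a reproducible synthetic cohort."""

    n: int = 20_000
    seed: int = 42
    blocks: tuple[Block, ...] = DEFAULT_BLOCKS
    marginal_prevalences: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MARGINALS))
    bp_model: BPModel = BPModel()
    #: self-report pool: fraction of the population whose hypertension
    #: liability qualifies for a physician diagnosis, and the fraction of
    #: those who report it (awareness).
    self_report_pool: float = 0.18
    report_rate: float = 0.65
    #: per-SD age loading on every disease liability (prevalence gradient)
    age_gradient: float = 0.2
    registry: DiseaseRegistry = DEFAULT_REGISTRY

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ConfigError("n must be >= 1")
        seen: set[str] = set()
        for blk in self.blocks:
            for code in blk.members:
                if code not in self.registry:
                    raise ConfigError(f"block {blk.name}: unknown disease "
                                      f"code {code!r}")
                if code in seen:
                    raise ConfigError(f"disease {code!r} assigned to more "
                                      "than one block")
                seen.add(code)
            if blk.rho + self.age_gradient ** 2 >= 1.0:
                raise ConfigError(f"block {blk.name}: rho + age_gradient^2 "
                                  "must stay below 1")
        for code, p in self.marginal_prevalences.items():
            if not 0.0 < p < 1.0:
                raise ConfigError(f"marginal prevalence of {code!r} must be "
                                  "in (0, 1)")
        for code in self.registry.self_report_codes:
            if code not in self.marginal_prevalences:
                raise ConfigError(f"no marginal prevalence for {code!r}")
        if not 0.0 < self.self_report_pool < 1.0:
            raise ConfigError("self_report_pool must be in (0, 1)")
        if not 0.0 <= self.report_rate <= 1.0:
            raise ConfigError("report_rate must be in [0, 1]")

    def with_(self, **kwargs) -> "SyntheticConfig":
        return replace(self, **kwargs)

    @property
    def block_of(self) -> dict[str, str]:
        return {code: blk.name for blk in self.blocks for code in blk.members}

    @property
    def noise_diseases(self) -> tuple[str, ...]:
        assigned = set(self.block_of)
        return tuple(c for c in self.registry.codes if c not in assigned)


def ground_truth(config: SyntheticConfig) -> ClusterAssignment:
    """The planted block partition (block members only), seed-independent."""
    mapping: dict[str, int] = {}
    for cid, blk in enumerate(config.blocks, start=1):
        for code in blk.members:
            mapping[code] = cid
    names = {cid: blk.name for cid, blk in enumerate(config.blocks, start=1)}
    return ClusterAssignment(mapping=mapping, k=len(config.blocks),
                             names=names)


def _liabilities(config: SyntheticConfig, rng: np.random.Generator,
                 age_std: np.ndarray) -> pd.DataFrame:
    """One liability column per registry code (unit variance each)."""
    n = config.n
    gamma = config.age_gradient
    factors = {blk.name: rng.standard_normal(n) for blk in config.blocks}
    block_of = config.block_of
    rho_of = {blk.name: blk.rho for blk in config.blocks}
    out = {}
    for code in config.registry.codes:
        eps = rng.standard_normal(n)
        if code in block_of:
            rho = rho_of[block_of[code]]
            resid = np.sqrt(max(1.0 - rho - gamma ** 2, 0.0))
            out[code] = (np.sqrt(rho) * factors[block_of[code]]
                         + gamma * age_std + resid * eps)
        else:
            resid = np.sqrt(max(1.0 - gamma ** 2, 0.0))
            out[code] = gamma * age_std + resid * eps
    return pd.DataFrame(out)


def generate(config: SyntheticConfig) -> Cohort:
    """Draw a fully reproducible synthetic cohort from the config.

    The same seed yields a byte-identical cohort; all randomness flows
    through one :class:`numpy.random.Generator`.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n

    age = np.floor(rng.uniform(35.0, 75.0, size=n)).astype(int)
    age_std = (age - 54.5) / (40.0 / np.sqrt(12.0))

    liab = _liabilities(config, rng, age_std)

    data: dict[str, object] = {
        "participant_id": [f"P{i:07d}" for i in range(n)],
        "age": age,
    }
    for name, (levels, probs) in DEFAULT_COVARIATES.items():
        data[name] = rng.choice(np.array(levels, dtype=object), size=n,
                                p=np.asarray(probs))

    # disease flags: threshold each liability at its marginal quantile
    for code in config.registry.self_report_codes:
        p = config.marginal_prevalences[code]
        data[code] = liab[code].to_numpy() > stats.norm.ppf(1.0 - p)

    # hypertension: self-report from the liability, measured BP shifted by it
    l_htn = liab["hypertension"].to_numpy()
    pool = l_htn > stats.norm.ppf(1.0 - config.self_report_pool)
    data["self_reported_hypertension"] = pool & (
        rng.random(n) < config.report_rate)

    bp = config.bp_model
    r = bp.liability_corr
    e1 = rng.standard_normal(n)
    e2 = rng.standard_normal(n)
    z_sbp = r * l_htn + np.sqrt(1 - r ** 2) * e1
    z_dbp = r * l_htn + np.sqrt(1 - r ** 2) * (
        bp.resid_corr * e1 + np.sqrt(1 - bp.resid_corr ** 2) * e2)
    sbp = np.round(bp.sbp_mean + bp.sbp_sd * z_sbp, 1)
    dbp = np.round(bp.dbp_mean + bp.dbp_sd * z_dbp, 1)
    sbp = np.maximum(sbp, 60.0)
    dbp = np.clip(dbp, 40.0, sbp - 2.0)  # physiology: DBP below SBP
    data["sbp"] = sbp
    data["dbp"] = dbp

    data["sleep_hours"] = np.clip(
        np.round(rng.normal(7.4, 1.1, size=n) * 2) / 2, 3.0, 12.0)
    male = np.asarray(data["sex"], dtype=object) == "male"
    height = np.where(male, rng.normal(169.0, 6.0, n), rng.normal(158.0, 6.0, n))
    bmi = rng.normal(24.5, 3.6, size=n)
    bmi = np.clip(bmi, 14.0, 45.0)
    data["height_cm"] = np.round(height, 1)
    data["weight_kg"] = np.round(bmi * (height / 100.0) ** 2, 1)
    data["waist_cm"] = np.round(
        2.3 * bmi + 28.0 + rng.normal(0.0, 5.0, size=n), 1)

    return Cohort(pd.DataFrame(data), config.registry)
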