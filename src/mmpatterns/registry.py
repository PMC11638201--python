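"""Canonical registry of the 26 chronic conditions under study.

The registry fixes the disease ordering used by every downstream matrix:
hypertension first (the only condition whose status combines measured blood
pressure with self-report), then the 25 purely self-reported conditions in
their canonical survey order.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class DiseaseRegistry:
    """Ordered set of disease codes with human-readable labels.

    The code order defines the column order of every disease matrix,
    association matrix and dissimilarity matrix in the pipeline.
    """

    codes: tuple[str, ...]
    labels: dict[str, str] = field(hash=False)

    def __post_init__(self) -> None:
        if len(self.codes) != len(set(self.codes)):
            raise ValueError("disease codes must be unique")
        if set(self.labels) != set(self.codes):
            raise ValueError("labels must cover exactly the registry codes")

    def __len__(self) -> int:
        return len(self.codes)

    def __contains__(self, code: str) -> bool:
        return code in self.codes

    def index(self, code: str) -> int:
        try:
            return self.codes.index(code)
        except ValueError:
            raise KeyError(f"unknown disease code: {code!r}") from None

    @property
    def self_report_codes(self) -> tuple[str, ...]:
        """All codes except hypertension (status taken from the survey flag)."""
        return tuple(c for c in self.codes if c != "hypertension")


_DISEASES: list[tuple[str, str]] = [
    ("hypertension", "Hypertension"),
    ("diabetes", "Diabetes"),
    ("acute_mi", "Acute myocardial infarction"),
    ("angina", "Angina"),
    ("other_ihd", "Other ischemic heart diseases"),
    ("stroke_tia", "Stroke or transient ischemic attack (TIA)"),
    ("pulmonary_heart_disease", "Pulmonary heart disease"),
    ("rheumatic_heart_disease", "Rheumatic heart disease"),
    ("pulmonary_tb", "Pulmonary tuberculosis"),
    ("emphysema", "Emphysema"),
    ("chronic_bronchitis", "Chronic bronchitis"),
    ("copd", "Chronic obstructive pulmonary disease (COPD)"),
    ("asthma", "Asthma"),
    ("chronic_hepatitis_cirrhosis", "Chronic hepatitis or cirrhosis"),
    ("peptic_ulcer", "Peptic ulcer"),
    ("gallstones_cholecystitis", "Gallstones or cholecystitis"),
    ("chronic_kidney_disease", "Chronic kidney disease"),
    ("osteoporosis", "Osteoporosis"),
    ("fracture", "Fracture"),
    ("rheumatoid_arthritis", "Rheumatoid arthritis"),
    ("depression", "Depression"),
    ("anxiety", "Anxiety"),
    ("neurasthenia", "Neurasthenia"),
    ("other_mental", "Other mental health disorders"),
    ("traumatic_brain_injury", "Traumatic brain injury"),
    ("cancer", "Cancer"),
]

#: The default 26-condition registry used throughout the package.
DEFAULT_REGISTRY = DiseaseRegistry(
    codes=tuple(code for code, _ in _DISEASES),
    labels={code: label for code, label in _DISEASES},
)

assert len(DEFAULT_REGISTRY) == 26
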