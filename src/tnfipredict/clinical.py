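"""Clinical records and EULAR DAS28 response classification.

Patients carry a DAS28-CRP composite at treatment start (M0) and after
three months (M3).  The EULAR grid turns the pair into Good / Moderate /
None using the attained score and its improvement; responder status is a
configurable subset of the categories (Good + Moderate by default).
"""

from __future__ import annotations

from dataclasses import dataclass

from .config import EularGrid, drug_class

GOOD = "Good"
MODERATE = "Moderate"
NONE = "None"
CATEGORIES = (GOOD, MODERATE, NONE)

DAS28_MAX = 12.0


@dataclass(frozen=True)
class ClinicalRecord:
    """One patient's drug, DAS28 trajectory, and recorded 3-month evolution.

    ``recorded_evolution`` is the clinician-assessed outcome ('+', '-' or
    None when unknown); it is the scoring ground truth, while EULAR
    categories recomputed from the scores serve as a consistency check.
    """

    patient_id: str
    drug: str
    das28_m0: float
    das28_m3: float
    recorded_evolution: str | None = None

    def __post_init__(self) -> None:
        for score in (self.das28_m0, self.das28_m3):
            if not 0.0 <= score < DAS28_MAX:
                raise ValueError(f"DAS28 score out of range: {score}")
        if self.recorded_evolution not in ("+", "-", None):
            raise ValueError(f"evolution must be '+', '-' or None: {self.recorded_evolution!r}")
        drug_class(self.drug)  # raises on unknown drug codes

    @property
    def drug_class(self) -> str:
        return drug_class(self.drug)


def eular_response(m0: float, m3: float, grid: EularGrid | None = None) -> str:
    """EULAR response category for a baseline/endpoint DAS28 pair.

    With the default grid: Good iff improvement > 1.2 and m3 <= 3.2;
    None iff improvement <= 0.6, or improvement <= 1.2 with m3 > 5.1;
    Moderate otherwise.
    """
    grid = grid or EularGrid()
    if m0 is None or m3 is None:
        raise ValueError("both DAS28 scores are required")
    delta = m0 - m3
    if delta > grid.major_improvement_min and m3 <= grid.good_endpoint_max:
        return GOOD
    if delta <= grid.minor_improvement_min:
        return NONE
    if delta <= grid.major_improvement_min and m3 > grid.moderate_endpoint_max:
        return NONE
    return MODERATE


def binary_response(category: str, grid: EularGrid | None = None) -> bool:
    """Collapse a EULAR category to responder / non-responder."""
    grid = grid or EularGrid()
    if category not in CATEGORIES:
        raise ValueError(f"unknown EULAR category {category!r}")
    return category in grid.responder_set


def record_response(record: ClinicalRecord, grid: EularGrid | None = None) -> bool:
    """Responder flag for a record, preferring the recorded clinical evolution.

    Falls back to the EULAR grid recomputed from the DAS28 pair when no
    evolution was recorded.
    """
    if record.recorded_evolution is not None:
        return record.recorded_evolution == "+"
    return binary_response(eular_response(record.das28_m0, record.das28_m3, grid), grid)
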