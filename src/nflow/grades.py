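"""Data-reliability grades and their coefficients of variation.

Input data are classed by provenance quality into three reliability grades.
Each grade maps to a fixed coefficient of variation used when perturbing the
input in Monte Carlo uncertainty propagation: high-reliability data (official
statistics) get cv 0.1, moderate 0.2, and low (expert judgement, transferred
factors) 0.3. The mapping is immutable.
"""

from __future__ import annotations

import enum


class ReliabilityGrade(str, enum.Enum):
    HIGH = "high"
    MODERATE = "moderate"
    LOW = "low"

    @property
    def cv(self) -> float:
        return GRADE_CV[self]

    @classmethod
    def coerce(cls, value: "ReliabilityGrade | str") -> "ReliabilityGrade":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value).lower())
        except ValueError as exc:
            raise ValueError(
                f"unknown reliability grade {value!r}; expected one of "
                f"{[g.value for g in cls]}"
            ) from exc


GRADE_CV: dict[ReliabilityGrade, float] = {
    ReliabilityGrade.HIGH: 0.1,
    ReliabilityGrade.MODERATE: 0.2,
    ReliabilityGrade.LOW: 0.3,
}

# Ordering used for "lowest reliability wins" propagation: lower rank = worse.
_RELIABILITY_RANK = {
    ReliabilityGrade.LOW: 0,
    ReliabilityGrade.MODERATE: 1,
    ReliabilityGrade.HIGH: 2,
}


def worst_grade(grades) -> ReliabilityGrade:
    """Return the least reliable grade among ``grades`` (conservative propagation)."""
    grades = [ReliabilityGrade.coerce(g) for g in grades]
    if not grades:
        raise ValueError("worst_grade() needs at least one grade")
    return min(grades, key=_RELIABILITY_RANK.__getitem__)
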