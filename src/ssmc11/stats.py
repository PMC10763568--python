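"""Cohort descriptive statistics and feature-group classification.

Counts follow the curated cohort columns; shapes are counted once per case by
the predominant shape; percentages are rounded half-up to one decimal with the
denominator recorded alongside. No inferential statistics are computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Optional, Sequence

from .types import CaseRecord, ClinicalStatus, Inheritance, Sex, Shape

__all__ = ["CohortSummary", "summarize", "classify_groups", "pct"]

#: derived labels classify_groups may attach beyond the curated group labels
_SHAPE_LABEL = {
    Shape.min: "shape:min",
    Shape.r: "shape:r",
    Shape.inv_dup: "shape:invdup",
    Shape.unknown: "shape:unknown",
}
_INHERIT_LABEL = {
    Inheritance.maternal: "inheritance:mat",
    Inheritance.paternal: "inheritance:pat",
    Inheritance.de_novo: "inheritance:dn",
}


def pct(count: int, denom: int) -> float:
    """Percentage rounded half-up to 1 decimal (the convention of printed
    cohort tables, where 5/57 appears as 8.8%)."""
    if denom == 0:
        return 0.0
    return float(
        (Decimal(count) * 100 / Decimal(denom)).quantize(
            Decimal("0.1"), rounding=ROUND_HALF_UP
        )
    )


@dataclass
class CohortSummary:
    n_total: int
    n_by_clinical: dict[str, int]
    n_by_shape: dict[str, int]
    n_shape_reported: int
    shape_percentages: dict[str, float]
    sex_counts: dict[str, int]
    male_female_ratio: Optional[float]
    group_counts: dict[str, int]
    group_fractions: dict[str, float]
    mosaic_count: int
    mosaic_fraction_pct: float
    inheritance_counts: dict[str, int]
    denominators: dict[str, int] = field(default_factory=dict)


def classify_groups(case: CaseRecord) -> set[str]:
    """Deterministic label set for one case: curated formation/feature labels
    plus parser-derived facts (shape, mosaicism, inheritance, clinical class).
    Labels are not mutually exclusive; a case may belong to several groups."""
    labels = set(case.group_labels)
    labels.add(_SHAPE_LABEL[case.predominant_shape])
    labels.add("mosaic" if case.mosaic else "non-mosaic")
    if case.inheritance in _INHERIT_LABEL:
        labels.add(_INHERIT_LABEL[case.inheritance])
    labels.add(f"clinical:{case.clinical_status.value}")
    return labels


def summarize(cohort: Sequence[CaseRecord]) -> CohortSummary:
    """Descriptive summary of a cohort; permutation-invariant over case order."""
    if not cohort:
        raise ValueError("empty cohort")
    n = len(cohort)
    clinical = {s.value: 0 for s in ClinicalStatus}
    sexes = {s.value: 0 for s in Sex}
    shapes: dict[str, int] = {}
    inherit = {i.value: 0 for i in Inheritance}
    groups: dict[str, int] = {}
    mosaic_count = 0
    for case in cohort:
        clinical[case.clinical_status.value] += 1
        sexes[case.sex.value] += 1
        inherit[case.inheritance.value] += 1
        shape = case.predominant_shape
        if shape is not Shape.unknown:
            shapes[shape.value] = shapes.get(shape.value, 0) + 1
        if case.mosaic:
            mosaic_count += 1
        for label in classify_groups(case):
            groups[label] = groups.get(label, 0) + 1
    n_shape = sum(shapes.values())
    males, females = sexes[Sex.male.value], sexes[Sex.female.value]
    ratio = round(males / females, 2) if females else None
    return CohortSummary(
        n_total=n,
        n_by_clinical=clinical,
        n_by_shape=shapes,
        n_shape_reported=n_shape,
        shape_percentages={k: pct(v, n_shape) for k, v in shapes.items()},
        sex_counts=sexes,
        male_female_ratio=ratio,
        group_counts=dict(sorted(groups.items())),
        group_fractions={k: pct(v, n) for k, v in sorted(groups.items())},
        mosaic_count=mosaic_count,
        mosaic_fraction_pct=pct(mosaic_count, n),
        inheritance_counts=inherit,
        denominators={"shapes": n_shape, "groups": n, "sex_ratio": males + females},
    )


def summary_lines(s: CohortSummary) -> list[str]:
    """Human-readable rendering of a summary (used by the CLI)."""
    lines = [
        f"Cases: {s.n_total}",
        "Clinical: " + ", ".join(f"{k}={v}" for k, v in s.n_by_clinical.items()),
        "Sex: " + ", ".join(f"{k}={v}" for k, v in s.sex_counts.items()),
    ]
    if s.male_female_ratio is not None:
        m, f = s.sex_counts["male"], s.sex_counts["female"]
        lines.append(f"Male:female = {m}:{f} (quotient {s.male_female_ratio})")
    lines.append(
        f"Shape reported for {s.n_shape_reported}: "
        + ", ".join(
            f"{k}={v} ({s.shape_percentages[k]}%)" for k, v in s.n_by_shape.items()
        )
    )
    lines.append(f"Mosaic: {s.mosaic_count} ({s.mosaic_fraction_pct}%)")
    for label in sorted(s.group_counts):
        lines.append(
            f"group {label}: {s.group_counts[label]} ({s.group_fractions[label]}%)"
        )
    return lines
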