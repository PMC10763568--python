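"""Arm-wise genotype-phenotype tabulation.

Cases whose trisomy extends telomere-ward beyond the insensitive span on the
short arm are compared against those extending on the long arm, sign by sign.
The controlled vocabulary is the nine-sign set used for centromere-near
chromosome-11 imbalances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .types import CaseRecord, ClinicalStatus, DosageMap

logger = logging.getLogger(__name__)

__all__ = ["PHENOTYPE_VOCABULARY", "PhenotypeMatrix", "assign_arm", "tabulate"]

PHENOTYPE_VOCABULARY = [
    "growth retardation",
    "blepharophimosis/ptosis",
    "strabism",
    "cleft palate",
    "facial dysmorphism (unspecific)",
    "heart defect",
    "developmental delay",
    "intellectual disability",
    "hypotonia",
]

_UNSPECIFIC = "facial dysmorphism (unspecific)"
_OTHER = "other"


@dataclass
class PhenotypeMatrix:
    rows: list[str]
    cells: dict[tuple[str, str], list[str]] = field(default_factory=dict)
    column_totals: dict[str, int] = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)

    def count(self, sign: str, arm: str) -> int:
        return len(self.cells.get((sign, arm), []))

    def case_ids(self, sign: str, arm: str) -> list[str]:
        return list(self.cells.get((sign, arm), []))

    def to_rows(self) -> list[dict]:
        out = []
        for sign in self.rows:
            out.append(
                {
                    "sign": sign,
                    "p_count": self.count(sign, "p"),
                    "p_cases": ";".join(self.case_ids(sign, "p")),
                    "q_count": self.count(sign, "q"),
                    "q_cases": ";".join(self.case_ids(sign, "q")),
                }
            )
        return out


def assign_arm(case: CaseRecord, dmap: DosageMap) -> str:
    """Which arm's sensitive territory a case's trisomy reaches into.

    ``p`` if the interval extends telomere-ward beyond the refined span start,
    ``q`` if beyond its end, ``both`` if both, ``none`` otherwise. A curated
    arm class on the record overrides the computed value with a logged note
    when they differ (published assignments sometimes rest on evidence that is
    not coordinate-resolvable, e.g. band-only duplication sizing).
    """
    iv = case.trisomy_interval
    if iv is None:
        computed = "none"
        if case.arm_class is None:
            logger.warning("case %s: no interval; arm=none", case.case_id)
    else:
        p = iv.start < dmap.refined_span.start
        q = iv.end > dmap.refined_span.end
        computed = "both" if (p and q) else "p" if p else "q" if q else "none"
    if case.arm_class and case.arm_class != computed:
        logger.info(
            "case %s: curated arm %s overrides computed %s",
            case.case_id, case.arm_class, computed,
        )
        return case.arm_class
    return case.arm_class or computed


def tabulate(
    cases: Sequence[CaseRecord],
    dmap: DosageMap,
    vocabulary: Optional[Sequence[str]] = None,
) -> PhenotypeMatrix:
    """Count each sign among cases assigned to p-arm vs q-arm territory.

    A case contributes to every row matching its phenotype terms but is
    counted once per arm in the column totals; ``both``-arm cases would count
    in both columns. Terms outside the vocabulary fall into the unspecific-
    dysmorphism row only when flagged as such, otherwise under "other" with a
    warning. Contributors without a confirmed abnormal status are flagged in
    the notes rather than dropped (published tabulations include cases whose
    cohort-level status is unresolved).
    """
    vocab = list(vocabulary) if vocabulary is not None else list(PHENOTYPE_VOCABULARY)
    matrix = PhenotypeMatrix(rows=vocab + [_OTHER])
    contributors: dict[str, set[str]] = {"p": set(), "q": set()}
    for case in cases:
        if not case.phenotype_terms:
            continue
        arm = assign_arm(case, dmap)
        if arm == "none":
            continue
        arms = ["p", "q"] if arm == "both" else [arm]
        if case.clinical_status is not ClinicalStatus.abnormal:
            matrix.notes.append(
                f"case {case.case_id}: contributes with status "
                f"{case.clinical_status.value}"
            )
        for term in case.phenotype_terms:
            if term in vocab:
                row = term
            elif "dysmorph" in term.lower() or "unspecific" in term.lower():
                row = _UNSPECIFIC
            else:
                row = _OTHER
                logger.warning(
                    "case %s: term %r outside vocabulary; counted under 'other'",
                    case.case_id, term,
                )
            for a in arms:
                matrix.cells.setdefault((row, a), []).append(case.case_id)
        for a in arms:
            contributors[a].add(case.case_id)
    matrix.column_totals = {a: len(ids) for a, ids in contributors.items()}
    return matrix
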