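"""Core domain types for pericentric dosage-sensitivity mapping.

All genomic coordinates are stored 1-based inclusive, exactly as printed in
cytogenomic case reports; conversion to the 0-based half-open BED convention
happens only at the BED file boundary (:mod:`ssmc11.io`).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

GRCH37 = "GRCh37"

#: Genome-build aliases normalised on input (the cohort tables mix hg19/GRCh37).
_BUILD_ALIASES = {"hg19": GRCH37, "grch37": GRCH37, "GRCh37": GRCH37}

#: Closed vocabulary of formation/feature labels a case may carry.
GROUP_LABELS = frozenset(
    {
        "complex",
        "discontinuous",
        "McClintock",
        "pseudo-McClintock",
        "multiple-sSMC",
        "acquired",
        "UPD-associated",
    }
)

#: Labels that exclude a case from span/window inference.
EXCLUSION_LABELS = frozenset(
    {
        "complex",
        "discontinuous",
        "multiple-sSMC",
        "McClintock",
        "pseudo-McClintock",
        "acquired",
        "UPD-associated",
    }
)

EVIDENCE_MODALITIES = frozenset({"banding", "ish", "aCGH", "sequencing"})


class BuildMismatchError(ValueError):
    """Raised when an operation mixes intervals from different genome builds."""


class Sex(str, enum.Enum):
    male = "male"
    female = "female"
    unknown = "unknown"


class ClinicalStatus(str, enum.Enum):
    #: clinically normal (may include infertility as sole finding)
    normal = "normal"
    abnormal = "abnormal"
    unknown = "unknown"


class Shape(str, enum.Enum):
    """The three sSMC shapes plus the not-reported bucket."""

    min = "min"  # centric minute
    r = "r"  # ring
    inv_dup = "inv dup"  # inverted duplication
    unknown = "unknown"


class Inheritance(str, enum.Enum):
    maternal = "maternal"
    paternal = "paternal"
    de_novo = "de novo"
    unknown = "unknown"


def normalize_build(token: str) -> str:
    return _BUILD_ALIASES.get(token.strip(), token.strip())


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 1-based inclusive span on a named chromosome of a named genome build."""

    chrom: str
    start: int
    end: int
    build: str = GRCH37

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(f"end ({self.end}) < start ({self.start})")
        if not self.build:
            raise ValueError("build must be a non-empty token")
        object.__setattr__(self, "build", normalize_build(self.build))

    # -- arithmetic ------------------------------------------------------

    def _check(self, other: "GenomicInterval") -> None:
        if self.build != other.build:
            raise BuildMismatchError(
                f"cannot mix builds {self.build!r} and {other.build!r}"
            )

    def length(self) -> int:
        """Printed-length convention: end - start (no +1)."""
        return self.end - self.start

    def span_bp(self) -> int:
        """Number of bases covered (inclusive length)."""
        return self.end - self.start + 1

    def overlaps(self, other: "GenomicInterval") -> bool:
        self._check(other)
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and other.start <= self.end
        )

    def abuts(self, other: "GenomicInterval") -> bool:
        """True when the two intervals are adjacent with no gap between them."""
        self._check(other)
        return self.chrom == other.chrom and (
            self.end + 1 == other.start or other.end + 1 == self.start
        )

    def contains(self, other: "GenomicInterval") -> bool:
        self._check(other)
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def contains_pos(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def union_extent(self, other: "GenomicInterval") -> "GenomicInterval":
        """Outermost extent of the two intervals (hull, gaps ignored)."""
        self._check(other)
        if self.chrom != other.chrom:
            raise ValueError("union_extent requires a single chromosome")
        return replace(
            self, start=min(self.start, other.start), end=max(self.end, other.end)
        )

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.start:,}-{self.end:,} ({self.build})"


def hull(intervals: Iterable[GenomicInterval]) -> GenomicInterval:
    """Outermost extent of a non-empty collection of same-chromosome intervals."""
    it = iter(intervals)
    try:
        acc = next(it)
    except StopIteration:
        raise ValueError("hull() of empty collection") from None
    for iv in it:
        acc = acc.union_extent(iv)
    return acc


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping or abutting 1-based inclusive intervals."""
    ivs = sorted(intervals, key=lambda i: (i.chrom, i.start, i.end))
    merged: list[GenomicInterval] = []
    for iv in ivs:
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end + 1:
            if iv.end > merged[-1].end:
                merged[-1] = replace(merged[-1], end=iv.end)
        else:
            merged.append(iv)
    return merged


@dataclass
class CaseRecord:
    """One sSMC(11) carrier (or sSMC-like duplication carrier)."""

    case_id: str
    karyotype_text: str = ""
    sex: Sex = Sex.unknown
    clinical_status: ClinicalStatus = ClinicalStatus.unknown
    shape_calls: list[Shape] = field(default_factory=list)
    mosaic: bool = False
    clone_counts: list[int] = field(default_factory=list)
    inheritance: Inheritance = Inheritance.unknown
    group_labels: set[str] = field(default_factory=set)
    trisomy_interval: Optional[GenomicInterval] = None
    evidence_modalities: set[str] = field(default_factory=set)
    phenotype_terms: list[str] = field(default_factory=list)
    arm_class: Optional[str] = None  # "p" or "q", curated
    source_table: str = ""

    def __post_init__(self) -> None:
        bad = self.group_labels - GROUP_LABELS
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        if self.clinical_status is ClinicalStatus.normal and self.phenotype_terms:
            raise ValueError(
                f"case {self.case_id}: clinically normal cases carry no phenotype terms"
            )
        if (
            self.trisomy_interval is not None
            and self.trisomy_interval.build != GRCH37
        ):
            raise ValueError(
                f"case {self.case_id}: trisomy interval must be on {GRCH37}"
            )
        if self.arm_class not in (None, "p", "q"):
            raise ValueError(f"arm_class must be p/q/None, got {self.arm_class!r}")

    @property
    def predominant_shape(self) -> Shape:
        if not self.shape_calls:
            return Shape.unknown
        return self.shape_calls[0]


@dataclass(frozen=True)
class EvidenceRecord:
    """A population-CNV or pathogenic-report record used for span refinement.

    ``flank_only`` marks records for which only the pericentric-facing boundary
    coordinate is asserted by the source; the record still carries a full
    interval, but only that boundary participates in inference.
    """

    record_id: str
    classification: str  # "benign" | "pathogenic"
    interval: GenomicInterval
    flank_only: bool = False

    def __post_init__(self) -> None:
        if self.classification not in ("benign", "pathogenic"):
            raise ValueError(f"classification must be benign/pathogenic: {self.record_id}")


@dataclass
class DosageMap:
    """The inferred dosage landscape of pericentric chromosome 11.

    insensitive_span : minimal triplo-insensitive span from normal carriers
    refined_span     : after extension with benign population gains
    p_window/q_window: sensitive-start uncertainty windows (evidence-bounded)
    coarse_*_window  : windows bounded only by in-cohort abnormal carriers
    """

    insensitive_span: GenomicInterval
    refined_span: GenomicInterval
    centromere_anchor: GenomicInterval
    p_window: Optional[GenomicInterval] = None
    q_window: Optional[GenomicInterval] = None
    coarse_p_window: Optional[GenomicInterval] = None
    coarse_q_window: Optional[GenomicInterval] = None
    p_window_open: bool = False
    q_window_open: bool = False
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.refined_span.contains(self.insensitive_span):
            raise ValueError("refined_span must contain insensitive_span")
        if self.p_window is not None and self.p_window.end != self.refined_span.start:
            raise ValueError("p_window must end at refined_span.start")
        if self.q_window is not None and self.q_window.start != self.refined_span.end:
            raise ValueError("q_window must start at refined_span.end")
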