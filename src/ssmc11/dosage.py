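"""Pericentric dosage-sensitivity inference.

The model is a two-zone assumption per chromosome arm: triplo-insensitive
territory adjacent to the centromere followed by triplo-sensitive territory
distally, with a single unknown changeover point per arm. Clinically normal
carriers of a pericentric gain prove every base they carry in three copies is
insensitive; benign population gains extend that proof; clinically abnormal
carriers and pathogenic patient reports prove their gained territory reaches
at or beyond the changeover point, bounding where sensitive territory begins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

from intervaltree import IntervalTree

from .types import (
    CaseRecord,
    ClinicalStatus,
    DosageMap,
    EvidenceRecord,
    EXCLUSION_LABELS,
    GenomicInterval,
    hull,
    merge_intervals,
)

logger = logging.getLogger(__name__)

__all__ = [
    "InferenceError",
    "FilterResult",
    "filter_informative",
    "insensitive_span",
    "refine_with_population",
    "sensitive_windows",
    "build_dosage_map",
    "report",
]


class InferenceError(ValueError):
    pass


@dataclass
class FilterResult:
    normals: list[CaseRecord]
    abnormals: list[CaseRecord]
    excluded: list[tuple[CaseRecord, str]] = field(default_factory=list)


def filter_informative(
    cohort: Sequence[CaseRecord],
    anchor: Optional[GenomicInterval] = None,
    min_mosaic_fraction: float = 0.0,
    mosaic_fractions: Optional[dict[str, float]] = None,
) -> FilterResult:
    """Partition a cohort into span-informative normals/abnormals and excluded.

    A case is informative iff its clinical status is known, its trisomy
    interval is resolved on GRCh37, it carries none of the exclusion labels
    (complex, discontinuous, multiple-sSMC, (pseudo-)McClintock, acquired,
    UPD-associated), and — when a centromere anchor is supplied — its interval
    demonstrates euchromatin beyond the anchor (a centromere-only signal such
    as an isolated D11Z1+ proves no euchromatic gain). Each excluded case
    carries the first matching exclusion reason.

    Mosaic cases participate regardless of mosaic level by default
    (``min_mosaic_fraction=0``); a threshold can be supplied together with
    per-case fractions.
    """
    if not cohort:
        raise InferenceError("empty cohort")
    res = FilterResult([], [])
    for case in cohort:
        bad = sorted(case.group_labels & EXCLUSION_LABELS)
        if bad:
            res.excluded.append((case, bad[0]))
            continue
        if case.clinical_status is ClinicalStatus.unknown:
            res.excluded.append((case, "status unknown"))
            continue
        iv = case.trisomy_interval
        if iv is None:
            res.excluded.append((case, "no resolvable GRCh37 interval"))
            continue
        if anchor is not None and iv.start >= anchor.start - 1 and iv.end <= anchor.end:
            # a centromere-only extent (e.g. isolated D11Z1+, whose operational
            # span starts one bp before the 1-based acen start) proves nothing
            # about euchromatic dosage tolerance
            res.excluded.append((case, "no euchromatic extent beyond centromere"))
            continue
        if min_mosaic_fraction > 0 and mosaic_fractions is not None:
            frac = mosaic_fractions.get(case.case_id)
            if frac is not None and frac < min_mosaic_fraction:
                res.excluded.append((case, "below mosaic-fraction threshold"))
                continue
        bucket = (
            res.normals
            if case.clinical_status is ClinicalStatus.normal
            else res.abnormals
        )
        bucket.append(case)
        logger.info(
            "case %s: informative %s (%s)", case.case_id,
            case.clinical_status.value, iv,
        )
    for case, reason in res.excluded:
        logger.info("case %s: excluded (%s)", case.case_id, reason)
    return res


def insensitive_span(
    normals: Sequence[GenomicInterval],
    anchor: GenomicInterval,
) -> tuple[GenomicInterval, list[str]]:
    """Minimal demonstrated triplo-insensitive span from normal carriers.

    Returns the outermost extent [min start, max end] of the inputs. When the
    union of the inputs does not contiguously cover that extent, the
    centromere-containing connected component is returned instead, with a gap
    warning. Every input must intersect or abut the anchor or be connected to
    it through the union of the inputs.
    """
    if not normals:
        raise InferenceError("no informative normal intervals")
    warnings: list[str] = []
    merged = merge_intervals(list(normals) + [anchor])
    anchored = [m for m in merged if m.overlaps(anchor) or m.abuts(anchor)]
    component = anchored[0]
    outer = hull(normals)
    if len(merged) > 1:
        warnings.append(
            f"inputs do not contiguously cover {outer}; returning the "
            f"centromere-anchored component {component}"
        )
        span = GenomicInterval(
            component.chrom,
            max(component.start, outer.start),
            min(component.end, outer.end),
            component.build,
        )
        return span, warnings
    # the anchor itself must not widen the span beyond demonstrated gains
    return outer, warnings


def refine_with_population(
    span: GenomicInterval,
    evidence: Sequence[EvidenceRecord],
) -> tuple[GenomicInterval, list[str]]:
    """Extend the insensitive span with overlapping benign population gains.

    Any benign record overlapping the current span proves its full extent is
    tolerated; the span absorbs the record's outer boundaries. The extension
    iterates to a fixed point so chained records propagate. Pathogenic records
    never extend the span; benign records on other chromosomes are skipped
    with a warning.
    """
    warnings: list[str] = []
    benign = []
    for rec in evidence:
        if rec.classification != "benign":
            continue
        if rec.interval.chrom != span.chrom:
            warnings.append(f"benign record {rec.record_id} on chr{rec.interval.chrom}; skipped")
            continue
        benign.append(rec)
    tree = IntervalTree()
    for rec in benign:
        # half-open tree coordinates; +1 keeps inclusive-end overlap semantics
        tree.addi(rec.interval.start, rec.interval.end + 1, rec)
    current = span
    while True:
        hits = tree.overlap(current.start, current.end + 1)
        if not hits:
            break
        extended = current
        for hit in hits:
            extended = extended.union_extent(hit.data.interval)
            logger.info("span absorbs benign record %s", hit.data.record_id)
        tree.remove_overlap(current.start, current.end + 1)
        if extended == current:
            break
        current = extended
    return current, warnings


def _pathogenic_flank(
    evidence: Sequence[EvidenceRecord], refined: GenomicInterval, arm: str
) -> Optional[int]:
    """Nearest pathogenic-covered coordinate on one side of the refined span.

    On p this is the maximum covered coordinate below the span start; on q the
    minimum covered coordinate above the span end. Ties collapse (equal
    coordinates deduplicate); the coordinate closest to the span wins.
    """
    coords: list[int] = []
    for rec in evidence:
        if rec.classification != "pathogenic" or rec.interval.chrom != refined.chrom:
            continue
        iv = rec.interval
        if arm == "p" and iv.start < refined.start:
            coords.append(min(iv.end, refined.start - 1) if iv.end >= refined.start else iv.end)
        elif arm == "q" and iv.end > refined.end:
            coords.append(max(iv.start, refined.end + 1) if iv.start <= refined.end else iv.start)
    if not coords:
        return None
    return max(coords) if arm == "p" else min(coords)


def sensitive_windows(
    refined: GenomicInterval,
    abnormals: Sequence[GenomicInterval],
    evidence: Sequence[EvidenceRecord],
    anchor: GenomicInterval,
    unrefined: Optional[GenomicInterval] = None,
) -> dict:
    """Bound where triplo-sensitive territory begins on each arm.

    Evidence-refined windows: the p window runs from the nearest pathogenic
    covered coordinate on the p side up to the refined span start (where
    insensitivity is proven); the q window from the refined span end to the
    nearest pathogenic coordinate on the q side. An arm with no pathogenic
    record is flagged open-ended.

    Coarse windows use only in-cohort abnormal case intervals against the
    *unrefined* span: an abnormal interval extending beyond the span proves a
    sensitive locus within its extension, so the innermost (centromere-
    nearest) telomere-ward extreme among such intervals is the tightest
    abnormal-derived bound.
    """
    if refined is None:
        raise InferenceError("refined span missing")
    base = unrefined if unrefined is not None else refined
    out: dict = {
        "p_window": None, "q_window": None,
        "coarse_p_window": None, "coarse_q_window": None,
        "p_open": False, "q_open": False, "warnings": [],
    }

    fp = _pathogenic_flank(evidence, refined, "p")
    if fp is None:
        out["p_open"] = True
        out["warnings"].append("no pathogenic evidence on p; window open-ended")
    else:
        out["p_window"] = GenomicInterval(refined.chrom, fp, refined.start, refined.build)
    fq = _pathogenic_flank(evidence, refined, "q")
    if fq is None:
        out["q_open"] = True
        out["warnings"].append("no pathogenic evidence on q; window open-ended")
    else:
        out["q_window"] = GenomicInterval(refined.chrom, refined.end, fq, refined.build)

    # only single-arm extenders localize the proven sensitive locus to an arm:
    # a case extending beyond the span on both arms is ambiguous and bounds
    # neither window
    p_starts = [
        iv.start for iv in abnormals if iv.start < base.start and iv.end <= base.end
    ]
    q_ends = [
        iv.end for iv in abnormals if iv.end > base.end and iv.start >= base.start
    ]
    ambiguous = [
        iv for iv in abnormals if iv.start < base.start and iv.end > base.end
    ]
    if ambiguous:
        out["warnings"].append(
            f"{len(ambiguous)} abnormal interval(s) extend beyond the span on "
            "both arms; arm-ambiguous, not used for coarse windows"
        )
    if p_starts:
        out["coarse_p_window"] = GenomicInterval(
            base.chrom, max(p_starts), base.start, base.build
        )
    if q_ends:
        out["coarse_q_window"] = GenomicInterval(
            base.chrom, base.end, min(q_ends), base.build
        )
    return out


def build_dosage_map(
    normals: Sequence[CaseRecord],
    abnormals: Sequence[CaseRecord],
    evidence: Sequence[EvidenceRecord],
    anchor: GenomicInterval,
) -> DosageMap:
    """End-to-end inference from informative cases + evidence to a DosageMap."""
    normal_ivs = [c.trisomy_interval for c in normals if c.trisomy_interval]
    abnormal_ivs = [c.trisomy_interval for c in abnormals if c.trisomy_interval]
    span, w1 = insensitive_span(normal_ivs, anchor)
    refined, w2 = refine_with_population(span, evidence)
    win = sensitive_windows(refined, abnormal_ivs, evidence, anchor, unrefined=span)
    return DosageMap(
        insensitive_span=span,
        refined_span=refined,
        centromere_anchor=anchor,
        p_window=win["p_window"],
        q_window=win["q_window"],
        coarse_p_window=win["coarse_p_window"],
        coarse_q_window=win["coarse_q_window"],
        p_window_open=win["p_open"],
        q_window_open=win["q_open"],
        warnings=w1 + w2 + win["warnings"],
    )


def _mb(bp: int) -> float:
    return round(bp / 1e6, 2)


def report(dmap: DosageMap) -> dict:
    """Structured report: BED track rows, boundary table, and text summary.

    Lengths follow the printed convention end - start (no +1), in Mb rounded
    to two decimals.
    """
    # three tracks: the centromere anchor, the insensitive spans, the windows
    # (a complete map emits 5 records; coarse windows live in the boundary TSV)
    bed: list[tuple[GenomicInterval, str]] = [
        (dmap.centromere_anchor, "centromere_anchor"),
        (dmap.insensitive_span, "triplo_insensitive_minimal"),
        (dmap.refined_span, "triplo_insensitive_refined"),
    ]
    for iv, label in (
        (dmap.p_window, "sensitive_start_window_p"),
        (dmap.q_window, "sensitive_start_window_q"),
    ):
        if iv is not None:
            bed.append((iv, label))

    boundaries = {
        "insensitive_start": dmap.insensitive_span.start,
        "insensitive_end": dmap.insensitive_span.end,
        "refined_start": dmap.refined_span.start,
        "refined_end": dmap.refined_span.end,
        "p_window_far": dmap.p_window.start if dmap.p_window else None,
        "q_window_far": dmap.q_window.end if dmap.q_window else None,
        "coarse_p_window_far": dmap.coarse_p_window.start if dmap.coarse_p_window else None,
        "coarse_q_window_far": dmap.coarse_q_window.end if dmap.coarse_q_window else None,
    }

    lines = [
        f"Minimal triplo-insensitive span: {dmap.insensitive_span} "
        f"({_mb(dmap.insensitive_span.length()):.2f} Mb)",
        f"Refined triplo-insensitive span: {dmap.refined_span} "
        f"({_mb(dmap.refined_span.length()):.2f} Mb)",
    ]
    if dmap.p_window is not None:
        lines.append(
            f"11p sensitive-start window: {dmap.p_window} "
            f"({_mb(dmap.p_window.length()):.2f} Mb)"
        )
    elif dmap.p_window_open:
        lines.append("11p sensitive-start window: not narrowable (open-ended)")
    if dmap.q_window is not None:
        lines.append(
            f"11q sensitive-start window: {dmap.q_window} "
            f"({_mb(dmap.q_window.length()):.2f} Mb)"
        )
    elif dmap.q_window_open:
        lines.append("11q sensitive-start window: not narrowable (open-ended)")
    if dmap.coarse_p_window is not None:
        lines.append(f"Coarse 11p window (in-cohort only): {dmap.coarse_p_window}")
    if dmap.coarse_q_window is not None:
        lines.append(f"Coarse 11q window (in-cohort only): {dmap.coarse_q_window}")
    lines.extend(f"WARNING: {w}" for w in dmap.warnings)

    return {"bed": bed, "boundaries": boundaries, "summary": "\n".join(lines)}
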