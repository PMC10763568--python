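"""Span/window inference: exact fixture boundaries, properties, brute-force oracle."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ssmc11.dosage import (
    InferenceError,
    build_dosage_map,
    filter_informative,
    insensitive_span,
    refine_with_population,
    report,
    sensitive_windows,
)
from ssmc11.simulate import SimConfig, generate, truth_evidence
from ssmc11.types import (
    CaseRecord,
    ClinicalStatus,
    EvidenceRecord,
    EXCLUSION_LABELS,
    GenomicInterval,
)

ANCHOR = GenomicInterval("11", 51_600_001, 55_700_000)
GRID = 10_000


def iv(start, end):
    return GenomicInterval("11", start, end)


# ----------------------------------------------------------------------
# independent oracles (plain per-position / per-case re-implementations)
# ----------------------------------------------------------------------

def oracle_partition(cohort, anchor):
    """Brute-force re-application of the informativeness rule list."""
    normals, abnormals, excluded = [], [], []
    for c in cohort:
        if c.group_labels & EXCLUSION_LABELS:
            excluded.append(c.case_id)
        elif c.clinical_status is ClinicalStatus.unknown:
            excluded.append(c.case_id)
        elif c.trisomy_interval is None:
            excluded.append(c.case_id)
        elif (c.trisomy_interval.start >= anchor.start - 1
              and c.trisomy_interval.end <= anchor.end):
            excluded.append(c.case_id)
        elif c.clinical_status is ClinicalStatus.normal:
            normals.append(c.case_id)
        else:
            abnormals.append(c.case_id)
    return normals, abnormals, excluded


def oracle_span(normal_ivs, anchor, grid=GRID):
    """Per-position scan: maximal anchored run covered by >=1 normal interval."""
    lo = min([n.start for n in normal_ivs] + [anchor.start]) - grid
    hi = max([n.end for n in normal_ivs] + [anchor.end]) + grid
    pos = np.arange(lo, hi + grid, grid)
    covered = np.zeros(len(pos), dtype=bool)
    for n in normal_ivs:
        covered |= (pos >= n.start) & (pos <= n.end)
    anchored = covered | ((pos >= anchor.start) & (pos <= anchor.end))
    centromere_idx = np.searchsorted(pos, (anchor.start + anchor.end) // 2)
    i = j = centromere_idx
    while i > 0 and anchored[i - 1]:
        i -= 1
    while j < len(pos) - 1 and anchored[j + 1]:
        j += 1
    run = covered[i : j + 1]
    sub = pos[i : j + 1][run]
    return int(sub.min()), int(sub.max())


def oracle_windows(span, abnormal_ivs, evidence, grid=GRID):
    """Per-position classification of pathogenic-implicated coordinates plus a
    per-case loop for the coarse in-cohort windows."""
    start, end = span
    path_p = [
        min(e.interval.end, start - 1)
        for e in evidence
        if e.classification == "pathogenic" and e.interval.start < start
    ]
    path_q = [
        max(e.interval.start, end + 1)
        for e in evidence
        if e.classification == "pathogenic" and e.interval.end > end
    ]
    fp = max(path_p) if path_p else None
    fq = min(path_q) if path_q else None
    coarse_p = [a.start for a in abnormal_ivs if a.start < start and a.end <= end]
    coarse_q = [a.end for a in abnormal_ivs if a.end > end and a.start >= start]
    return (
        fp,
        fq,
        max(coarse_p) if coarse_p else None,
        min(coarse_q) if coarse_q else None,
    )


# ----------------------------------------------------------------------
# filter_informative
# ----------------------------------------------------------------------

class TestFilterInformative:
    def test_packaged_cohort_normals_are_the_five_span_cases(
        self, full_cohort, anchor
    ):
        res = filter_informative(full_cohort, anchor=anchor)
        assert sorted(c.case_id for c in res.normals) == ["1", "2", "6", "7", "A"]

    def test_all_excluded_cohort_carries_reason(self):
        cases = [
            CaseRecord(case_id=str(i), group_labels={"multiple-sSMC"},
                       clinical_status=ClinicalStatus.abnormal,
                       trisomy_interval=iv(40_000_000, 60_000_000))
            for i in range(3)
        ]
        res = filter_informative(cases)
        assert not res.normals and not res.abnormals
        assert all(reason == "multiple-sSMC" for _, reason in res.excluded)

    def test_empty_cohort_raises(self):
        with pytest.raises(InferenceError):
            filter_informative([])

    def test_partition_matches_independent_predicate_on_synthetic(self):
        cohort, _ = generate(SimConfig(seed=11, n_cases=200, frac_uninformative=0.5))
        res = filter_informative(cohort, anchor=ANCHOR)
        n, a, e = oracle_partition(cohort, ANCHOR)
        assert sorted(c.case_id for c in res.normals) == sorted(n)
        assert sorted(c.case_id for c in res.abnormals) == sorted(a)
        assert sorted(c.case_id for c, _ in res.excluded) == sorted(e)


# ----------------------------------------------------------------------
# insensitive_span
# ----------------------------------------------------------------------

class TestInsensitiveSpan:
    def test_five_published_intervals_give_printed_span(self, table3, anchor):
        span, warnings = insensitive_span(
            [c.trisomy_interval for c in table3], anchor
        )
        assert (span.start, span.end) == (48_303_671, 60_473_821)
        assert warnings == []

    def test_single_interval_is_identity(self, anchor):
        single = iv(50_000_000, 56_000_000)
        span, _ = insensitive_span([single], anchor)
        assert span == single

    def test_gap_returns_anchored_component_with_warning(self, anchor):
        near = iv(50_000_000, 56_000_000)
        far = iv(70_000_000, 72_000_000)  # disconnected from the centromere
        span, warnings = insensitive_span([near, far], anchor)
        assert span == near
        assert any("gap" in w or "component" in w for w in warnings)

    def test_empty_input_raises(self, anchor):
        with pytest.raises(InferenceError):
            insensitive_span([], anchor)

    def test_matches_per_position_oracle_on_random_sets(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            ivs = []
            for _ in range(rng.integers(1, 8)):
                s = int(rng.integers(3_000, 5_160)) * GRID
                e = int(rng.integers(5_570, 8_000)) * GRID
                ivs.append(iv(s, e))
            span, _ = insensitive_span(ivs, ANCHOR)
            assert (span.start, span.end) == oracle_span(ivs, ANCHOR)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(
        st.tuples(st.integers(3_000, 5_160), st.integers(5_570, 8_000)),
        min_size=1, max_size=10,
    ))
    def test_adding_a_normal_interval_never_shrinks(self, pairs):
        ivs = [iv(s * GRID, e * GRID) for s, e in pairs]
        base, _ = insensitive_span(ivs, ANCHOR)
        grown, _ = insensitive_span(ivs + [iv(50_000_000, 56_000_000)], ANCHOR)
        assert grown.start <= base.start and grown.end >= base.end


# ----------------------------------------------------------------------
# refine_with_population
# ----------------------------------------------------------------------

SPAN = iv(48_303_671, 60_473_821)


def benign(rid, s, e):
    return EvidenceRecord(rid, "benign", iv(s, e))


class TestRefineWithPopulation:
    def test_packaged_evidence_gives_printed_refined_span(self, evidence):
        refined, _ = refine_with_population(SPAN, evidence)
        assert (refined.start, refined.end) == (47_675_469, 60_516_539)

    def test_no_overlapping_benign_is_identity(self):
        refined, _ = refine_with_population(
            SPAN, [benign("x", 70_000_000, 71_000_000)]
        )
        assert refined == SPAN

    def test_chained_records_reach_fixed_point(self):
        # A overlaps the span, B overlaps only A: transitive closure
        a = benign("a", 47_000_000, 48_400_000)
        b = benign("b", 45_500_000, 47_100_000)
        refined, _ = refine_with_population(SPAN, [a, b])
        assert refined.start == 45_500_000

    def test_refinement_is_idempotent(self, evidence):
        once, _ = refine_with_population(SPAN, evidence)
        twice, _ = refine_with_population(once, evidence)
        assert once == twice

    def test_pathogenic_records_never_extend(self, evidence):
        pathogenic_only = [e for e in evidence if e.classification == "pathogenic"]
        refined, _ = refine_with_population(SPAN, pathogenic_only)
        assert refined == SPAN

    def test_other_chromosome_benign_skipped_with_warning(self):
        rec = EvidenceRecord("y", "benign", GenomicInterval("12", 1, 2))
        refined, warnings = refine_with_population(SPAN, [rec])
        assert refined == SPAN
        assert any("chr12" in w for w in warnings)


# ----------------------------------------------------------------------
# sensitive_windows
# ----------------------------------------------------------------------

class TestSensitiveWindows:
    def test_printed_window_boundaries_and_widths(self, table4, evidence, anchor):
        refined = iv(47_675_469, 60_516_539)
        win = sensitive_windows(
            refined, [c.trisomy_interval for c in table4], evidence, anchor,
            unrefined=SPAN,
        )
        p, q = win["p_window"], win["q_window"]
        assert (p.start, p.end) == (45_048_321, 47_675_469)
        assert (q.start, q.end) == (60_516_539, 61_479_322)
        assert round(p.length() / 1e6, 2) == 2.63
        assert round(q.length() / 1e6, 2) == 0.96
        assert (win["coarse_p_window"].start, win["coarse_p_window"].end) == (
            42_922_228, 48_303_671,
        )
        assert (win["coarse_q_window"].start, win["coarse_q_window"].end) == (
            60_473_821, 79_072_352,
        )

    def test_missing_q_evidence_flags_open_window(self, table4, anchor):
        p_only = [
            EvidenceRecord("p", "pathogenic", iv(44_000_000, 45_048_321), True)
        ]
        win = sensitive_windows(
            iv(47_675_469, 60_516_539),
            [c.trisomy_interval for c in table4], p_only, anchor,
        )
        assert win["q_window"] is None and win["q_open"]
        assert win["p_window"] is not None and not win["p_open"]

    def test_adding_pathogenic_record_never_widens(self, evidence, anchor):
        refined = iv(47_675_469, 60_516_539)
        base = sensitive_windows(refined, [], evidence, anchor)
        closer = list(evidence) + [
            EvidenceRecord("c", "pathogenic", iv(46_000_000, 47_000_000), True)
        ]
        tighter = sensitive_windows(refined, [], closer, anchor)
        assert tighter["p_window"].length() <= base["p_window"].length()

    def test_matches_oracle_on_random_cohorts(self):
        rng = np.random.default_rng(13)
        for _ in range(60):
            span = iv(
                int(rng.integers(4_400, 4_900)) * GRID,
                int(rng.integers(5_800, 6_400)) * GRID,
            )
            abnormals = []
            for _ in range(rng.integers(0, 6)):
                s = int(rng.integers(3_500, 5_160)) * GRID
                e = int(rng.integers(5_570, 7_500)) * GRID
                abnormals.append(iv(s, e))
            evidence = []
            for k in range(rng.integers(0, 4)):
                s = int(rng.integers(3_500, 7_400)) * GRID
                e = s + int(rng.integers(1, 50)) * GRID
                evidence.append(EvidenceRecord(f"e{k}", "pathogenic", iv(s, e)))
            win = sensitive_windows(span, abnormals, evidence, ANCHOR)
            fp, fq, cp, cq = oracle_windows(
                (span.start, span.end), abnormals, evidence
            )
            assert (win["p_window"].start if win["p_window"] else None) == fp
            assert (win["q_window"].end if win["q_window"] else None) == fq
            assert (
                win["coarse_p_window"].start if win["coarse_p_window"] else None
            ) == cp
            assert (
                win["coarse_q_window"].end if win["coarse_q_window"] else None
            ) == cq


# ----------------------------------------------------------------------
# end-to-end map + report
# ----------------------------------------------------------------------

class TestReport:
    def test_summary_reports_refined_length_in_mb(self, dosage_map):
        rep = report(dosage_map)
        assert "12.84 Mb" in rep["summary"]

    def test_complete_map_emits_five_bed_records(self, dosage_map):
        rep = report(dosage_map)
        assert len(rep["bed"]) == 5

    def test_open_q_window_marked_not_narrowable(self, table3, table4, anchor):
        p_only = [
            EvidenceRecord("p", "pathogenic", iv(44_000_000, 45_048_321), True)
        ]
        dmap = build_dosage_map(table3, table4, p_only, anchor)
        rep = report(dmap)
        assert "not narrowable" in rep["summary"]

    def test_map_invariants(self, dosage_map):
        d = dosage_map
        assert d.refined_span.contains(d.insensitive_span)
        assert d.p_window.end == d.refined_span.start
        assert d.q_window.start == d.refined_span.end
        assert d.coarse_p_window.start <= d.p_window.start
        assert d.coarse_q_window.end >= d.q_window.end
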