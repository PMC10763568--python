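"""Synthetic cohort generator: determinism, noise model, recovery mechanics."""

import pytest

from ssmc11.io import read_cohort, write_cohort
from ssmc11.iscn import parse_karyotype
from ssmc11.simulate import (
    ConfigError,
    SimConfig,
    generate,
    recovery_experiment,
    truth_evidence,
)
from ssmc11.types import ClinicalStatus, GenomicInterval


def noise_free(seed, n=50, **kw):
    return SimConfig(seed=seed, n_cases=n, penetrance=1.0,
                     misclassification_rate=0.0, frac_uninformative=0.0, **kw)


class TestGenerate:
    def test_same_seed_gives_byte_identical_tables(self, tmp_path):
        a, b = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_cohort(generate(noise_free(1))[0], a)
        write_cohort(generate(noise_free(1))[0], b)
        assert a.read_bytes() == b.read_bytes()

    def test_different_seeds_differ(self):
        a, _ = generate(noise_free(1))
        b, _ = generate(noise_free(2))
        assert any(x.karyotype_text != y.karyotype_text for x, y in zip(a, b))

    def test_noise_free_abnormal_iff_covers_locus(self):
        cohort, truth = generate(noise_free(1))
        covers = {f["case_id"]: f["covers"] for f in truth.flags}
        for case in cohort:
            assert (case.clinical_status is ClinicalStatus.abnormal) == covers[
                case.case_id
            ]

    def test_penetrance_fraction_within_binomial_bound(self):
        cfg = SimConfig(seed=4, n_cases=2000, penetrance=0.8,
                        misclassification_rate=0.0, frac_uninformative=0.0)
        cohort, truth = generate(cfg)
        status = {c.case_id: c.clinical_status for c in cohort}
        covering = [f["case_id"] for f in truth.flags if f["covers"]]
        assert len(covering) > 200
        frac = sum(
            status[cid] is ClinicalStatus.abnormal for cid in covering
        ) / len(covering)
        assert abs(frac - 0.8) <= 0.03

    def test_intervals_are_grid_aligned_and_contain_anchor(self):
        cfg = noise_free(9)
        cohort, _ = generate(cfg)
        for case in cohort:
            iv = case.trisomy_interval
            assert iv.start % cfg.grid == 0 and iv.end % cfg.grid == 0
            assert iv.start <= cfg.anchor.start and iv.end >= cfg.anchor.end

    def test_generated_karyotypes_parse_and_match_interval(self):
        cohort, _ = generate(noise_free(3))
        for case in cohort:
            pk = parse_karyotype(case.karyotype_text)
            assert pk.array_interval == case.trisomy_interval
            assert pk.mosaic == case.mosaic

    def test_cohort_round_trips_through_io(self, tmp_path):
        cohort, _ = generate(SimConfig(seed=5, n_cases=30, frac_uninformative=0.4))
        path = tmp_path / "c.tsv"
        write_cohort(cohort, path)
        again = read_cohort(path)
        assert [c.case_id for c in again] == [c.case_id for c in cohort]
        assert [c.trisomy_interval for c in again] == [
            c.trisomy_interval for c in cohort
        ]
        assert [c.clinical_status for c in again] == [
            c.clinical_status for c in cohort
        ]

    @pytest.mark.parametrize(
        "field,value",
        [
            ("penetrance", 1.5),
            ("misclassification_rate", -0.1),
            ("frac_uninformative", 2.0),
            ("n_cases", 0),
            ("extent_scale_p", 0.0),
        ],
    )
    def test_invalid_config_names_field(self, field, value):
        cfg = noise_free(1)
        setattr(cfg, field, value)
        with pytest.raises(ConfigError, match=field):
            cfg.validate()

    def test_sensitive_loci_must_lie_outside_true_span(self):
        cfg = noise_free(1)
        cfg.sensitive_loci_p = (50_000_000,)
        with pytest.raises(ConfigError, match="sensitive_loci_p"):
            cfg.validate()


class TestTruthEvidence:
    def test_benign_outer_bounds_are_true_span_edges(self):
        cfg = noise_free(1)
        ev = truth_evidence(cfg)
        benign = [e for e in ev if e.classification == "benign"]
        assert min(e.interval.start for e in benign) == cfg.true_insensitive.start
        assert max(e.interval.end for e in benign) == cfg.true_insensitive.end

    def test_pathogenic_flanks_sit_at_loci(self):
        cfg = noise_free(1)
        ev = [e for e in truth_evidence(cfg) if e.classification == "pathogenic"]
        p_bounds = {e.interval.end for e in ev if e.interval.end < cfg.anchor.start}
        q_bounds = {e.interval.start for e in ev if e.interval.start > cfg.anchor.end}
        assert p_bounds == set(cfg.sensitive_loci_p)
        assert q_bounds == set(cfg.sensitive_loci_q)


class TestRecovery:
    def test_noise_free_run_recovers_truth(self):
        rep = recovery_experiment(noise_free(2, n=200))
        assert rep["span_excludes_loci"]
        assert rep["p_window_contains_true"] and rep["q_window_contains_true"]

    def test_misclassification_flags_contamination(self):
        found = False
        for seed in range(5):
            rep = recovery_experiment(
                SimConfig(seed=seed, n_cases=200, penetrance=1.0,
                          misclassification_rate=0.3, frac_uninformative=0.0)
            )
            if rep.get("contamination_cases"):
                found = True
                break
        assert found, "30% label flipping should produce contaminated normals"

    def test_fully_uninformative_cohort_reports_failure(self):
        rep = recovery_experiment(
            SimConfig(seed=1, n_cases=20, frac_uninformative=1.0)
        )
        assert rep["n_normal"] == 0
        assert "failed" in rep
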