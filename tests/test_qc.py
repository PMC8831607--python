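"""Sample gates, variant QC conjunction, and coverage harmonization."""

import dataclasses
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import exocollapse as xc
from oracles import binom_two_sided_exact, brute_force_max_independent_set


def sm(sid, contamination=0.0, ccds=0.95):
    return xc.SampleMetrics(sid, contamination, ccds)


class TestSampleGates:
    def test_contamination_boundary(self):
        kept, log = xc.filter_samples([sm("a", contamination=0.09),
                                       sm("b", contamination=0.08)])
        assert kept == {"b"}
        assert log[0][0] == "a" and "contamination" in log[0][1]

    def test_ccds_coverage_boundary(self):
        kept, _ = xc.filter_samples([sm("a", ccds=0.87), sm("b", ccds=0.88)])
        assert kept == {"b"}

    def test_kinship_path_keeps_endpoints(self):
        metrics = [sm(x) for x in "ABC"]
        kept, log = xc.filter_samples(metrics, [("A", "B"), ("B", "C")])
        assert kept == {"A", "C"}
        assert ("B", "related (third degree or closer)") in log

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError):
            xc.filter_samples([sm("a"), sm("a")])

    def test_unknown_kinship_sample_rejected(self):
        with pytest.raises(ValueError):
            xc.filter_samples([sm("a")], [("a", "zzz")])

    def test_pruning_matches_brute_force_max_independent_set(self, rng):
        for trial in range(40):
            n = int(rng.integers(2, 11))
            nodes = [f"s{i}" for i in range(n)]
            edges = set()
            for i in range(n):
                for j in range(i + 1, n):
                    if rng.random() < 0.35:
                        edges.add((nodes[i], nodes[j]))
            kept, _ = xc.filter_samples([sm(x) for x in nodes], edges)
            best = brute_force_max_independent_set(nodes, edges)
            # maximum cardinality, and genuinely independent
            assert len(kept) == len(best)
            assert all((a, b) not in edges and (b, a) not in edges
                       for a in kept for b in kept if a != b)

    def test_excluded_samples_never_reappear(self):
        # a contaminated sample also in a kinship pair is excluded once,
        # and its partner survives
        metrics = [sm("a", contamination=0.5), sm("b")]
        kept, log = xc.filter_samples(metrics, [("a", "b")])
        assert kept == {"b"}
        assert [s for s, _ in log] == ["a"]


def metrics(**kw):
    base = dict(qual=100.0, qd=10.0, gq=50.0, mq=60.0, depth=30.0, fs=5.0,
                read_pos_rank_sum=0.0, mq_rank_sum=0.0, alt_allele_ratio=0.5,
                is_indel=False, evs_failure=False)
    base.update(kw)
    return xc.VariantQCMetrics(**base)


class TestVariantQC:
    def test_every_threshold_at_inclusive_boundary_passes(self):
        v = metrics(qual=30, qd=2, gq=20, read_pos_rank_sum=-3, mq=40,
                    mq_rank_sum=-9.9, depth=10, fs=60, alt_allele_ratio=0.25)
        ok, failed = xc.apply_variant_qc(v)
        assert ok and failed == []

    def test_fs_rule_differs_for_indels(self):
        assert xc.apply_variant_qc(metrics(fs=100, is_indel=True))[0]
        ok, failed = xc.apply_variant_qc(metrics(fs=100, is_indel=False))
        assert not ok and failed == ["fs"]

    def test_het_allele_balance(self):
        ok, failed = xc.apply_variant_qc(metrics(alt_allele_ratio=0.20))
        assert not ok and failed == ["alt_allele_ratio"]

    def test_absent_rank_sums_pass(self):
        v = metrics(read_pos_rank_sum=None, mq_rank_sum=None)
        assert xc.apply_variant_qc(v)[0]

    def test_evs_failure_fails(self):
        assert not xc.apply_variant_qc(metrics(evs_failure=True))[0]

    def test_mq_rank_sum_strictly_greater(self):
        assert not xc.apply_variant_qc(metrics(mq_rank_sum=-10.0))[0]
        assert xc.apply_variant_qc(metrics(mq_rank_sum=-9.999))[0]

    def test_negative_depth_rejected(self):
        with pytest.raises(ValueError):
            metrics(depth=-1)

    @settings(max_examples=80, deadline=None, derandomize=True)
    @given(qual=st.floats(0, 300), qd=st.floats(0, 40), gq=st.floats(0, 99),
           mq=st.floats(0, 70), depth=st.floats(0, 200), fs=st.floats(0, 300),
           ratio=st.floats(0, 1))
    def test_relaxing_thresholds_is_monotone(self, qual, qd, gq, mq, depth,
                                             fs, ratio):
        """The verdict is a pure conjunction: relaxing any single
        threshold can only turn fail into pass, never the reverse."""
        v = metrics(qual=qual, qd=qd, gq=gq, mq=mq, depth=depth, fs=fs,
                    alt_allele_ratio=ratio)
        strict = xc.QCThresholds()
        ok_strict, _ = xc.apply_variant_qc(v, strict)
        relaxations = dict(min_qual=0.0, min_qd=0.0, min_gq=0.0,
                           min_read_pos_rank_sum=-1e9, min_mq=0.0,
                           min_mq_rank_sum_exclusive=-1e9, min_depth=0.0,
                           max_fs_snv=1e9, max_fs_indel=1e9,
                           min_het_alt_ratio=0.0)
        for name, value in relaxations.items():
            relaxed = dataclasses.replace(strict, **{name: value})
            ok_relaxed, _ = xc.apply_variant_qc(v, relaxed)
            if ok_strict:
                assert ok_relaxed


class TestCoverageIndependence:
    def test_full_coverage_both_cohorts(self):
        assert xc.coverage_independence_test(849, 849, 15640, 15640) == 1.0

    def test_maximal_disparity_is_essentially_zero(self):
        p = xc.coverage_independence_test(0, 849, 15640, 15640)
        assert p < 1e-300

    def test_matches_exact_binomial_enumeration(self):
        cases = [(800, 849, 15000, 15640), (40, 50, 90, 100),
                 (10, 20, 25, 30), (49, 50, 99, 100)]
        for ca, n1, cc, n2 in cases:
            pooled = Fraction(ca + cc, n1 + n2)
            expected = float(binom_two_sided_exact(ca, n1, pooled))
            got = xc.coverage_independence_test(ca, n1, cc, n2)
            assert got == pytest.approx(expected, rel=1e-6)

    def test_label_swap_with_tested_side_is_identical(self, rng):
        # swapping the cohorts while also swapping which side is tested
        # is a pure relabeling and must give the same p exactly
        for _ in range(60):
            n1, n2 = 80, 400
            ca = int(rng.integers(0, n1 + 1))
            cc = int(rng.integers(0, n2 + 1))
            p1 = xc.coverage_independence_test(ca, n1, cc, n2, "cases")
            p2 = xc.coverage_independence_test(cc, n2, ca, n1, "controls")
            assert p1 == pytest.approx(p2, rel=1e-12)

    def test_zero_cohort_rejected(self):
        with pytest.raises(ValueError):
            xc.coverage_independence_test(0, 0, 5, 10)


class TestHarmonization:
    def test_fully_covered_cohort_keeps_everything(self):
        fx = xc.make_fixture_from_counts(3, 20, 5, 40)
        res = xc.harmonize_sites(fx.callset)
        assert len(res.excluded) == 0
        assert len(res.retained) == fx.callset.n_variants

    def test_control_only_coverage_excluded(self):
        fx = xc.make_fixture_from_counts(0, 849, 0, 15640)
        cs = xc.simulate_coverage_imbalance(fx.callset, 1, 0.0, 1.0, seed=5)
        res = xc.harmonize_sites(cs)
        assert len(res.excluded) == 1
        assert res.excluded[0][2] < 1e-100

    def test_moderate_imbalance_matches_per_site_oracle(self):
        fx = xc.make_fixture_from_counts(0, 300, 0, 1500, n_variants=8)
        cs = xc.simulate_coverage_imbalance(fx.callset, 8, 0.95, 0.99,
                                            seed=11)
        cov_case, cov_ctrl = cs.covered_counts()
        res = xc.harmonize_sites(cs, alpha=0.01)
        excluded = {j for j, _, _ in res.excluded}
        for j in range(cs.n_variants):
            pooled = Fraction(int(cov_case[j] + cov_ctrl[j]), 1800)
            p = float(binom_two_sided_exact(int(cov_case[j]), 300, pooled))
            assert (j in excluded) == (p <= 0.01)

    def test_imbalanced_sites_all_excluded_at_half_coverage(self):
        fx = xc.make_fixture_from_counts(0, 849, 0, 15640, n_variants=12)
        cs = xc.simulate_coverage_imbalance(fx.callset, 10, 0.5, 1.0, seed=3)
        res = xc.harmonize_sites(cs)
        assert len(res.excluded) == 10

    def test_null_exclusion_rate_near_alpha(self):
        """Equal coverage fractions in both cohorts: the harmonization
        test should exclude roughly 1% of sites at alpha = 0.01."""
        fx = xc.make_fixture_from_counts(0, 849, 0, 15640, n_variants=1200)
        cs = xc.simulate_coverage_imbalance(fx.callset, 1200, 0.95, 0.95,
                                            seed=7)
        res = xc.harmonize_sites(cs, alpha=0.01)
        rate = len(res.excluded) / 1200
        assert 0.001 <= rate <= 0.025
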