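"""Fisher exact machinery, odds ratios, thresholds, and gene collapsing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import exocollapse as xc
from oracles import fisher_two_sided_exact, naive_carrier_recount


class TestFisherTwoSided:
    def test_empty_table_is_one(self):
        assert xc.fisher_two_sided(0, 0, 0, 0) == 1.0
        assert xc.fisher_two_sided(0, 849, 0, 15640) == 1.0

    @pytest.mark.parametrize("table,expected", [
        # carrier tables of the three nested KRT82 models
        ((19, 830, 88, 15552), 2.03e-6),
        ((47, 802, 376, 15264), 9.19e-7),
        ((51, 798, 404, 15236), 2.18e-7),
    ])
    def test_large_cohort_tables(self, table, expected):
        assert xc.fisher_two_sided(*table) == pytest.approx(expected,
                                                            rel=5e-3)

    def test_matches_exact_enumeration_on_random_tables(self, rng):
        for _ in range(300):
            n = int(rng.integers(1, 120))
            r1 = int(rng.integers(0, n + 1))
            c1 = int(rng.integers(0, n + 1))
            a = int(rng.integers(max(0, c1 - (n - r1)), min(r1, c1) + 1))
            table = (a, r1 - a, c1 - a, n - r1 - c1 + a)
            assert xc.fisher_two_sided(*table) == pytest.approx(
                float(fisher_two_sided_exact(*table)), rel=1e-9, abs=1e-300)

    def test_paper_scale_matches_exact_enumeration(self):
        for table in [(19, 830, 88, 15552), (15, 834, 72, 15568),
                      (0, 849, 29, 15611)]:
            assert xc.fisher_two_sided(*table) == pytest.approx(
                float(fisher_two_sided_exact(*table)), rel=1e-9)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.tuples(*[st.integers(0, 40)] * 4))
    def test_label_swap_symmetry(self, table):
        a, b, c, d = table
        assert xc.fisher_two_sided(a, b, c, d) == pytest.approx(
            xc.fisher_two_sided(c, d, a, b), rel=1e-12)

    def test_p_monotone_in_case_excess(self):
        # moving carriers from controls to cases at fixed margins
        ps = [xc.fisher_two_sided(a, 100 - a, 50 - a, 950 + a)
              for a in range(8, 30)]
        assert all(p2 <= p1 + 1e-12 for p1, p2 in zip(ps, ps[1:]))

    @pytest.mark.parametrize("bad", [(-1, 2, 3, 4), (1.5, 2, 3, 4),
                                     (True, 2, 3, 4)])
    def test_invalid_cells_rejected(self, bad):
        with pytest.raises((ValueError, TypeError)):
            xc.fisher_two_sided(*bad)


class TestOddsRatio:
    @pytest.mark.parametrize("table,expected", [
        ((47, 802, 376, 15264), 2.38),
        ((51, 798, 404, 15236), 2.41),
    ])
    def test_sample_or_matches_printed(self, table, expected):
        assert round(xc.odds_ratio(*table, method="sample"), 2) == expected

    def test_cmle_or_for_lof_table(self):
        # cross-product gives 4.05 here; the conditional MLE rounds to 4.04
        assert round(xc.odds_ratio(19, 830, 88, 15552, method="cmle"),
                     2) == 4.04

    def test_symmetric_table_is_one(self):
        assert xc.odds_ratio(5, 5, 5, 5, "sample") == pytest.approx(1.0)
        assert xc.odds_ratio(5, 5, 5, 5, "cmle") == pytest.approx(1.0,
                                                                  abs=1e-6)

    def test_undefined_cases(self):
        assert xc.odds_ratio(5, 0, 3, 7, "sample") is None
        assert xc.odds_ratio(5, 5, 0, 10, "cmle") is None       # infinite
        assert xc.odds_ratio(0, 0, 3, 7, "cmle") is None        # empty row
        with pytest.raises(ValueError):
            xc.odds_ratio(1, 1, 1, 1, method="wald")

    def test_ci_brackets_estimate(self):
        lo, hi = xc.odds_ratio_ci(19, 830, 88, 15552, method="sample")
        assert lo < xc.odds_ratio(19, 830, 88, 15552) < hi
        lo_c, hi_c = xc.odds_ratio_ci(19, 830, 88, 15552, method="cmle")
        assert lo_c < xc.odds_ratio(19, 830, 88, 15552, "cmle") < hi_c
        assert xc.odds_ratio_ci(0, 10, 3, 7, method="sample") is None


class TestThresholds:
    def test_genome_and_study_wide(self):
        spec = xc.thresholds(18653, 7)
        assert spec.alpha_genome == pytest.approx(2.68e-6, rel=5e-3)
        assert spec.alpha_study == pytest.approx(3.83e-7, rel=5e-3)

    def test_degenerate_universe(self):
        spec = xc.thresholds(1, 1)
        assert spec.alpha_genome == spec.alpha_study == 0.05

    def test_invalid(self):
        with pytest.raises(ValueError):
            xc.thresholds(0, 7)


class TestPerVariant:
    @pytest.mark.parametrize("a,c,expected,tol", [
        (15, 72, 3.42e-5, 5e-8),     # most frequent nonsense variant
        (1, 3, 0.19, 5e-3),          # singleton frameshift
        (0, 29, 0.4014, 5e-5),       # control-only carriers
    ])
    def test_printed_per_variant_p(self, a, c, expected, tol):
        fx = xc.make_fixture_from_counts(a, 849, c, 15640, n_variants=1)
        res = xc.per_variant_test(fx.callset, 0)
        assert res.p_two_sided == pytest.approx(expected, abs=tol)
        assert (res.case_carriers, res.control_carriers) == (a, c)


class TestCollapse:
    def test_single_enriched_gene_ranks_first(self, registry):
        fx = xc.make_fixture_from_counts(19, 849, 88, 15640, gene_id="KRT82")
        qual = xc.qualifying_sets(fx.callset, fx.records, registry["lof"])
        res = xc.collapse_and_test(qual, fx.callset, registry["lof"],
                                   xc.thresholds(18653, 7))
        top = res[0]
        assert top.gene == "KRT82"
        assert top.table == (19, 830, 88, 15552)
        assert top.genome_wide_flag
        assert not top.study_wide_flag

    def test_multi_variant_sample_counts_once(self, registry):
        # one case sample het at three qualifying variants in the same gene
        import pandas as pd
        from scipy import sparse
        g = sparse.csr_matrix(np.array(
            [[1, 1, 1], [0, 0, 0], [0, 0, 0], [0, 0, 0]], dtype=np.int8))
        cs = xc.CallSet(["s1", "s2", "s3", "s4"], [True, True, False, False],
                        ["1:100:A:T", "1:110:A:T", "1:120:A:T"], g)
        recs = [xc.VariantRecord("1", 100 + 10 * j, "A", "T", "G1",
                                 "stop_gained") for j in range(3)]
        qual = xc.qualifying_sets(cs, recs, registry["lof"])
        res = xc.collapse_and_test(qual, cs, registry["lof"],
                                   xc.thresholds(1, 1))
        assert res[0].case_carriers == 1
        assert res[0].control_carriers == 0

    def test_counts_match_naive_recount(self, small_cohort, registry):
        model = registry["lof_missense_splicing"]
        recs = small_cohort.records
        qual = xc.qualifying_sets(small_cohort.callset, recs, model)
        res = xc.collapse_and_test(
            qual, small_cohort.callset, model, xc.thresholds(30, 7),
            gene_universe=sorted({r.gene for r in recs}))
        expected = naive_carrier_recount(
            small_cohort.callset, recs,
            lambda r: xc.is_qualifying(r, model)[0])
        for r in res:
            assert (r.case_carriers, r.control_carriers) == expected[r.gene]

    def test_zero_variant_genes_report_p_one(self, registry):
        fx = xc.make_fixture_from_counts(2, 10, 1, 20, gene_id="G1")
        qual = xc.qualifying_sets(fx.callset, fx.records, registry["lof"])
        res = xc.collapse_and_test(qual, fx.callset, registry["lof"],
                                   xc.thresholds(2, 1),
                                   gene_universe=["G1", "G2"])
        empty = [r for r in res if r.gene == "G2"][0]
        assert empty.table == (0, 10, 0, 20)
        assert empty.p_two_sided == 1.0

    def test_results_sorted_by_p_then_gene(self, small_cohort, registry):
        model = registry["lof"]
        qual = xc.qualifying_sets(small_cohort.callset, small_cohort.records,
                                  model)
        res = xc.collapse_and_test(qual, small_cohort.callset, model,
                                   xc.thresholds(30, 7))
        keys = [(r.p_two_sided, r.gene) for r in res]
        assert keys == sorted(keys)

    def test_sample_outside_cohort_rejected(self, registry):
        fx = xc.make_fixture_from_counts(1, 5, 0, 5)
        qual = {"GENE": {(99, 0)}}
        with pytest.raises(ValueError):
            xc.collapse_and_test(qual, fx.callset, registry["lof"],
                                 xc.thresholds(1, 1))


class TestRecessiveCollapse:
    def _run(self, zygosity, registry):
        fx = xc.make_fixture_from_counts(6, 500, 4, 2000, gene_id="R1",
                                         effect="missense", zygosity=zygosity)
        model = registry["recessive"]
        qual = xc.qualifying_sets(fx.callset, fx.records, model)
        res = xc.collapse_and_test(qual, fx.callset, model,
                                   xc.thresholds(1, 1))
        return res[0]

    def test_hom_alt_counts_as_recessive_carrier(self, registry):
        r = self._run("hom", registry)
        assert (r.case_carriers, r.control_carriers) == (6, 4)

    def test_compound_het_counts_as_recessive_carrier(self, registry):
        r = self._run("two_het", registry)
        assert (r.case_carriers, r.control_carriers) == (6, 4)

    def test_single_het_not_a_recessive_carrier(self, registry):
        r = self._run("het", registry)
        assert (r.case_carriers, r.control_carriers) == (0, 0)
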