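"""TE flank density, enrichment testing, overrepresentation and FPKM."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from famex.enrichment import (
    domain_overrepresentation,
    filter_silent,
    fpkm,
    merge_intervals,
    te_enrichment_test,
    te_flank_density,
)
from famex.io_formats import TEInterval

from .conftest import make_gene

SIZES = {"chr1": 1_000_000}


def te(start, end, klass="DNA", chrom="chr1"):
    return TEInterval(chrom, start, end, klass)


class TestFlankDensity:
    def test_coverage_fraction_arithmetic(self):
        gene = make_gene("g", [3_000], start=100_000)  # flanks 90-100 kb, 103-113 kb
        tes = [te(92_000, 93_200), te(104_000, 105_200)]
        d = te_flank_density(gene, tes, SIZES)
        assert d.flank_bp_available == 20_000
        assert d.density == pytest.approx(2_400 / 20_000)

    def test_overlapping_tes_merged_before_summing(self):
        gene = make_gene("g", [3_000], start=100_000)
        tes = [te(92_100, 92_200), te(92_150, 92_250)]
        d = te_flank_density(gene, tes, SIZES)
        assert d.covered_bp == 150  # not 200

    def test_density_invariant_to_interval_splitting(self):
        gene = make_gene("g", [3_000], start=100_000)
        whole = [te(92_000, 93_000)]
        split = [te(92_000, 92_400), te(92_400, 92_650), te(92_650, 93_000)]
        assert (
            te_flank_density(gene, whole, SIZES).density
            == te_flank_density(gene, split, SIZES).density
        )

    def test_chromosome_start_truncates_flank(self):
        gene = make_gene("g", [3_000], start=4_000)
        d = te_flank_density(gene, [], SIZES)
        assert d.flank_bp_available == 4_000 + 10_000

    def test_other_te_classes_ignored(self):
        gene = make_gene("g", [3_000], start=100_000)
        d = te_flank_density(gene, [te(92_000, 93_000, "LINE")], SIZES, te_class="DNA")
        assert d.density == 0.0

    def test_nonpositive_window_raises(self):
        gene = make_gene("g", [3_000], start=100_000)
        with pytest.raises(ValueError, match="window"):
            te_flank_density(gene, [], SIZES, window_bp=0)


class TestEnrichmentTest:
    def test_upward_shift_gives_positive_t(self):
        rng = np.random.default_rng(0)
        bg = rng.uniform(0.0, 0.1, 400)
        fam = bg[:100] + 0.05
        r = te_enrichment_test(fam, bg)
        assert r.t_statistic > 0 and r.p_value < 1e-6
        assert r.mean_family > r.mean_background

    def test_label_exchange_negates_t_keeps_p(self):
        rng = np.random.default_rng(1)
        a, b = rng.uniform(0, 0.2, 50), rng.uniform(0, 0.25, 60)
        fwd = te_enrichment_test(a, b)
        rev = te_enrichment_test(b, a)
        assert fwd.p_value == pytest.approx(rev.p_value)
        assert fwd.t_statistic == pytest.approx(-rev.t_statistic)

    def test_constant_identical_groups_flagged_degenerate(self):
        r = te_enrichment_test([0.1, 0.1, 0.1], [0.1, 0.1])
        assert r.degenerate and r.p_value == 1.0

    def test_null_rejection_rate_near_alpha(self):
        rng = np.random.default_rng(2)
        rejections = 0
        n_reps = 300
        for _ in range(n_reps):
            fam = rng.uniform(0, 0.2, 40)
            bg = rng.uniform(0, 0.2, 60)
            if te_enrichment_test(fam, bg).p_value < 0.05:
                rejections += 1
        assert 0.02 <= rejections / n_reps <= 0.09

    def test_fewer_than_two_per_group_raises(self):
        with pytest.raises(ValueError, match="at least two"):
            te_enrichment_test([0.1], [0.1, 0.2])


class TestOverrepresentation:
    def _matrix(self, focal_with, focal_total, other_with, other_total):
        return pd.DataFrame(
            {"BIR": [focal_with, other_with],
             "total_genes": [focal_total, other_total]},
            index=["focal", "other"],
        )

    def test_enriched_domain_found_significant(self):
        (r,) = domain_overrepresentation(self._matrix(20, 100, 10, 1000), "focal")
        # independent closed-form chi-square for the same 2x2 table
        table = np.array([[20, 80], [10, 990]])
        n = table.sum()
        row, col = table.sum(1), table.sum(0)
        expected = np.outer(row, col) / n
        chi2 = ((table - expected) ** 2 / expected).sum()
        assert r.chi2 == pytest.approx(chi2)
        assert r.p_raw < 0.001
        assert r.p_raw == pytest.approx(stats.chi2.sf(chi2, 1))

    def test_identical_proportions_give_chi2_zero(self):
        (r,) = domain_overrepresentation(self._matrix(10, 100, 100, 1000), "focal")
        assert r.chi2 == pytest.approx(0.0)
        assert r.p_raw == pytest.approx(1.0)

    def test_domain_absent_everywhere_skipped(self):
        (r,) = domain_overrepresentation(self._matrix(0, 100, 0, 1000), "focal")
        assert r.method == "skipped" and r.p_raw is None

    def test_small_expected_cell_falls_back_to_fisher(self):
        (r,) = domain_overrepresentation(self._matrix(2, 3000, 0, 5), "focal")
        assert r.method == "fisher"

    def test_bh_adjustment_preserves_order_and_dominates_raw(self):
        matrix = pd.DataFrame(
            {
                "BIR": [30, 10], "RING": [15, 100], "TNF": [5, 45],
                "total_genes": [200, 2000],
            },
            index=["focal", "other"],
        )
        results = domain_overrepresentation(matrix, "focal")
        tested = [r for r in results if r.p_raw is not None]
        by_raw = sorted(tested, key=lambda r: r.p_raw)
        adj = [r.p_adjusted for r in by_raw]
        assert adj == sorted(adj)
        assert all(r.p_adjusted >= r.p_raw for r in tested)

    def test_single_species_raises(self):
        m = pd.DataFrame({"BIR": [1], "total_genes": [10]}, index=["focal"])
        with pytest.raises(ValueError, match="two species"):
            domain_overrepresentation(m, "focal")


class TestExpression:
    def test_printed_formula(self):
        counts = pd.DataFrame({"s1": [10, 999_990]}, index=["g1", "g2"])
        lengths = {"g1": 1_000, "g2": 50_000}
        expr = fpkm(counts, lengths)
        # 10 reads * 1e9 / (1e6 total reads * 1000 nt) = 10
        assert expr.loc["g1", "s1"] == pytest.approx(10.0)

    def test_zero_reads_give_zero_fpkm(self):
        counts = pd.DataFrame({"s1": [0, 100]}, index=["g1", "g2"])
        expr = fpkm(counts, {"g1": 500, "g2": 500})
        assert expr.loc["g1", "s1"] == 0.0

    def test_silent_threshold_is_strict_less_than(self):
        expr = pd.DataFrame(
            {"s1": [0.09, 0.11, 0.10], "s2": [0.09, 0.11, 0.10]},
            index=["silent", "kept", "borderline"],
        )
        retained = set(filter_silent(expr, threshold=0.1))
        assert retained == {"kept", "borderline"}

    def test_zero_total_reads_in_sample_raises(self):
        counts = pd.DataFrame({"s1": [0, 0]}, index=["g1", "g2"])
        with pytest.raises(ValueError, match="zero total reads"):
            fpkm(counts, {"g1": 500, "g2": 500})

    def test_missing_gene_length_raises(self):
        counts = pd.DataFrame({"s1": [5]}, index=["g1"])
        with pytest.raises(ValueError, match="length missing"):
            fpkm(counts, {})


def test_merge_intervals_collapses_overlaps():
    assert merge_intervals([(0, 10), (5, 15), (20, 30), (30, 40)]) == [
        (0, 15),
        (20, 40),
    ]
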