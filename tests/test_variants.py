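"""Panel assembly, variant classification, HWE filtering, coverage and
robust correlation."""

import numpy as np
import pytest

from painpanel.pipeline import load_packaged_panel
from painpanel.variants import (GeneModel, VariantRecord, assemble_panel,
                                classify_location, coverage_accept,
                                expected_outcome_count, freeman_halton_2x3,
                                hwe_filter, intersect_gene_sets,
                                percentage_bend_correlation,
                                variant_location_table, zero_variant_genes)


class TestPanelAssembly:
    def test_packaged_panel_arithmetic(self):
        summary = load_packaged_panel().summary()
        assert summary == {"subset1": 29, "subset2": 50,
                           "intersection": 7, "union": 72}

    def test_identical_lists(self):
        p = assemble_panel(["a", "b"], ["A", "B"])
        assert p.summary() == {"subset1": 2, "subset2": 2,
                               "intersection": 2, "union": 2}

    def test_disjoint_lists(self):
        p = assemble_panel(["a", "b", "c"], ["d", "e", "f", "g"])
        assert p.summary()["union"] == 7
        assert p.summary()["intersection"] == 0

    def test_planted_intersection_recovered(self):
        rng = np.random.default_rng(17)
        shared = [f"SH{i}" for i in range(50)]
        a = shared + [f"A{i}" for i in range(77)]     # 127 symbols
        b = shared + [f"B{i}" for i in range(102)]    # 152 symbols
        rng.shuffle(a)
        rng.shuffle(b)
        assert intersect_gene_sets(a, b) == {s.upper() for s in shared}

    def test_cohort_ratio_arithmetic(self):
        # planned 60 samples at the 74:779 case:control ratio
        assert expected_outcome_count(60, 74, 779) == pytest.approx(5.7, abs=0.05)


@pytest.fixture
def gene_model():
    # span 1000-2000; 5'UTR 1000-1100, CDS 1100-1300 and 1500-1700,
    # 3'UTR 1900-2000; introns elsewhere inside the span
    return GeneModel(
        gene_symbol="DEMO", chrom="chr1", span=(1000, 2000),
        cds_exons=[(1100, 1300), (1500, 1700)],
        utr5=[(1000, 1100)], utr3=[(1900, 2000)],
    )


def _variant(pos):
    return VariantRecord(chrom="chr1", pos=pos, ref="A", alt="G")


class TestLocationClassification:
    def test_cds_position_is_exonic(self, gene_model):
        assert classify_location(_variant(1101), [gene_model]) == "exonic"

    def test_utr3_position(self, gene_model):
        assert classify_location(_variant(1950), [gene_model]) == "utr3"

    def test_intron_position(self, gene_model):
        assert classify_location(_variant(1400), [gene_model]) == "intronic"

    def test_padding_fringe_is_intergenic(self, gene_model):
        # 10 bp past the gene end but inside the 25 bp padding
        v = _variant(2010)
        assert classify_location(v, [gene_model]) == "intergenic"
        assert v.gene_symbol == "DEMO"

    def test_outside_everything_is_intergenic(self, gene_model):
        v = _variant(5000)
        assert classify_location(v, [gene_model]) == "intergenic"
        assert v.gene_symbol is None

    def test_every_base_against_interval_scan(self, gene_model):
        # independent per-base oracle from the raw interval lists
        def oracle(pos0):
            if not (975 <= pos0 < 2025):
                return "intergenic"
            for s, e in gene_model.cds_exons:
                if s <= pos0 < e:
                    return "exonic"
            for s, e in gene_model.utr5:
                if s <= pos0 < e:
                    return "utr5"
            for s, e in gene_model.utr3:
                if s <= pos0 < e:
                    return "utr3"
            return "intronic" if 1000 <= pos0 < 2000 else "intergenic"

        for pos0 in range(950, 2050):
            got = classify_location(_variant(pos0 + 1), [gene_model])
            assert got == oracle(pos0), pos0

    def test_overlapping_genes_prefer_cds_owner(self, gene_model):
        other = GeneModel(gene_symbol="OTHER", chrom="chr1", span=(900, 1600),
                          cds_exons=[], utr5=[], utr3=[])
        v = _variant(1101)
        assert classify_location(v, [other, gene_model]) == "exonic"
        assert v.gene_symbol == "DEMO"


class TestHWEFilter:
    def test_exact_proportions_retained(self):
        res = hwe_filter((25, 50, 25))
        assert res.p_value > 0.99
        assert res.retained
        assert sum(res.expected) == pytest.approx(100)

    def test_monomorphic_is_retained(self):
        res = hwe_filter((100, 0, 0))
        assert res.p_value == 1.0 and res.retained

    @pytest.mark.parametrize("method",
                             ["fisher_expected", "exact_hwe", "exact_hwe_midp"])
    def test_no_heterozygotes_dropped(self, method):
        res = hwe_filter((50, 0, 50), method=method)
        assert res.p_value < 0.05
        assert not res.retained
        assert res.expected == pytest.approx((25, 50, 25))

    def test_expected_counts_sum_to_n(self):
        res = hwe_filter((40, 18, 3))
        assert sum(res.expected) == pytest.approx(61)
        p = (2 * 40 + 18) / 122
        assert res.expected[0] == pytest.approx(61 * p * p)

    def test_freeman_halton_matches_R_fisher_test(self):
        # reference p-values from R 4.3 fisher.test on the same tables
        cases = [
            (([25, 50, 25], [25, 50, 25]), 1.0),
            (([50, 0, 50], [25, 50, 25]), 1.64378233871e-18),
            (([40, 18, 3], [39, 19, 3]), 1.0),
            (([10, 30, 21], [5, 28, 28]), 0.277488151101),
            (([0, 5, 56], [2, 20, 39]), 0.000415747985972),
        ]
        for (row1, row2), expected in cases:
            assert freeman_halton_2x3([row1, row2]) == \
                pytest.approx(expected, rel=1e-9)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            hwe_filter((-1, 2, 3))
        with pytest.raises(ValueError):
            hwe_filter((0, 0, 0))


class TestCoverage:
    def test_all_above_threshold_accepted(self):
        assert coverage_accept([21] * 50)

    def test_single_base_at_threshold_rejected(self):
        assert not coverage_accept([21] * 49 + [20])

    def test_typical_deep_coverage_accepted(self):
        assert coverage_accept([200] * 50)

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError):
            coverage_accept([])


class TestLocationTable:
    def test_empty_input_all_zero(self):
        table = variant_location_table([])
        assert table["total"] == 0
        assert set(table["by_class"].values()) == {0}

    def test_counts_partition_total(self):
        variants = []
        class_counts = {"exonic": 7, "utr5": 2, "utr3": 5, "intronic": 11,
                "intergenic": 3}
        pos = 1
        for cls, n in class_counts.items():
            for _ in range(n):
                v = VariantRecord("chr1", pos, "A", "G", gene_symbol="G1",
                                  location=cls)
                variants.append(v)
                pos += 1
        table = variant_location_table(variants)
        assert table["by_class"] == class_counts
        assert table["total"] == sum(class_counts.values())
        assert table["per_gene"] == {"G1": 28}
        assert zero_variant_genes(table["per_gene"], ["G1", "G2"]) == ["G2"]


class TestPercentageBendCorrelation:
    def test_perfect_concordance(self):
        x = np.arange(10.0)
        r, p = percentage_bend_correlation(x, x)
        assert r == 1.0 and p == 0.0

    def test_antisymmetry(self):
        x = np.arange(10.0)
        r, _ = percentage_bend_correlation(x, -x)
        assert r == -1.0

    def test_matches_independent_reference_with_outlier(self):
        # frozen from pingouin's percbend (independent implementation) on a
        # contaminated 10-point pair; identical m at n = 10
        x = np.array([1.0, 2, 3, 4, 5, 6, 7, 8, 9, 10])
        y = np.array([1.2, 1.9, 3.1, 4.2, 4.8, 6.1, 7.0, 8.2, 8.8, 40.0])
        r, p = percentage_bend_correlation(x, y)
        assert r == pytest.approx(0.9986191182372648, abs=1e-10)
        assert p == pytest.approx(1.5881232347725644e-11, rel=1e-6)
        # the robust estimate resists the outlier that drags Pearson down
        pearson = np.corrcoef(x, y)[0, 1]
        assert abs(r) > abs(pearson)

    def test_close_to_pearson_on_clean_gaussian(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=200)
        y = 0.6 * x + 0.8 * rng.normal(size=200)
        r, _ = percentage_bend_correlation(x, y)
        pearson = np.corrcoef(x, y)[0, 1]
        assert abs(r - pearson) < 0.05
        assert -1.0 <= r <= 1.0

    def test_constant_vector_is_error(self):
        with pytest.raises(ValueError):
            percentage_bend_correlation([1, 1, 1, 1, 1], [1, 2, 3, 4, 5])

    def test_bounded_on_random_pairs(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            x = rng.standard_t(2, size=12)
            y = rng.standard_t(2, size=12)
            r, _ = percentage_bend_correlation(x, y)
            assert -1.0 <= r <= 1.0
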