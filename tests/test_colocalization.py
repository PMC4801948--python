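import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from peakshift.colocalization import (
    conditional_loss_fraction,
    feature_distribution,
    occupancy_vectors,
    overlap_venn,
    pairwise_overlap_correlation,
    promoter_enrichment_ratio,
    subset_overlapping,
)
from peakshift.io_genomics import PeakSet

from conftest import make_gene, make_peak, make_set


def random_peak_set(rng, label, n, chrom="chr1", span=10000, width=400):
    starts = rng.integers(0, span, size=n)
    return make_set(label, [(chrom, int(s), int(s) + width) for s in starts])


class TestOverlapVenn:
    def test_identical_sets(self):
        a = make_set("A", [("chr1", 0, 400), ("chr1", 1000, 1400)])
        b = make_set("B", [("chr1", 0, 400), ("chr1", 1000, 1400)])
        res = overlap_venn(a, b)
        assert res.a_only == 0 and res.fraction_a_in_b == 1.0

    def test_disjoint_sets(self):
        a = make_set("A", [("chr1", 0, 400)])
        b = make_set("B", [("chr1", 1000, 1400)])
        res = overlap_venn(a, b)
        assert res.both_a == 0 and res.both_b == 0

    def test_empty_set_gives_zero_fractions(self):
        a = make_set("A", [("chr1", 0, 400)])
        b = PeakSet("B", [])
        res = overlap_venn(a, b)
        assert res.fraction_b_in_a == 0.0 and res.both_a == 0

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(30):
            a = random_peak_set(rng, "A", int(rng.integers(1, 11)))
            b = random_peak_set(rng, "B", int(rng.integers(1, 11)))
            res = overlap_venn(a, b)
            both_a = sum(
                1 for p in a if any(
                    min(p.end, q.end) - max(p.start, q.start) >= 1 for q in b
                )
            )
            both_b = sum(
                1 for q in b if any(
                    min(p.end, q.end) - max(p.start, q.start) >= 1 for p in a
                )
            )
            assert res.both_a == both_a and res.both_b == both_b
            assert res.a_only == len(a) - both_a
            assert res.b_only == len(b) - both_b


class TestConditionalLoss:
    def test_everything_lost_when_later_set_empty(self):
        shared = make_set("S", [("chr1", 0, 400)])
        assert conditional_loss_fraction(shared, PeakSet("L", [])) == 1.0

    def test_nothing_lost_when_identical(self):
        shared = make_set("S", [("chr1", 0, 400), ("chr1", 1000, 1400)])
        assert conditional_loss_fraction(shared, shared) == 0.0

    def test_planted_retention(self):
        # 20 shared peaks, 5 retained in the later condition -> 0.75 lost
        shared = make_set("S", [("chr1", i * 1000, i * 1000 + 400)
                                for i in range(20)])
        retained = make_set("L", [("chr1", i * 1000, i * 1000 + 400)
                                  for i in range(5)])
        assert conditional_loss_fraction(shared, retained) == 0.75

    def test_empty_shared_is_an_error(self):
        with pytest.raises(ValueError):
            conditional_loss_fraction(PeakSet("S", []), PeakSet("L", []))

    def test_subset_then_loss_pipeline(self):
        # A∩B selection feeding the loss computation
        a = make_set("A", [("chr1", 0, 400), ("chr1", 1000, 1400),
                           ("chr1", 5000, 5400)])
        b = make_set("B", [("chr1", 100, 500), ("chr1", 1100, 1500)])
        shared = subset_overlapping(a, b)
        assert len(shared) == 2
        later = make_set("C", [("chr1", 0, 400)])
        assert conditional_loss_fraction(shared, later) == 0.5


class TestPairwiseCorrelation:
    def test_identical_sets_give_r_one(self):
        a = make_set("A", [("chr1", 0, 400), ("chr1", 1000, 1400)])
        b = make_set("B", [("chr1", 0, 400), ("chr1", 5000, 5400)])
        c = make_set("C", [("chr1", 0, 400), ("chr1", 1000, 1400)])
        cm = pairwise_overlap_correlation([a, b, c])
        i, j = cm.labels.index("A"), cm.labels.index("C")
        assert cm.r[i, j] == pytest.approx(1.0)

    def test_complementary_partition_gives_minus_one(self):
        a = make_set("A", [("chr1", 0, 400)])
        b = make_set("B", [("chr1", 1000, 1400)])
        cm = pairwise_overlap_correlation([a, b])
        assert cm.r[0, 1] == pytest.approx(-1.0)

    def test_matrix_matches_explicit_binary_matrix(self):
        rng = np.random.default_rng(5)
        sets = [random_peak_set(rng, l, 8, span=30000) for l in "ABCD"]
        cm = pairwise_overlap_correlation(sets)
        mat, _ = occupancy_vectors(sets)
        expected = np.corrcoef(mat.astype(float))
        np.testing.assert_allclose(cm.r, expected, atol=1e-12)
        assert np.allclose(cm.r, cm.r.T)
        assert np.allclose(np.diag(cm.r), 1.0)

    def test_order_invariance_up_to_label_permutation(self):
        rng = np.random.default_rng(9)
        sets = [random_peak_set(rng, l, 10, span=30000) for l in "ABCD"]
        cm1 = pairwise_overlap_correlation(sets)
        cm2 = pairwise_overlap_correlation(sets[::-1])
        for i, li in enumerate(cm1.labels):
            for j, lj in enumerate(cm1.labels):
                i2, j2 = cm2.labels.index(li), cm2.labels.index(lj)
                assert cm1.r[i, j] == pytest.approx(cm2.r[i2, j2])

    def test_degenerate_set_reported_missing(self):
        # B occupies every union region -> zero variance -> NaN with warning
        a = make_set("A", [("chr1", 0, 400), ("chr1", 5000, 5400)])
        b = make_set("B", [("chr1", 0, 400), ("chr1", 5000, 5400),
                           ("chr1", 9000, 9400)])
        c = make_set("C", [("chr1", 0, 400)])
        with pytest.warns(UserWarning, match="constant occupancy"):
            cm = pairwise_overlap_correlation([a, b, c])
        i = cm.labels.index("B")
        assert np.isnan(cm.r[i, (i + 1) % 3])
        assert cm.r[i, i] == 1.0

    def test_ward_leaf_order_groups_similar_sets(self):
        # planted block structure: A~B highly similar, C~D highly similar
        base1 = [("chr1", i * 2000, i * 2000 + 400) for i in range(10)]
        base2 = [("chr1", 100000 + i * 2000, 100000 + i * 2000 + 400)
                 for i in range(10)]
        a = make_set("A", base1)
        b = make_set("B", base1[:9] + [("chr1", 50000, 50400)])
        c = make_set("C", base2)
        d = make_set("D", base2[:9] + [("chr1", 60000, 60400)])
        cm = pairwise_overlap_correlation([a, c, b, d])
        order = list(cm.ordered_labels)
        assert abs(order.index("A") - order.index("B")) == 1
        assert abs(order.index("C") - order.index("D")) == 1


class TestFeatureDistribution:
    GENES = [make_gene("g1", "chr1", 10000, 20000, "+"),
             make_gene("g2", "chr1", 50000, 60000, "-")]

    def test_promoter_precedence_over_body(self):
        # + strand promoter [8000, 10500); a summit at 10200 is in both the
        # promoter window and the body -> promoter wins
        peaks = PeakSet("x", [make_peak("chr1", 10000, 10400, summit=10200)])
        dist = feature_distribution(peaks, self.GENES)
        assert dist.counts["promoter"] == 1

    def test_minus_strand_promoter_is_downstream_in_genome(self):
        # g2 TSS at 59999; promoter covers (59999-500, 59999+2000]
        peaks = PeakSet("x", [make_peak("chr1", 60800, 61200, summit=61000)])
        dist = feature_distribution(peaks, self.GENES)
        assert dist.counts["promoter"] == 1

    def test_body_without_promoter(self):
        peaks = PeakSet("x", [make_peak("chr1", 14800, 15200, summit=15000)])
        dist = feature_distribution(peaks, self.GENES)
        assert dist.counts["gene_body"] == 1

    def test_gene_free_chromosome_is_all_intergenic(self):
        peaks = PeakSet("x", [make_peak("chr9", 0, 400)])
        dist = feature_distribution(peaks, self.GENES)
        assert dist.fractions["intergenic"] == 1.0

    @given(st.lists(st.integers(0, 80000), min_size=1, max_size=30))
    @settings(max_examples=30, deadline=None)
    def test_fractions_always_sum_to_one(self, summits):
        peaks = PeakSet("x", [
            make_peak("chr1", max(0, s - 200), s + 200, summit=s, name=f"p{i}")
            for i, s in enumerate(summits)
        ])
        dist = feature_distribution(peaks, self.GENES)
        assert sum(dist.counts.values()) == len(peaks)
        assert sum(dist.fractions.values()) == pytest.approx(1.0)


class TestPromoterEnrichment:
    def test_identical_distributions(self):
        peaks = PeakSet("x", [make_peak("chr1", 9000, 9400, summit=9200)])
        genes = [make_gene("g1", "chr1", 10000, 20000, "+")]
        d = feature_distribution(peaks, genes)
        assert promoter_enrichment_ratio(d, d) == pytest.approx(1.0)

    def test_simple_arithmetic(self):
        from peakshift.colocalization import FeatureDistribution

        a = FeatureDistribution({"promoter": 30, "gene_body": 10,
                                 "intergenic": 60}, 100)
        b = FeatureDistribution({"promoter": 10, "gene_body": 10,
                                 "intergenic": 80}, 100)
        assert promoter_enrichment_ratio(a, b) == pytest.approx(3.0)

    def test_zero_denominator_rejected(self):
        from peakshift.colocalization import FeatureDistribution

        a = FeatureDistribution({"promoter": 1, "gene_body": 0,
                                 "intergenic": 0}, 1)
        b = FeatureDistribution({"promoter": 0, "gene_body": 0,
                                 "intergenic": 1}, 1)
        with pytest.raises(ValueError):
            promoter_enrichment_ratio(a, b)

    def test_planted_three_to_one_placement(self):
        # place summits in promoters with probability 0.3 vs 0.1; the ratio
        # of promoter fractions estimates 3 within binomial sampling error
        rng = np.random.default_rng(21)
        genes = [make_gene(f"g{i}", "chr1", 100000 * i + 50000,
                           100000 * i + 60000, "+") for i in range(10)]
        n = 600

        def placed(p_prom, label):
            peaks = []
            for i in range(n):
                g = genes[int(rng.integers(0, len(genes)))]
                if rng.random() < p_prom:
                    s = int(rng.integers(g.tss - 2000, g.tss + 500))
                else:
                    s = int(rng.integers(g.body.end + 3000, g.body.end + 30000))
                peaks.append(make_peak("chr1", s - 200, s + 200, summit=s,
                                       name=f"{label}{i}"))
            return PeakSet(label, peaks)

        da = feature_distribution(placed(0.3, "a"), genes)
        db = feature_distribution(placed(0.1, "b"), genes)
        ratio = promoter_enrichment_ratio(da, db)
        assert 2.2 < ratio < 4.2
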