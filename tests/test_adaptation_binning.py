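"""Ordered binning and hypergeometric enrichment, against enumeration oracles."""

import numpy as np
import pytest

import codonadapt as ca
from codonadapt.codon_usage import AdaptationScore
from conftest import hypergeom_tails_oracle


def scores_from(values):
    return [AdaptationScore(f"g{i}", v) for i, v in enumerate(values)]


class TestAssignBins:
    def test_156_genes_6_bins_of_26(self):
        rng = np.random.default_rng(0)
        bins = ca.assign_bins(scores_from(rng.random(156)), 6)
        sizes = np.bincount([b.bin for b in bins])[1:]
        assert list(sizes) == [26] * 6

    def test_remainder_goes_to_earlier_bins(self):
        bins = ca.assign_bins(scores_from(np.linspace(1, 0, 7)), 3)
        sizes = np.bincount([b.bin for b in bins])[1:]
        assert list(sizes) == [3, 2, 2]

    def test_ranks_are_a_permutation_and_bins_nondecreasing(self):
        rng = np.random.default_rng(1)
        bins = ca.assign_bins(scores_from(rng.random(53)), 6)
        ranks = sorted(b.rank for b in bins)
        assert ranks == list(range(1, 54))
        by_rank = sorted(bins, key=lambda b: b.rank)
        assert all(a.bin <= b.bin for a, b in zip(by_rank, by_rank[1:]))

    def test_descending_by_score(self):
        bins = ca.assign_bins(scores_from([0.2, 0.9, 0.5]), 3)
        by_rank = sorted(bins, key=lambda b: b.rank)
        assert [b.gene_id for b in by_rank] == ["g1", "g2", "g0"]

    def test_ties_keep_input_order(self):
        bins = ca.assign_bins(scores_from([0.5] * 6), 3)
        by_rank = sorted(bins, key=lambda b: b.rank)
        assert [b.gene_id for b in by_rank] == [f"g{i}" for i in range(6)]
        assert [b.bin for b in by_rank] == [1, 1, 2, 2, 3, 3]

    def test_more_bins_than_genes_rejected(self):
        with pytest.raises(ValueError):
            ca.assign_bins(scores_from([0.1, 0.2]), 3)


class TestHypergeomTail:
    def test_boundary_k0(self):
        from math import comb

        p_enrich, p_deplete = ca.hypergeom_tail(0, 4, 5, 10)
        assert p_enrich == pytest.approx(1.0)
        assert p_deplete == pytest.approx(comb(6, 5) / comb(10, 5))

    def test_empty_category(self):
        p_enrich, p_deplete = ca.hypergeom_tail(0, 0, 5, 10)
        assert p_enrich == pytest.approx(1.0)
        assert p_deplete == pytest.approx(1.0)

    def test_hand_enumerated_example(self):
        # N=10, K=4, n=5, k=4: of C(10,5)=252 draws, C(4,4)*C(6,1)=6 have k=4
        p_enrich, _ = ca.hypergeom_tail(4, 4, 5, 10)
        assert p_enrich == pytest.approx(6 / 252)

    def test_matches_enumeration_for_all_small_configs(self):
        for N in range(1, 13):
            for K in range(N + 1):
                for n in range(N + 1):
                    for k in range(max(0, n + K - N), min(n, K) + 1):
                        got = ca.hypergeom_tail(k, K, n, N)
                        want = hypergeom_tails_oracle(k, K, n, N)
                        assert got[0] == pytest.approx(want[0], abs=1e-12)
                        assert got[1] == pytest.approx(want[1], abs=1e-12)

    def test_tails_overlap_at_k(self):
        p_enrich, p_deplete = ca.hypergeom_tail(10, 26, 26, 156)
        assert p_enrich + p_deplete >= 1.0

    def test_monotonicity_in_k(self):
        K, n, N = 26, 26, 156
        previous_e, previous_d = None, None
        for k in range(0, 27):
            pe, pd = ca.hypergeom_tail(k, K, n, N)
            if previous_e is not None:
                assert pe <= previous_e + 1e-12
                assert pd >= previous_d - 1e-12
            previous_e, previous_d = pe, pd

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            ca.hypergeom_tail(5, 4, 5, 10)  # k > K
        with pytest.raises(ValueError):
            ca.hypergeom_tail(1, 11, 5, 10)  # K > N


def make_bins(categories, n_bins):
    """Bins in input order (equal scores) with the given category labels."""
    scores = scores_from([1.0] * len(categories))
    bins = ca.assign_bins(scores, n_bins)
    ann = ca.AnnotationTable({f"g{i}": c for i, c in enumerate(categories)})
    return bins, ann


class TestCategoryScan:
    def test_single_category_is_never_significant(self):
        bins, ann = make_bins(["x"] * 12, 3)
        for r in ca.category_scan(bins, ann, include_functional_meta=False):
            assert r.p_enrich == pytest.approx(1.0)
            assert r.p_deplete == pytest.approx(1.0)

    def test_toy_scan_matches_enumeration(self):
        # 12 genes, 2 bins of 6; bin 1 = 5 of category A + 1 B; K_A=6
        cats = ["A"] * 5 + ["B"] + ["A"] + ["B"] * 5
        bins, ann = make_bins(cats, 2)
        results = {(r.bin, r.category): r
                   for r in ca.category_scan(bins, ann,
                                             include_functional_meta=False)}
        r = results[(1, "A")]
        assert (r.k, r.n, r.K, r.N) == (5, 6, 6, 12)
        want = hypergeom_tails_oracle(5, 6, 6, 12)
        assert r.p_enrich == pytest.approx(want[0])
        assert r.p_deplete == pytest.approx(want[1])

    def test_category_counts_conserved_across_bins(self, gene_set, host_profile):
        scores = ca.adaptation_scores(gene_set.genes, host_profile)
        bins = ca.assign_bins(scores, 6)
        results = ca.category_scan(bins, gene_set.annotations)
        for category in {r.category for r in results}:
            rows = [r for r in results if r.category == category]
            assert sum(r.k for r in rows) == rows[0].K

    def test_functional_meta_category_is_complement_of_hypothetical(self, gene_set, host_profile):
        scores = ca.adaptation_scores(gene_set.genes, host_profile)
        bins = ca.assign_bins(scores, 6)
        results = ca.category_scan(bins, gene_set.annotations)
        fun = [r for r in results if r.category == "functional"]
        hyp = [r for r in results if r.category == "hypothetical"]
        assert fun and fun[0].K == 156 - hyp[0].K
        for f, h in zip(sorted(fun, key=lambda r: r.bin),
                        sorted(hyp, key=lambda r: r.bin)):
            assert f.k + h.k == f.n

    def test_missing_annotation_is_a_hard_error(self):
        bins, _ = make_bins(["A"] * 6, 2)
        ann = ca.AnnotationTable({"g0": "A"})
        with pytest.raises(ValueError, match="g1"):
            ca.category_scan(bins, ann)

    def test_deterministic_output(self, gene_set, host_profile):
        scores = ca.adaptation_scores(gene_set.genes, host_profile)
        bins = ca.assign_bins(scores, 6)
        a = ca.enrichment_to_frame(ca.category_scan(bins, gene_set.annotations))
        b = ca.enrichment_to_frame(ca.category_scan(bins, gene_set.annotations))
        assert a.to_csv() == b.to_csv()

    def test_constructed_enrichment_detected(self):
        """Top bin 90% one category vs 30% overall: strong enrichment call."""
        rng = np.random.default_rng(3)
        # 60 genes, 3 bins of 20; bin 1 has 18 functional, overall 18+0+0=30%
        cats = (["structural"] * 18 + ["hypothetical"] * 2
                + ["hypothetical"] * 40)
        bins, ann = make_bins(cats, 3)
        results = {(r.bin, r.category): r for r in ca.category_scan(bins, ann)}
        assert results[(1, "functional")].significant_enriched
        assert results[(3, "functional")].significant_depleted


def test_permutation_null_validity():
    """For random labelings the enrichment test is one-sided valid: the
    rejection fraction at alpha stays at or below alpha (+ Monte Carlo slack)."""
    rng = np.random.default_rng(12)
    alpha = 0.05
    n_reps = 2000
    labels = np.array([1] * 40 + [0] * 116)  # 40 of 156 in the category
    rejections = 0
    for _ in range(n_reps):
        perm = rng.permutation(labels)
        k = int(perm[:26].sum())
        p_enrich, _ = ca.hypergeom_tail(k, 40, 26, 156)
        rejections += p_enrich < alpha
    rate = rejections / n_reps
    se = np.sqrt(alpha * (1 - alpha) / n_reps)
    assert rate <= alpha + 2 * se
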