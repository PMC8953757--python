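"""Determinism and generative structure of the synthetic fixtures."""

import numpy as np
import pytest

import codonadapt as ca
from codonadapt.synthetic_data import _GC_PER_CODON


def profile_gc(cu: ca.CodonUsageVector) -> float:
    p = cu.counts / cu.counts.sum()
    return float((p * _GC_PER_CODON / 3.0).sum())


class TestHostProfile:
    def test_deterministic_per_seed(self):
        a = ca.gen_host_profile(0.65, seed=3)
        b = ca.gen_host_profile(0.65, seed=3)
        assert np.array_equal(a.counts, b.counts)
        c = ca.gen_host_profile(0.65, seed=4)
        assert not np.array_equal(a.counts, c.counts)

    def test_sampled_codons_hit_gc_target(self):
        host = ca.gen_host_profile(0.65, seed=5)
        p = host.counts / host.counts.sum()
        rng = np.random.default_rng(0)
        draws = rng.choice(64, size=10_000, p=p)
        gc = _GC_PER_CODON[draws].sum() / (3 * 10_000)
        assert 0.63 <= gc <= 0.67

    @pytest.mark.parametrize("gc", [0.35, 0.5, 0.62, 0.72])
    def test_profile_gc_matches_target(self, gc):
        host = ca.gen_host_profile(gc, seed=9)
        assert profile_gc(host) == pytest.approx(gc, abs=0.002)

    def test_unbiased_prior_has_no_extreme_codon(self):
        for seed in range(20):
            host = ca.gen_host_profile(0.5, seed=seed)
            p = host.counts / host.counts.sum()
            assert p.max() <= 10.0 / 64

    def test_gc_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ca.gen_host_profile(0.8, seed=0)


class TestDivergentProfile:
    def test_preserves_amino_acid_composition(self, host_profile):
        from codonadapt.synthetic_data import _FAMILIES

        p = host_profile.counts / host_profile.counts.sum()
        d = ca.divergent_profile(host_profile)
        for family in _FAMILIES:
            assert d[family].sum() == pytest.approx(p[family].sum())

    def test_inverts_synonymous_preference(self, host_profile):
        p = host_profile.counts / host_profile.counts.sum()
        d = ca.divergent_profile(host_profile)
        # Leu family (6 codons): the host's most-used codon takes the
        # host's least-used probability
        leu = [ca.CODONS.index(c) for c in
               ("CTA", "CTC", "CTG", "CTT", "TTA", "TTG")]
        top = max(leu, key=lambda i: p[i])
        assert d[top] == pytest.approx(min(p[i] for i in leu))

    def test_single_codon_families_unchanged(self, host_profile):
        p = host_profile.counts / host_profile.counts.sum()
        d = ca.divergent_profile(host_profile)
        for codon in ("TGG", "ATG"):  # Trp, Met
            i = ca.CODONS.index(codon)
            assert d[i] == pytest.approx(p[i])


class TestGeneSet:
    def test_exact_gene_count_and_frame(self, gene_set):
        assert len(gene_set.genes) == 156
        assert all(len(g.cds) % 3 == 0 for g in gene_set.genes)
        assert all(g.cds.startswith("ATG") for g in gene_set.genes)
        assert all(g.cds[-3:] in ca.STOP_CODONS for g in gene_set.genes)

    def test_no_interior_stops(self, gene_set):
        for g in gene_set.genes:
            interior = [g.cds[i:i + 3] for i in range(3, len(g.cds) - 3, 3)]
            assert not set(interior) & set(ca.STOP_CODONS)

    def test_determinism(self, host_profile):
        a = ca.gen_gene_set(ca.GeneSetSpec(seed=2), host_profile)
        b = ca.gen_gene_set(ca.GeneSetSpec(seed=2), host_profile)
        assert [g.cds for g in a.genes] == [g.cds for g in b.genes]
        assert a.boosted_gene_ids == b.boosted_gene_ids

    def test_category_proportions_realised(self, gene_set):
        from collections import Counter

        counts = Counter(g.category for g in gene_set.genes)
        assert counts["hypothetical"] == 87  # round(0.56 * 156)
        assert sum(counts.values()) == 156

    def test_functional_genes_better_adapted(self, host_profile):
        """The generative separation: mean cosine similarity of functional
        genes exceeds hypothetical genes, across seeds."""
        wins = 0
        for seed in range(20):
            gs = ca.gen_gene_set(ca.GeneSetSpec(seed=seed), host_profile)
            scores = ca.adaptation_scores(gs.genes, host_profile)
            fun = [s.similarity for s, g in zip(scores, gs.genes)
                   if g.category != "hypothetical"]
            hyp = [s.similarity for s, g in zip(scores, gs.genes)
                   if g.category == "hypothetical"]
            wins += np.mean(fun) > np.mean(hyp)
        assert wins == 20

    def test_boosted_genes_have_elevated_cognate_usage(self, gene_set):
        trp = ca.TRNASpec("tRNA-Trp", "CCA")
        boosted = set(gene_set.boosted_gene_ids)
        scores = {s.gene_id: s.trci
                  for s in ca.trci_scores(gene_set.genes, trp)}
        mean_boosted = np.mean([scores[g] for g in boosted])
        mean_rest = np.mean([v for g, v in scores.items() if g not in boosted])
        assert mean_boosted > 3 * mean_rest

    def test_invalid_proportions_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            ca.GeneSetSpec(category_proportions={"a": 0.5, "b": 0.4},
                           adaptation_mixture={"a": 0.9, "b": 0.4})


class TestCoverage:
    def test_noiseless_step_is_exact(self):
        spec = ca.CoverageSpec(genome_length=10_000, dtr_length=1_000,
                               depth_rest=100.0, fold=2.0, noise="none")
        profile = ca.gen_coverage(spec)
        assert np.all(profile.depths[:1_000] == 200.0)
        assert np.all(profile.depths[1_000:] == 100.0)

    def test_poisson_deterministic_per_seed(self):
        spec = ca.CoverageSpec(genome_length=5_000, dtr_length=500, seed=6)
        a, b = ca.gen_coverage(spec), ca.gen_coverage(spec)
        assert np.array_equal(a.depths, b.depths)

    def test_default_segment_means_near_motivating_values(self):
        profile = ca.gen_coverage(ca.CoverageSpec(seed=1))
        seg = ca.summarize_segments(profile, 10_992)
        assert seg["mean_high"] == pytest.approx(434.3, rel=0.02)
        assert seg["mean_rest"] == pytest.approx(231.0, rel=0.02)

    def test_dtr_too_long_rejected(self):
        with pytest.raises(ValueError):
            ca.CoverageSpec(genome_length=1_000, dtr_length=600)


class TestGenome:
    def test_roundtrip(self, small_gene_set, tmp_path):
        genome = ca.gen_genome(small_gene_set.genes, seed=4)
        path = tmp_path / "g.gb"
        ca.write_genbank(genome, path)
        back = ca.extract_cds(ca.read_genome(path))
        assert [g.cds for g in back] == [g.cds for g in small_gene_set.genes]

    def test_wrap_first_requires_circular(self, small_gene_set):
        with pytest.raises(ValueError):
            ca.gen_genome(small_gene_set.genes, circular=False, wrap_first=True)

    def test_strand_randomisation_within_binomial_bounds(self, small_gene_set):
        minus = 0
        total = 0
        for seed in range(50):
            genome = ca.gen_genome(small_gene_set.genes, seed=seed)
            minus += sum(1 for f in genome.features if f.strand == "-")
            total += len(genome.features)
        # binomial(500, 0.5): 99% bounds ~ 250 +/- 2.58*11.2
        assert abs(minus - total / 2) < 2.58 * np.sqrt(total / 4)
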