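"""Synthetic fixtures with controlled codon-usage structure.

Everything the analysis consumes can be generated here, deterministically
per seed: a GC-biased host codon-usage profile, a phage-scale gene set whose
per-gene codon usage is a category-dependent mixture of the host profile and
a maximally divergent profile, a subpopulation of genes enriched for one
cognate codon, a coverage profile with an elevated terminal-repeat segment,
and a genome record that round-trips through the GenBank reader.

Defaults emulate the scale of a high-GC siphophage and its
alphaproteobacterial host: ~156 genes, host coding GC near 0.65,
a 104,206 bp genome with a 10,992 bp terminal repeat at ~1.88-fold
coverage over a ~231× baseline, and a single tRNA-Trp whose cognate codon
is TGG.  Functional genes are generated closer to the host profile than
hypothetical genes (mixture weights 0.95 vs 0.4), reproducing the
adaptation gradient the binned enrichment analysis is designed to detect.

The divergent profile keeps the host's amino-acid composition but inverts
the synonymous-codon preference within each amino-acid family, so mixture
weight moves cosine similarity without distorting protein statistics.
Codons are drawn i.i.d. within a gene: the downstream analysis uses only
codon counts, so positional structure is irrelevant to what is tested.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from Bio.Data import CodonTable
from scipy.optimize import brentq

from .codon_usage import CODON_INDEX, CODONS, STOP_CODONS, CodonUsageVector
from .dtr_coverage import CoverageProfile
from .genome_io import (
    AnnotationTable,
    FeatureSpan,
    GeneRecord,
    GenomeRecord,
    reverse_complement,
)

# GC count per codon, in CODONS order.
_GC_PER_CODON = np.array([sum(ch in "GC" for ch in c) for c in CODONS], dtype=float)

_STOP_IDX = np.array([CODON_INDEX[c] for c in STOP_CODONS])


def _amino_acid_families() -> list[list[int]]:
    """Codon indices grouped by encoded amino acid (stops form one family)."""
    table = CodonTable.unambiguous_dna_by_id[1]
    groups: dict[str, list[int]] = {}
    for codon in CODONS:
        aa = "*" if codon in table.stop_codons else table.forward_table[codon]
        groups.setdefault(aa, []).append(CODON_INDEX[codon])
    return list(groups.values())


_FAMILIES = _amino_acid_families()


# ---------------------------------------------------------------------------
# Host profile


def _tilt_to_gc(probs: np.ndarray, gc: float) -> np.ndarray:
    """Exponentially retilt a codon distribution so its expected GC is gc."""

    def gc_gap(log_s: float) -> float:
        w = probs * np.exp(log_s * _GC_PER_CODON)
        return float((w * _GC_PER_CODON / 3.0).sum() / w.sum()) - gc

    log_s = brentq(gc_gap, -25.0, 25.0, xtol=1e-12)
    w = probs * np.exp(log_s * _GC_PER_CODON)
    return w / w.sum()


def gen_host_profile(gc: float, seed: int) -> CodonUsageVector:
    """A random 64-codon host usage profile with coding GC at ``gc``.

    Sampled from a Dirichlet prior tilted toward the GC target, then exactly
    retilted so the profile's expected GC equals ``gc``; deterministic per
    seed.  Stored as integer counts on a 10^6-codon scale (all downstream
    comparisons are scale-invariant).
    """
    if not (0.25 <= gc <= 0.75):
        raise ValueError(f"gc must be within [0.25, 0.75], got {gc}")
    rng = np.random.default_rng(seed)
    prior = _tilt_to_gc(np.full(64, 1.0 / 64), gc)
    probs = rng.dirichlet(prior * 300.0)
    probs = _tilt_to_gc(probs, gc)
    counts = np.round(probs * 1_000_000).astype(np.int64)
    counts[counts == 0] = 1  # keep full 64-codon support
    return CodonUsageVector(counts)


def divergent_profile(host: CodonUsageVector) -> np.ndarray:
    """Host profile with synonymous preferences inverted per amino acid.

    Within each synonymous family the probabilities are reassigned in
    reversed preference order (the most-used codon receives the least-used
    codon's probability).  Amino-acid composition — and therefore the usage
    of single-codon families such as Trp/TGG — is unchanged.
    """
    p = host.counts / host.counts.sum()
    out = p.copy()
    for family in _FAMILIES:
        if len(family) < 2:
            continue
        idx = np.asarray(family)
        order = np.argsort(-p[idx], kind="stable")
        out[idx[order]] = p[idx[order[::-1]]]
    return out


# ---------------------------------------------------------------------------
# Gene sets

DEFAULT_CATEGORY_PROPORTIONS: dict[str, float] = {
    "structural": 0.13,
    "DNA metabolism": 0.10,
    "transcription": 0.06,
    "lysis": 0.01,
    "lysogeny": 0.04,
    "AMG": 0.10,
    "hypothetical": 0.56,
}

DEFAULT_ADAPTATION_MIXTURE: dict[str, float] = {
    "structural": 0.95,
    "DNA metabolism": 0.95,
    "transcription": 0.95,
    "lysis": 0.95,
    "lysogeny": 0.95,
    "AMG": 0.95,
    "hypothetical": 0.40,
}


@dataclass
class GeneSetSpec:
    """Generative conditions for a synthetic phage gene set.

    ``adaptation_mixture`` maps category → λ, the probability that each
    codon is drawn from the host profile rather than the divergent profile;
    functional categories default to λ=0.95 and hypothetical genes to
    λ=0.40, the separation the enrichment analysis is built to detect.
    ``cognate_boost`` multiplies the cognate codon's probability in
    ``n_boosted`` designated genes of ``boosted_category``, emulating genes
    whose translation leans on the phage's own tRNA.
    """

    n_genes: int = 156
    length_range: tuple[int, int] = (60, 400)  # codons, start/stop included
    host_gc: float = 0.65
    adaptation_mixture: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ADAPTATION_MIXTURE)
    )
    category_proportions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_PROPORTIONS)
    )
    cognate_boost: float = 5.0
    cognate_codon: str = "TGG"
    n_boosted: int = 12
    boosted_category: str = "hypothetical"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        lo, hi = self.length_range
        if lo < 3 or hi < lo:
            raise ValueError(f"invalid length_range {self.length_range}")
        total = sum(self.category_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"category proportions sum to {total}, not 1")
        for cat, lam in self.adaptation_mixture.items():
            if not (0.0 <= lam <= 1.0):
                raise ValueError(f"λ for {cat!r} outside [0,1]: {lam}")
        missing = set(self.category_proportions) - set(self.adaptation_mixture)
        if missing:
            raise ValueError(f"no mixture weight for categories: {sorted(missing)}")
        if self.cognate_codon not in CODON_INDEX:
            raise ValueError(f"invalid cognate codon {self.cognate_codon!r}")
        if self.cognate_boost < 0:
            raise ValueError("cognate_boost must be non-negative")


@dataclass
class SyntheticGeneSet:
    """Generated genes plus their labels and the designated boosted genes.

    Unpacks as ``genes, annotations = gen_gene_set(...)`` for callers that
    only need the pair.
    """

    genes: list[GeneRecord]
    annotations: AnnotationTable
    boosted_gene_ids: list[str]

    def __iter__(self):
        return iter((self.genes, self.annotations))


def _largest_remainder_counts(
    proportions: Mapping[str, float], n: int
) -> dict[str, int]:
    cats = list(proportions)
    raw = np.array([proportions[c] * n for c in cats])
    base = np.floor(raw).astype(int)
    short = n - int(base.sum())
    order = np.argsort(-(raw - base), kind="stable")
    for i in order[:short]:
        base[i] += 1
    return {c: int(k) for c, k in zip(cats, base)}


def gen_gene_set(
    spec: GeneSetSpec, host: Optional[CodonUsageVector] = None
) -> SyntheticGeneSet:
    """Generate a labelled gene set with controlled host adaptation.

    Each gene's codons are i.i.d. draws from
    λ_category·host + (1−λ_category)·divergent, with an ATG start forced, a
    single stop forced at the end, and no interior stops.  Designated genes
    get the cognate codon's interior probability multiplied by
    ``cognate_boost`` (renormalised).  Deterministic per ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    if host is None:
        host = gen_host_profile(spec.host_gc, seed=spec.seed)
    p_host = host.counts / host.counts.sum()
    p_div = divergent_profile(host)

    counts = _largest_remainder_counts(spec.category_proportions, spec.n_genes)
    labels = [cat for cat, k in counts.items() for _ in range(k)]
    labels = [labels[i] for i in rng.permutation(spec.n_genes)]

    boosted_idx: set[int] = set()
    if spec.n_boosted and spec.cognate_boost != 1.0:
        pool = [i for i, c in enumerate(labels) if c == spec.boosted_category]
        if len(pool) < spec.n_boosted:
            raise ValueError(
                f"only {len(pool)} genes of category {spec.boosted_category!r}; "
                f"cannot designate {spec.n_boosted}"
            )
        boosted_idx = set(
            rng.choice(pool, size=spec.n_boosted, replace=False).tolist()
        )

    width = len(str(spec.n_genes))
    cognate = CODON_INDEX[spec.cognate_codon]
    genes: list[GeneRecord] = []
    mapping: dict[str, str] = {}
    boosted_ids: list[str] = []
    lo, hi = spec.length_range
    for i in range(spec.n_genes):
        gene_id = f"gene_{i + 1:0{width}d}"
        lam = spec.adaptation_mixture[labels[i]]
        mix = lam * p_host + (1.0 - lam) * p_div
        interior = mix.copy()
        interior[_STOP_IDX] = 0.0
        if i in boosted_idx:
            interior[cognate] *= spec.cognate_boost
        interior /= interior.sum()
        stops = np.zeros(64)
        stops[_STOP_IDX] = mix[_STOP_IDX]
        if stops.sum() == 0:
            stops[CODON_INDEX["TAA"]] = 1.0
        stops /= stops.sum()

        n_codons = int(rng.integers(lo, hi + 1))
        body = rng.choice(64, size=max(n_codons - 2, 0), p=interior)
        stop = rng.choice(64, p=stops)
        cds = "ATG" + "".join(CODONS[j] for j in body) + CODONS[stop]
        genes.append(GeneRecord(gene_id=gene_id, cds=cds, category=labels[i]))
        mapping[gene_id] = labels[i]
        if i in boosted_idx:
            boosted_ids.append(gene_id)

    annotations = AnnotationTable(mapping, list(spec.category_proportions))
    return SyntheticGeneSet(genes=genes, annotations=annotations, boosted_gene_ids=boosted_ids)


# ---------------------------------------------------------------------------
# Coverage profiles


@dataclass
class CoverageSpec:
    """Generative conditions for a coverage profile with a terminal repeat.

    Defaults mirror the scale of the motivating assembly: a 104,206 bp
    genome whose first 10,992 bp show ~1.88× the baseline 231× depth.
    """

    genome_length: int = 104_206
    dtr_length: int = 10_992
    depth_rest: float = 231.0
    fold: float = 1.88
    noise: str = "poisson"  # or "none"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dtr_length >= self.genome_length / 2:
            raise ValueError("dtr_length must be below half the genome length")
        if self.depth_rest <= 0:
            raise ValueError("depth_rest must be positive")
        if self.fold < 1.0:
            raise ValueError("fold must be >= 1")
        if self.noise not in ("poisson", "none"):
            raise ValueError(f"unknown noise model {self.noise!r}")


def gen_coverage(spec: CoverageSpec) -> CoverageProfile:
    """Step coverage profile: elevated on [0, dtr_length), baseline after.

    Poisson noise per position, or the exact means when ``noise="none"``.
    """
    means = np.full(spec.genome_length, spec.depth_rest, dtype=float)
    means[: spec.dtr_length] *= spec.fold
    if spec.noise == "none":
        depths = means
    else:
        rng = np.random.default_rng(spec.seed)
        depths = rng.poisson(means).astype(float)
    return CoverageProfile(depths=depths, genome_id="synthetic")


# ---------------------------------------------------------------------------
# Genomes


def _random_spacer(rng: np.random.Generator, length: int, gc: float) -> str:
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join("ACGT"[i] for i in rng.choice(4, size=length, p=probs))


def gen_genome(
    genes: Sequence[GeneRecord],
    spacer_gc: float = 0.62,
    circular: bool = False,
    seed: int = 0,
    wrap_first: bool = False,
    spacer_range: tuple[int, int] = (20, 200),
) -> GenomeRecord:
    """Place genes on a genome with random spacers and strands.

    ``wrap_first`` (circular genomes only) rotates the assembly so the first
    gene straddles the origin, exercising origin-spanning feature handling.
    The result round-trips through the GenBank writer/reader, and CDS
    extraction recovers the input gene sequences exactly.
    """
    if not genes:
        raise ValueError("need at least one gene")
    if wrap_first and not circular:
        raise ValueError("wrap_first requires a circular genome")
    rng = np.random.default_rng(seed)
    lo, hi = spacer_range
    parts: list[str] = []
    features: list[FeatureSpan] = []
    pos = 0
    for gene in genes:
        spacer = _random_spacer(rng, int(rng.integers(lo, hi + 1)), spacer_gc)
        parts.append(spacer)
        pos += len(spacer)
        strand = "+" if rng.random() < 0.5 else "-"
        seq = gene.cds if strand == "+" else reverse_complement(gene.cds)
        features.append(
            FeatureSpan(
                gene_id=gene.gene_id,
                start=pos,
                end=pos + len(seq),
                strand=strand,
                kind="CDS",
            )
        )
        parts.append(seq)
        pos += len(seq)
    parts.append(_random_spacer(rng, int(rng.integers(lo, hi + 1)), spacer_gc))
    sequence = "".join(parts)
    L = len(sequence)

    if wrap_first:
        first = features[0]
        offset = first.start + (first.end - first.start) // 2
        sequence = sequence[offset:] + sequence[:offset]
        rotated: list[FeatureSpan] = []
        for f in features:
            start = (f.start - offset) % L
            end = (f.end - offset) % L
            if end == 0:
                end = L
            rotated.append(
                FeatureSpan(
                    gene_id=f.gene_id,
                    start=start,
                    end=end,
                    strand=f.strand,
                    kind=f.kind,
                    wraps=end <= start,
                )
            )
        features = rotated

    return GenomeRecord(
        id="synthetic_phage",
        sequence=sequence,
        is_circular=circular,
        features=features,
    )
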