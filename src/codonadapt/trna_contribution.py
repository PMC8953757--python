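"""tRNA Relative Contribution Index (tRCI) for phage-encoded tRNAs.

A phage that carries its own tRNA can partially decouple the translation of
some of its genes from the host tRNA pool.  The tRCI quantifies, per gene,
how much that tRNA can contribute: the default definition is the frequency
of the tRNA's cognate codon within the gene (cognate count / total codons).
The definition is pluggable — any monotone per-gene cognate-usage measure
preserves the downstream ranking and binning — but the default is what the
rest of the package uses.

Genes that never use the cognate codon cannot benefit from the tRNA at all;
they are excluded before binning.  The remaining genes are sorted by tRCI
descending and pushed through the same ordered-bin + hypergeometric
enrichment machinery as the cosine-similarity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

from .adaptation_binning import (
    DEFAULT_ALPHA,
    DEFAULT_N_BINS,
    AdaptationScore,
    BinAssignment,
    EnrichmentResult,
    assign_bins,
    category_scan,
)
from .codon_usage import CODON_INDEX, count_codons
from .genome_io import AnnotationTable, GeneRecord, reverse_complement


def anticodon_to_codon(anticodon: str) -> str:
    """The cognate mRNA codon of a tRNA anticodon, in DNA alphabet.

    The anticodon pairs antiparallel with the codon, so the cognate codon is
    the reverse complement.  RNA input (U) is accepted: tRNA-Trp anticodon
    CCA reads the codon TGG (UGG in mRNA).
    """
    if len(anticodon) != 3:
        raise ValueError(f"anticodon must have 3 letters, got {anticodon!r}")
    ac = anticodon.upper().replace("U", "T")
    if any(ch not in "ACGT" for ch in ac):
        raise ValueError(f"anticodon {anticodon!r} has characters outside A,C,G,T,U")
    return reverse_complement(ac)


@dataclass(frozen=True)
class TRNASpec:
    """A phage-encoded tRNA: name, anticodon and derived cognate codon."""

    name: str
    anticodon: str

    @property
    def cognate_codon(self) -> str:
        return anticodon_to_codon(self.anticodon)

    def __post_init__(self) -> None:
        anticodon_to_codon(self.anticodon)  # validates


@dataclass(frozen=True)
class TRCIScore:
    gene_id: str
    trci: float
    contains_cognate: bool

    def __post_init__(self) -> None:
        if self.trci < 0:
            raise ValueError("tRCI cannot be negative")
        if (self.trci == 0) != (not self.contains_cognate):
            raise ValueError("trci == 0 iff the cognate codon is absent")


TRCIDefinition = Callable[[GeneRecord, str], float]


def _cognate_frequency(gene: GeneRecord, cognate_codon: str) -> float:
    counts = count_codons(gene.cds)
    return counts.counts[CODON_INDEX[cognate_codon]] / counts.total_codons


def trci(
    gene: GeneRecord,
    trna: TRNASpec,
    definition: TRCIDefinition = _cognate_frequency,
) -> TRCIScore:
    """tRCI of one gene for one tRNA.

    Default definition: cognate-codon count divided by total codons.  Pass a
    different ``definition`` to swap in another per-gene measure; binning
    depends only on the induced ranking.
    """
    value = definition(gene, trna.cognate_codon)
    return TRCIScore(
        gene_id=gene.gene_id, trci=value, contains_cognate=value > 0
    )


def trci_scores(
    genes: Sequence[GeneRecord],
    trna: TRNASpec,
    definition: TRCIDefinition = _cognate_frequency,
) -> list[TRCIScore]:
    return [trci(g, trna, definition) for g in genes]


def aggregate_trci(
    gene: GeneRecord, trnas: Sequence[TRNASpec]
) -> TRCIScore:
    """Aggregate tRCI over several tRNAs: sum of per-cognate frequencies.

    The single-tRNA path is the default throughout; this exists for phages
    carrying more than one tRNA.
    """
    value = sum(_cognate_frequency(gene, t.cognate_codon) for t in trnas)
    return TRCIScore(gene_id=gene.gene_id, trci=value, contains_cognate=value > 0)


def trci_bins(
    genes: Sequence[GeneRecord],
    trna: TRNASpec,
    annotations: AnnotationTable,
    n_bins: int = DEFAULT_N_BINS,
    alpha: float = DEFAULT_ALPHA,
    definition: TRCIDefinition = _cognate_frequency,
) -> tuple[list[TRCIScore], list[BinAssignment], list[EnrichmentResult]]:
    """Filter to cognate-containing genes, bin by tRCI, scan categories.

    Returns (all scores including excluded genes, bin assignments of the
    retained genes, enrichment results).  The bin machinery and remainder
    rule are shared with the cosine-similarity analysis.
    """
    scores = trci_scores(genes, trna, definition)
    retained = [s for s in scores if s.contains_cognate]
    if len(retained) < n_bins:
        raise ValueError(
            f"only {len(retained)} genes contain the cognate codon "
            f"{trna.cognate_codon}; cannot form {n_bins} bins"
        )
    as_adaptation = [
        AdaptationScore(gene_id=s.gene_id, similarity=_unit_scale(s.trci))
        for s in retained
    ]
    bins = assign_bins(as_adaptation, n_bins)
    results = category_scan(bins, annotations, alpha)
    return scores, bins, results


def _unit_scale(x: float) -> float:
    # tRCI as cognate frequency is already in [0,1]; clamp defensively so a
    # swapped-in definition with larger range still sorts correctly only if
    # it stays within [0,1].
    if not (0.0 <= x <= 1.0):
        raise ValueError(
            f"tRCI value {x} outside [0,1]; rescale the custom definition"
        )
    return x


__all__ = [
    "TRNASpec",
    "TRCIScore",
    "anticodon_to_codon",
    "trci",
    "trci_scores",
    "trci_bins",
    "aggregate_trci",
]
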