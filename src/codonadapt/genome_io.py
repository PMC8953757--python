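"""Genome I/O: reading GenBank/FASTA records, extracting in-frame coding
sequences, and basic genome statistics.

Coordinates are 0-based half-open internally; GenBank's 1-based inclusive
convention is converted at the parsing boundary.  A feature on a circular
genome may wrap the origin, in which case ``wraps`` is set and the span is
read as ``sequence[start:] + sequence[:end]``.

Minus-strand coding sequences are stored already reverse-complemented, i.e.
5'→3' of the coding strand, so downstream codon counting never needs strand
logic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("codonadapt")

VALID_BASES = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

UNASSIGNED = "UNASSIGNED"


class ParseError(ValueError):
    """A record could not be interpreted in the named format."""


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string over {A,C,G,T,N}."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class FeatureSpan:
    """A located feature: 0-based half-open [start, end) on one strand.

    ``wraps`` marks an origin-spanning feature on a circular genome; the
    feature then covers ``[start, L) + [0, end)``.
    """

    gene_id: str
    start: int
    end: int
    strand: str  # "+" or "-"
    kind: str = "CDS"  # CDS, tRNA, other
    wraps: bool = False

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.start < 0:
            raise ValueError(f"negative start for {self.gene_id}")
        if not self.wraps and self.end <= self.start:
            raise ValueError(
                f"feature {self.gene_id}: end ({self.end}) must exceed start "
                f"({self.start}) unless the span wraps the origin"
            )

    def length(self, genome_length: int) -> int:
        if self.wraps:
            return (genome_length - self.start) + self.end
        return self.end - self.start


@dataclass
class GenomeRecord:
    """A genome sequence plus its located features."""

    id: str
    sequence: str
    is_circular: bool = False
    features: list[FeatureSpan] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if len(self.sequence) < 1:
            raise ValueError("genome sequence must be non-empty")
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise ValueError(f"invalid characters in sequence: {sorted(bad)}")
        for f in self.features:
            if f.start >= len(self.sequence):
                raise ValueError(
                    f"feature {f.gene_id} starts beyond the sequence end"
                )
            if f.wraps and not self.is_circular:
                raise ValueError(
                    f"feature {f.gene_id} wraps the origin of a linear genome"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    def feature_sequence(self, span: FeatureSpan) -> str:
        """Sequence of a span, 5'→3' of its coding strand."""
        if span.wraps:
            raw = self.sequence[span.start:] + self.sequence[: span.end]
        else:
            raw = self.sequence[span.start: span.end]
        return reverse_complement(raw) if span.strand == "-" else raw


@dataclass(frozen=True)
class GeneRecord:
    """One coding sequence, in frame, 5'→3' of the coding strand."""

    gene_id: str
    cds: str
    category: str = UNASSIGNED

    def __post_init__(self) -> None:
        if len(self.cds) < 3 or len(self.cds) % 3:
            raise ValueError(
                f"gene {self.gene_id}: CDS length {len(self.cds)} is not a "
                "positive multiple of 3"
            )

    @property
    def n_codons(self) -> int:
        return len(self.cds) // 3


class AnnotationTable:
    """gene_id → functional category, with a controlled category vocabulary.

    Unknown gene_ids queried through :meth:`category_of` are flagged by the
    caller's policy; :meth:`missing` reports binned genes with no annotation.
    """

    def __init__(self, mapping: Mapping[str, str], categories: Optional[Sequence[str]] = None):
        items = list(mapping.items())
        ids = [g for g, _ in items]
        if len(set(ids)) != len(ids):
            dupes = sorted({g for g in ids if ids.count(g) > 1})
            raise ValueError(f"duplicate gene_ids in annotation table: {dupes}")
        self._map = dict(items)
        if categories is None:
            categories = sorted(set(self._map.values()))
        self.categories = list(dict.fromkeys(categories))

    def __len__(self) -> int:
        return len(self._map)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._map

    def category_of(self, gene_id: str) -> str:
        return self._map.get(gene_id, UNASSIGNED)

    def missing(self, gene_ids: Iterable[str]) -> list[str]:
        return [g for g in gene_ids if g not in self._map]

    def items(self):
        return self._map.items()

    @classmethod
    def read_tsv(cls, path: str | Path) -> "AnnotationTable":
        """Read a two-column ``gene_id<TAB>category`` table.

        A header line whose first field is ``gene_id`` is recognised; its
        remaining fields, if any, declare the category vocabulary.
        """
        path = Path(path)
        mapping: dict[str, str] = {}
        vocab: Optional[list[str]] = None
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if lineno == 1 and parts[0] == "gene_id":
                    if len(parts) > 2:
                        vocab = parts[2:]
                    continue
                if len(parts) < 2:
                    raise ParseError(
                        f"{path}:{lineno}: expected gene_id<TAB>category, got {line!r}"
                    )
                gene_id, category = parts[0], parts[1]
                if gene_id in mapping:
                    raise ValueError(f"{path}:{lineno}: duplicate gene_id {gene_id!r}")
                mapping[gene_id] = category
        return cls(mapping, vocab)

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("gene_id\tcategory\n")
            for g, c in self._map.items():
                fh.write(f"{g}\t{c}\n")


# ---------------------------------------------------------------------------
# Reading


def _span_from_location(location, kind: str, gene_id: str, length: int) -> FeatureSpan:
    strand = "-" if location.strand == -1 else "+"
    if isinstance(location, CompoundLocation):
        parts = sorted(location.parts, key=lambda p: int(p.start))
        # An origin-spanning join has one part ending at L and one starting at 0.
        if (
            len(parts) == 2
            and int(parts[0].start) == 0
            and int(parts[1].end) == length
        ):
            return FeatureSpan(
                gene_id=gene_id,
                start=int(parts[1].start),
                end=int(parts[0].end),
                strand=strand,
                kind=kind,
                wraps=True,
            )
        raise ParseError(
            f"feature {gene_id}: unsupported compound location {location} "
            "(only a two-part join across the origin is recognised)"
        )
    return FeatureSpan(
        gene_id=gene_id,
        start=int(location.start),
        end=int(location.end),
        strand=strand,
        kind=kind,
    )


def _feature_id(feat: SeqFeature, index: int) -> str:
    for key in ("locus_tag", "gene", "protein_id", "product"):
        if key in feat.qualifiers:
            return str(feat.qualifiers[key][0])
    return f"feature_{index}"


def read_genome(path: str | Path, format: Optional[str] = None) -> GenomeRecord:
    """Read a genome from a GenBank flat file or FASTA.

    ``format`` is ``genbank`` or ``fasta``; when omitted it is inferred from
    the file extension.  GenBank CDS and tRNA features become
    :class:`FeatureSpan` with 0-based half-open coordinates.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        suffix = path.suffix.lower()
        format = "genbank" if suffix in (".gb", ".gbk", ".genbank", ".gbff") else "fasta"
    if format not in ("genbank", "fasta"):
        raise ValueError(f"unknown format {format!r}")
    try:
        record: SeqRecord = next(SeqIO.parse(str(path), format))
    except StopIteration:
        raise ParseError(f"{path}: no records found in {format} file") from None
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc

    sequence = str(record.seq).upper()
    is_circular = False
    if format == "genbank":
        topology = record.annotations.get("topology", "")
        is_circular = topology == "circular"

    features: list[FeatureSpan] = []
    for i, feat in enumerate(record.features):
        if feat.type not in ("CDS", "tRNA"):
            continue
        try:
            span = _span_from_location(
                feat.location, feat.type, _feature_id(feat, i), len(sequence)
            )
        except ParseError:
            raise
        features.append(span)
    return GenomeRecord(
        id=record.id or path.stem,
        sequence=sequence,
        is_circular=is_circular,
        features=features,
    )


# ---------------------------------------------------------------------------
# CDS extraction


def extract_cds(
    genome: GenomeRecord, annotations: Optional[AnnotationTable] = None
) -> list[GeneRecord]:
    """One :class:`GeneRecord` per CDS feature, in feature order.

    Minus-strand spans are reverse-complemented and origin-spanning spans
    concatenated.  Genes whose length is not a multiple of 3 or that contain
    N are logged and excluded — they cannot enter codon-usage arithmetic.
    """
    cds_features = [f for f in genome.features if f.kind == "CDS"]
    if not cds_features:
        raise ValueError(f"genome {genome.id} has no CDS features")
    genes: list[GeneRecord] = []
    for span in cds_features:
        seq = genome.feature_sequence(span)
        if len(seq) % 3 or len(seq) < 3:
            logger.warning(
                "gene %s: length %d not a positive multiple of 3; excluded",
                span.gene_id,
                len(seq),
            )
            continue
        if "N" in seq:
            logger.warning("gene %s contains N bases; excluded", span.gene_id)
            continue
        category = annotations.category_of(span.gene_id) if annotations else UNASSIGNED
        genes.append(GeneRecord(gene_id=span.gene_id, cds=seq, category=category))
    return genes


def genome_stats(genome: GenomeRecord) -> dict:
    """Length, GC percentage and feature counts.

    GC% = 100·(G+C)/(A+C+G+T); N bases are excluded from both numerator and
    denominator.  Reported to 2 decimals; full precision is available from
    the sequence itself.
    """
    seq = genome.sequence
    n_count = seq.count("N")
    gc = seq.count("G") + seq.count("C")
    denom = len(seq) - n_count
    gc_percent = 100.0 * gc / denom if denom else float("nan")
    return {
        "length": len(seq),
        "gc_percent": round(gc_percent, 2),
        "n_cds": sum(1 for f in genome.features if f.kind == "CDS"),
        "n_trna": sum(1 for f in genome.features if f.kind == "tRNA"),
    }


# ---------------------------------------------------------------------------
# Writing


def write_gene_table(
    genome: GenomeRecord,
    path: str | Path,
    annotations: Optional[AnnotationTable] = None,
) -> None:
    """Write a TSV of CDS features: gene_id, start, end, strand, length_codons, category."""
    with open(path, "w") as fh:
        fh.write("gene_id\tstart\tend\tstrand\tlength_codons\tcategory\n")
        for f in genome.features:
            if f.kind != "CDS":
                continue
            n_codons = f.length(len(genome)) // 3
            category = annotations.category_of(f.gene_id) if annotations else UNASSIGNED
            fh.write(
                f"{f.gene_id}\t{f.start}\t{f.end}\t{f.strand}\t{n_codons}\t{category}\n"
            )


def write_genbank(genome: GenomeRecord, path: str | Path) -> None:
    """Write a GenomeRecord as a GenBank flat file, including wrap joins."""
    L = len(genome)
    record = SeqRecord(
        Seq(genome.sequence),
        id=genome.id,
        name=genome.id[:16].replace("|", "_"),
        description="",
        annotations={
            "molecule_type": "DNA",
            "topology": "circular" if genome.is_circular else "linear",
        },
    )
    for span in genome.features:
        strand = -1 if span.strand == "-" else 1
        if span.wraps:
            # join(start..L, 1..end) — Biopython orders parts 5'→3'.
            parts = [
                SimpleLocation(span.start, L, strand),
                SimpleLocation(0, span.end, strand),
            ]
            if strand == -1:
                parts = parts[::-1]
            location = CompoundLocation(parts)
        else:
            location = SimpleLocation(span.start, span.end, strand)
        record.features.append(
            SeqFeature(
                location,
                type=span.kind,
                qualifiers={"locus_tag": [span.gene_id]},
            )
        )
    SeqIO.write(record, str(path), "genbank")


def write_fasta(genome: GenomeRecord, path: str | Path) -> None:
    record = SeqRecord(Seq(genome.sequence), id=genome.id, description="")
    SeqIO.write(record, str(path), "fasta")
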