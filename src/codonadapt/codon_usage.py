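"""Codon-usage vectors and the per-gene cosine-similarity adaptation index.

A codon-usage (CU) vector is the 64-dimensional profile of codon counts of a
gene or a genome's pooled coding complement.  The adaptation of a phage gene
to its host is the cosine similarity between the gene's CU vector and the
host's: 1 means the gene uses codons in exactly the host's proportions, and
larger values mean better adaptation to the host translation machinery.

All 64 codons, stop codons included, are counted by default (the convention
of codon-table utilities such as Countcodon); ``exclude_stops`` drops
TAA/TAG/TGA from the vectors before comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .genome_io import GeneRecord

#: The 64 DNA codons in lexicographic order; the canonical axis of every
#: CU vector in this package.
CODONS: tuple[str, ...] = tuple("".join(c) for c in product("ACGT", repeat=3))

CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(CODONS)}

STOP_CODONS: tuple[str, ...] = ("TAA", "TAG", "TGA")

_STOP_IDX = np.array([CODON_INDEX[c] for c in STOP_CODONS])


class CodonValidationError(ValueError):
    """A sequence cannot be decomposed into valid codons."""


@dataclass(frozen=True)
class CodonUsageVector:
    """Codon counts over the 64 DNA codons, in :data:`CODONS` order."""

    counts: np.ndarray  # shape (64,), non-negative integers

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts)
        if arr.shape != (64,):
            raise ValueError(f"expected 64 codon counts, got shape {arr.shape}")
        if np.any(arr < 0):
            raise ValueError("codon counts must be non-negative")
        object.__setattr__(self, "counts", arr.astype(np.int64))

    @property
    def total_codons(self) -> int:
        return int(self.counts.sum())

    def count(self, codon: str) -> int:
        return int(self.counts[CODON_INDEX[codon]])

    def frequencies_per_1000(self) -> np.ndarray:
        """Per-1000 frequency view; sums to 1000 up to rounding."""
        total = self.total_codons
        if total == 0:
            raise ValueError("cannot express frequencies of an empty vector")
        return 1000.0 * self.counts / total

    def as_dict(self) -> dict[str, int]:
        return {c: int(n) for c, n in zip(CODONS, self.counts)}

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, int]) -> "CodonUsageVector":
        unknown = set(mapping) - set(CODONS)
        if unknown:
            raise ValueError(f"unknown codons: {sorted(unknown)}")
        counts = np.zeros(64, dtype=np.int64)
        for codon, n in mapping.items():
            counts[CODON_INDEX[codon]] = n
        return cls(counts)

    def __add__(self, other: "CodonUsageVector") -> "CodonUsageVector":
        return CodonUsageVector(self.counts + other.counts)


@dataclass(frozen=True)
class AdaptationScore:
    """Cosine similarity of one gene's CU vector to the host profile."""

    gene_id: str
    similarity: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.similarity <= 1.0 + 1e-12):
            raise ValueError(
                f"similarity {self.similarity} outside [0,1] for {self.gene_id}"
            )


# Base-4 digits A=0, C=1, G=2, T=3 make 16a+4b+c the codon's position in
# the lexicographic CODONS order, so counting reduces to one bincount.
_BASE_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _ch in enumerate("ACGT"):
    _BASE_LUT[ord(_ch)] = _i
    _BASE_LUT[ord(_ch.lower())] = _i


def count_codons(cds: str) -> CodonUsageVector:
    """Codon counts of an in-frame coding sequence.

    Codon i occupies positions [3i, 3i+3).  All 64 codons are present in the
    result, zero-filled where unused.
    """
    if len(cds) == 0 or len(cds) % 3:
        raise CodonValidationError(
            f"sequence length {len(cds)} is not a positive multiple of 3"
        )
    digits = _BASE_LUT[np.frombuffer(cds.encode("ascii"), dtype=np.uint8)]
    bad = np.nonzero(digits == 255)[0]
    if bad.size:
        pos = int(bad[0])
        raise CodonValidationError(
            f"invalid character {cds[pos]!r} at position {pos}"
        )
    idx = (
        digits[0::3].astype(np.int64) * 16
        + digits[1::3].astype(np.int64) * 4
        + digits[2::3].astype(np.int64)
    )
    return CodonUsageVector(np.bincount(idx, minlength=64))


def aggregate_cu(genes: Iterable[GeneRecord]) -> CodonUsageVector:
    """Pooled codon counts over a gene set — e.g. the host genome profile."""
    total = np.zeros(64, dtype=np.int64)
    n = 0
    for gene in genes:
        total += count_codons(gene.cds).counts
        n += 1
    if n == 0:
        raise ValueError("cannot aggregate an empty gene list")
    return CodonUsageVector(total)


def _vector(u: CodonUsageVector | np.ndarray) -> np.ndarray:
    if isinstance(u, CodonUsageVector):
        return u.counts.astype(float)
    return np.asarray(u, dtype=float)


def cosine_similarity(
    u: CodonUsageVector | np.ndarray,
    v: CodonUsageVector | np.ndarray,
    exclude_stops: bool = False,
) -> float:
    """dot(u,v)/(‖u‖·‖v‖) over 64-dimensional CU vectors.

    Scale-invariant: counts and per-1000 frequencies give identical results.
    Always in [0,1] because CU vectors are non-negative.
    """
    a, b = _vector(u), _vector(v)
    if exclude_stops:
        a = a.copy()
        b = b.copy()
        a[_STOP_IDX] = 0.0
        b[_STOP_IDX] = 0.0
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise ValueError("cosine similarity is undefined for a zero vector")
    return float(np.clip(a @ b / (na * nb), 0.0, 1.0))


def adaptation_scores(
    genes: Sequence[GeneRecord],
    host: CodonUsageVector,
    exclude_stops: bool = False,
) -> list[AdaptationScore]:
    """Per-gene cosine similarity to the host CU profile, input order kept."""
    if host.total_codons < 1:
        raise ValueError("host CU vector is empty")
    return [
        AdaptationScore(
            gene_id=g.gene_id,
            similarity=cosine_similarity(count_codons(g.cds), host, exclude_stops),
        )
        for g in genes
    ]


# ---------------------------------------------------------------------------
# Host CU table I/O (Countcodon-export compatible: codon<TAB>count, 64 rows)


def read_cu_table(path: str | Path) -> CodonUsageVector:
    mapping: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#") or line.lower().startswith("codon"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected codon<TAB>count")
            codon = parts[0].upper().replace("U", "T")
            mapping[codon] = int(round(float(parts[1])))
    if len(mapping) != 64:
        raise ValueError(
            f"{path}: expected 64 codon rows, found {len(mapping)}"
        )
    return CodonUsageVector.from_mapping(mapping)


def write_cu_table(cu: CodonUsageVector, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("codon\tcount\n")
        for codon, n in zip(CODONS, cu.counts):
            fh.write(f"{codon}\t{int(n)}\n")
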