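"""Ordered binning of scored genes and hypergeometric category enrichment.

Genes are sorted by a score from high to low and partitioned into ordered
bins of (near-)equal size — bin 1 holds the best-adapted genes.  For each
(bin, category) pair, enrichment and underrepresentation are tested with
exact hypergeometric tail probabilities:

    p_enrich  = P(X >= k),   p_deplete = P(X <= k),
    X ~ Hypergeometric(N population, K category members, n drawn)

Both one-sided tests are reported separately and no multiple-testing
correction is applied; a call is significant when its raw p < alpha
(default 0.05).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd
from scipy.stats import hypergeom

from .codon_usage import AdaptationScore
from .genome_io import AnnotationTable

#: Genes outside this category count as "functional" in the meta-category scan.
HYPOTHETICAL = "hypothetical"

#: Name of the derived meta-category: every category except hypothetical.
FUNCTIONAL = "functional"

DEFAULT_N_BINS = 6
DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class BinAssignment:
    """A gene's 1-based rank after descending sort and its 1-based bin."""

    gene_id: str
    rank: int
    bin: int
    score: float


@dataclass(frozen=True)
class EnrichmentResult:
    """One (bin, category) hypergeometric test."""

    bin: int
    category: str
    k: int  # category genes in the bin
    n: int  # bin size
    K: int  # category genes overall
    N: int  # total genes
    p_enrich: float
    p_deplete: float
    significant_enriched: bool
    significant_depleted: bool


def bin_sizes(n_items: int, n_bins: int) -> list[int]:
    """Near-equal bin sizes; earlier (better-adapted) bins take the remainder."""
    base, extra = divmod(n_items, n_bins)
    return [base + 1 if i < extra else base for i in range(n_bins)]


def assign_bins(
    scores: Sequence[AdaptationScore], n_bins: int = DEFAULT_N_BINS
) -> list[BinAssignment]:
    """Stable descending sort, then slice into ordered bins.

    Ties keep input (genomic) order, so identical inputs always produce the
    identical assignment.  With 156 genes and 6 bins every bin holds 26.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if len(scores) < n_bins:
        raise ValueError(
            f"cannot split {len(scores)} genes into {n_bins} bins"
        )
    order = sorted(
        range(len(scores)), key=lambda i: (-scores[i].similarity, i)
    )
    sizes = bin_sizes(len(scores), n_bins)
    boundaries: list[int] = []
    acc = 0
    for s in sizes:
        acc += s
        boundaries.append(acc)
    assignments: list[BinAssignment] = []
    current_bin = 1
    for rank, idx in enumerate(order, start=1):
        while rank > boundaries[current_bin - 1]:
            current_bin += 1
        assignments.append(
            BinAssignment(
                gene_id=scores[idx].gene_id,
                rank=rank,
                bin=current_bin,
                score=scores[idx].similarity,
            )
        )
    return assignments


def hypergeom_tail(k: int, K: int, n: int, N: int) -> tuple[float, float]:
    """Exact one-sided tail probabilities of the hypergeometric law.

    Returns ``(P(X >= k), P(X <= k))`` for X ~ Hypergeometric(N, K, n).
    Both tails include P(X = k), so they always sum to at least 1.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"inconsistent counts: K={K}, n={n}, N={N}")
    lo, hi = max(0, n + K - N), min(n, K)
    if not (lo <= k <= hi):
        raise ValueError(
            f"k={k} outside admissible range [{lo}, {hi}] for K={K}, n={n}, N={N}"
        )
    dist = hypergeom(N, K, n)
    p_enrich = float(dist.sf(k - 1))  # P(X >= k)
    p_deplete = float(dist.cdf(k))  # P(X <= k)
    return min(p_enrich, 1.0), min(p_deplete, 1.0)


def category_scan(
    bins: Sequence[BinAssignment],
    annotations: AnnotationTable,
    alpha: float = DEFAULT_ALPHA,
    include_functional_meta: bool = True,
) -> list[EnrichmentResult]:
    """Hypergeometric enrichment/underrepresentation scan per (bin, category).

    Every named category is tested in every bin, plus the derived
    meta-category ``functional`` (all categories except ``hypothetical``).
    Raw p-values are compared to ``alpha`` per test, with no
    multiple-testing correction.
    """
    missing = annotations.missing(b.gene_id for b in bins)
    if missing:
        raise ValueError(
            f"no annotation for binned genes: {sorted(missing)}"
        )
    N = len(bins)
    gene_cat = {b.gene_id: annotations.category_of(b.gene_id) for b in bins}
    categories = sorted({gene_cat[b.gene_id] for b in bins})

    def members(cat: str) -> set[str]:
        if cat == FUNCTIONAL:
            return {g for g, c in gene_cat.items() if c != HYPOTHETICAL}
        return {g for g, c in gene_cat.items() if c == cat}

    scan_cats = list(categories)
    if include_functional_meta and FUNCTIONAL not in scan_cats:
        scan_cats.append(FUNCTIONAL)

    bin_ids = sorted({b.bin for b in bins})
    results: list[EnrichmentResult] = []
    for cat in scan_cats:
        cat_members = members(cat)
        K = len(cat_members)
        for bin_id in bin_ids:
            in_bin = [b.gene_id for b in bins if b.bin == bin_id]
            n = len(in_bin)
            k = sum(1 for g in in_bin if g in cat_members)
            p_enrich, p_deplete = hypergeom_tail(k, K, n, N)
            results.append(
                EnrichmentResult(
                    bin=bin_id,
                    category=cat,
                    k=k,
                    n=n,
                    K=K,
                    N=N,
                    p_enrich=p_enrich,
                    p_deplete=p_deplete,
                    significant_enriched=p_enrich < alpha,
                    significant_depleted=p_deplete < alpha,
                )
            )
    return results


# ---------------------------------------------------------------------------
# Tabular views


def bins_to_frame(bins: Sequence[BinAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [b.gene_id for b in bins],
            "rank": [b.rank for b in bins],
            "bin": [b.bin for b in bins],
            "score": [b.score for b in bins],
        }
    )


def enrichment_to_frame(
    results: Sequence[EnrichmentResult], display_decimals: Optional[int] = None
) -> pd.DataFrame:
    """EnrichmentResults as a DataFrame.

    ``display_decimals`` optionally rounds p-values for presentation (a tail
    probability below the display resolution then prints as 0, mirroring how
    very small p-values are usually reported); the default keeps full
    precision.
    """
    df = pd.DataFrame(
        {
            "bin": [r.bin for r in results],
            "category": [r.category for r in results],
            "k": [r.k for r in results],
            "n": [r.n for r in results],
            "K": [r.K for r in results],
            "N": [r.N for r in results],
            "p_enrich": [r.p_enrich for r in results],
            "p_deplete": [r.p_deplete for r in results],
            "significant_enriched": [r.significant_enriched for r in results],
            "significant_depleted": [r.significant_depleted for r in results],
        }
    )
    if display_decimals is not None:
        df["p_enrich"] = df["p_enrich"].round(display_decimals)
        df["p_deplete"] = df["p_deplete"].round(display_decimals)
    return df
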