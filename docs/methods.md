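# Methods

## Codon-usage vectors and the adaptation index

A coding sequence of length 3·m is decomposed into m consecutive,
non-overlapping triplets; the CU vector is the count of each of the 64 DNA
codons. Stop codons are counted like any other codon (the convention of
common codon-table utilities); `exclude_stops` removes TAA/TAG/TGA from
both vectors before comparison and is off by default. The host profile is
the elementwise sum of CU vectors over the host's coding sequences —
"codon usage of a genome" is only defined over its reading frames, so a
genome input is always reduced to its CDS complement first. A precomputed
64-row codon table is accepted in place of a host genome.

Adaptation of gene *g* to host profile **h** is the cosine similarity
`⟨u_g, h⟩/(‖u_g‖‖h‖)`. It is scale-invariant (counts vs per-1000
frequencies are equivalent), bounded in [0,1] for non-negative vectors,
and equal to 1 exactly when the gene uses codons in the host's
proportions. The index is reported at full floating precision; only the
induced ranking feeds the bins, so no rounding is applied before sorting.

## Ordered bins and the enrichment scan

Genes are sorted by the index descending with a stable sort (ties keep
input order, which makes the assignment reproducible byte-for-byte) and
sliced into `n_bins` ordered bins, as equal as possible; when N is not a
multiple of the bin count the earlier (better-adapted) bins take one extra
gene each. The default is 6 bins, which at the motivating scale of 156
genes gives exactly 26 genes per bin.

Each (bin, category) cell is tested with exact hypergeometric tails in
both directions — `p_enrich = P(X ≥ k)`, `p_deplete = P(X ≤ k)` — and the
two one-sided results are reported separately, since enrichment and
underrepresentation are distinct findings. Both tails include P(X = k), so
they sum to ≥ 1. Significance is raw `p < α` per test with α = 0.05 and no
multiple-testing correction; both are configurable. A derived
meta-category `functional` (every category except `hypothetical`) is
scanned alongside the named categories. The tails come from
`scipy.stats.hypergeom`; the test suite checks them against exhaustive
enumeration (all configurations with N ≤ 12) and a 100,000-permutation
null at N=156, n=26.

## tRCI

The cognate codon of a tRNA is the reverse complement of its anticodon
(tRNA-Trp-CCA → TGG). The default per-gene tRCI is the cognate codon's
frequency within the gene (count / total codons): zero exactly when the
gene never uses the codon. The definition is deliberately isolated behind
a single callable parameter — any monotone per-gene cognate-usage measure
yields the same ranking, bins and enrichment calls, which is all the
downstream analysis consumes — so a weighted variant (e.g. discounting
codons well-served by the host tRNA pool) can be swapped in without
touching the binning. Genes lacking the cognate codon are filtered out
before binning (they cannot benefit from the tRNA); the retained genes
reuse the same bin and scan machinery. Wobble pairing is not modelled:
only the exact Watson–Crick cognate codon counts. When several tRNAs are
supplied an aggregate (sum of per-cognate frequencies) is available, but
the single-tRNA path is the default.

## Terminal-repeat detection from coverage

The model is a step function: depth `f·μ` over the repeat `[0, b)` and `μ`
over `[b, L)`. The boundary estimate minimises the pooled within-segment
sum of squared deviations over candidate boundaries in
`[min_len, max_frac·L]` (defaults 500 bp and 0.25), computed in O(L) with
cumulative sums; on a noiseless step the minimiser is exact at any
boundary inside the window. The search covers a prefix window because the
repeat conventionally sits at the physical start of the packaged genome; a
`both_ends` flag scans a mirrored suffix window and keeps the
better-separating end. The fold change is the ratio of segment means and
the copy number its nearest integer. Calls below a fold change of 1.5
(configurable) are suppressed: a one-copy "repeat" is indistinguishable
from no repeat, so the default detector never emits copies = 1. Segment
summaries report arithmetic means and sample standard deviations
(ddof = 1). Coverage is consumed as a precomputed depth table
(`pos<TAB>depth`, 1-based, gaps read as 0, or one value per line);
alignment is upstream of this package.

## Phenotype summaries

Lethal rate: `100·S/(S+I)` over a phage's row of a host-range matrix with
cells sensitive/insensitive/untested, rounded to 1 decimal (matching how
such rates are conventionally reported); untested strains never enter the
denominator. Burst size: mean titer over a plateau window divided by
initially infected cells. The plateau window is user-specified by default;
the automatic rule takes the longest suffix of time points whose titers
agree pairwise within 20%, since "plateau" has no standard operational
definition.

## Synthetic data: what it emulates and what it does not

The generator reproduces the statistical structure the analysis is built
to detect, at the scale of a large siphophage infecting a high-GC
alphaproteobacterium:

- **Host profile** (`gen_host_profile`): a Dirichlet draw (concentration
  300, tilted exponentially in codon GC content) retilted exactly so the
  profile's expected coding GC equals the target (default 0.65, matching a
  host genome in the low 60s). The retilt makes the GC constraint exact
  while the Dirichlet keeps codon preferences irregular, as in real
  genomes.
- **Divergent profile**: the host profile with synonymous-codon
  preferences reversed within each amino-acid family. Amino-acid
  composition is untouched, so divergence lives purely in codon choice —
  and single-codon families (Met, Trp) are unchanged, which keeps the
  cognate-codon (TGG) frequency independent of the adaptation mixture.
- **Gene sets** (`gen_gene_set`): 156 genes of 60–400 codons (mean ≈ 230,
  i.e. a ~100 kb genome's worth), each codon drawn i.i.d. from
  `λ_cat·host + (1−λ_cat)·divergent`, ATG start and a single terminal stop
  forced, no interior stops. Functional categories (structural, DNA
  metabolism, transcription, lysis, lysogeny, AMG — 44% of genes) default
  to λ = 0.95 and hypothetical genes (56%) to λ = 0.40: a strong,
  recoverable adaptation gradient. Twelve designated hypothetical genes
  get the cognate codon's probability multiplied by 5, emulating genes
  whose translation leans on the phage tRNA.
- **Coverage** (`gen_coverage`): position-wise Poisson depths around a
  step profile; defaults L = 104,206 bp, repeat 10,992 bp, baseline 231×,
  fold 1.88 — the geometry of the motivating assembly.
- **Genomes** (`gen_genome`): genes placed with random 20–200 bp spacers
  and random strands, optionally rotated so one gene straddles the origin
  of a circular record; written and re-read as GenBank.

Codons are i.i.d. within a gene — no autocorrelation, no amino-acid-level
constraints beyond composition, no gene-order or operon structure — which
is sufficient because the analysis consumes only codon counts. Passing
tests therefore demonstrate that the ranking, binning, testing and
changepoint machinery recover known generative structure; they say nothing
about biological questions the generator does not model (e.g. whether real
functional genes are host-adapted). Everything is deterministic per seed.

## Numerical choices and degenerate inputs

- Coordinates are 0-based half-open internally; GenBank's 1-based
  inclusive intervals are converted at the parse boundary. Origin-spanning
  features on circular records are a single span with a wrap flag and read
  as the concatenation of the two arcs.
- Minus-strand CDS are stored reverse-complemented (coding-strand 5'→3').
- CDS whose length is not a positive multiple of 3, or that contain N, are
  excluded from codon arithmetic with a logged warning rather than an
  error: degenerate annotations should not abort a genome-scale run.
- GC% excludes N from numerator and denominator and is displayed to
  2 decimals; full precision is recoverable from the sequence.
- Sorting ties (equal scores) keep input order; bin remainders go to
  earlier bins. Both choices are arbitrary but fixed, for reproducibility.
- Tail probabilities are clamped to [0, 1] against floating round-off;
  a p of exactly 0 is impossible for admissible counts, so a displayed 0
  is always under-resolution (the tables keep full precision, with an
  optional fixed-decimal display mode).

## Known limitations

- The enrichment scan tests each (bin, category) cell marginally; with
  many categories and bins, some raw p < 0.05 calls are expected by chance
  (by design — the convention here is raw per-test significance).
- The changepoint detector fits exactly one step; profiles with repeats at
  both ends *and* internal coverage artefacts can mislead it.
- The tRCI default ignores host tRNA abundances; it measures cognate-codon
  usage only.
- The GenBank reader handles simple spans and two-part origin-spanning
  joins — multi-exon joins (not expected in phage CDS) are rejected with a
  parse error rather than guessed at.
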