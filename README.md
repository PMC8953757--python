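# codonadapt

Quantifying how well a bacteriophage's genes are adapted to the codon usage
of their bacterial host — and what the phage's own tRNA contributes where
they are not.

A phage relies almost entirely on the host translation machinery, so genes
the phage needs expressed efficiently tend to match the host's codon
preferences, while genes unique to the phage may diverge and instead lean
on phage-encoded tRNAs. `codonadapt` implements the analysis chain that
makes this visible from a genome record alone, for anyone characterising a
newly isolated phage:

- **Codon-usage (CU) vectors.** Each gene, and the host's pooled coding
  complement, is summarised as a 64-dimensional codon-count vector
  (stop codons included by default).
- **Cosine-similarity adaptation index.** For gene *g* with CU vector
  **u**_g and host profile **h**,
  `sim(g) = ⟨u_g, h⟩ / (‖u_g‖‖h‖) ∈ [0, 1]`,
  with values near 1 meaning the gene uses codons in the host's
  proportions.
- **Ordered bins + hypergeometric enrichment.** Genes are sorted by the
  index from high to low and split into equal ordered bins (default 6).
  For each bin and functional category, enrichment and underrepresentation
  are tested exactly: `p_enrich = P(X ≥ k)` and `p_deplete = P(X ≤ k)` for
  `X ~ Hypergeometric(N, K, n)`, significant at raw `p < 0.05`.
- **tRNA Relative Contribution Index (tRCI).** For a phage tRNA with
  anticodon *a*, the cognate codon is the reverse complement of *a*
  (tRNA-Trp-CCA reads TGG). A gene's tRCI is its cognate-codon frequency
  (count / total codons); genes never using the cognate codon are excluded,
  the rest are binned and scanned with the same machinery.
- **Direct terminal repeat (DTR) detection.** A packaged genome with a DTR
  shows ~2× read depth over the repeat. A two-segment least-squares
  changepoint on the per-base coverage profile locates the boundary; the
  segment-mean ratio, rounded, is the repeat copy number.
- **Phenotype summaries.** Intraspecific lethal rate from a host-range
  matrix (100·sensitive/tested) and burst size from a one-step growth
  curve (plateau titer / initially infected cells).

A synthetic-data generator produces host profiles, gene sets with a
controlled adaptation gradient and cognate-codon-boosted subpopulations,
coverage profiles with terminal repeats, and GenBank genome fixtures, so
the whole pipeline runs and is tested without any downloads.

## Worked example

```python
import codonadapt as ca

host = ca.gen_host_profile(gc=0.65, seed=1)                # host CU profile
genes, annotations = ca.gen_gene_set(ca.GeneSetSpec(seed=1), host)  # 156 genes

scores = ca.adaptation_scores(genes, host)
bins = ca.assign_bins(scores, n_bins=6)
scan = ca.category_scan(bins, annotations, alpha=0.05)
for r in scan:
    if r.category == "functional":
        print(f"bin {r.bin}: {r.k}/{r.n} functional  "
              f"p_enrich={r.p_enrich:.4g}  p_deplete={r.p_deplete:.4g}")

trp = ca.TRNASpec(name="tRNA-Trp", anticodon="CCA")
t_scores, t_bins, t_scan = ca.trci_bins(genes, trp, annotations)
print("cognate codon:", trp.cognate_codon,
      "| genes with cognate:", sum(s.contains_cognate for s in t_scores),
      "of", len(t_scores))

profile = ca.gen_coverage(ca.CoverageSpec(seed=1))
call = ca.detect_dtr(profile)
print(f"DTR boundary={call.boundary}  fold={call.fold_change:.2f}  copies={call.copies}")
```

prints

```
bin 1: 26/26 functional  p_enrich=2.452e-11  p_deplete=1
bin 2: 26/26 functional  p_enrich=2.452e-11  p_deplete=1
bin 3: 11/26 functional  p_enrich=0.6653  p_deplete=0.5023
bin 4: 2/26 functional  p_enrich=1  p_deplete=1.511e-05
bin 5: 2/26 functional  p_enrich=1  p_deplete=1.511e-05
bin 6: 2/26 functional  p_enrich=1  p_deplete=1.511e-05
cognate codon: TGG | genes with cognate: 154 of 156
DTR boundary=10992  fold=1.88  copies=2
```

The 156 genes split into six bins of 26. Functional genes (everything not
annotated hypothetical) are generated closer to the host profile, so they
fill the top two bins (strong enrichment) and all but vanish from the
bottom three (strong underrepresentation) — the signature of a phage whose
functional genes depend on the host tRNA pool. The coverage profile's
elevated first segment ends at 10,992 bp with a 1.88-fold depth ratio:
two repeat copies per packaged genome.

The same workflow runs from the shell on real files
(GenBank/FASTA genome, `gene_id<TAB>category` annotations, 64-row codon
table or host genome):

```sh
codonadapt run --config run.yaml      # full bundle: bins, enrichment, tRCI, manifest
codonadapt stats phage.gb             # length, GC%, feature counts
codonadapt dtr --depths coverage.tsv  # terminal-repeat call as JSON
codonadapt simulate geneset --seed 1 -o sim/   # synthetic fixtures
```

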