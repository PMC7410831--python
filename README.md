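# loopscape

Cross-cell-type analysis of cohesin-mediated chromatin loops.

Cohesin (RAD21) ChIA-PET experiments read out which pairs of genomic loci
are held in physical proximity by cohesin rings. Run across a panel of cell
types, they yield, for every candidate loop, a per-sample count of
paired-end tags (PETs) linking its two anchor regions — an "interaction
frequency" matrix whose rows are loops and whose columns are samples.
`loopscape` implements the full downstream analysis of such a panel for
computational genomicists:

* **Loop calling** — pool per-sample peak calls into a unified set of
  disjoint *anchors* (peaks extended by 500 bp, merged,
  blacklist-filtered), tabulate PETs between anchor pairs 10 kb–5 Mb apart,
  and score each candidate pair against a null that accounts for genomic
  distance and local ChIP efficiency: candidates are placed into
  equal-occupancy distance bins, the expected rate of pair *(i, j)* within
  a bin is λᵢⱼ = T·eᵢeⱼ / Σ eₐe_b, and the reported p-value is the Poisson
  upper tail P(X ≥ k; λᵢⱼ), with BH and Bonferroni control.
* **CTCF convergence** — for loops with exactly one CTCF motif in each
  anchor, classify the orientation pair (convergent / divergent / tandem).
* **Variability across cell types** — normalize the count matrix (row
  z-score → column quantile normalization → rescale to [0, 1000]), derive
  voom-style precision weights from the mean–variance trend of log counts,
  and test each loop with a weighted random-intercept model (cell type as
  random effect) against an intercept-only model via a likelihood-ratio
  test; weighted one-way ANOVA and Kruskal–Wallis alternates included.
  Non-variable ("static") control sets come from an entropy-based static
  score (mean PET frequency / relative entropy) or matched sampling.
* **Specificity** — cell-type- and group-specific loops, enhancers and
  genes by Welch-t ranking; group-specific sets use the three-way rule
  (T₁ ∩ T₂) − T₃ so a loop is high in its group against both others while
  the others do not differ.
* **Enrichment** — two-sided Fisher 2×2 machinery for anchor-connectivity
  ("hub") profiles, chromatin-state enrichment at specific loop ends,
  ENH–ENH / ENH–TSS / TSS–TSS pair types, TF motifs at group-specific loop
  ends, gene-connectivity vs gene lists, and motif-centred signal
  aggregation.
* **Expression and splicing coupling** — map loops to genes under four
  geometric schemes (all / promoter / contained / promoter–enhancer),
  correlate interaction frequency with expression across cell types against
  a mapping-shuffled null, and couple intragenic promoter→gene-body loops
  to exon counts against a permutation null.
* **GWAS enrichment** — LD-aware SNP pruning and proxy expansion, binned
  rank fold-change enrichment of trait-associated SNPs in loop-anchor sets
  with a 200-permutation empirical p, and Fisher comparison of genome-wide
  significant SNP overlap between two region sets.
* **Synthetic studies** — a seeded generator that emulates the whole data
  universe at desk scale (anchors with log-normal ChIP efficiencies,
  distance-decay negative-binomial PET counts, planted variable and
  group-specific loops, convergent CTCF motifs, coupled expression and exon
  usage, GWAS panels with planted enrichment), with truth tables for
  recovery testing.

## Worked example

```python
from loopscape import (SynthConfig, generate_dataset, filter_testable,
                       normalize_matrix, voom_weights, test_variability,
                       group_specific)
from loopscape.loopstats import zero_variance_rows

ds = generate_dataset(SynthConfig(seed=1), with_annotations=False,
                      with_gwas=False)
M = ds.true_counts
M = M.loc[filter_testable(M).index]          # >=4 PETs in one sample
M = M.loc[~zero_variance_rows(M)]
norm = normalize_matrix(M)
w = voom_weights(M, ds.sample_sheet)
res = test_variability(norm, ds.sample_sheet, w, method="lmm_lrt", fdr=0.10)
sets = group_specific(norm, ds.sample_sheet, top_frac=0.10)
```

prints, with the summaries shown in the snippet's full version:

```
true loops: 5000; samples: 12
testable loops (>=4 PETs in one sample): 4989
variable loops at FDR 10%: 1037
recovery of planted variable loops: 0.918
blood-specific loops: 260
embryonic-specific loops: 275
solid-specific loops: 274
```

The synthetic study plants 500 variable loops (10% of 5,000, 3-fold effect
in one target cell type each) and 200 group-specific loops per group; the
mixed-model test recovers 92% of the planted variable loops at FDR 10% and
the t-ranking set algebra returns group-specific sets of the expected size.

The same analysis runs file-to-file through the pipeline CLI:

```sh
loopscape run --outdir out/ --seed 1        # simulate ... report
loopscape run --outdir out/ --dry-run       # list the stages
```

which writes anchors (BED), loop calls and scores, the normalized matrix,
variability and specificity tables, enrichment results and a run manifest
with checksums under `out/`.

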