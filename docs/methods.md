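# Methods

This note records the statistical models, the synthetic study design, and
the numerical choices behind `loopscape`, at the level of detail a user
needs to judge what a passing test suite does and does not establish.

## Loop significance model

Candidate loops are all anchor pairs on one chromosome whose midpoint
distance lies strictly inside (10 kb, 5 Mb). Two nuisance effects dominate
raw PET counts: contact probability decays with genomic distance, and
anchors differ in ChIP pull-down efficiency. The scorer therefore places
candidates into equal-occupancy distance bins (default 50; bins widen
until each holds ≥ 20 pairs) and, within a bin with total count T, assigns
pair (i, j) the expected rate

    lambda_ij = T * e_i * e_j / sum_bin(e_a * e_b),

where e_i is the anchor's pooled PET-endpoint count (or a supplied
efficiency). The p-value is the Poisson upper tail P(X ≥ k; lambda_ij);
BH and Bonferroni q-values are reported and the called set defaults to
BH q < 0.01. A genome-scale analysis with billions of PETs would instead
use an extreme fixed threshold; at desk scale the FDR form is the
meaningful control.

Two numerical notes. First, the Poisson tail is discrete: calibration is
checked with the randomized probability-integral transform
u = P(X > k) + V·P(X = k), V ~ U(0, 1), which is exactly uniform when the
model holds; a plain KS test on the discrete p-values rejects by
construction at low counts. Second, within-bin distance decay biases
lambda when bins are wide relative to the decay; desk-scale calibration
runs use 400 equal-occupancy bins (~40 pairs per bin at ~17k candidates),
at which the residual bias is negligible. The 50-bin default reflects
genome-scale candidate lists where bins are naturally narrow.

## Normalization

The raw matrix (loops × samples) is reduced to rows with ≥ 4 PETs in at
least one sample, then (1) each row is z-scored ((x − mean)/sd, sample
sd), (2) each column is quantile-normalized to the across-column mean of
order statistics, with ties receiving the mean of their tied ranks'
reference values, and (3) each column is affinely rescaled to [0, 1000].
Zero-variance rows cannot be z-scored; callers must drop them first
(`zero_variance_rows`) and the function errors rather than dropping
silently. With continuous data all columns share one value multiset
exactly; tied entries (possible with integer counts) deviate from that
multiset by the tie-averaging convention.

## Variability testing

The response is log(normalized frequency + 1); the offset is needed
because the normalized range includes 0. Precision weights follow the
voom construction: log2(count + 0.5), per-loop residual standard
deviations about cell-type means, a lowess trend of sqrt(sd) against mean
log-count, and per-observation weights (predicted sqrt-sd)^-4 evaluated at
each observation's fitted log-count. Below 50 loops no trend is fit and
unit weights are returned with a warning.

The primary test fits, per loop, the weighted one-way random-intercept
model y_ij = mu + b_i + eps_ij with b_i ~ N(0, theta·sigma²) (cell type as
random effect) and Var(eps_ij) = sigma²/w_ij, by maximum likelihood with
the profile over theta evaluated on a log-spaced grid (theta in [0.01,
200]) plus a bounded refinement; mu and sigma² have closed-form profiles
via Sherman–Morrison. The LRT statistic against the weighted
intercept-only model is referred to chi²(1) by default — conservative at
the boundary theta = 0 — with the 50:50 chi²(0)/chi²(1) mixture available
by flag. The fit is cross-checked against statsmodels MixedLM (ML) on the
unweighted case in the test suite. Alternates: a weighted fixed-effect
one-way ANOVA F-test, and Kruskal–Wallis (note its discrete p-value floor
of ~0.10 at 6 cell types × 2 replicates makes BH selection impossible at
that size; it is a ranking method there). BH is applied per method and the
variable set is q < 0.10.

Static (non-variable) controls: `score_ranked` ranks loops by
Score_static = mean PET frequency / relative entropy (relative entropy in
bits against the uniform distribution over samples); loops with zero
entropy are perfectly uniform and rank above all others, ordered by mean
frequency — this avoids the division by zero while honouring the score's
intent. `matched` samples loops with variability FDR > 50% matching the
variable set's joint (span decile × loop-score-p decile) distribution,
seeded, and errors listing deficient strata when infeasible.

## Specificity

Cell-type-specific entities are the top floor(f·N) by Welch t (query
samples vs all others), f = 0.10 by default (0.20 for genes in the
pair-type analysis). Welch rather than pooled variance because two
replicates per condition give no licence to pool; a pooled option exists.
Ties in t break by entity id so results are deterministic.
Group-specific calling computes t₁ (query vs other₁), t₂ (query vs
other₂), t₃ (other₁ vs other₂), takes the top fraction of each, and
returns (T₁ ∩ T₂) − T₃.

## Enrichment machinery

All enrichments are two-sided Fisher exact tests on 2×2 tables with the
cross-product odds ratio; a zero cell flags the OR as degenerate (∞ or 0;
0/0 is reported as 1 with the flag), and a table with an empty margin is
an error at the primitive level — callers that can legitimately produce
such tables (a chromatin state absent from every loop end, a gene list
covering all genes) skip or report OR = 1 explicitly. BH families mirror
the analysis unit: (cell × state) for chromatin states, TFs per group,
X thresholds for gene connectivity. "Loop end" means the anchor interval
itself and overlap means ≥ 1 shared base. Promoters are 500 bp
strand-aware windows immediately upstream of the TSS; the loop-gene maps
use their own 1-kb rules. Anchor-connectivity bins default to
{1, 2, 3, 4, 5+}.

## Loop–gene maps and couplings

Four mapping schemes: *all* (gene body padded by 1 kb overlaps the loop
interval, anchor outer edge to outer edge — the simplest reading of
"ORF overlapped partially"), *promoter* (TSS within 1 kb of either
anchor), *contained* (gene body inside the loop interval and TSS > 1 kb
from both anchors), *promoter–enhancer* (promoter rule at one anchor,
H3K27ac peak at the other). Loop-expression coupling is Spearman across
cell types with replicate columns averaged first (a supported flag
disables averaging); the null shuffles the gene column of the mapping,
preserving each loop's gene multiplicity, 100 times; positive/negative
coefficient counts for real vs shuffled pairs are compared by Fisher.
Pairs with fewer than 5 complete observations are dropped with a count.

Intragenic loops: protein-coding genes with ≥ 1 middle exon, exons
overlapping CAGE peaks removed, promoter window TSS ± 1 kb, upstream
window 5 kb promoter-ward of a non-first exon's 5′ boundary (strand-aware;
a flag disables strand handling). A loop qualifies when one anchor
overlaps the promoter window and the other the upstream window of the
same gene. Exon–anchor pairs form when the exon and gene-body anchor 5′
boundaries lie within 5 kb; same-gene control exons must lie > 20 kb from
the anchor centre; the null permutes exon identity among real pairs 100
times (Pearson, complete observations).

## GWAS enrichment

The SNP table holds one row per SNP with an LD-cluster id and r² to its
cluster lead; pruning keeps the minimum-p SNP per cluster (ties by snp id)
and drops studies under 1,000 pruned SNPs. Overlap of a pruned SNP with a
region set is delegated to the SNP or any cluster mate with r² ≥ 0.8,
since the causal variant is unknown. Rank bins are cumulative thresholds
at pruned ranks 50, 150, 350, 750 and then quartiles of the remainder;
fold = (fraction of bin SNPs overlapping) / (fraction of all pruned SNPs
overlapping). The permutation null shuffles p-values among the study's
SNPs with positions fixed — equivalent to drawing the top bin uniformly —
200 times, and the empirical p uses add-one smoothing. The genome-wide
threshold for between-set comparison defaults to 1e-7 (the printed
"10 × 10⁻⁸" read literally), with 5e-8 available by flag.

## Synthetic study design

The generator is the package's study bench: it emulates the data universe
at desk scale with planted truth, so recovery and calibration are
measurable. Defaults (all in `SynthConfig`):

| parameter | default | why |
|---|---|---|
| genome | 2 chromosomes × 20 Mb | full pipeline in minutes |
| anchors | 400 × 2 kb, jittered grid | typical anchor width; disjoint by construction |
| true loops | 5,000, sampled ∝ d⁻¹ | desk-scale loop panel with contact-decay spans |
| cell panel | 3 groups × 2 cell types × 2 replicates | smallest panel supporting the group set algebra |
| library depth | 500,000 PETs/sample | ~100 PETs per true loop: deep-library regime |
| NB dispersion φ | 0.01 (var = μ + φμ²) | cell-line replicate concordance, not inter-individual variation |
| decay exponent α | 1.0 | standard contact-decay shape |
| background rate | 0.05 | non-loop candidate pairs at 5% of loop weight |
| effect size | 3× | planted fold in target cells |
| frac variable / group-specific | 0.10 / 0.04 per group | minority of planted effects |
| CTCF convergent fraction | 0.72 | observed convergence of two-motif loops |
| expr / exon coupling β, γ | 0.8 | strong planted couplings |

Counts are negative binomial with mean
μ_ls = depth · w_l · m_l,cell(s) / Σ w·m, where
w_l = d⁻α·e_i·e_j·(1 for true loops, background otherwise) and m is the
planted multiplier; normalizing by the sample total makes `library_depth`
the expected library size. Replicates share μ. Gene placement prefers
loops whose promoter anchor has low degree, as real promoters do, so the
promoter map points mostly at the coupled loop. CTCF motifs are planted
loop-by-loop at anchors not yet carrying a motif (low-degree anchors
first), each planted loop drawing convergent orientation with probability
0.72 and otherwise uniformly among the other three; a fraction of leftover
anchors receives two motifs to exercise the exclusion rule. The
`exclusive_loop_anchors` mode selects true loops as a decay-weighted
greedy matching (each anchor hosts one loop), which convergence
calibration runs use so that every two-motif loop carries an independently
drawn orientation.

What the generator does **not** emulate: sequence content and read-level
artefacts, self-ligation/re-ligation PETs, locus-specific chromatin
context, realistic LD block structure, batch effects (batch labels exist
but carry no signal), or the long-tailed loop-span and expression
distributions of real genomes. Passing recovery tests therefore
demonstrates correctness of the statistical machinery under the stated
model, not performance on real libraries.

## Problem sizes in tests

The default test and acceptance runs use the desk-scale panel above
(~17,400 candidate pairs, ~5,000 testable loops). Scoring calibration uses
Poisson counts (dispersion 0) because the Poisson-tail model is the null
being checked; the NB default would test a composite question. The
convergence estimate uses a sparser 15 × 10 Mb panel (6,000 anchors, 2,600
exclusive-anchor loops) to reach ≥ 2,000 clean two-motif loops, and the
coupling analyses a 3 × 20 Mb panel (600 anchors, 300 loops) so promoter
anchors have realistic degree ~1 and the promoter map is not dominated by
co-anchored bystander loops. GWAS calibration summarizes 50 independent
null studies of ~1,100 pruned SNPs each.

## Known limitations

* The anchor-efficiency estimate from loop-PET endpoints is contaminated
  by each anchor's neighbourhood when, as in the generator, all PETs are
  loop PETs; real libraries' endpoint counts are dominated by local ChIP
  coverage. Calibration runs therefore may pass planted efficiencies.
* The LRT against chi²(1) is conservative; with two replicates per cell
  type the mixture reference roughly doubles power at the margin but is
  not the default.
* Matched static sampling requires every joint stratum of the variable
  set to be populated among FDR > 50% candidates; sparse panels can make
  it infeasible (it errors, listing the strata).
* The quantile-normalization "shared multiset" property is exact only
  without ties.
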