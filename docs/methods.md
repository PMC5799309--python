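# Methods

## Overlap model

Coordinates are 1-based and closed on both ends throughout (the Gramene/GFF
convention); BED input is converted on read (`start+1, end`). A gene hits a
QTL only by **complete containment** — gene ⊆ QTL on the same chromosome.
Partial overlap never counts, so a gene longer than every QTL can never hit;
this is deliberate and matches the interval semantics the statistic is
defined on. Chromosome names are compared as exact trimmed strings; the
`--normalize-chrom` flag strips the `chr` prefix on both inputs
symmetrically rather than coercing silently.

**NQhits counts distinct genes.** A gene contained in several overlapping
QTLs contributes once, which keeps Pr(GQ) = NQhits/n a proportion in [0, 1].
The raw (gene, QTL)-pair double sum, which multi-counts such genes, is
reported separately (`nqhits_multicount`, CLI `--multicount`) as a
diagnostic. When G = Ω the complement proportion is undefined and reported
as NaN with a warning.

## The enrichment tests

Let N_Q be the genome-wide number of hit genes. The single-shot test
(`gsvq_test`) computes one inclusive upper tail P[X ≥ NQhits(G)] under
X ~ Hypergeom(N, N_Q, n).

The gene-sampling test (`gsaq_test`) draws K simple random samples without
replacement of size m ≤ n **from G** (each sample independently of the
others), computes each sample's hit count against the genome-wide margin,
takes per-sample inclusive upper tails p_k = P[X_k ≥ x_k] under
Hypergeom(N, N_Q, m), and combines them.

**Tail convention.** The inclusive upper tail P[X ≥ x] = 1 − P[X ≤ x−1] is
the default everywhere (the standard enrichment convention: the observed
count belongs to the rejection evidence). `tail="exclusive"` /
`--tail exclusive` gives the strict exceedance P[X > x] for comparison.

**Combination methods and direction conventions.** All four are oriented so
that *small combined p = enrichment*:

| method         | statistic                                | null reference | combined p      |
|----------------|------------------------------------------|----------------|-----------------|
| inverse_normal | T = Σ w_k Φ⁻¹(p_k), w_k = 1/√K default   | N(0,1)         | Φ(T)            |
| mean_p         | W = (0.5 − p̄)·√(12K)                    | N(0,1)         | 1 − Φ(W)        |
| inverse_chisq  | L = Σ −2 log p_k                         | χ²(2K)         | upper tail at L |
| logit          | S = Σ log(p_k/(1−p_k))                   | t(5K+4)        | lower tail S/C  |

Inverse-normal weights must satisfy ‖w‖₂ = 1 so T is standard normal under
independence; the default equal weights 1/√K give the unweighted Stouffer
statistic. The logit scale constant is the Mudholkar–George standardization
C = √(Kπ²(5K+2)/(3(5K+4))), which matches Var(S) = Kπ²/3 to the t reference
variance (5K+4)/(5K+2); with it, combined p-values from independent uniform
inputs are uniform to within KS resolution at 10⁴ replicates for every
method. Before any transform, p-values are clamped to
[10⁻¹⁰, 1 − 10⁻¹⁰]: a hypergeometric p of exactly 1 (zero observed hits) is
common and must not produce infinities.

**Defaults.** K = 50 samples and m = ⌈n/2⌉ when not specified; both are
always recorded in the output together with seed, N, N_Q, n, method and
tail, so any run can be reproduced exactly.

**Known limitation — dependence of the K p-values.** The K samples are
drawn from the same gene set, so the p_k share G's overall hit count and are
strongly positively correlated (for subsamples of size m from a null set of
size n, corr(Φ⁻¹p_j, Φ⁻¹p_k) ≈ m(1/n − 1/N)/(1 − q), where q is the
background hit fraction — about 0.5 at m = n/2). The combination step
nevertheless treats them as independent, which is the procedure's defining
convention. Consequence: under replication of the *whole* experiment with
fresh null gene sets, the combined test is anticonservative — at N = 5000,
n = 200, K = 20, m = 100 the measured type-I error at α = 0.05 is ≈ 0.2–0.25
for all four combiners, not 0.05 (the acceptance suite records this
directly). The combined p is therefore best read as a sensitive *ranking and
comparison* score across gene sets — the use the sweep report puts it to —
not as a calibrated frequentist error rate; the single-shot test is the
calibrated one. Users can trade dependence off explicitly by lowering m
relative to n.

**FDR.** Across a family of gene-set tests (in the sweep: the sizes within
one ranker method), Benjamini–Hochberg step-up adjustment is applied per
p-value column. BH was chosen over empirical-null local-FDR estimation
because a sweep produces a handful to a few dozen p-values — far too few to
estimate a null density from.

## Gene selection

The preliminary filter keeps genes with |log2 FC| ≥ 1 (difference of class
means on log2 data) **and** Welch two-sample t-test p < 0.05; both
thresholds are parameters. On pure-noise data the joint criterion retains
≈ 3% of genes at 6+6 samples.

Rankers use standard textbook definitions, declared in the output metadata:
Welch t; one-way ANOVA F (equal to t² at equal group sizes); |Pearson| and
|Spearman| correlation with the 0/1 class vector (zero-variance genes score
0 with a warning, never NaN); information gain, gain ratio and symmetrical
uncertainty computed with log2 entropies on an equal-frequency 3-bin
discretization of each gene; MRMR with the MID (difference) scheme on the
same discretization, greedy over all genes. Ties are broken
lexicographically by gene id, making every ranking deterministic; the MRMR
list is in greedy selection order and its recorded score (the MID criterion
at selection time) is not monotone along the list, unlike the univariate
rankers' scores. Learner-based selectors (random forests, SVM-RFE and the
like) are not implemented; `register_ranker` accepts any external callable
returning a `RankedList`, which then participates in `rank_genes` and the
sweep like a built-in.

Power note: at effect size 2 sd with 10+10 samples and 50 planted genes
among 2000, the location/correlation rankers and MRMR place ≥ 90% of planted
genes in the top 100, but the discretized-MI trio (IG/GR/SU) reaches only
≈ 85%: 3-bin mutual information on 20 samples is a noisier statistic. The
property tests encode these measured floors (0.9 and 0.75 respectively).

## Simulator

`SimConfig` defaults sketch a rice-like layout at desk scale: 12 chromosomes
× 2 Mb, 5000 genes of uniform length 1–5 kb placed uniformly (overlap
between genes allowed, as in real annotations), 60 QTLs of 50–150 kb
(≈ 25% expected genome coverage before QTL-QTL overlap, giving a background
hit fraction around 0.2), expression with 10 controls + 10 cases, N(0,1)
log2 background, 100 planted DE genes shifted by δ = 2 sd in cases, half of
them inside QTL regions. These are the package's standing test conditions;
the acceptance checks vary only what they explicitly study (δ = 3 and 80%
in-QTL for the end-to-end check, ρ ∈ {1, 1.5, 2, 3} for calibration/power).

Enriched gene sets are drawn by weighted sampling without replacement with
odds ρ ≥ 1 on hit genes, implemented with exponential sort keys
(Efraimidis–Spirakis), which is equivalent to sequential draws with weight
renormalization — stated explicitly because "weighted SRSWOR" has
inequivalent definitions. ρ = 1 is exactly the uniform competitive null.
Genome, QTL, gene-set and expression streams use distinct child seeds of the
config seed, so each output is bit-reproducible and independent of the
others given the config.

What the simulator does **not** emulate: linkage disequilibrium and
clustering of QTLs around true loci, microarray noise models
(probe effects, intensity-dependent variance), correlated co-expression
modules, and RNA-seq counts. Passing tests therefore demonstrate
correctness of the statistical machinery and its stated distributional
properties, not robustness to those real-data features.

## Numerical and degenerate-input choices

- Hypergeometric tails come from scipy's `hypergeom.sf` and are validated
  against exact integer combinatorics (and literal enumeration of all
  C(N, m) samples at tiny N) to 10⁻¹² relative error for every N ≤ 25.
- Empty QTL set: every hit count is 0 and every p-value is exactly 1.
- m = n reduces each sample to G itself; with K = 1 and unit weight the
  resampling test equals the single-shot test to machine precision.
- Combined p-values are clamped to [0, 1] after transforms; −log10 p is
  reported with p floored at 10⁻³⁰⁰.
- Report floats are serialized with 12 significant digits; JSON reports
  round-trip to equal values.

## Problem sizes used by the test suite

The acceptance checks run at N = 5000 genes with 1000 null replicates and
200 power replicates per ρ (seconds to a couple of minutes on one CPU);
brute-force cross-checks use N ≤ 200; the exact-tail sweep covers every
(N ≤ 25, N_Q, m, x). MRMR recovery is checked at 500 genes because its
greedy pass is O(G²) in mutual-information evaluations.
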