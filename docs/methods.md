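# Methods

This note documents the models, parameter choices and numerical conventions
behind `agesplit`, and what the synthetic-data tests do and do not
demonstrate about real data.

## Study design and effect axes

The package models a three-arm human skeletal-muscle study: young healthy
controls (YH, n = 15), young osteoarthritis patients (YP, n = 8) and older
patients (OP, n = 37). Two planted effect axes drive every downstream
recovery test:

* **pathology** effects shift YP and OP equally relative to YH (the
  chronic-inflammation / inactivity axis shared by the patient groups);
* **primary** effects shift OP relative to both YH and YP (the
  primary-aging axis, visible only in the older group).

A gene is assigned one class from {null, pathology_up, pathology_down,
primary_up, primary_down}. Defaults: 10,000 genes, 1.5% primary (150
genes), 10% pathology (1,000 genes), |log2 fold change| = 1. These sizes
make each recovery statistic (sensitivity, precision, specificity) rest on
enough planted genes to be stable without inflating runtimes.

## Synthetic count model

Counts are negative binomial with the RNA-seq convention
Var = μ + α μ², where α is the per-gene dispersion (default 0.05, a typical
magnitude for human bulk RNA-seq across biological replicates). Per-gene
baseline means are log-uniform on [20, 5000] — covering low- to
high-expressed genes without zero-inflation machinery — and gene lengths
log-uniform on [500, 10000] bp (TPM only needs relative lengths).
Per-sample size factors are log-uniform in a configurable range (default
degenerate at 1). One master seed yields per-stage child seeds by fixed
offsets, so counts, proteome and promoters are independently reproducible.

The protein layer quantifies a random 15% of genes (the study detected
under a third of expressed proteins; sarcomeric dominance limits shotgun
depth in muscle). For a quantified gene, log2 reporter intensity is
baseline (uniform 14–20) + planted group effect + batch offset + N(0, 0.3).
Three regulation modes connect the layers: `transcriptional` (protein
tracks the mRNA effect), `post_transcriptional_only` (protein-only effect;
the gene's mRNA is left at baseline by the count generator) and `buffered`
(mRNA effect with a flat protein). Mode fractions default to 50/25/25 among
quantified genes. Samples split into a "10-plex" batch (10 samples, spread
evenly across the sample list so batch is not confounded with group) and a
"16-plex" batch, with a global 2× intensity ratio; a 5% fraction of values
is removed completely at random. Informative missingness is out of scope —
the downstream filter is presence-based only.

Promoters are i.i.d. background sequence with configurable base
composition; motif instances sampled from a PWM's column distributions are
planted into the promoters of a target class (default `primary_down`) at a
per-promoter rate, with every insertion's coordinates recorded.

## RNA-seq differential expression

The DE stage re-implements the standard negative-binomial workflow in
simplified form:

* **Size factors** — median-of-ratios: over genes positive in all samples,
  the median of count / geometric-mean. Matches the reference
  implementation (pydeseq2) exactly on test fixtures.
* **Dispersion** — pooled within-group method of moments,
  α̂ = Σₖ(nₖ−1)(s²ₖ−μₖ) / Σₖ(nₖ−1)μₖ², floored at 1e-8. Raw per-gene
  moments at n = 8 are noisy, and underestimated dispersions inflate Wald
  statistics; the estimate is therefore combined in log space with a
  parametric trend a₀ + a₁/μ fitted across genes (weight 0.6 on the trend)
  and floored at the trend — a simplified analogue of empirical-Bayes
  dispersion moderation. Null simulations at n = 8 vs 8 put the Wald
  false-positive rate at p < 0.01 inside [0.005, 0.02].
* **Wald test** — per-gene NB GLM with log link, sample-specific size
  factor offsets and a group indicator, fitted by iteratively reweighted
  least squares (weights μ/(1+αμ)) at fixed dispersion; two-sided normal
  p-values; BH across converged genes. Non-converged genes get missing
  p-values and leave the BH denominator. All-zero groups are initialised at
  a pseudo-mean floor of 0.5 normalized counts, keeping degenerate
  estimates finite and monotone.
* **DEG gates** — padj < 0.01, point-estimate fold change 2^|log2FC| ≥ 1.25
  and mean TPM > 1 in at least one of the two contrast groups. The
  per-group-mean reading of the TPM gate keeps genes expressed in only one
  condition; it is a config value, not a claim about the only possible
  reading. No independent filtering and no fold-change shrinkage are
  applied; the FC gate uses the unshrunk estimate.

Deliberate omissions relative to full DESeq2: Cox–Reid adjustment,
independent filtering, lfc shrinkage. Validation is by simulation
calibration (null FPR, fold-change recovery within ±0.15 at |lfc| = 1,
n = 8) rather than output matching; a cross-check test confirms size-factor
and fold-change agreement with pydeseq2 on a small fixture.

**Power study** — for each group size, replicate two-group datasets are
simulated and pushed through the full calling chain; power is the mean
fraction of truly DE genes called, alongside the observed FDR. Default
simulation: 10,000 genes, 10% DE at fold change 2, dispersion 0.05,
baselines log-uniform [50, 2000]. Under these conditions power crosses 0.8
between n = 5 and n = 8.

## Proteome statistics

* **Batch normalization** — the non-reference batch is rescaled by the
  ratio of batch means over present values (by default the "10-plex" batch
  is scaled onto the "16-plex" one, following the lexicographic order of
  the labels). Idempotent; equalizes batch means to machine precision.
* **Presence filter** — keep proteins present in strictly more than 70% of
  samples (7/10 drops, 8/10 keeps).
* **ANOVA + Tukey** — one-way ANOVA on log2 intensities across the three
  groups (log2 is the default and configurable; reporter intensities are
  approximately log-normal). Missing values are excluded per protein with
  no imputation; a protein is testable when every group retains ≥ 2 values.
  BH q-values run over testable proteins only. Pairwise comparisons use the
  Tukey–Kramer studentized-range statistic |m_i−m_j| / √(MSW/2·(1/n_i+1/n_j))
  with k = 3 and df = N−k; a pairwise call requires q < 0.05 *and* Tukey
  p < 0.05. Degenerate rows with zero within-group scatter map to p = 0
  (nonzero difference) or p = 1 (no difference). Because the flags depend
  on the Tukey p only when q < 0.05, `tukey_scope="candidates"` evaluates
  the (expensive) studentized-range distribution just for those rows; the
  flags are provably identical to the full computation.

## Integration

Concordance classes are the six combinations of a changed protein (up/down)
with its mRNA status (up/ns/down); the concordant fraction (protein and
mRNA moving together) estimates the transcriptionally driven share of the
proteome change. Primary-aging selection applies the unidirectionality rule
described in the README; "protein did not change" means detected and
non-significant in **both** OP comparisons, and the strict mode (default)
requires protein significance in both comparisons, with a lenient
one-significant-plus-same-sign-trend mode behind a flag. The ANOVA q is a
per-protein (not per-comparison) quantity, so one global q gate plus two
pairwise Tukey gates is the reading implemented. Trajectory z-scores
standardize each feature across **all** samples (population sd), matching
the YH→YP→OP trajectory axis; zero-variance features are skipped. Gene-set
overlap uses the one-sided hypergeometric tail with the sample odds ratio
of the 2×2 table. PCA (QC only) runs on log2(x+1), centered, via
scikit-learn.

## TFBS enrichment

PWMs are parsed from the TRANSFAC text dialect (AC/ID/DE/P0 blocks, via
Biopython), pseudocount 0.01 per column. Scanning scores every position on
both strands with log2 odds against the background base composition
estimated from the background pool; N scores −∞; overlapping sites all
count. "Site frequency" is sites per scanned position, where scanned
positions = 2·(L−w+1) summed over promoters. Per PWM the threshold is the
smallest observed background score keeping the background frequency ≤ 1
site / 2000 bp; PWMs that cannot meet the cap even at their maximum score
(e.g. information-free matrices) are flagged unscannable and excluded. The
scanner is validated against a naive per-position rescoring oracle
(exact count equality).

FE_adj is implemented as the 99% CI lower bound of the log odds ratio
(Woolf SE, Haldane–Anscombe +0.5 on zero cells) — the natural reading of a
"statistically corrected odds ratio with a 99% confidence interval" — in
two variants: site-frequency table and promoter-count table. Significance
requires FE_adj > 1 in both variants plus FDR < 0.05, where the FDR is BH
over the one-sided binomial site-count p across all scannable PWMs
**before** per-TF collapse (the order is configurable). Per factor the PWM
with the largest FE_adj_freq is kept (ties: smaller Fisher p, then matrix
id), and factors with mean TPM ≤ 1 in the OP group are dropped. The
one-sided (enrichment) binomial test is used; depletion is not tested.
Both up- and down-regulated foregrounds can be scanned — the pipeline
defaults to the down-regulated set, but this is a run choice, not a rule.

## What the synthetic tests show — and what they do not

The generator realises the design's effect structure, NB noise, a batch
factor, MCAR missingness and plantable motifs. It does **not** model
correlated genes, GC or length biases, isoforms, outlier samples,
informative missingness, peptide-level noise or real promoter sequence
structure. Passing recovery tests therefore demonstrates that the
*procedures are correct and calibrated under their assumed models*, not
that the biological conclusions of any particular dataset are reproduced.
Headline counts from the real cohort (thousands of DEGs, hundreds of DE
proteins) depend on the deposited data and are outside what desk-scale
simulation can or should reproduce.

## Problem sizes and numerics

Simulation-backed tests use 10,000 genes (n = 8 per group for null
calibration and power; the 15/8/37 design for recovery), 2,000 null
proteins, and 50 foreground vs 5,000 background promoters of 1,000 bp
against a 21-PWM library — sizes chosen so each statistic rests on enough
events while a full suite run stays in the minutes range. Dispersion floor
1e-8; IRLS convergence 1e-8 on coefficients with step clipping at ±5 and a
50-iteration cap; BH via statsmodels (verified against a sort-and-cummin
oracle); hypergeometric/binomial tails via scipy. Every stochastic
component takes an explicit integer seed.
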