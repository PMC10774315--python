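# Methods

This note documents the models, numerical choices and limitations of
`pairmet`. It describes what the code computes; every number quoted here is
produced by the test suite or `scripts/acceptance.py` at run time.

## Hurdle differential expression

Single-cell expression is zero-inflated. For a gene with log1p-normalized
expression x over cells split into a binary grouping (cluster vs rest), the
two-part model is

* **detection**: Pr(x > 0) follows a logistic model on the group indicator.
  With a single binary covariate the MLE is the 2×2 detection table; the
  reported `detect_coef` is its log odds ratio, and the likelihood-ratio
  statistic has the closed multinomial form (0·log 0 ≡ 0). When both groups
  sit on the same boundary (all or no cells detected) the coefficient is 0.
* **continuous**: among detected cells, x follows a Gaussian with a group
  mean shift. At the MLE variance the LRT is n·ln(RSS₀/RSS₁); `cont_coef`
  is the difference of detected-cell means.

The two statistics add to a χ²(2) test; if either group has no detected
cells the continuous part is dropped, the reference becomes χ²(1), and the
row is flagged (`cont_dropped`). No cellular-detection-rate covariate is
included: with the single binary covariate both parts have closed-form
solutions, which the property tests exploit (agreement with an independent
GLM oracle to 1e-8 on random instances).

**Prefilters** run before any test: |avg logFC| ≥ 0.25 and detection ≥ 10%
in either group, so the number of tests equals the number of rows entering
Benjamini–Hochberg correction (applied within each cluster-vs-rest
comparison). avg logFC is the natural-log difference of
ln(mean(expm1(x)) + 1) between groups — the dominant single-cell
convention for the 0.25 default. Counts are library-size normalized to
10,000 per cell and log1p-transformed before testing; `normalize=False`
accepts pre-normalized input. Markers feed the mechanism only at
FDR < 0.05.

## Mechanism construction

Each cluster's significant markers are split by the sign of avg logFC; the
top `n_top` (default 100) of each side — ties at the boundary broken by
lexicographic gene id for reproducibility — are crossed into oriented
(up, down) pairs. The cluster-tagged total is Σ min(n_top, n_pos)·
min(n_top, n_neg); with three clusters fully populated, 30,000. Training
uses the deduplicated pooled set; the tagged multiset is retained for
audit. A cluster lacking one side contributes zero pairs with a warning.

## Cohort harmonization, split, quantile normalization

Harmonization: per dataset, optional log2(x+1) (for linear-scale input),
then gene-wise z-scoring with population SD; genes constant in any dataset
are dropped everywhere; gene sets are intersected and samples concatenated.
Z-scoring is idempotent, and removes the simulator's per-dataset
location/scale batch effects exactly (in expectation), which a test checks
by the non-predictability of the dataset label afterwards.

Split: strata are the full cross of dataset × Gleason × age tertile × PSA
tertile × stage (tertiles computed on the whole cohort; missing values form
an "unknown" level so the partition stays exhaustive). Allocation is
largest-remainder: each stratum contributes ⌊n_s·f⌋ training samples plus
at most one more, awarded by descending fractional remainder until the
global count reaches ⌈f·n⌉; singleton strata go wholly to training. With
the full strata cross on a few hundred samples many strata are singletons —
this is the price of stratifying on five variables and is reported via a
warning, while the global ⌈f·n⌉ count is always exact (1,239 → 930/309).

Quantile normalization maps each sample's order statistics onto the
across-sample mean order-statistic profile; ties within a sample receive
the average of their target quantiles. It is applied to the training and
testing partitions separately (a leakage test asserts the test partition is
never touched before prediction time).

## k-TSP classifier

For candidate pair (u, d) the primary score is
Δ = P̂(X_u > X_d | met) − P̂(X_u > X_d | non-met) ∈ [−1, 1], from empirical
within-class frequencies with exact expression ties counting ½. The
secondary score Γ is the absolute between-class gap of the mean
within-sample rank difference (midranks over the cohort's gene panel).
Because the mechanism fixes each pair's orientation, pairs are ranked by
*signed* Δ and pairs with Δ ≤ 0 are discarded: the constraint encodes the
direction expected in metastatic samples.

Selection is a greedy scan in (Δ desc, Γ desc, lexicographic gene ids)
order, skipping any pair sharing a gene with an already selected pair,
until k pairs are found. On small instances this equals exhaustive
enumeration of disjoint chains under the same ordering (tested). k is
either fixed (the default pipeline uses k = 13, the signature size the
method is known for) or chosen by 5-fold stratified cross-validation of
the vote-fraction AUROC over odd k ∈ {3,…,25}, taking the smallest
maximizer; a fold in which no positive-Δ pair exists scores 0.5
(uninformative), and folds missing an outcome class trigger a reseeded
refold (at most 10 attempts).

Prediction: each pair votes 1 if X_u > X_d, 0 if <, ½ on an exact tie; the
vote fraction is the mean and the sample is called metastatic when it is
≥ 0.5 (tie to the metastatic class — sensitivity-favoring, configurable).
Everything downstream of the within-sample orderings is invariant to
strictly increasing per-sample transforms (property-tested).

## Evaluation

AUROC is the Mann–Whitney statistic with midrank ties. The logistic
probability score is fit by Newton/IRLS on the signature genes of the
training partition and applied unchanged to held-out data; perfect
separation raises an error recommending the L2 (ridge) option, which the
pipeline uses by default (strength 1.0) since 2k signature genes can
separate small training sets. Kaplan–Meier, the log-rank test and the Cox
model are provided through lifelines: Efron tie correction, Wald 95% CIs,
complete-case handling with the dropped count reported. Gleason enters as
indicator columns for 7/8/9/10 with ≤6 as reference. A fit with no events
raises; a monotone partial likelihood (all events in one covariate level)
is detected post-fit by a diverged coefficient (|β| > 10 or SE > 100) and
raised as a convergence error.

## Synthetic data

The generator emulates the structure the analysis assumes, with planted
ground truth for recovery tests. All outputs are byte-identical under a
fixed seed.

* **Single cell**: counts are negative-binomial (shared dispersion 2.0)
  around per-gene log-normal base means, thinned by independent Bernoulli
  dropout (rate 0.3). A planted marker multiplies the mean in its cluster
  by exp(effect); the default study plants the 26 bulk pair genes as
  markers (ln-fold ±1.0) across three stromal-like clusters of 150 cells
  each plus a 300-cell rest cluster.
* **Bulk**: log-scale Gaussian expression (noise SD 1). Each planted
  (up, down) pair shares a base mean and receives class-conditional offsets
  ±δ_c/2 with δ_c = √2·σ·Φ⁻¹(target), so P(X_up > X_down | class) equals
  the configured inversion probability exactly on the batch-free scale
  (0.65 metastatic / 0.35 non-metastatic by default; equal probabilities
  give the null study). The two genes of a pair additionally share a
  per-sample latent factor (SD 2.0, within-pair correlation ≈ 0.8),
  modeling co-regulation; it cancels in the up−down difference — leaving
  the probit calibration intact — while making cross-pairings of genes
  from different pairs strictly weaker, so the planted *pairing* is
  identifiable after per-gene z-scoring, not just the gene set. Datasets
  (3 by default, 600 samples total, 35% metastasis prevalence) receive
  per-gene additive N(0, 1) shifts and log-normal (SD 0.25) scales,
  removable by the harmonization step. Gleason is drawn from a
  proportional-odds model tilted by the metastasis label (log-odds 1.0);
  age, PSA and stage are drawn from plausible clinical marginals,
  independent of outcome.
* **Survival**: exponential event times with hazard
  rate·exp(β·met + γ·gleason_index), baseline 0.02/month, β = ln 2,
  γ = 0.3 by default; independent exponential censoring (0.01/month).
  The metastasis label is the signature-linked hazard covariate, so
  hazard-ratio recovery checks against the planted β directly and the
  predicted-class survival analyses are non-trivial.

What the generator does **not** emulate: ambient RNA, doublets, UMI
saturation, gene–gene correlation beyond the planted pairs, non-Gaussian
bulk noise, platform-specific probe effects, informative censoring, and
non-proportional hazards. Passing recovery tests therefore demonstrates the
pipeline's correctness under its stated assumptions, not performance on any
real cohort.

## Problem sizes and determinism

The default study (2,000 genes, 750 cells, 600 bulk samples) runs end to
end in under a second, so the recovery and calibration suites use 20–50
independent seeds and the type-I-error study 500–1,000 replicates. Every
random draw flows from a single configured seed through
`numpy.random.default_rng`; the pipeline report is reproducible
byte-for-byte given the config.

## Known limitations

* The hurdle test omits the cellular-detection-rate covariate common in
  reference implementations; with strong per-cell depth gradients its
  p-values can be anticonservative. The extension point is the `fit_hurdle`
  design; it is off by default to preserve the closed forms.
* With ~540 potential strata on a 600-sample cohort, most strata are
  singletons and stratification degenerates gracefully toward a random
  split with exact global counts.
* Hazard-ratio estimation at n = 1,000 with a binary covariate has a
  sampling SD of the log HR of at least √(4/n) ≈ 0.063 (all events,
  balanced arms), so an estimate within ±10% of a true HR of 2 is expected
  in only ~86% of replicates; the acceptance suite documents this bound
  where it checks recovery.
* Genes absent from a cohort a trained signature is applied to raise an
  error naming the gene; no imputation is attempted.
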