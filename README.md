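# pairmet

**Mechanism-constrained k-top-scoring-pairs metastasis signatures from
stromal single-cell markers.**

Aggressive prostate cancer reshapes its stromal microenvironment. If the
stromal transcriptional program that accompanies neuroendocrine-prone
disease can be read out of *bulk* tumor expression profiles, it can flag
patients at risk of metastasis at diagnosis. `pairmet` implements that
analysis as a reusable, tested pipeline:

1. **Stromal markers.** From a clustered single-cell count matrix,
   cluster-vs-rest differential expression with a two-part *hurdle model*:
   a logistic component for detection (the dropout-driven zeros of
   single-cell data) and a Gaussian component for log expression among
   detected cells, combined in a χ²(2) likelihood-ratio test. Genes are
   prefiltered to |avg logFC| ≥ 0.25 (natural log) and detection in ≥ 10%
   of cells in either group, then Benjamini–Hochberg corrected.
2. **Mechanism.** Per stromal cluster, the top 100 up-regulated and top 100
   down-regulated markers are crossed into oriented (up, down) candidate
   gene pairs — with three clusters, 30,000 cluster-tagged pairs. This set
   is the *biological constraint*: the classifier may only use these pairs.
3. **Cohort preparation.** Multi-dataset bulk cohorts are harmonized
   (per-dataset log2 + gene-wise z-score, gene intersection), split 75/25
   with stratification on dataset × Gleason × age × PSA × stage
   (largest-remainder allocation), and quantile-normalized per partition.
4. **k-TSP classifier.** Each candidate pair is scored by
   Δ = P̂(X_up > X_down | met) − P̂(X_up > X_down | non-met), with the
   within-sample rank-difference gap Γ as tie-breaker. The signature is the
   greedy gene-disjoint top-k (k odd; fixed, or chosen by stratified CV);
   prediction is the majority vote of the pairs' within-sample orderings —
   invariant to any per-sample monotone normalization.
5. **Evaluation.** AUROC (Mann–Whitney, midrank ties), logistic probability
   scoring on the signature genes, Kaplan–Meier curves and log-rank test
   between predicted classes, and a Gleason-adjusted Cox proportional-hazards
   model (Efron ties, Wald 95% CIs) of progression-free survival.

A synthetic-data module generates both inputs with planted ground truth —
negative-binomial single-cell counts with Bernoulli dropout and cluster
marker shifts; Gaussian log-scale bulk cohorts with per-dataset batch
location/scale effects, probit-calibrated rank-inverting pairs, Gleason
grade correlated with metastasis, and exponential progression-free survival
with independent censoring — so every stage's recovery can be tested.

## Worked example

Run the full pipeline on the default planted study (13 gene-disjoint pairs
with per-class inversion probabilities 0.65/0.35 among 2,000 genes; a
600-sample, three-dataset cohort; the same 26 genes planted as up/down
markers of three stromal clusters):

```bash
pairmet run --out demo/ --seed 42
```

prints (abridged):

```
k-TSP signature
  pairs selected: 13 (requested 13)
  unique genes:   26
  candidates:     909

 rank up_gene down_gene    delta      gamma
    1   g0004     g0005 0.329570 268.044959
    2   g0008     g0009 0.321648 312.327788
    3   g0000     g0001 0.318281 308.754605
    ...
AUROC train = 0.922  test = 0.913
log-rank p (test, predicted classes) = 2.32e-02
Cox proportional hazards  n=150  events=112
                     coef        hr  ci_lower  ci_upper         p
predicted_class  0.438775  1.550806  1.060109  2.268635  0.023777
gleason_7        0.264837  1.303219  0.738561  2.299581  0.360698
...
```

Reading the output: the mechanism derived from the simulated single-cell
markers contained 909 candidate pairs; the selected signature consists of
13 disjoint pairs (12 of them planted pairs, e.g. `g0004 > g0005` voting
for metastasis), each with its class-separation score Δ. The vote-fraction
score separates held-out metastatic from non-metastatic samples with AUROC
0.91, and the predicted class carries prognostic information for simulated
progression-free survival beyond Gleason grade (HR 1.55).

The same objects are available as a library:

```python
from pairmet import KTSP, SimConfig, run_pipeline, PipelineConfig

cfg = PipelineConfig(sim=SimConfig.default_study(seed=42), seed=42, k=13)
result = run_pipeline(cfg)
result.report.auroc_test        # held-out AUROC
result.ktsp.summary()           # the signature table
result.ktsp.predict(result.test)
```

or, statsmodels-style, from your own frames:

```python
model = KTSP.from_dataframe(expr, met_event, pairs)   # samples x genes, labels, (up, down)
results = model.fit(k=13)                             # or k=None for CV over odd k
vote_fraction, predicted = results.predict(cohort)
```

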