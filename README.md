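# tsizesig

Tumor-size expression signatures for breast cancer: discover a gene set
that separates clinical T1 (≤ 2 cm) from T2 (> 2 cm, ≤ 5 cm) tumors in a
small two-channel microarray cohort, classify independent samples as
**T1-like** or **T2-like** by correlation to the signature centroids, and
quantify the prognostic value of that call for distant-metastasis-free
survival (DMFS).

The package is aimed at translational cancer researchers who want the full
analysis chain — preprocessing, covariate-adjusted differential
expression, nearest-centroid risk classification, gene-set
overrepresentation, and a complete survival-statistics battery — as
tested, reusable components, runnable end to end on synthetic cohorts with
known ground truth.

## The statistics at the core

**Differential expression.** Genes associated with size class are found
with the permutation-based regularized statistic

```
d_i = (x̄_{T2,i} − x̄_{T1,i}) / (s_i + s0)
```

where `s_i` is the pooled standard error of the mean difference and `s0` a
shared fudge factor damping small-variance genes. The false discovery rate
at a threshold Δ on |d| is estimated as the expected number of permuted
exceedances (over class-size-preserving label permutations) divided by the
observed count; a gene's q-value is the smallest such FDR at any threshold
that calls it. Before the comparison, expression is residualized on
clinical covariates (node status, grade, ER/PgR, molecular subtype) via
partial least squares, so covariate-driven genes are not mistaken for
size-associated ones.

**Classification.** The signature is the pair of class-mean profiles
(centroids) over the selected genes. A new sample gets the label of the
centroid with the higher Pearson correlation over shared genes — no
correlation cutoff, every sample is classified.

**Survival evaluation.** Kaplan–Meier curves and the logrank test per risk
group; Cox proportional-hazards models (Efron ties, optionally
ER-stratified) reporting HR with 95% CI, the likelihood-ratio test,
deviance (= the overall-model LRT statistic), Harrell's C-index, and the
likelihood-based proportion of variation explained, `PVE = 1 − exp(−LRT/n)`,
with partial PVE per covariate in multivariate models.

**Enrichment.** Up- and down-regulated gene sets are tested against
user-supplied GMT collections with the conservative EASE variant of the
hypergeometric test (overlap reduced by one) and Benjamini–Hochberg
adjustment.

## Worked example

```python
from tsizesig import SyntheticConfig, TSizeSignatureModel
from tsizesig.synthetic import generate_discovery_cohort

cfg = SyntheticConfig(seed=11, n_genes=600, effect_size=3.0)
expression, clinical, truth = generate_discovery_cohort(cfg)

model = TSizeSignatureModel(expression, clinical, n_permutations=200)
results = model.fit(seed=11)
print(results.summary())
```

prints

```
T-size signature discovery
==========================
samples:              46 (27 T1, 19 T2)
genes analyzed:       600
covariate adjustment: PLS on node, grade, er, pgr, subtype
SAM fudge factor s0:  0.2895
permutations:         200 (seed 11)
FDR threshold:        0.01
selected genes:       30 (17 up in T1, 13 up in T2)
two-cluster cut vs stage:
stage    T1  T2
cluster
1         0  19
2        27   0
```

The cohort has the discovery study's structure (46 samples, 27 T1 / 19 T2
by the 2 cm rule). All 30 genes planted with a true class effect pass the
1% FDR threshold, and the confirmatory two-cluster cut of the samples on
those genes recovers the size classes exactly. `results.classify(matrix)` then labels
an independent cohort, and `results.evaluate_survival(clinical,
assignments)` produces the univariate and ER-stratified multivariate
survival tables plus logrank tests on the complete set and within each pT
subgroup.

The same flow is scriptable from the shell:

```bash
tsizesig run-all --config config.yaml --out runs/demo
```

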