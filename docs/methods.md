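# Methods

This note documents the models, estimators and numerical choices behind
`tsizesig`, the parameters that matter, and what the synthetic-data
generator does and does not emulate.

## Problem setting

Clinical tumor size is the second-strongest prognostic factor in breast
cancer after nodal status; T1 denotes tumors no more than 2 cm in largest
diameter, T2 tumors above 2 cm up to 5 cm. The package derives an
expression signature separating T1 from T2 tumors in a small two-channel
microarray discovery cohort, applies it as a nearest-centroid classifier
to an independent single-channel compendium, and evaluates whether the
resulting T1-like/T2-like call carries prognostic information for
distant-metastasis-free survival (DMFS) beyond, and within, the clinical
size categories themselves. Sizes above 5 cm are outside scope and are
reported as an explicit `T3+` sentinel rather than silently binned.

## Preprocessing

**Two-channel discovery arrays.** Spots flagged as poor by the image
analysis are masked; probes left without any observation are dropped.
Each array's log-ratios M are then detrended against spot mean intensity
A with a loess fit (default span 0.3, local-linear; exposed as
`preprocess.loess_span`) — the standard within-array normalization for
two-channel data. Arrays with fewer than 10 usable spots are rejected as
underdetermined. Remaining missing values are imputed only for genes with
a missing fraction strictly below 5%: the k = 10 complete genes most
correlated with the target (absolute Pearson over the target's observed
samples) enter an ordinary least-squares regression whose fitted values
fill the gaps — a gene-wise reduction of least-squares imputation. Genes
at or above the 5% threshold are dropped and counted in the log; when no
complete predictor genes exist, the gene mean is used with a warning.

The imputation floor is worth stating: the masked entry's own
idiosyncratic noise is part of the value being recovered, so no imputer
can push the expected RMSE below the residual noise SD. The test suite
checks proximity to that floor, not an impossible bound below it.

**Single-channel validation datasets.** Inputs are accepted as already
RMA-like (raw CEL processing is out of scope). Each dataset is median
centered per gene — removing additive per-gene dataset offsets exactly at
the population level — then the datasets are merged on their common probe
set. Known duplicate samples across cohorts are removed by an explicit ID
exclusion list, not by correlation heuristics. For cross-platform
matching, probes are collapsed to gene symbols keeping the
highest-variance probe; unannotated probes are dropped. Deterministic and
order-invariant by construction.

## Covariate adjustment

Node status, grade, ER, PgR and molecular subtype are dummy-encoded
(ordinal grade contrasts against grade 1; node as positive-vs-negative
plus an extensive-involvement indicator) and expression is residualized
on them by partial least squares (NIPALS, unscaled): the covariates are
the predictors, the genes×samples expression block the multivariate
response, and the returned matrix is the response minus its PLS
prediction. Residuals are orthogonal to the extracted score vectors;
constant covariate columns are dropped with a warning; samples with
incomplete covariates are excluded from the fit and residualized against
the covariate-mean prediction.

The number of components defaults to **2**. A full-rank residualization
(the design has ~8 columns at n = 46) removes, partly through sheer
overfitting, around half of the class contrast along with the confounding
— enough to destroy genuine size-associated signal. Two components
capture the dominant covariate-driven expression structure (in the
generator, confounder-linked genes are suppressed completely) while
leaving the class contrast essentially intact. The count is exposed
(`n_components`) for sensitivity analysis. With a single binary covariate
and one component the adjustment reduces exactly to within-group mean
centering, which the tests exploit as a closed-form oracle.

The composition is: adjust first, then test. Centroids, by contrast, are
built on the *normalized but unadjusted* expression, so that the signature
can be applied to validation cohorts for which the discovery covariates
are unavailable.

## Differential expression

The class comparison uses the regularized statistic
`d_i = (x̄_T2 − x̄_T1) / (s_i + s0)` with `s_i` the pooled standard error
and `s0` a shared stabilizer. `s0` defaults to the median of the `s_i`;
the classic alternative — searching the percentiles {0, 5, …, 100} of
`s_i` for the value minimizing the coefficient of variation of the
d-spread (median absolute deviation) across `s`-quantile bins — is
available as `s0_method="percentile_search"`.

FDR comes from class-size-preserving label permutations (default 1000,
seeded; exhaustive enumeration whenever the number of distinct
arrangements is no larger than the requested count). At each candidate
threshold (the observed |d| values) the estimated FDR is the **mean**
permuted exceedance count divided by the observed count, capped at 1; a
gene's q-value is the smallest FDR over the thresholds at which it is
called, which a cumulative minimum along the |d| ranking makes monotone.
The mean (rather than median) count follows the original formulation of
the permutation procedure and matters in practice: with the median, the
top gene's estimated FDR collapses to 0 in roughly half of all null
datasets because the count at the maximum threshold is a small integer.
With the mean, about 5% of 2000-gene null cohorts produce any q < 0.05
call — the calibration the acceptance suite verifies. A tiny relative
tolerance (1e−9) is applied when counting permuted exceedances so that a
permuted statistic equal to an observed threshold (e.g. the identity
arrangement in exhaustive mode) is counted.

Genes below the FDR threshold (default 1%, with 2% a supported
alternative convention) are partitioned by the sign of d into up-in-T1
and up-in-T2 sets. As confirmation, samples are clustered on the selected
genes (correlation distance, average linkage) after per-gene mean
centering — without which between-gene location differences dominate
sample-profile correlations — and the two-cluster cut is cross-tabulated
against stage.

## Signature and classification

The signature stores the per-class arithmetic mean profile of the
selected genes. Classification computes each sample's Pearson correlation
with both centroids over the genes shared between sample and signature
(at least 3 required; the shared fraction is reported and a warning
issued below 50%) and assigns the label of the larger correlation. No
correlation cutoff is applied. Exact ties go to T1-like — the
conservative, lower-risk call — and are flagged. Classification is
invariant to positive-scale affine transforms of a sample's profile, a
property the suite asserts.

Generic risk-score mechanics shared by published signatures are included:
a linear combination of centroid correlations (the ROR-S pattern) and
population-quantile group assignment (fixed proportions of the ranked
population per risk group, stable-order tie handling). The specific gene
lists and coefficients of published signatures are deliberately not
bundled; externally supplied centroid files in the same JSON format are
accepted.

## Enrichment

Overrepresentation uses the EASE variant of the hypergeometric test: with
overlap k, set size m, query size n and universe N, the reported p is the
upper tail at k − 1 (k ≤ 1 gives p = 1), a deliberate penalization of
single-gene overlaps; Benjamini–Hochberg adjustment is applied across
terms. The universe defaults to the genes present on the analyzed matrix,
matching array-based background logic, since which background a given
annotation service used is generally unknowable.

## Survival battery

Kaplan–Meier product-limit curves and the logrank test (chi-square with
groups − 1 df) per risk group; Cox proportional-hazards fits with Efron
tie handling (validation follow-up is in whole months, so ties are
common), optional ER stratification as separate baseline hazards, Wald
95% CIs, and Newton convergence tightened to 1e−12 so the estimates match
a brute-force partial-likelihood maximization to ~1e−8. Monotone
likelihood (perfect separation) raises an error naming the covariates.

The overall effect is judged by the likelihood-ratio statistic
`2(l(β̂) − l(0))`; **deviance** is reported as that same statistic (the
identity reading; they agree exactly, and the suite asserts it).
**PVE** is the likelihood-based `1 − exp(−LRT/n)`; the partial PVE of a
covariate group in a multivariate model uses the LRT comparing the full
model to the model refit without that group's dummy columns (the columns
of one clinical variable leave together). The published summary pairing
of deviance 25.55 with PVE 2.76e−2 at n = 912 is reproduced by this
formula, which is why it was adopted; the formula is a package choice and
is pluggable. Harrell's C counts, among censoring-comparable pairs, how
often the higher risk score precedes the event, with score ties worth
0.5.

## Synthetic data

The generator defines the study conditions for every test.

**Discovery cohort** (defaults): 2000 genes × 46 samples, 27/19 T1/T2;
tumor sizes drawn uniformly within (0.5, 2.0] for T1 and (2.0, 5.0] for
T2 so the 2 cm rule reproduces the labels exactly; log-ratio-like
expression (mean ≈ 0) with residual SD 1.0 (log2). A fraction (default
5%) of genes carries a true class shift of ±`effect_size` (default 1.0
log2; the "strong signal" regime used in recovery checks is 3.0). A
disjoint fraction (default 5%) of *confounded* genes tracks node status
— not class — with amplitude 4.0 log2. Clinical covariates follow
class-dependent prevalences (node positive 25% in T1 vs 75% in T2; milder
gradients for grade, ER, PgR and subtype), so node-linked genes show a
spurious class effect of about `4.0 × Δprevalence ≈ 2` log2. The large
amplitude is forced by arithmetic: a binary confounder inflates
within-class variance by `c²p(1−p)`, so the spurious t statistic
saturates near `Δp/(0.3·√(p(1−p)))` regardless of c, and smaller
amplitudes leave naive selection of confounded genes unreliable.
Optional per-spot intensities, poor-spot flags, an M~A trend
(`dye_bias`) and uniform missingness exercise the preprocessing chain.

**Validation compendium** (defaults): 6 datasets × 158 samples
(~948 total, the scale of the emulated compendium), log-intensity-like
expression (per-gene base level uniform on [5, 12]) sharing the
discovery cohort's gene architecture, per-dataset per-gene N(0, 0.5²)
batch offsets (removed exactly in expectation by median centering), and
~5% per-dataset probe dropout to exercise common-probe merging. Latent
class is Bernoulli(½) per sample; observed pT stage agrees with it with
probability 0.75, so within-stage subgroup analyses are meaningful. DMFS
times follow a Weibull proportional-hazards model (default shape 1,
i.e. exponential; baseline 0.008 events/month, median ≈ 87 months) with
the hazard multiplied by `true_hazard_ratio` (default 2.0) for latent
T2-like samples; independent exponential censoring is calibrated to the
requested censored fraction (default 50%).

What the generator does **not** emulate: probe-sequence effects, raw
image artifacts, dye-swap designs, non-additive batch effects,
covariate-dependent censoring, and hazards driven by anything other than
the latent class. Passing tests therefore demonstrate the estimators'
correctness and calibration under a clean proportional-hazards,
additive-batch world — not robustness to violations of those
assumptions in real cohorts.

## Problem sizes and determinism

Simulation-based checks run at desk scale, chosen to keep the full suite
in a few minutes: 2000-gene null cohorts (50–100 replicates at 200
permutations) for FDR calibration, 2000 replicates of n = 200 for logrank
type-I error, 100 replicates of n ≈ 900 for hazard-ratio CI coverage, 500
replicates of n = 500 for C-index calibration, and means over 3 cohorts
for recall/agreement metrics (a single 46-sample cohort's recall is noisy
because the realized covariate–class R² occasionally reaches 0.6+).
Every stochastic component takes an explicit seed; a fixed seed gives
bit-identical generator output and hash-identical pipeline manifests.

## Known limitations

- The q-value estimator ignores the fraction of truly null genes (no π0
  correction), making it conservative when many genes are truly
  differential.
- PLS adjustment with few components removes only the dominant
  covariate-driven variation; weak confounding aligned with minor
  components can survive.
- The probe-to-gene collapse (max variance) and the Pearson choice for
  centroid correlation are conventions; alternatives (mean collapse,
  Spearman) are not implemented.
- The survival battery offers no proportional-hazards diagnostics beyond
  the model contracts; time-dependent covariates and competing risks are
  out of scope.
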