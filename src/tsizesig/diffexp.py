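"""Size-associated differential expression.

The comparison of T1 vs T2 tumors is run on expression residuals after a
partial-least-squares adjustment for clinical covariates (node status,
grade, ER/PgR status, molecular subtype), so that genes tracking those
covariates rather than size itself are not selected.  Significance uses
the SAM-style regularized statistic

    d_i = (mean_T2,i - mean_T1,i) / (s_i + s0)

with s_i the pooled standard error of the group-mean difference and s0 a
shared "fudge factor" damping small-variance genes.  The false discovery
rate is estimated from class-size-preserving label permutations: at each
candidate threshold on |d| the expected number of permuted exceedances is
divided by the observed count, and each gene's q-value is the smallest
such FDR at any threshold that calls it (made monotone along the |d|
ranking by a cumulative minimum).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd
from sklearn.cross_decomposition import PLSRegression

from .containers import ExpressionMatrix, numeric_grade

__all__ = [
    "PLSAdjustment",
    "pls_adjust",
    "sam_statistic",
    "estimate_s0",
    "permutation_fdr",
    "sam_analysis",
    "select_signature_genes",
    "hierarchical_cluster",
    "DEFAULT_COVARIATES",
]

logger = logging.getLogger(__name__)

DEFAULT_COVARIATES = ("node", "grade", "er", "pgr", "subtype")


# ---------------------------------------------------------------------------
# PLS covariate adjustment
# ---------------------------------------------------------------------------

@dataclass
class PLSAdjustment:
    """Fitted adjustment: design, component scores/loadings, residuals."""

    covariate_design: pd.DataFrame   # samples x dummy-encoded covariates
    n_components: int
    x_scores: np.ndarray             # samples x components
    y_loadings: np.ndarray           # genes x components
    residuals: pd.DataFrame          # genes x samples


def build_covariate_design(clinical: pd.DataFrame, covariates=DEFAULT_COVARIATES) -> pd.DataFrame:
    """Dummy-encode clinical covariates into a samples x columns design.

    Binary status columns (er/pgr) become 0/1 indicators; node is encoded
    as positive-vs-negative plus an extensive-involvement indicator; grade
    (coerced numeric) and categorical subtype are dummy-coded against their
    first level.
    """
    idx = pd.Index(clinical["sample_id"].astype(str), name="sample_id")
    cols: dict[str, np.ndarray] = {}
    for cov in covariates:
        if cov not in clinical.columns:
            raise ValueError(f"covariate {cov!r} missing from clinical table")
        col = clinical[cov]
        if cov in ("er", "pgr"):
            cols[f"{cov}_pos"] = (col.astype(str).str.lower().str.startswith("pos")).astype(float).to_numpy()
        elif cov == "node":
            v = pd.to_numeric(col, errors="coerce").to_numpy(dtype=float)
            cols["node_pos"] = (v > 0).astype(float)
            if (v >= 2).any():
                cols["node_extensive"] = (v >= 2).astype(float)
        elif cov == "grade":
            g = numeric_grade(col)
            for level in sorted(g.unique())[1:]:
                cols[f"grade_{int(level)}"] = (g == level).astype(float).to_numpy()
        else:
            cats = pd.Categorical(col.astype(str))
            for level in cats.categories[1:]:
                cols[f"{cov}_{level}"] = (cats == level).astype(float)
    design = pd.DataFrame(cols, index=idx)
    constant = design.nunique() <= 1
    if constant.any():
        logger.warning("dropping constant covariate columns: %s",
                       list(design.columns[constant]))
        design = design.loc[:, ~constant]
    return design


def pls_adjust(
    matrix: ExpressionMatrix,
    clinical: pd.DataFrame,
    covariates=DEFAULT_COVARIATES,
    n_components: int | None = None,
) -> tuple[ExpressionMatrix, PLSAdjustment]:
    """Residualize expression on clinical covariates via PLS (NIPALS).

    Expression (samples x genes) is the response, the dummy-encoded
    covariates the predictors; the returned matrix holds the residuals
    after removing the covariate-predictable part of each gene.  With a
    single binary covariate and one component this reduces exactly to
    within-group mean centering.

    Samples with incomplete covariates are excluded from the fit and
    residualized against the covariate-mean prediction (their design row
    filled with the training means).
    """
    design = build_covariate_design(clinical, covariates)
    design = design.reindex(pd.Index(matrix.sample_ids.astype(str)))
    if matrix.values.isna().any().any():
        raise ValueError("pls_adjust requires a complete matrix (impute first)")

    complete = design.notna().all(axis=1).to_numpy()
    if (~complete).any():
        logger.warning("pls_adjust: %d samples lack covariates; residualized "
                       "against covariate-mean prediction", int((~complete).sum()))
    X_fit = design.to_numpy(dtype=float)[complete]
    rank = np.linalg.matrix_rank(X_fit - X_fit.mean(axis=0))
    if n_components is None:
        # a small fixed number of components captures the dominant
        # covariate-driven expression structure without the overfitting a
        # full-rank regression suffers at ~46 samples
        n_components = max(min(2, rank), 1)
    if n_components > rank:
        raise ValueError(f"n_components={n_components} exceeds design rank {rank}")

    Y = matrix.values.to_numpy(dtype=float).T  # samples x genes
    pls = PLSRegression(n_components=n_components, scale=False)
    pls.fit(X_fit, Y[complete])

    X_all = design.to_numpy(dtype=float).copy()
    col_means = X_fit.mean(axis=0)
    nan_rows, nan_cols = np.where(np.isnan(X_all))
    X_all[nan_rows, nan_cols] = col_means[nan_cols]
    resid = Y - pls.predict(X_all)

    out = matrix.copy()
    out.values = pd.DataFrame(resid.T, index=matrix.probe_ids, columns=matrix.sample_ids)
    adj = PLSAdjustment(
        covariate_design=design,
        n_components=n_components,
        x_scores=pls.x_scores_,
        y_loadings=pls.y_loadings_,
        residuals=out.values,
    )
    return out, adj


# ---------------------------------------------------------------------------
# SAM statistic and permutation FDR
# ---------------------------------------------------------------------------

def _group_arrays(matrix_values: np.ndarray, labels: np.ndarray):
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes, got {list(classes)}")
    t1 = labels == "T1" if "T1" in classes else labels == classes[0]
    n1, n2 = int(t1.sum()), int((~t1).sum())
    if n1 < 2 or n2 < 2:
        raise ValueError(f"both classes need >= 2 samples (got {n1}, {n2})")
    return t1, n1, n2


def _d_and_s(values: np.ndarray, t1_mask: np.ndarray, s0: float):
    """Vectorized d_i and pooled SE s_i for one labeling."""
    x1 = values[:, t1_mask]
    x2 = values[:, ~t1_mask]
    n1, n2 = x1.shape[1], x2.shape[1]
    m1, m2 = x1.mean(axis=1), x2.mean(axis=1)
    ss = ((x1 - m1[:, None]) ** 2).sum(axis=1) + ((x2 - m2[:, None]) ** 2).sum(axis=1)
    s = np.sqrt((1.0 / n1 + 1.0 / n2) * ss / (n1 + n2 - 2))
    d = (m2 - m1) / (s + s0)
    return d, s


def sam_statistic(matrix: ExpressionMatrix, labels, s0: float):
    """Per-gene SAM statistic ``d`` and pooled standard error ``s``.

    ``d_i = (mean_T2 - mean_T1) / (s_i + s0)``; with ``s0 = 0`` this is the
    pooled two-sample t statistic.  Returns a DataFrame indexed by probe
    with columns ``d_stat`` and ``pooled_se``.
    """
    if matrix.values.isna().any().any():
        raise ValueError("sam_statistic requires a complete matrix")
    labels = np.asarray(pd.Series(labels).astype(str))
    t1, _, _ = _group_arrays(matrix.values.to_numpy(), labels)
    d, s = _d_and_s(matrix.values.to_numpy(dtype=float), t1, s0)
    return pd.DataFrame({"d_stat": d, "pooled_se": s}, index=matrix.probe_ids)


def estimate_s0(pooled_ses, method: str = "median", n_bins: int = 20, d_num=None) -> float:
    """Fudge factor s0 from the per-gene pooled standard errors.

    ``median`` (default) returns the median s_i.  ``percentile_search``
    performs the classic search over the percentiles {0, 5, ..., 100} of
    s_i, choosing the candidate that minimizes the coefficient of variation
    of the spread (median absolute deviation) of d across s-quantile bins;
    it requires ``d_num``, the per-gene mean differences (the d numerators).
    """
    s = np.asarray(pooled_ses, dtype=float)
    if s.size == 0:
        raise ValueError("estimate_s0 needs at least one gene")
    if np.all(s == 0):
        logger.warning("all pooled SEs are zero; returning s0 floor 1e-6")
        return 1e-6
    if method == "median":
        return float(np.median(s))
    if method != "percentile_search":
        raise ValueError(f"unknown s0 method {method!r}")
    if d_num is None:
        raise ValueError("percentile_search requires d_num (per-gene mean differences)")
    d_num = np.asarray(d_num, dtype=float)
    candidates = np.percentile(s, np.arange(0, 101, 5))
    bins = pd.qcut(s, q=min(n_bins, max(2, s.size // 5)), duplicates="drop")
    best_s0, best_cv = candidates[0], np.inf
    for s0 in candidates:
        d = d_num / (s + s0)
        spread = pd.Series(d).groupby(bins, observed=True).apply(
            lambda v: float(np.median(np.abs(v - np.median(v))))
        )
        mu = spread.mean()
        cv = spread.std(ddof=1) / mu if mu > 0 else np.inf
        if cv < best_cv:
            best_cv, best_s0 = cv, s0
    return float(best_s0)


def _permutation_masks(n: int, n1: int, n_permutations: int, rng) -> np.ndarray:
    """Class-size-preserving label permutations as boolean masks (perm x n).

    Exhaustive enumeration when the number of distinct arrangements fits in
    ``n_permutations``; otherwise independent random shuffles.
    """
    total = math.comb(n, n1)
    if total <= n_permutations:
        masks = np.zeros((total, n), dtype=bool)
        for i, combo in enumerate(itertools.combinations(range(n), n1)):
            masks[i, list(combo)] = True
        return masks
    masks = np.zeros((n_permutations, n), dtype=bool)
    base = np.zeros(n, dtype=bool)
    base[:n1] = True
    for i in range(n_permutations):
        masks[i] = rng.permutation(base)
    return masks


def permutation_fdr(
    matrix: ExpressionMatrix,
    labels,
    s0: float,
    n_permutations: int = 1000,
    seed: int = 0,
    center: str = "mean",
) -> pd.Series:
    """Per-gene q-values from class-size-preserving label permutations.

    For each candidate threshold (the observed |d| values), the estimated
    FDR is the expected permuted exceedance count — the mean over
    permutations by default, the median with ``center='median'`` — divided
    by the observed count, capped at 1.  A gene's q is the smallest FDR at
    any threshold that calls it, which makes q monotone non-decreasing as
    |d| decreases.
    """
    if n_permutations < 100:
        labels_arr = np.asarray(pd.Series(labels).astype(str))
        n = len(labels_arr)
        t1_tmp = labels_arr == np.unique(labels_arr)[0]
        if math.comb(n, int(t1_tmp.sum())) > n_permutations:
            raise ValueError("n_permutations must be >= 100 unless exhaustive")
    if center not in ("mean", "median"):
        raise ValueError("center must be 'mean' or 'median'")
    labels = np.asarray(pd.Series(labels).astype(str))
    values = matrix.values.to_numpy(dtype=float)
    t1, n1, _ = _group_arrays(values, labels)
    d_obs, _ = _d_and_s(values, t1, s0)
    abs_obs = np.abs(d_obs)

    rng = np.random.default_rng(seed)
    masks = _permutation_masks(len(labels), n1, n_permutations, rng)

    # vectorized |d*| for every permutation via group-sum matmuls
    n = len(labels)
    P = masks.astype(float)                      # perms x n (class-1 indicator)
    n1s = P.sum(axis=1)
    n2s = n - n1s
    X, X2 = values, values ** 2
    sum1 = P @ X.T                               # perms x genes
    sum2 = (1.0 - P) @ X.T
    sq1 = P @ X2.T
    sq2 = (1.0 - P) @ X2.T
    m1 = sum1 / n1s[:, None]
    m2 = sum2 / n2s[:, None]
    ss = (sq1 - n1s[:, None] * m1 ** 2) + (sq2 - n2s[:, None] * m2 ** 2)
    ss = np.maximum(ss, 0.0)
    s_perm = np.sqrt((1.0 / n1s + 1.0 / n2s)[:, None] * ss / (n - 2))
    d_perm = np.abs((m2 - m1) / (s_perm + s0))   # perms x genes

    # exceedance counts at each observed-|d| threshold, per permutation
    order = np.argsort(-abs_obs)                 # genes sorted by |d| desc
    thresholds = abs_obs[order]
    d_perm_sorted = np.sort(d_perm, axis=1)      # ascending per permutation
    # tiny relative tolerance so a permuted |d*| equal to the observed
    # threshold (e.g. the identity arrangement) counts as an exceedance
    thr_eff = thresholds - 1e-9 * (1.0 + thresholds)
    counts = np.empty((d_perm.shape[0], len(thresholds)))
    for p in range(d_perm.shape[0]):
        counts[p] = d_perm.shape[1] - np.searchsorted(d_perm_sorted[p], thr_eff, side="left")
    expected = counts.mean(axis=0) if center == "mean" else np.median(counts, axis=0)

    # observed count >= threshold; tied |d| values are called together
    observed = np.searchsorted(-thresholds, -thresholds, side="right").astype(float)
    fdr = np.minimum(expected / observed, 1.0)
    q_sorted = np.minimum.accumulate(fdr[::-1])[::-1]
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return pd.Series(q, index=matrix.probe_ids, name="q_value")


def sam_analysis(
    matrix: ExpressionMatrix,
    labels,
    s0: float | None = None,
    s0_method: str = "median",
    n_permutations: int = 1000,
    seed: int = 0,
    fdr_threshold: float = 0.01,
    center: str = "mean",
) -> pd.DataFrame:
    """Full SAM run: statistic, s0, permutation q-values, selection flags.

    Returns the per-gene table with columns ``d_stat``, ``pooled_se``,
    ``fudge``, ``q_value``, ``direction`` (up_in_T2 for positive d, i.e.
    higher in T2) and ``selected``.
    """
    labels_arr = np.asarray(pd.Series(labels).astype(str))
    values = matrix.values.to_numpy(dtype=float)
    t1, _, _ = _group_arrays(values, labels_arr)
    num = values[:, ~t1].mean(axis=1) - values[:, t1].mean(axis=1)
    _, se = _d_and_s(values, t1, 0.0)
    stats = pd.DataFrame({"pooled_se": se}, index=matrix.probe_ids)
    if s0 is None:
        s0 = estimate_s0(stats["pooled_se"], method=s0_method, d_num=num)
    d = pd.Series(num / (se + s0), index=matrix.probe_ids)
    q = permutation_fdr(matrix, labels, s0, n_permutations=n_permutations,
                        seed=seed, center=center)
    table = pd.DataFrame({
        "d_stat": d,
        "pooled_se": stats["pooled_se"],
        "fudge": s0,
        "q_value": q,
        "direction": np.where(d >= 0, "up_in_T2", "up_in_T1"),
    })
    table["selected"] = table["q_value"] < fdr_threshold
    return table


def select_signature_genes(de_table: pd.DataFrame, fdr_threshold: float = 0.01):
    """Partition genes below the FDR threshold by direction.

    Returns ``(up_in_T1, up_in_T2)`` gene-ID sets; either may be empty.
    """
    selected = de_table[de_table["q_value"] < fdr_threshold]
    up_t2 = set(selected.index[selected["d_stat"] >= 0])
    up_t1 = set(selected.index[selected["d_stat"] < 0])
    if selected.empty:
        logger.info("no genes selected at q < %.3g", fdr_threshold)
    return up_t1, up_t2


# ---------------------------------------------------------------------------
# Hierarchical clustering of samples on the selected genes
# ---------------------------------------------------------------------------

def hierarchical_cluster(matrix: ExpressionMatrix, labels=None):
    """Cluster samples on the selected genes (1 - Pearson, average linkage).

    Genes are mean-centered first, the usual convention before sample
    clustering: otherwise between-gene location differences induce a
    shared profile that swamps the class contrast.  Returns a dict with
    the scipy ``linkage`` matrix, the two-cluster cut labels (Series per
    sample), and — when true stage labels are provided — the cluster x
    stage contingency table.
    """
    raw = matrix.values.to_numpy(dtype=float)
    if raw.shape[1] < 2 or raw.shape[0] < 2:
        raise ValueError("hierarchical_cluster needs >= 2 samples and >= 2 genes")
    sd = raw.std(axis=0)
    if (sd == 0).any():
        bad = matrix.sample_ids[np.flatnonzero(sd == 0)]
        raise ValueError(f"constant expression profile; correlation undefined for {list(bad)}")
    vals = (raw - raw.mean(axis=1, keepdims=True)).T  # samples x genes
    sd_centered = vals.std(axis=1)
    if (sd_centered == 0).any():
        bad = matrix.sample_ids[np.flatnonzero(sd_centered == 0)]
        raise ValueError(f"constant expression profile; correlation undefined for {list(bad)}")
    dist = ssd.pdist(vals, metric="correlation")
    dist = np.clip(dist, 0.0, None)
    linkage = sch.linkage(dist, method="average")
    cut = sch.fcluster(linkage, t=2, criterion="maxclust")
    clusters = pd.Series(cut, index=matrix.sample_ids, name="cluster")
    result = {"linkage": linkage, "clusters": clusters, "contingency": None}
    if labels is not None:
        labels = pd.Series(np.asarray(pd.Series(labels).astype(str)),
                           index=matrix.sample_ids, name="stage")
        result["contingency"] = pd.crosstab(clusters, labels)
    return result


def linkage_to_newick(linkage: np.ndarray, leaf_names) -> str:
    """Serialize a scipy linkage matrix as a Newick tree string."""
    tree = sch.to_tree(linkage)
    names = list(leaf_names)

    def _walk(node) -> str:
        if node.is_leaf():
            return f"{names[node.id]}:{0.0:.6g}"
        left, right = _walk(node.left), _walk(node.right)
        return f"({left},{right}):{node.dist:.6g}"

    return _walk(tree) + ";"
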