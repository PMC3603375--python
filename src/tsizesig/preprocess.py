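"""Expression preprocessing and multi-dataset merging.

Discovery (two-channel) arrays: poor spots flagged by the image analysis
are masked, the M ~ A intensity trend is removed per array by loess, and
residual missing values are imputed for genes with fewer than 5% missing
entries by least-squares regression on their most correlated complete
neighbours (an LSimpute-style gene-wise reduction); genes at or above the
missing threshold are dropped.

Validation (single-channel) datasets arrive RMA-like: each is median
centered per gene, merged on the common probe set with known duplicate
samples excluded, and collapsed from probes to gene symbols (highest
variance probe wins) for cross-platform centroid matching.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .containers import ExpressionMatrix

__all__ = [
    "stage_from_size",
    "stages_from_sizes",
    "filter_flagged",
    "loess_normalize",
    "impute_missing",
    "median_center_genes",
    "merge_datasets",
    "collapse_probes_to_genes",
]

logger = logging.getLogger(__name__)

T1_MAX_CM = 2.0
T2_MAX_CM = 5.0


def stage_from_size(size_cm: float) -> str:
    """T category from tumor diameter: <= 2 cm is T1, (2, 5] cm is T2.

    Sizes above 5 cm fall outside the two categories handled here and
    return the explicit sentinel ``"T3+"`` rather than being silently
    binned as T2.
    """
    if not np.isfinite(size_cm) or size_cm <= 0:
        raise ValueError(f"tumor size must be positive, got {size_cm!r}")
    if size_cm <= T1_MAX_CM:
        return "T1"
    if size_cm <= T2_MAX_CM:
        return "T2"
    return "T3+"


def stages_from_sizes(sizes) -> pd.Series:
    """Vectorised :func:`stage_from_size` over a Series/array of sizes."""
    sizes = pd.Series(sizes, dtype=float)
    return sizes.map(stage_from_size)


def filter_flagged(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Mask poor-quality spots and drop probes left with no data at all."""
    out = matrix.copy()
    if out.flags is None:
        logger.warning("no quality flags present; filter_flagged is a no-op")
        return out
    vals = out.values.to_numpy(dtype=float, copy=True)
    flagged = out.flags.to_numpy(dtype=bool)
    n_new = int((flagged & ~np.isnan(vals)).sum())
    vals[flagged] = np.nan
    out.values = pd.DataFrame(vals, index=out.values.index, columns=out.values.columns)
    all_missing = out.values.isna().all(axis=1)
    if all_missing.any():
        keep = out.values.index[~all_missing]
        out = out.subset_probes(keep)
    logger.info("filter_flagged: masked %d entries, dropped %d all-missing probes",
                n_new, int(all_missing.sum()))
    out.flags = None
    return out


def loess_normalize(matrix: ExpressionMatrix, span: float = 0.3) -> ExpressionMatrix:
    """Remove the per-array M ~ A intensity trend by loess.

    Each array's log-ratios are replaced by their residuals from a loess
    fit of M on the spot mean intensity A, the standard two-channel
    within-array normalization.  Requires ``intensity`` to be present.
    """
    if matrix.intensity is None:
        raise ValueError("loess_normalize requires per-spot intensity (A) values")
    if not 0 < span <= 1:
        raise ValueError(f"span must be in (0, 1], got {span}")
    out = matrix.copy()
    m = out.values.to_numpy(dtype=float, copy=True)
    a = out.intensity.to_numpy(dtype=float)
    for j in range(m.shape[1]):
        ok = ~np.isnan(m[:, j]) & ~np.isnan(a[:, j])
        if ok.sum() < 10:
            raise ValueError(
                f"array {out.sample_ids[j]!r} has {int(ok.sum())} usable spots; "
                "loess fit is underdetermined"
            )
        mj, aj = m[ok, j], a[ok, j]
        if np.ptp(mj) == 0.0:
            # constant M: the trend is the constant itself
            m[ok, j] = 0.0
            continue
        fit = lowess(mj, aj, frac=span, return_sorted=False)
        m[ok, j] = mj - fit
    out.values = pd.DataFrame(m, index=out.values.index, columns=out.values.columns)
    return out


def impute_missing(
    matrix: ExpressionMatrix,
    max_missing_frac: float = 0.05,
    k_neighbors: int = 10,
) -> ExpressionMatrix:
    """Impute genes with < ``max_missing_frac`` missing values; drop the rest.

    For each gene with missing entries, the ``k_neighbors`` complete genes
    most correlated with it (absolute Pearson, over the gene's observed
    samples) serve as predictors in an ordinary least-squares fit; missing
    entries are filled with the fitted values.  If no complete predictor
    genes exist the gene mean is used instead, with a warning.
    """
    if not 0.0 <= max_missing_frac < 1.0:
        raise ValueError("max_missing_frac must be in [0, 1)")
    out = matrix.copy()
    vals = out.values.to_numpy(dtype=float, copy=True)
    miss = np.isnan(vals)
    if not miss.any():
        return out
    frac = miss.mean(axis=1)
    keep = frac < max_missing_frac
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("impute_missing: dropped %d genes at >= %.1f%% missing",
                    n_dropped, 100 * max_missing_frac)
    out = out.subset_probes(out.probe_ids[keep])
    vals = out.values.to_numpy(dtype=float, copy=True)
    miss = np.isnan(vals)
    complete = ~miss.any(axis=1)
    comp_vals = vals[complete]
    if comp_vals.shape[0] == 0:
        logger.warning("impute_missing: no complete genes; falling back to gene means")

    for gi in np.flatnonzero(miss.any(axis=1)):
        obs = ~miss[gi]
        y = vals[gi]
        if comp_vals.shape[0] == 0 or obs.sum() < 3:
            vals[gi, ~obs] = np.nanmean(y)
            continue
        yo = y[obs]
        xo = comp_vals[:, obs]
        yc = yo - yo.mean()
        xc = xo - xo.mean(axis=1, keepdims=True)
        denom = np.sqrt((xc ** 2).sum(axis=1) * (yc ** 2).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.where(denom > 0, (xc * yc).sum(axis=1) / denom, 0.0)
        top = np.argsort(-np.abs(corr))[: min(k_neighbors, comp_vals.shape[0])]
        design = np.column_stack([np.ones(obs.sum()), xo[top].T])
        beta, *_ = np.linalg.lstsq(design, yo, rcond=None)
        pred_design = np.column_stack([np.ones((~obs).sum()), comp_vals[top][:, ~obs].T])
        vals[gi, ~obs] = pred_design @ beta
    out.values = pd.DataFrame(vals, index=out.values.index, columns=out.values.columns)
    return out


def median_center_genes(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Subtract each gene's median so every row has median exactly 0."""
    if matrix.values.isna().any().any():
        raise ValueError("median_center_genes requires a complete matrix (impute first)")
    out = matrix.copy()
    med = out.values.median(axis=1)
    out.values = out.values.sub(med, axis=0)
    return out


def merge_datasets(
    matrices: list[ExpressionMatrix],
    exclusion_list: list[str] | None = None,
) -> ExpressionMatrix:
    """Merge datasets on their common probes, dropping excluded samples.

    Each input is expected to be median-centered per gene already; the
    merged matrix keeps the probe intersection, concatenates samples, and
    records each sample's dataset of origin in ``sample_datasets``.
    Duplicate sample IDs across datasets must be covered by
    ``exclusion_list`` (the explicit known-overlap mechanism).
    """
    if not matrices:
        raise ValueError("merge_datasets requires at least one matrix")
    exclusion = set(exclusion_list or [])
    common = matrices[0].probe_ids
    for m in matrices[1:]:
        common = common.intersection(m.probe_ids)
    if len(common) == 0:
        raise ValueError("empty probe intersection across datasets")
    common = common.sort_values()

    blocks, origins, symbols = [], [], []
    seen: set[str] = set()
    for i, m in enumerate(matrices):
        ds = m.dataset_id or f"dataset{i + 1}"
        keep_samples = [s for s in m.sample_ids if s not in exclusion]
        dupes = [s for s in keep_samples if s in seen]
        if dupes:
            raise ValueError(
                f"duplicate sample IDs not covered by exclusion_list: {dupes[:5]}"
            )
        seen.update(keep_samples)
        blocks.append(m.values.loc[common, keep_samples])
        origins.append(pd.Series(ds, index=keep_samples))
        if m.gene_symbols is not None:
            symbols.append(m.gene_symbols.loc[common])
    merged = pd.concat(blocks, axis=1)
    gene_symbols = symbols[0] if symbols else None
    return ExpressionMatrix(
        values=merged,
        gene_symbols=gene_symbols,
        dataset_id="merged",
        sample_datasets=pd.concat(origins),
    )


def collapse_probes_to_genes(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """One row per gene symbol, keeping the highest-variance probe.

    Unannotated probes are dropped.  Needed to match centroids derived on
    one platform against expression measured on another.
    """
    if matrix.gene_symbols is None:
        raise ValueError("collapse_probes_to_genes requires gene-symbol annotation")
    symbols = matrix.gene_symbols.dropna()
    if symbols.empty:
        raise ValueError("no annotated probes to collapse")
    variances = matrix.values.loc[symbols.index].var(axis=1, ddof=1)
    order = pd.DataFrame({"symbol": symbols, "var": variances})
    best = order.sort_values("var", ascending=False).drop_duplicates("symbol")
    keep = best.index
    out = matrix.subset_probes(keep)
    out.values = out.values.set_axis(best["symbol"].to_numpy(), axis=0)
    out.values.index.name = "gene_symbol"
    out.values = out.values.sort_index()
    out.gene_symbols = pd.Series(out.values.index, index=out.values.index)
    out.intensity = None
    out.flags = None
    return out
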