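"""T-size expression centroids and correlation-based risk classification.

A signature is the pair of per-class mean expression profiles (T1-like and
T2-like centroids) over the selected genes.  A new sample is assigned the
label of the centroid with the higher Pearson correlation over the genes
shared between sample and signature; no correlation cutoff is applied, so
every sample receives a classification.  Exact ties go to T1-like (the
lower-risk call) and are logged.

The module also provides the generic risk-score mechanics shared by
published signatures: a linear combination of centroid correlations (the
ROR-S style score) and population-quantile risk-group assignment (a fixed
proportion of the population per risk group).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix

__all__ = [
    "SignatureModel",
    "build_centroids",
    "classify",
    "linear_combination_score",
    "assign_by_population_quantile",
]

logger = logging.getLogger(__name__)


@dataclass
class SignatureModel:
    """Ordered gene list with T1-like / T2-like centroid vectors."""

    gene_ids: list[str]
    centroid_t1like: np.ndarray
    centroid_t2like: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.centroid_t1like = np.asarray(self.centroid_t1like, dtype=float)
        self.centroid_t2like = np.asarray(self.centroid_t2like, dtype=float)
        if len(self.gene_ids) != len(set(self.gene_ids)):
            raise ValueError("duplicate genes in signature")
        for name in ("centroid_t1like", "centroid_t2like"):
            c = getattr(self, name)
            if c.shape != (len(self.gene_ids),):
                raise ValueError(f"{name} length {c.shape} != {len(self.gene_ids)} genes")
            if not np.isfinite(c).all():
                raise ValueError(f"{name} contains non-finite values")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps({
            "gene_ids": list(self.gene_ids),
            "centroid_t1like": self.centroid_t1like.tolist(),
            "centroid_t2like": self.centroid_t2like.tolist(),
            "provenance": self.provenance,
        }, indent=2) + "\n")

    @classmethod
    def from_json(cls, path) -> "SignatureModel":
        obj = json.loads(Path(path).read_text())
        return cls(
            gene_ids=obj["gene_ids"],
            centroid_t1like=np.asarray(obj["centroid_t1like"], dtype=float),
            centroid_t2like=np.asarray(obj["centroid_t2like"], dtype=float),
            provenance=obj.get("provenance", {}),
        )


def build_centroids(matrix: ExpressionMatrix, labels, genes, provenance=None) -> SignatureModel:
    """Per-class per-gene arithmetic means over the selected genes.

    ``labels`` gives the T1/T2 stage per sample (aligned with the matrix
    columns); both classes must be non-empty and every selected gene must
    be present in the matrix.
    """
    genes = list(genes)
    missing = [g for g in genes if g not in matrix.probe_ids]
    if missing:
        raise ValueError(f"genes absent from matrix: {missing[:10]}"
                         + ("..." if len(missing) > 10 else ""))
    labels = np.asarray(pd.Series(labels).astype(str))
    if set(labels) - {"T1", "T2"}:
        raise ValueError(f"labels must be T1/T2, got {sorted(set(labels))}")
    t1 = labels == "T1"
    if t1.sum() == 0 or (~t1).sum() == 0:
        raise ValueError("both classes must be non-empty")
    sub = matrix.values.loc[genes]
    return SignatureModel(
        gene_ids=genes,
        centroid_t1like=sub.loc[:, t1].mean(axis=1).to_numpy(),
        centroid_t2like=sub.loc[:, ~t1].mean(axis=1).to_numpy(),
        provenance=provenance or {},
    )


def classify(matrix: ExpressionMatrix, model: SignatureModel) -> pd.DataFrame:
    """Assign each sample to the nearest centroid by Pearson correlation.

    Correlations use the genes shared between matrix and signature (>= 3
    required; the retained fraction is logged and returned in the frame's
    ``attrs['shared_gene_fraction']``).  Every sample is labeled; exact
    correlation ties resolve to T1-like with ``tie`` flagged.
    """
    shared = [g for g in model.gene_ids if g in matrix.probe_ids]
    frac = len(shared) / model.n_genes
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} signature genes shared with matrix (need >= 3)")
    if frac < 0.5:
        logger.warning("only %.0f%% of signature genes found in matrix", 100 * frac)

    sub = matrix.values.loc[shared].to_numpy(dtype=float)
    if np.isnan(sub).any():
        raise ValueError("classification requires complete expression for shared genes")
    sd = sub.std(axis=0)
    if (sd == 0).any():
        bad = matrix.sample_ids[np.flatnonzero(sd == 0)]
        raise ValueError(f"zero variance across shared genes; correlation undefined for {list(bad)}")

    keep = [model.gene_ids.index(g) for g in shared]
    c1 = model.centroid_t1like[keep]
    c2 = model.centroid_t2like[keep]

    def _corr(centroid: np.ndarray) -> np.ndarray:
        cc = centroid - centroid.mean()
        denom_c = np.sqrt((cc ** 2).sum())
        if denom_c == 0:
            raise ValueError("constant centroid over shared genes; correlation undefined")
        xc = sub - sub.mean(axis=0)
        return (cc @ xc) / (denom_c * np.sqrt((xc ** 2).sum(axis=0)))

    r1, r2 = _corr(c1), _corr(c2)
    tie = r1 == r2
    label = np.where(r2 > r1, "T2-like", "T1-like")
    if tie.any():
        logger.info("classify: %d exact correlation ties resolved to T1-like", int(tie.sum()))
    out = pd.DataFrame({
        "sample_id": matrix.sample_ids,
        "corr_t1like": r1,
        "corr_t2like": r2,
        "label": label,
        "tie": tie,
    }).set_index("sample_id")
    out.attrs["shared_gene_fraction"] = frac
    return out


def linear_combination_score(assignments: pd.DataFrame, weights) -> pd.Series:
    """ROR-S-style continuous risk score: weighted sum of centroid correlations.

    ``weights`` pairs with the centroid correlation columns in order
    (T1-like, T2-like); generalizes to any number of ``corr_*`` columns.
    """
    corr_cols = [c for c in assignments.columns if c.startswith("corr_")]
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (len(corr_cols),):
        raise ValueError(f"{len(weights)} weights for {len(corr_cols)} centroid correlations")
    score = assignments[corr_cols].to_numpy() @ weights
    return pd.Series(score, index=assignments.index, name="score")


def assign_by_population_quantile(scores: pd.Series, proportions) -> pd.Series:
    """Fixed-proportion risk groups from ranked scores.

    ``proportions`` are ordered from highest-risk group downward and must
    sum to 1; the top fraction of scores becomes group 1, the next group 2,
    etc.  Boundary ties keep the stable input order and the tie count is
    logged.
    """
    scores = pd.Series(scores)
    if scores.empty:
        raise ValueError("no scores to assign")
    proportions = np.asarray(proportions, dtype=float)
    if abs(proportions.sum() - 1.0) > 1e-9:
        raise ValueError(f"proportions sum to {proportions.sum()}, expected 1")
    n = len(scores)
    order = np.argsort(-scores.to_numpy(), kind="stable")
    boundaries = np.round(np.cumsum(proportions) * n).astype(int)
    groups = np.empty(n, dtype=int)
    start = 0
    for g, stop in enumerate(boundaries, start=1):
        groups[order[start:stop]] = g
        start = stop
    n_ties = int(scores.duplicated(keep=False).sum())
    if n_ties:
        logger.info("assign_by_population_quantile: %d tied scores split by stable order", n_ties)
    return pd.Series(groups, index=scores.index, name="risk_group")
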