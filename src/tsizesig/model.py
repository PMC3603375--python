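"""Model/Results facade for T-size signature discovery and evaluation.

:class:`TSizeSignatureModel` is constructed from a discovery expression
matrix and its clinical table; :meth:`~TSizeSignatureModel.fit` runs the
discovery pipeline (spot filtering, loess normalization, imputation, PLS
covariate adjustment, SAM with permutation FDR, gene selection, centroid
construction, confirmatory hierarchical clustering) and returns a
:class:`TSizeSignatureResults` carrying the per-gene statistics, the
signature, and a ``summary()`` table.  Classification of new cohorts and
the survival battery hang off the results object.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import diffexp, preprocess, signature as sigmod, survival as survmod
from .containers import ExpressionMatrix

__all__ = ["TSizeSignatureModel", "TSizeSignatureResults"]


class TSizeSignatureModel:
    """Discovery-cohort model for a tumor-size expression signature.

    Parameters
    ----------
    expression
        Discovery :class:`ExpressionMatrix` (log-ratio scale; may carry
        spot flags, intensities and missing values).
    clinical
        Clinical table with ``sample_id``, ``stage`` (or ``size_cm``) and
        the adjustment covariates.
    covariates
        Clinical columns removed by PLS before the class comparison.
    fdr_threshold
        q-value cutoff for signature membership (default 1%; the
        supplementary convention of 2% is a config choice away).
    adjust
        Set False to skip the PLS step (naive two-class comparison).
    """

    def __init__(
        self,
        expression: ExpressionMatrix,
        clinical: pd.DataFrame,
        covariates=diffexp.DEFAULT_COVARIATES,
        fdr_threshold: float = 0.01,
        s0_method: str = "median",
        n_permutations: int = 1000,
        loess_span: float = 0.3,
        max_missing_frac: float = 0.05,
        k_neighbors: int = 10,
        n_components: int | None = None,
        adjust: bool = True,
    ) -> None:
        self.expression = expression
        self.clinical = clinical.copy()
        if "stage" not in self.clinical.columns:
            self.clinical["stage"] = preprocess.stages_from_sizes(self.clinical["size_cm"])
        self.covariates = tuple(covariates)
        self.fdr_threshold = fdr_threshold
        self.s0_method = s0_method
        self.n_permutations = n_permutations
        self.loess_span = loess_span
        self.max_missing_frac = max_missing_frac
        self.k_neighbors = k_neighbors
        self.n_components = n_components
        self.adjust = adjust

    @classmethod
    def from_dataframes(cls, values: pd.DataFrame, clinical: pd.DataFrame, **kwargs):
        """Build from a plain genes x samples DataFrame and a clinical table."""
        return cls(ExpressionMatrix(values=values), clinical, **kwargs)

    def fit(self, seed: int = 0) -> "TSizeSignatureResults":
        stage_counts = {"input_genes": self.expression.n_genes}
        mat = self.expression
        if mat.flags is not None:
            mat = preprocess.filter_flagged(mat)
            stage_counts["after_flag_filter"] = mat.n_genes
        if mat.intensity is not None:
            mat = preprocess.loess_normalize(mat, span=self.loess_span)
        if mat.values.isna().any().any():
            mat = preprocess.impute_missing(mat, self.max_missing_frac, self.k_neighbors)
            stage_counts["after_imputation"] = mat.n_genes

        order = pd.Index(self.clinical["sample_id"].astype(str))
        labels = pd.Series(
            self.clinical["stage"].astype(str).to_numpy(), index=order
        ).reindex(mat.sample_ids.astype(str)).to_numpy()

        adjustment = None
        analysis_mat = mat
        if self.adjust:
            analysis_mat, adjustment = diffexp.pls_adjust(
                mat, self.clinical, covariates=self.covariates,
                n_components=self.n_components,
            )
        de_table = diffexp.sam_analysis(
            analysis_mat, labels,
            s0_method=self.s0_method,
            n_permutations=self.n_permutations,
            seed=seed,
            fdr_threshold=self.fdr_threshold,
        )
        up_t1, up_t2 = diffexp.select_signature_genes(de_table, self.fdr_threshold)
        selected = sorted(up_t1 | up_t2)
        stage_counts["selected_genes"] = len(selected)

        sig = None
        clustering = None
        if selected:
            # centroids on normalized (pre-adjustment) expression so they
            # apply to cohorts lacking the discovery covariates
            sig = sigmod.build_centroids(
                mat, labels, selected,
                provenance={
                    "fdr_threshold": self.fdr_threshold,
                    "seed": seed,
                    "n_genes": len(selected),
                    "n_up_in_t1": len(up_t1),
                    "n_up_in_t2": len(up_t2),
                },
            )
            if len(selected) >= 2:
                clustering = diffexp.hierarchical_cluster(
                    mat.subset_probes(selected), labels
                )
        return TSizeSignatureResults(
            model=self,
            normalized=mat,
            adjusted=analysis_mat,
            adjustment=adjustment,
            labels=pd.Series(labels, index=mat.sample_ids),
            de_table=de_table,
            up_in_t1=up_t1,
            up_in_t2=up_t2,
            signature=sig,
            clustering=clustering,
            stage_counts=stage_counts,
            seed=seed,
        )


class TSizeSignatureResults:
    """Fitted discovery results: statistics, signature, diagnostics."""

    def __init__(self, model, normalized, adjusted, adjustment, labels, de_table,
                 up_in_t1, up_in_t2, signature, clustering, stage_counts, seed):
        self.model = model
        self.normalized = normalized
        self.adjusted = adjusted
        self.adjustment = adjustment
        self.labels = labels
        self.de_table = de_table
        self.up_in_t1 = up_in_t1
        self.up_in_t2 = up_in_t2
        self.signature = signature
        self.clustering = clustering
        self.stage_counts = stage_counts
        self.seed = seed

    @property
    def n_selected(self) -> int:
        return len(self.up_in_t1) + len(self.up_in_t2)

    def summary(self) -> str:
        """Human-readable account of the fitted discovery run."""
        n1 = int((self.labels == "T1").sum())
        n2 = int((self.labels == "T2").sum())
        s0 = float(self.de_table["fudge"].iloc[0]) if len(self.de_table) else float("nan")
        lines = [
            "T-size signature discovery",
            "==========================",
            f"samples:              {len(self.labels)} ({n1} T1, {n2} T2)",
            f"genes analyzed:       {len(self.de_table)}",
            f"covariate adjustment: "
            + (f"PLS on {', '.join(self.model.covariates)}" if self.model.adjust else "none"),
            f"SAM fudge factor s0:  {s0:.4g}",
            f"permutations:         {self.model.n_permutations} (seed {self.seed})",
            f"FDR threshold:        {self.model.fdr_threshold:g}",
            f"selected genes:       {self.n_selected} "
            f"({len(self.up_in_t1)} up in T1, {len(self.up_in_t2)} up in T2)",
        ]
        if self.clustering is not None and self.clustering["contingency"] is not None:
            ct = self.clustering["contingency"]
            lines += ["two-cluster cut vs stage:", ct.to_string()]
        return "\n".join(lines)

    # -- downstream -------------------------------------------------------
    def classify(self, matrix: ExpressionMatrix) -> pd.DataFrame:
        """Nearest-centroid T1-like/T2-like calls for a new cohort."""
        if self.signature is None:
            raise ValueError("empty signature: no genes passed the FDR threshold")
        return sigmod.classify(matrix, self.signature)

    def evaluate_survival(
        self,
        clinical: pd.DataFrame,
        assignments: pd.DataFrame,
        strata_col: str = "er_pos",
    ) -> dict:
        """Survival battery for signature calls on a validation cohort.

        Runs logrank/KM on the complete set and within each pT subgroup,
        univariate Cox summaries for the signature and clinical predictors,
        and the ER-stratified multivariate model with partial PVE.
        """
        frame = survmod.prepare_survival_frame(clinical, assignments["label"])
        frame = frame.dropna(subset=["dmfs_months", "dmfs_event"])
        labels = assignments["label"].reindex(frame["sample_id"])

        out: dict = {"n_evaluable": len(frame)}
        chi2, p = survmod.logrank_test(frame["dmfs_months"], frame["dmfs_event"], labels)
        out["logrank"] = {"complete": {"chi2": chi2, "p": p, "n": len(frame)}}
        out["km"] = {"complete": survmod.km_estimate(
            frame["dmfs_months"], frame["dmfs_event"], labels)}
        if "size_t2" in frame.columns:
            for sub_name, sel in (("pT1", frame["size_t2"] == 0), ("pT2", frame["size_t2"] == 1)):
                sub = frame[sel]
                sub_labels = labels[sel.to_numpy()]
                if sub_labels.nunique() > 1 and sub["dmfs_event"].sum() > 0:
                    chi2, p = survmod.logrank_test(sub["dmfs_months"], sub["dmfs_event"], sub_labels)
                    out["logrank"][sub_name] = {"chi2": chi2, "p": p, "n": len(sub)}

        predictors = {"T-size signature": ["tsig_t2like"]}
        for name, cols in (("Tumor size", ["size_t2"]), ("Node", ["node_pos"]),
                           ("ER", ["er_pos"]), ("Histological grade", ["grade_2", "grade_3"])):
            if all(c in frame.columns for c in cols) and all(frame[c].nunique() > 1 for c in cols):
                predictors[name] = cols
        out["univariate"] = survmod.summarize_univariate(frame, predictors)

        multi_groups = {k: v for k, v in predictors.items() if k != "ER"}
        strata = strata_col if strata_col in frame.columns else None
        try:
            out["multivariate"] = survmod.summarize_multivariate(
                frame, multi_groups, strata=strata)
        except (ValueError, RuntimeError) as err:
            out["multivariate"] = None
            out["multivariate_error"] = str(err)
        return out
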