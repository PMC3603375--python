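"""End-to-end discovery and validation runs driven by a single config.

A run config is a YAML/dict with optional blocks ``synthetic`` (generator
parameters), ``preprocess``, ``diffexp``, ``signature``, ``enrichment``
and ``survival``, plus ``seed`` and input paths when real data are
supplied.  Every stage logs its drop counts; each run writes its artifacts
plus a JSON manifest (parameters, seed, gene and sample counts at every
stage, SHA-256 of each artifact) so reruns can be compared by hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import enrichment as enrmod
from . import io as iomod
from . import preprocess, synthetic
from .diffexp import DEFAULT_COVARIATES, linkage_to_newick
from .model import TSizeSignatureModel
from .signature import SignatureModel

__all__ = ["load_config", "run_discovery", "run_validation", "run_all"]

logger = logging.getLogger(__name__)


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("run config must be a mapping")
    return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_manifest(outdir: Path, manifest: dict) -> None:
    artifacts = manifest.setdefault("artifacts", {})
    for p in sorted(outdir.iterdir()):
        if p.name != "manifest.json" and p.is_file():
            artifacts[p.name] = _sha256(p)
    iomod.write_json(manifest, outdir / "manifest.json")


def _synthetic_config(cfg: dict, seed: int) -> synthetic.SyntheticConfig:
    params = dict(cfg.get("synthetic") or {})
    params.setdefault("seed", seed)
    return synthetic.SyntheticConfig(**params)


def run_discovery(cfg: dict, outdir) -> dict:
    """Discovery pipeline: preprocess, adjust, SAM, signature, cluster, enrich.

    Returns the manifest dict; artifacts (DE table TSV, signature JSON,
    dendrogram Newick, cluster-vs-stage contingency CSV, optional
    enrichment TSVs, manifest JSON) are written to ``outdir``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    manifest: dict = {"run": "discovery", "seed": seed, "config": cfg}

    if "synthetic" in cfg:
        scfg = _synthetic_config(cfg, seed)
        matrix, clinical, truth = synthetic.generate_discovery_cohort(scfg)
        manifest["n_true_de_genes"] = len(truth.de_gene_ids)
    elif "expression" in cfg and "clinical" in cfg:
        matrix = iomod.read_expression_tsv(cfg["expression"], dataset_id="discovery")
        clinical = iomod.read_clinical_csv(cfg["clinical"])
        truth = None
    else:
        raise ValueError("config needs either a 'synthetic' block or "
                         "'expression' and 'clinical' paths")

    pp = cfg.get("preprocess") or {}
    de = cfg.get("diffexp") or {}
    model = TSizeSignatureModel(
        matrix, clinical,
        covariates=tuple(de.get("covariates", DEFAULT_COVARIATES)),
        fdr_threshold=float(de.get("fdr_threshold", 0.01)),
        s0_method=de.get("s0_method", "median"),
        n_permutations=int(de.get("n_permutations", 1000)),
        loess_span=float(pp.get("loess_span", 0.3)),
        max_missing_frac=float(pp.get("max_missing_frac", 0.05)),
        k_neighbors=int(pp.get("k_neighbors", 10)),
        adjust=bool(de.get("adjust", True)),
    )
    try:
        results = model.fit(seed=seed)
    except Exception as err:
        manifest["error"] = {"stage": "fit", "message": str(err)}
        _write_manifest(outdir, manifest)
        raise

    results.de_table.rename_axis("gene_id").to_csv(outdir / "de_result.tsv", sep="\t")
    manifest["stage_counts"] = results.stage_counts
    manifest["n_selected"] = results.n_selected
    manifest["n_up_in_t1"] = len(results.up_in_t1)
    manifest["n_up_in_t2"] = len(results.up_in_t2)
    manifest["sample_counts"] = {
        "input": int(matrix.n_samples),
        "analyzed": int(len(results.labels)),
        "dropped": int(matrix.n_samples - len(results.labels)),
    }
    if truth is not None and truth.de_gene_ids:
        recovered = (results.up_in_t1 | results.up_in_t2) & truth.de_gene_ids
        manifest["true_de_recall"] = len(recovered) / len(truth.de_gene_ids)

    if results.signature is not None:
        results.signature.to_json(outdir / "signature.json")
        if results.clustering is not None:
            (outdir / "dendrogram.newick").write_text(
                linkage_to_newick(results.clustering["linkage"],
                                  results.normalized.sample_ids) + "\n")
            results.clustering["contingency"].to_csv(outdir / "cluster_vs_stage.csv")
    else:
        logger.warning("run_discovery: empty signature at FDR < %g",
                       model.fdr_threshold)

    gmt_path = (cfg.get("enrichment") or {}).get("gmt")
    if gmt_path and results.n_selected:
        collection = iomod.read_gmt(gmt_path)
        universe = _gene_universe(results)
        for direction, genes in (("up_in_t1", results.up_in_t1),
                                 ("up_in_t2", results.up_in_t2)):
            if genes:
                symbols = _to_symbols(results, genes)
                res = enrmod.enrich(symbols, collection, universe)
                enrmod.write_enrichment_tsv(res, outdir / f"enrichment_{direction}.tsv")

    (outdir / "summary.txt").write_text(results.summary() + "\n")
    _write_manifest(outdir, manifest)
    return manifest


def _gene_universe(results) -> set[str]:
    syms = results.normalized.gene_symbols
    if syms is not None:
        return set(syms.dropna())
    return set(results.normalized.probe_ids)


def _to_symbols(results, probes) -> set[str]:
    syms = results.normalized.gene_symbols
    if syms is None:
        return set(probes)
    return set(syms.reindex(list(probes)).dropna())


def run_validation(cfg: dict, model: SignatureModel, outdir) -> dict:
    """Validation pipeline: center, merge, collapse, classify, survival.

    Returns the manifest; writes risk assignments, the univariate and
    multivariate survival summary tables, tidy KM exports, and the
    manifest to ``outdir``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    manifest: dict = {"run": "validation", "seed": seed, "config": cfg}

    if "synthetic" in cfg:
        scfg = _synthetic_config(cfg, seed)
        matrices, clinical, truth = synthetic.generate_validation_compendium(scfg)
    elif "expression_sets" in cfg and "clinical" in cfg:
        matrices = [iomod.read_expression_tsv(p, dataset_id=f"DS{i+1}")
                    for i, p in enumerate(cfg["expression_sets"])]
        clinical = iomod.read_clinical_csv(cfg["clinical"])
        truth = None
    else:
        raise ValueError("config needs a 'synthetic' block or 'expression_sets' + 'clinical'")
    if "dmfs_months" not in clinical.columns or "dmfs_event" not in clinical.columns:
        raise ValueError("validation clinical table needs dmfs_months and dmfs_event")

    exclusion = list(cfg.get("exclusion_list") or [])
    if isinstance(exclusion, str):
        exclusion = iomod.read_exclusion_list(exclusion)

    centered = [preprocess.median_center_genes(m) for m in matrices]
    merged = preprocess.merge_datasets(centered, exclusion)
    manifest["n_common_probes"] = int(merged.n_genes)
    manifest["sample_counts"] = {
        "input": int(sum(m.n_samples for m in matrices)),
        "merged": int(merged.n_samples),
        "excluded": int(sum(m.n_samples for m in matrices) - merged.n_samples),
    }
    if merged.gene_symbols is not None:
        merged = preprocess.collapse_probes_to_genes(merged)
        manifest["n_genes_after_collapse"] = int(merged.n_genes)

    from .signature import classify
    assignments = classify(merged, model)
    manifest["shared_gene_fraction"] = assignments.attrs["shared_gene_fraction"]
    if manifest["shared_gene_fraction"] < 0.5:
        manifest["warning"] = "shared-gene fraction below 50%"
    counts = assignments["label"].value_counts().to_dict()
    manifest["classification_counts"] = {k: int(v) for k, v in counts.items()}
    assert sum(counts.values()) == merged.n_samples
    assignments.to_csv(outdir / "risk_assignments.csv")

    if truth is not None:
        latent = truth.per_sample_latent_class.reindex(assignments.index)
        agree = (assignments["label"].str[:2] == latent).mean()
        manifest["latent_class_agreement"] = float(agree)

    from .model import TSizeSignatureResults  # facade reuse for the battery
    clinical = clinical[clinical["sample_id"].astype(str).isin(assignments.index)]
    facade = TSizeSignatureResults(
        model=None, normalized=merged, adjusted=None, adjustment=None,
        labels=None, de_table=pd.DataFrame(), up_in_t1=set(), up_in_t2=set(),
        signature=model, clustering=None, stage_counts={}, seed=seed,
    )
    surv = facade.evaluate_survival(clinical, assignments)
    manifest["logrank"] = {
        k: {kk: (float(vv) if isinstance(vv, (int, float, np.floating)) else vv)
            for kk, vv in v.items()}
        for k, v in surv["logrank"].items()
    }
    surv["univariate"].to_csv(outdir / "survival_univariate.csv", index=False)
    if surv.get("multivariate") is not None:
        surv["multivariate"].to_csv(outdir / "survival_multivariate.csv", index=False)
    surv["km"]["complete"].to_csv(outdir / "km_complete.tsv", sep="\t", index=False)
    _write_manifest(outdir, manifest)
    return manifest


def run_all(cfg: dict, outdir) -> dict:
    """Discovery followed by validation with the discovered signature."""
    outdir = Path(outdir)
    disc = run_discovery(cfg, outdir / "discovery")
    sig_path = outdir / "discovery" / "signature.json"
    if not sig_path.exists():
        logger.warning("run_all: discovery produced no signature; validation skipped")
        return {"discovery": disc, "validation": None}
    model = SignatureModel.from_json(sig_path)
    val_cfg = dict(cfg)
    if "validation" in cfg:
        val_cfg.update(cfg["validation"])
    val = run_validation(val_cfg, model, outdir / "validation")
    return {"discovery": disc, "validation": val}
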