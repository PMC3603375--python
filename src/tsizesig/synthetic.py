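"""Synthetic discovery cohorts and validation compendia with known truth.

The generators emulate the structure of a two-channel 44k-style discovery
cohort (log-ratio expression, clinical covariates confounded with tumor
size class) and a merged multi-dataset single-channel validation compendium
(log-intensity expression with per-dataset batch offsets, DMFS follow-up
drawn from a Weibull proportional-hazards model keyed to the latent
T1-like/T2-like class).  Every quantity that downstream stages are supposed
to recover — the differentially expressed gene set, per-gene effects, the
latent class of every sample, the true hazard ratio — is returned as
:class:`GroundTruth`.

The gene architecture (which genes carry a class effect, with which sign)
is derived deterministically from the seed alone, so a discovery cohort and
a validation compendium generated from the same config share their true
signature genes and a signature learned on one transfers to the other.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "generate_discovery_cohort",
    "generate_validation_compendium",
    "inject_missing",
]


class ConfigurationError(ValueError):
    """Raised when a synthetic configuration violates its invariants."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic study.

    Defaults mirror the emulated study design: a 46-sample discovery cohort
    split 27/19 between T1 (<= 2 cm) and T2 (> 2 cm), and six validation
    datasets totalling ~948 samples with roughly half the patients
    experiencing a distant metastasis during follow-up.  Magnitudes the
    design leaves open (effect size, residual noise, confounding strength)
    are documented package choices, all in log2 units.
    """

    n_genes: int = 2000
    n_samples_discovery: int = 46
    class_proportions: tuple[float, float] = (27 / 46, 19 / 46)
    frac_de_genes: float = 0.05
    effect_size: float = 1.0
    noise_sd: float = 1.0
    confounding_strength: float = 4.0
    frac_confounded_genes: float = 0.05
    n_datasets_validation: int = 6
    n_samples_per_dataset: int = 158
    true_hazard_ratio: float = 2.0
    censoring_rate: float = 0.5
    missing_rate: float = 0.0
    seed: int = 0
    # secondary knobs
    weibull_shape: float = 1.0          # 1 = exponential baseline
    baseline_hazard: float = 0.008      # events / month for T1-like
    batch_sd: float = 0.5               # per-dataset per-gene offset SD (log2)
    probe_dropout: float = 0.05         # probes absent from a given dataset
    flag_rate: float = 0.0              # poor-spot rate on discovery arrays
    dye_bias: float = 0.0               # slope of the M~A intensity trend

    def validate(self) -> None:
        fracs = {
            "frac_de_genes": self.frac_de_genes,
            "frac_confounded_genes": self.frac_confounded_genes,
            "censoring_rate": self.censoring_rate,
            "missing_rate": self.missing_rate,
            "probe_dropout": self.probe_dropout,
            "flag_rate": self.flag_rate,
        }
        for name, value in fracs.items():
            if not 0.0 <= value <= 1.0:
                raise ConfigurationError(f"{name}={value} outside [0, 1]")
        counts = {
            "n_genes": self.n_genes,
            "n_samples_discovery": self.n_samples_discovery,
            "n_datasets_validation": self.n_datasets_validation,
            "n_samples_per_dataset": self.n_samples_per_dataset,
        }
        for name, value in counts.items():
            if value <= 0:
                raise ConfigurationError(f"{name}={value} must be positive")
        if self.true_hazard_ratio <= 0:
            raise ConfigurationError("true_hazard_ratio must be > 0")
        p1, p2 = self.class_proportions
        if not (0 <= p1 <= 1 and 0 <= p2 <= 1 and abs(p1 + p2 - 1) < 1e-9):
            raise ConfigurationError("class_proportions must be a pair summing to 1")
        if self.noise_sd < 0 or self.weibull_shape <= 0 or self.baseline_hazard <= 0:
            raise ConfigurationError("noise_sd >= 0 and positive Weibull shape/hazard required")

    def with_seed(self, seed: int) -> "SyntheticConfig":
        return replace(self, seed=seed)


@dataclass
class GroundTruth:
    """What the generators know and the pipeline is asked to recover."""

    de_gene_ids: set[str]
    per_gene_effect: dict[str, float]
    per_sample_latent_class: pd.Series  # 'T1' / 'T2' per sample_id
    true_hazard_ratio: float
    confounded_gene_ids: set[str] = field(default_factory=set)


# class-conditional covariate prevalences: node/grade correlate strongly
# with size class so that covariate-linked genes confound a naive analysis
_COVARIATE_MODEL = {
    "node_pos": {"T1": 0.25, "T2": 0.75},
    "grade_probs": {"T1": (0.25, 0.55, 0.2), "T2": (0.15, 0.45, 0.4)},
    "er_pos": {"T1": 0.8, "T2": 0.65},
    "pgr_pos": {"T1": 0.7, "T2": 0.6},
    "subtype_probs": {
        "T1": (0.5, 0.25, 0.12, 0.13),
        "T2": (0.35, 0.3, 0.18, 0.17),
    },
}
_SUBTYPES = ("LumA", "LumB", "Basal", "Her2")


def _gene_ids(n_genes: int) -> pd.Index:
    return pd.Index([f"G{i:05d}" for i in range(1, n_genes + 1)], name="probe_id")


def _gene_architecture(config: SyntheticConfig):
    """Seed-determined truth shared by discovery and validation generators."""
    rng = np.random.default_rng([config.seed, 0])
    genes = _gene_ids(config.n_genes)
    n_de = int(round(config.frac_de_genes * config.n_genes))
    n_conf = int(round(config.frac_confounded_genes * config.n_genes))
    chosen = rng.choice(config.n_genes, size=min(n_de + n_conf, config.n_genes), replace=False)
    de_idx = chosen[:n_de]
    conf_idx = chosen[n_de:]
    signs = rng.choice([-1.0, 1.0], size=n_de)
    effects = np.zeros(config.n_genes)
    effects[de_idx] = signs * config.effect_size
    conf_signs = rng.choice([-1.0, 1.0], size=len(conf_idx))
    conf_effects = np.zeros(config.n_genes)
    conf_effects[conf_idx] = conf_signs * config.confounding_strength
    return genes, effects, conf_effects, set(genes[de_idx]), set(genes[conf_idx])


def _draw_covariates(rng: np.random.Generator, classes: np.ndarray) -> pd.DataFrame:
    n = len(classes)
    node = np.empty(n, dtype=int)
    grade = np.empty(n, dtype=int)
    er = np.empty(n, dtype=object)
    pgr = np.empty(n, dtype=object)
    subtype = np.empty(n, dtype=object)
    for i, cls in enumerate(classes):
        node[i] = int(rng.random() < _COVARIATE_MODEL["node_pos"][cls])
        if node[i] and rng.random() < 0.25:
            node[i] = 2
        grade[i] = rng.choice([1, 2, 3], p=_COVARIATE_MODEL["grade_probs"][cls])
        er[i] = "Positive" if rng.random() < _COVARIATE_MODEL["er_pos"][cls] else "Negative"
        pgr[i] = "Positive" if rng.random() < _COVARIATE_MODEL["pgr_pos"][cls] else "Negative"
        subtype[i] = _SUBTYPES[rng.choice(4, p=_COVARIATE_MODEL["subtype_probs"][cls])]
    return pd.DataFrame({"node": node, "grade": grade, "er": er, "pgr": pgr, "subtype": subtype})


def generate_discovery_cohort(config: SyntheticConfig):
    """Generate a two-channel-style discovery cohort.

    Returns ``(ExpressionMatrix, clinical DataFrame, GroundTruth)``.  Tumor
    sizes are drawn so the 2 cm rule reproduces the class labels exactly;
    differentially expressed genes are shifted by ``effect_size`` in T2
    relative to T1; confounded genes track node status (not class) with
    amplitude ``confounding_strength``.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 1])
    genes, effects, conf_effects, de_set, conf_set = _gene_architecture(config)

    n = config.n_samples_discovery
    n1 = int(round(config.class_proportions[0] * n))
    n1 = min(max(n1, 0), n)
    classes = np.array(["T1"] * n1 + ["T2"] * (n - n1))
    rng.shuffle(classes)
    sample_ids = pd.Index([f"S{i:03d}" for i in range(1, n + 1)], name="sample_id")

    sizes = np.where(
        classes == "T1",
        rng.uniform(0.5, 2.0, size=n),
        rng.uniform(2.05, 5.0, size=n),
    ).round(2)
    sizes = np.clip(sizes, 0.5, 5.0)
    sizes[(classes == "T1") & (sizes > 2.0)] = 2.0
    sizes[(classes == "T2") & (sizes <= 2.0)] = 2.1

    covars = _draw_covariates(rng, classes)

    is_t2 = (classes == "T2").astype(float)
    node_pos = (covars["node"].to_numpy() > 0).astype(float)
    values = rng.normal(0.0, config.noise_sd, size=(config.n_genes, n))
    values += np.outer(effects, is_t2)
    values += np.outer(conf_effects, node_pos - node_pos.mean())

    intensity = rng.uniform(6.0, 14.0, size=values.shape)
    if config.dye_bias:
        values += config.dye_bias * (intensity - intensity.mean())
    flags = rng.random(values.shape) < config.flag_rate

    matrix = ExpressionMatrix(
        values=pd.DataFrame(values, index=genes, columns=sample_ids),
        gene_symbols=pd.Series(genes, index=genes, name="gene_symbol"),
        intensity=pd.DataFrame(intensity, index=genes, columns=sample_ids),
        flags=pd.DataFrame(flags, index=genes, columns=sample_ids),
        dataset_id="discovery",
    )
    if config.missing_rate > 0:
        matrix = inject_missing(matrix, config.missing_rate, seed=config.seed + 97)

    clinical = pd.DataFrame({
        "sample_id": sample_ids,
        "stage": classes,
        "size_cm": sizes,
        **{c: covars[c].to_numpy() for c in covars.columns},
    })
    truth = GroundTruth(
        de_gene_ids=de_set,
        per_gene_effect={g: e for g, e in zip(genes, effects) if e != 0.0},
        per_sample_latent_class=pd.Series(classes, index=sample_ids, name="latent_class"),
        true_hazard_ratio=config.true_hazard_ratio,
        confounded_gene_ids=conf_set,
    )
    return matrix, clinical, truth


def _draw_survival(rng, latent_t2: np.ndarray, config: SyntheticConfig):
    """Weibull proportional-hazards DMFS times with independent censoring.

    S(t) = exp(-lambda * t^k) with lambda = baseline * HR^{1[T2-like]}.
    The censoring hazard is set so the marginal censored fraction is about
    ``censoring_rate`` when the baseline is exponential.
    """
    lam = config.baseline_hazard * np.where(latent_t2, config.true_hazard_ratio, 1.0)
    k = config.weibull_shape
    event_t = (rng.exponential(1.0, size=lam.size) / lam) ** (1.0 / k)
    if config.censoring_rate <= 0:
        return event_t, np.ones(lam.size, dtype=int)
    if config.censoring_rate >= 1:
        raise ConfigurationError("censoring_rate must be < 1 to observe events")
    mu = lam.mean() * config.censoring_rate / (1.0 - config.censoring_rate)
    censor_t = rng.exponential(1.0 / mu, size=lam.size)
    time = np.minimum(event_t, censor_t)
    event = (event_t <= censor_t).astype(int)
    return time, event


def generate_validation_compendium(config: SyntheticConfig, probe_subsets=None):
    """Generate a multi-dataset single-channel validation compendium.

    Returns ``(list of ExpressionMatrix, clinical DataFrame, GroundTruth)``.
    Each dataset carries its own additive per-gene batch offset (to be
    removed by per-gene median centering) and its own probe subset (to
    exercise common-probe merging); DMFS follow-up comes from a Weibull
    proportional-hazards model with hazard multiplied by
    ``true_hazard_ratio`` for latent T2-like samples.

    Parameters
    ----------
    probe_subsets
        Optional explicit list (one entry per dataset) of probe IDs to keep;
        overrides the random ``probe_dropout`` mechanism.
    """
    config.validate()
    if probe_subsets is not None and len(probe_subsets) != config.n_datasets_validation:
        raise ConfigurationError("probe_subsets must have one entry per dataset")
    rng = np.random.default_rng([config.seed, 2])
    genes, effects, _conf, de_set, conf_set = _gene_architecture(config)
    base_level = rng.uniform(5.0, 12.0, size=config.n_genes)

    matrices: list[ExpressionMatrix] = []
    clin_frames: list[pd.DataFrame] = []
    latent_all: list[pd.Series] = []
    for d in range(config.n_datasets_validation):
        ds = f"DS{d + 1}"
        m = config.n_samples_per_dataset
        sample_ids = pd.Index([f"{ds}_S{i:03d}" for i in range(1, m + 1)], name="sample_id")
        latent = np.where(rng.random(m) < 0.5, "T1", "T2")
        is_t2 = (latent == "T2").astype(float)

        batch = rng.normal(0.0, config.batch_sd, size=config.n_genes)
        values = (
            base_level[:, None]
            + batch[:, None]
            + np.outer(effects, is_t2)
            + rng.normal(0.0, config.noise_sd, size=(config.n_genes, m))
        )
        df = pd.DataFrame(values, index=genes, columns=sample_ids)
        if probe_subsets is not None:
            keep = pd.Index(probe_subsets[d])
        else:
            keep = genes[rng.random(config.n_genes) >= config.probe_dropout]
        mat = ExpressionMatrix(
            values=df.loc[keep],
            gene_symbols=pd.Series(keep, index=keep, name="gene_symbol"),
            dataset_id=ds,
        )
        matrices.append(mat)

        # observed pT stage agrees with latent class only imperfectly
        observed_t2 = np.where(
            latent == "T2", rng.random(m) < 0.75, rng.random(m) < 0.25
        )
        sizes = np.where(
            observed_t2, rng.uniform(2.05, 5.0, size=m), rng.uniform(0.5, 2.0, size=m)
        ).round(2)
        sizes[observed_t2 & (sizes <= 2.0)] = 2.1
        sizes[~observed_t2 & (sizes > 2.0)] = 2.0
        covars = _draw_covariates(rng, latent)
        time, event = _draw_survival(rng, latent == "T2", config)
        clin_frames.append(pd.DataFrame({
            "sample_id": sample_ids,
            "dataset_id": ds,
            "stage": np.where(observed_t2, "T2", "T1"),
            "size_cm": sizes,
            **{c: covars[c].to_numpy() for c in covars.columns},
            "dmfs_months": time,
            "dmfs_event": event,
        }))
        latent_all.append(pd.Series(latent, index=sample_ids))

    clinical = pd.concat(clin_frames, ignore_index=True)
    truth = GroundTruth(
        de_gene_ids=de_set,
        per_gene_effect={g: e for g, e in zip(genes, effects) if e != 0.0},
        per_sample_latent_class=pd.concat(latent_all).rename("latent_class"),
        true_hazard_ratio=config.true_hazard_ratio,
        confounded_gene_ids=conf_set,
    )
    return matrices, clinical, truth


def inject_missing(matrix: ExpressionMatrix, missing_rate: float, seed: int) -> ExpressionMatrix:
    """Mask a uniform random fraction of entries as missing (NaN).

    The input matrix is not modified; callers keep it as the ground truth
    for imputation-recovery checks.
    """
    if not 0.0 <= missing_rate < 1.0:
        raise ConfigurationError(f"missing_rate={missing_rate} must be in [0, 1)")
    out = matrix.copy()
    if missing_rate == 0.0:
        return out
    rng = np.random.default_rng(seed)
    mask = rng.random(out.values.shape) < missing_rate
    vals = out.values.to_numpy(dtype=float, copy=True)
    vals[mask] = np.nan
    out.values = pd.DataFrame(vals, index=out.values.index, columns=out.values.columns)
    return out
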