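"""Survival evaluation of risk groups and clinical covariates for DMFS.

Implements the full battery used to judge a risk grouping: Kaplan–Meier
curves per group, the logrank test, Cox proportional-hazards fits
(univariate, multivariate, and ER-stratified, with Efron tie handling),
the likelihood-ratio test of the overall effect, the deviance of the fit
(read here as the overall-model LRT statistic 2*(l(beta) - l(0))), the
likelihood-based proportion of variation explained

    PVE = 1 - exp(-LRT / n)

(with the partial PVE of covariate j from the LRT comparing the full
model to the model without j), and Harrell's concordance index.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from lifelines.utils import concordance_index as _lifelines_cindex

from .containers import numeric_grade

__all__ = [
    "km_estimate",
    "logrank_test",
    "CoxFit",
    "cox_fit",
    "likelihood_ratio_test",
    "deviance",
    "pve",
    "partial_pve",
    "c_index",
    "prepare_survival_frame",
    "summarize_univariate",
    "summarize_multivariate",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Nonparametric pieces
# ---------------------------------------------------------------------------

def km_estimate(time, event, groups) -> pd.DataFrame:
    """Kaplan–Meier product-limit curves per group, as a tidy frame.

    Returns columns ``group``, ``time``, ``survival``, ``at_risk``; each
    curve implicitly starts at S(0) = 1.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    groups = np.asarray(pd.Series(groups).astype(str))
    if event.sum() < 1:
        logger.warning("km_estimate: no events; curves are identically 1")
    frames = []
    for g in pd.unique(groups):
        sel = groups == g
        if sel.sum() == 0:
            raise ValueError(f"empty group {g!r}")
        kmf = KaplanMeierFitter()
        kmf.fit(time[sel], event[sel])
        sf = kmf.survival_function_.iloc[:, 0]
        at_risk = kmf.event_table["at_risk"].reindex(sf.index)
        frames.append(pd.DataFrame({
            "group": g,
            "time": sf.index.to_numpy(dtype=float),
            "survival": sf.to_numpy(dtype=float),
            "at_risk": at_risk.to_numpy(),
        }))
    return pd.concat(frames, ignore_index=True)


def plot_km(km: pd.DataFrame, ax=None):
    """Step-plot a tidy Kaplan–Meier export (group/time/survival columns)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for g, sub in km.groupby("group"):
        t = np.concatenate([[0.0], sub["time"].to_numpy()])
        s = np.concatenate([[1.0], sub["survival"].to_numpy()])
        ax.step(t, s, where="post", label=str(g))
    ax.set_xlabel("time (months)")
    ax.set_ylabel("DMFS probability")
    ax.set_ylim(0, 1.02)
    ax.legend()
    return ax


def logrank_test(time, event, groups) -> tuple[float, float]:
    """Standard O-E logrank across >= 2 groups; returns (chi2, p)."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    groups = np.asarray(pd.Series(groups).astype(str))
    if len(pd.unique(groups)) < 2:
        raise ValueError("logrank_test needs at least two groups")
    if event.sum() < 1:
        raise ValueError("logrank_test needs at least one event")
    res = multivariate_logrank_test(time, groups, event)
    return float(res.test_statistic), float(res.p_value)


# ---------------------------------------------------------------------------
# Cox proportional hazards
# ---------------------------------------------------------------------------

@dataclass
class CoxFit:
    """A fitted (optionally stratified) Cox model and its log-likelihoods."""

    fitter: CoxPHFitter
    covariate_cols: list[str]
    duration_col: str
    event_col: str
    strata: str | list[str] | None
    n: int
    n_events: int
    ll_fit: float
    ll_null: float

    @property
    def params(self) -> pd.Series:
        return self.fitter.params_

    @property
    def summary(self) -> pd.DataFrame:
        """Per-coefficient HR, 95% CI and Wald p."""
        s = self.fitter.summary
        return pd.DataFrame({
            "hr": s["exp(coef)"],
            "ci_low": s["exp(coef) lower 95%"],
            "ci_high": s["exp(coef) upper 95%"],
            "p_wald": s["p"],
        })


def cox_fit(
    data: pd.DataFrame,
    covariates: list[str],
    duration_col: str = "dmfs_months",
    event_col: str = "dmfs_event",
    strata=None,
) -> CoxFit:
    """Maximize the (stratified) Cox partial likelihood with Efron ties.

    Wald 95% CIs come with the fit; the null partial log-likelihood is
    recovered from the overall likelihood-ratio test.  Raises on constant
    covariates, more covariates than events, or non-convergence (e.g.
    monotone likelihood under perfect separation).
    """
    cols = [duration_col, event_col, *covariates]
    if strata is not None:
        strata_cols = [strata] if isinstance(strata, str) else list(strata)
        cols += strata_cols
    df = data[cols].dropna().copy()
    n_events = int(df[event_col].sum())
    if n_events < len(covariates):
        raise ValueError(f"{n_events} events for {len(covariates)} covariates")
    for c in covariates:
        if df[c].nunique() <= 1:
            raise ValueError(f"covariate {c!r} is constant")
    cph = CoxPHFitter()
    import warnings as _warnings

    try:
        with _warnings.catch_warnings(record=True) as caught:
            _warnings.simplefilter("always")
            cph.fit(df, duration_col=duration_col, event_col=event_col, strata=strata,
                    fit_options={"precision": 1e-12})
        for w in caught:
            msg = str(w.message)
            if "complete separation" in msg or "norm(delta)" in msg:
                raise RuntimeError(
                    f"monotone likelihood / non-convergence for covariates {covariates}: {msg}"
                )
    except RuntimeError:
        raise
    except Exception as err:  # lifelines ConvergenceError and friends
        raise RuntimeError(f"Cox fit failed for covariates {covariates}: {err}") from err
    lrt = cph.log_likelihood_ratio_test()
    ll_fit = float(cph.log_likelihood_)
    ll_null = ll_fit - float(lrt.test_statistic) / 2.0
    return CoxFit(
        fitter=cph,
        covariate_cols=list(covariates),
        duration_col=duration_col,
        event_col=event_col,
        strata=strata,
        n=len(df),
        n_events=n_events,
        ll_fit=ll_fit,
        ll_null=ll_null,
    )


def likelihood_ratio_test(fit: CoxFit) -> tuple[float, int, float]:
    """Overall-effect LRT: 2*(l(beta) - l(0)), chi-square df = #coefficients."""
    from scipy.stats import chi2

    stat = 2.0 * (fit.ll_fit - fit.ll_null)
    df = len(fit.params)
    p = float(chi2.sf(stat, df)) if stat > 0 else 1.0
    return float(stat), df, p


def deviance(fit: CoxFit) -> float:
    """Goodness of fit as the overall-model LRT statistic (>= 0)."""
    return 2.0 * (fit.ll_fit - fit.ll_null)


def pve(fit: CoxFit, n: int | None = None) -> float:
    """Likelihood-based proportion of variation explained, 1 - exp(-LRT/n)."""
    n = fit.n if n is None else n
    if n <= 0:
        raise ValueError("n must be positive")
    stat, _, _ = likelihood_ratio_test(fit)
    return float(1.0 - np.exp(-stat / n))


def partial_pve(
    data: pd.DataFrame,
    covariate_groups: dict[str, list[str]],
    duration_col: str = "dmfs_months",
    event_col: str = "dmfs_event",
    strata=None,
) -> tuple[CoxFit, pd.Series]:
    """Partial PVE of each covariate group in the multivariate model.

    For group j, PVE_j = 1 - exp(-LRT_j / n) where LRT_j compares the full
    model to the model refit without group j's columns (dummy columns of
    one clinical variable are dropped together).  Returns the full-model
    fit and the per-group partial PVEs.
    """
    all_cols = [c for cols in covariate_groups.values() for c in cols]
    full = cox_fit(data, all_cols, duration_col, event_col, strata)
    out = {}
    for name, cols in covariate_groups.items():
        reduced_cols = [c for c in all_cols if c not in cols]
        if reduced_cols:
            reduced = cox_fit(data, reduced_cols, duration_col, event_col, strata)
            lrt_j = 2.0 * (full.ll_fit - reduced.ll_fit)
        else:
            lrt_j = 2.0 * (full.ll_fit - full.ll_null)
        out[name] = float(1.0 - np.exp(-max(lrt_j, 0.0) / full.n))
    return full, pd.Series(out, name="partial_pve")


def c_index(scores, time, event) -> float:
    """Harrell's C over censoring-comparable pairs; score ties count 0.5.

    ``scores`` are risk scores (higher = worse expected outcome).
    """
    try:
        return float(_lifelines_cindex(np.asarray(time, dtype=float),
                                       -np.asarray(scores, dtype=float),
                                       np.asarray(event, dtype=int)))
    except ZeroDivisionError as err:
        raise ValueError("no usable (comparable) pairs for the C-index") from err


# ---------------------------------------------------------------------------
# Table-style summaries
# ---------------------------------------------------------------------------

def prepare_survival_frame(clinical: pd.DataFrame, risk_labels: pd.Series | None = None) -> pd.DataFrame:
    """Encode a clinical table (plus optional signature calls) for Cox fits.

    Produces dummy contrasts against the reference level: ``tsig_t2like``
    (T2-like vs T1-like), ``size_t2`` (pT2 vs pT1), ``node_pos``,
    ``er_pos``, ``grade_2``/``grade_3`` (vs grade 1).  Rows without DMFS
    follow-up are retained (Cox fits drop them per-model).
    """
    df = pd.DataFrame({"sample_id": clinical["sample_id"].astype(str)})
    for col in ("dmfs_months", "dmfs_event"):
        if col in clinical.columns:
            df[col] = pd.to_numeric(clinical[col], errors="coerce").to_numpy()
    if "stage" in clinical.columns:
        df["size_t2"] = (clinical["stage"].astype(str) == "T2").astype(float).to_numpy()
    if "node" in clinical.columns:
        df["node_pos"] = (pd.to_numeric(clinical["node"], errors="coerce") > 0).astype(float).to_numpy()
    if "er" in clinical.columns:
        df["er_pos"] = clinical["er"].astype(str).str.lower().str.startswith("pos").astype(float).to_numpy()
    if "grade" in clinical.columns:
        g = numeric_grade(clinical["grade"])
        df["grade_2"] = (g == 2).astype(float).to_numpy()
        df["grade_3"] = (g == 3).astype(float).to_numpy()
    df = df.set_index("sample_id")
    if risk_labels is not None:
        df["tsig_t2like"] = (risk_labels.reindex(df.index).astype(str) == "T2-like").astype(float)
    return df.reset_index()


def summarize_univariate(
    data: pd.DataFrame,
    predictors: dict[str, list[str]],
    duration_col: str = "dmfs_months",
    event_col: str = "dmfs_event",
) -> pd.DataFrame:
    """Univariate comparison of predictors, one Cox model per predictor.

    ``predictors`` maps a display name to the dummy columns encoding it.
    Output rows mirror the HR [95% CI] / P / PVE / Deviance / C layout:
    one overall row per predictor (LRT p, PVE, deviance, C-index) plus one
    row per contrast (HR, CI, Wald p).
    """
    rows = []
    for name, cols in predictors.items():
        fit = cox_fit(data, cols, duration_col, event_col)
        stat, dfree, p_overall = likelihood_ratio_test(fit)
        rows.append({
            "predictor": name, "contrast": "(overall)",
            "hr": np.nan, "ci_low": np.nan, "ci_high": np.nan,
            "p": p_overall, "pve": pve(fit), "deviance": deviance(fit),
            "c_index": float(fit.fitter.concordance_index_),
            "n": fit.n, "events": fit.n_events,
        })
        summ = fit.summary
        for c in cols:
            rows.append({
                "predictor": name, "contrast": c,
                "hr": summ.loc[c, "hr"], "ci_low": summ.loc[c, "ci_low"],
                "ci_high": summ.loc[c, "ci_high"], "p": summ.loc[c, "p_wald"],
                "pve": np.nan, "deviance": np.nan, "c_index": np.nan,
                "n": fit.n, "events": fit.n_events,
            })
    return pd.DataFrame(rows)


def summarize_multivariate(
    data: pd.DataFrame,
    covariate_groups: dict[str, list[str]],
    duration_col: str = "dmfs_months",
    event_col: str = "dmfs_event",
    strata=None,
) -> pd.DataFrame:
    """ER-stratified (or unstratified) multivariate model with partial PVE."""
    full, ppve = partial_pve(data, covariate_groups, duration_col, event_col, strata)
    summ = full.summary
    rows = []
    for name, cols in covariate_groups.items():
        for c in cols:
            rows.append({
                "predictor": name, "contrast": c,
                "hr": summ.loc[c, "hr"], "ci_low": summ.loc[c, "ci_low"],
                "ci_high": summ.loc[c, "ci_high"], "p": summ.loc[c, "p_wald"],
                "partial_pve": ppve[name], "n": full.n, "events": full.n_events,
            })
    return pd.DataFrame(rows)
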