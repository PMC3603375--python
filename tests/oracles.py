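"""Independent oracles used by the unit and acceptance tests.

Each function recomputes a quantity by brute force (enumeration, closed
form, or explicit likelihood evaluation) without touching the package's
own implementation path.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.optimize import minimize_scalar


def pooled_t(x1: np.ndarray, x2: np.ndarray) -> float:
    """Classic pooled two-sample t statistic (x2 minus x1)."""
    n1, n2 = len(x1), len(x2)
    sp2 = (((x1 - x1.mean()) ** 2).sum() + ((x2 - x2.mean()) ** 2).sum()) / (n1 + n2 - 2)
    return (x2.mean() - x1.mean()) / math.sqrt(sp2 * (1 / n1 + 1 / n2))


def cox_beta_1d(time, event, x) -> float:
    """Brute-force maximizer of the 1-covariate Cox partial likelihood.

    No ties allowed.  Scans the explicit log partial likelihood
    sum_{events} [beta*x_i - log sum_{j in risk set} exp(beta*x_j)].
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    x = np.asarray(x, dtype=float)
    assert len(np.unique(time)) == len(time), "oracle requires no ties"

    def neg_ll(beta: float) -> float:
        ll = 0.0
        for i in np.flatnonzero(event):
            risk = time >= time[i]
            ll += beta * x[i] - math.log(np.exp(beta * x[risk]).sum())
        return -ll

    res = minimize_scalar(neg_ll, bounds=(-10, 10), method="bounded",
                          options={"xatol": 1e-10})
    return float(res.x)


def cox_loglik_1d(time, event, x, beta: float) -> float:
    """Explicit 1-covariate Cox log partial likelihood at beta."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    x = np.asarray(x, dtype=float)
    ll = 0.0
    for i in np.flatnonzero(event):
        risk = time >= time[i]
        ll += beta * x[i] - math.log(np.exp(beta * x[risk]).sum())
    return ll


def harrell_c(scores, time, event) -> float:
    """Exhaustive pair enumeration of Harrell's C (score ties count 0.5).

    A pair is usable when the shorter observed time belongs to an event
    (ties in time with one event are usable in the standard extension;
    here only strictly ordered times are enumerated, matching fixtures
    without time ties).
    """
    scores = np.asarray(scores, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    num = den = 0.0
    for i, j in itertools.combinations(range(len(time)), 2):
        if time[i] == time[j]:
            continue
        first, second = (i, j) if time[i] < time[j] else (j, i)
        if not event[first]:
            continue  # censored before the other: ordering unknown
        den += 1
        if scores[first] > scores[second]:
            num += 1
        elif scores[first] == scores[second]:
            num += 0.5
    if den == 0:
        raise ZeroDivisionError("no usable pairs")
    return num / den


def hypergeom_tail(k_min: int, m: int, n: int, N: int) -> float:
    """P(X >= k_min) for hypergeometric X by direct combinatorial sum."""
    total = math.comb(N, n)
    p = 0.0
    for k in range(max(k_min, 0), min(m, n) + 1):
        p += math.comb(m, k) * math.comb(N - m, n - k) / total
    return p


def sam_d(values: np.ndarray, class1: np.ndarray, s0: float) -> np.ndarray:
    """Straightforward per-gene SAM d for a boolean class-1 mask."""
    x1, x2 = values[:, class1], values[:, ~class1]
    n1, n2 = x1.shape[1], x2.shape[1]
    m1, m2 = x1.mean(1), x2.mean(1)
    ss = ((x1 - m1[:, None]) ** 2).sum(1) + ((x2 - m2[:, None]) ** 2).sum(1)
    s = np.sqrt((1 / n1 + 1 / n2) * ss / (n1 + n2 - 2))
    return (m2 - m1) / (s + s0)


def exhaustive_sam_q(values: np.ndarray, class1: np.ndarray, s0: float) -> np.ndarray:
    """q-values from exhaustive enumeration of all label arrangements.

    Implements the definition directly: for each threshold (the observed
    |d| values), FDR = mean permuted exceedance count / observed count,
    capped at 1; per-gene q is the minimum FDR over thresholds at or below
    its own |d|.
    """
    n = values.shape[1]
    n1 = int(class1.sum())
    d_obs = np.abs(sam_d(values, class1, s0))
    perms = []
    for combo in itertools.combinations(range(n), n1):
        mask = np.zeros(n, dtype=bool)
        mask[list(combo)] = True
        perms.append(np.abs(sam_d(values, mask, s0)))
    perms = np.array(perms)

    order = np.argsort(-d_obs)
    q = np.empty_like(d_obs)
    fdrs = []
    for rank, gi in enumerate(order):
        thr = d_obs[gi]
        observed = (d_obs >= thr).sum()
        expected = (perms >= thr).sum(axis=1).mean()
        fdrs.append(min(expected / observed, 1.0))
    # min FDR over thresholds at which the gene is called (itself or smaller |d|)
    fdrs = np.array(fdrs)
    running = np.minimum.accumulate(fdrs[::-1])[::-1]
    q[order] = running
    return q
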