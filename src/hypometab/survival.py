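"""Survival stratification: Kaplan–Meier, log-rank, Cox PH.

Kaplan–Meier estimation and the two-group log-rank test delegate to
lifelines (deaths precede censorings at tied times, the convention this
module promises).  The Cox proportional-hazards fit is implemented here
as a Newton maximization of the Breslow partial likelihood, which keeps
tie handling explicit; lifelines' Efron-tie fitter agrees with it exactly
on tie-free data and serves as an independent cross-check in the test
suite.  Note the small known numerical difference from R's survival
package, whose coxph defaults to Efron ties.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats

from .io import ClinicalTable
from .signatures import ScoreTable


@dataclass
class SurvivalCurve:
    """Product-limit curve evaluated at the observed event times."""

    times: np.ndarray      # ascending distinct event times
    survival: np.ndarray   # S(t) at those times, nonincreasing, S(0)=1
    at_risk: np.ndarray
    events: np.ndarray
    label: str = ""


def _check_time_event(time, event) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(time, float)
    e = np.asarray(event, float)
    if t.size != e.size:
        raise ValueError("time and event have different lengths")
    if (t < 0).any():
        raise ValueError("negative survival time")
    if not np.isin(e[~np.isnan(e)], [0, 1]).all():
        raise ValueError("event indicator outside {0,1}")
    keep = ~(np.isnan(t) | np.isnan(e))
    return t[keep], e[keep].astype(int)


def km_estimate(time, event, label: str = "") -> SurvivalCurve:
    """Kaplan–Meier product-limit estimate of the survival function."""
    t, e = _check_time_event(time, event)
    if t.size == 0:
        raise ValueError("no usable observations")
    kmf = KaplanMeierFitter().fit(t, e, label=label or "km")
    tab = kmf.event_table
    ev = tab[tab["observed"] > 0]
    times = ev.index.to_numpy(float)
    surv = kmf.survival_function_.loc[ev.index].to_numpy().ravel()
    return SurvivalCurve(
        times=times,
        survival=surv,
        at_risk=ev["at_risk"].to_numpy(float),
        events=ev["observed"].to_numpy(float),
        label=label,
    )


def logrank(time, event, group) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p)."""
    t_all = np.asarray(time, float)
    e_all = np.asarray(event, float)
    keep = ~(np.isnan(t_all) | np.isnan(e_all))
    t, e = _check_time_event(t_all[keep], e_all[keep])
    g = np.asarray(group)[keep]
    levels = pd.unique(g)
    if len(levels) != 2:
        raise ValueError(f"log-rank needs exactly two non-empty groups, "
                         f"got {len(levels)}")
    mask = g == levels[0]
    res = logrank_test(t[mask], t[~mask], e[mask], e[~mask])
    return float(res.test_statistic), float(res.p_value)


@dataclass
class CoxResult:
    """Per-covariate hazard ratios with Wald inference.

    ``flags`` carries warnings (e.g. suspected separation when a
    standardized coefficient runs away) instead of raising.
    """

    table: pd.DataFrame        # coef, hr, se, ci_low, ci_high, z, p
    loglik: float
    converged: bool
    n: int
    n_events: int
    flags: tuple[str, ...] = ()

    def hr(self, name: str) -> float:
        return float(self.table.loc[name, "hr"])


def _breslow_negloglik_grad_hess(beta, x, order_idx, tie_first, d_events, x_events_sum):
    """Breslow partial log-likelihood pieces on time-sorted data.

    x is sorted by descending time so risk sets are cumulative prefixes.
    ``tie_first`` marks, for each distinct event time, the last index
    (in the descending order) belonging to its risk set.
    """
    eta = x @ beta
    shift = eta.max()                     # guard the exp; restored in loglik
    w = np.exp(eta - shift)
    s0 = np.cumsum(w)
    s1 = np.cumsum(w[:, None] * x, axis=0)
    s2 = np.cumsum(w[:, None, None] * (x[:, :, None] * x[:, None, :]), axis=0)
    s0_t = s0[tie_first]
    s1_t = s1[tie_first]
    s2_t = s2[tie_first]
    loglik = float(
        x_events_sum @ beta
        - (d_events * np.log(s0_t)).sum()
        - d_events.sum() * shift
    )
    mean1 = s1_t / s0_t[:, None]
    grad = x_events_sum - (d_events[:, None] * mean1).sum(axis=0)
    cov = s2_t / s0_t[:, None, None] - mean1[:, :, None] * mean1[:, None, :]
    hess = -(d_events[:, None, None] * cov).sum(axis=0)
    return loglik, grad, hess


def cox_ph(
    time,
    event,
    covariates: pd.DataFrame,
    max_iter: int = 100,
    grad_tol: float = 1e-8,
    min_events: int = 10,
) -> CoxResult:
    """Cox proportional-hazards regression (Breslow ties, Newton solver).

    ``covariates`` must be numeric (one-hot categorical covariates
    beforehand; see :func:`encode_covariates`).  Non-convergence — e.g.
    under complete separation — is reported through the ``converged``
    flag rather than raised.
    """
    t, e = _check_time_event(time, event)
    x_df = covariates.astype(float)
    x = x_df.to_numpy()
    if x.shape[0] != t.size:
        raise ValueError("covariates and times have different lengths")
    n_events = int(e.sum())
    if n_events == 0:
        raise ValueError("no events")
    if n_events < min_events:
        raise ValueError(f"{n_events} events < {min_events} required")

    # standardize for Newton stability; coefficients mapped back at the end
    scale = x.std(axis=0, ddof=0)
    scale[scale == 0] = 1.0
    xs = (x - x.mean(axis=0)) / scale

    order = np.argsort(-t, kind="stable")         # descending time
    xs_o, t_o, e_o = xs[order], t[order], e[order]
    ev_mask = e_o == 1
    ev_times = t_o[ev_mask]
    distinct, inv = np.unique(ev_times, return_inverse=True)
    d_events = np.bincount(inv).astype(float)      # deaths per distinct time
    # risk set of an event time = all with time >= it: in descending order,
    # the prefix up to the LAST index with that time (ties included).
    last_idx = np.searchsorted(-t_o, -distinct, side="right") - 1
    x_events_sum = xs_o[ev_mask].sum(axis=0)

    beta = np.zeros(xs.shape[1])
    ll, grad, hess = _breslow_negloglik_grad_hess(
        beta, xs_o, order, last_idx, d_events, x_events_sum)
    converged = False
    for _ in range(max_iter):
        if np.linalg.norm(grad) < grad_tol:
            converged = True
            break
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            break
        step_size = 1.0
        for _ in range(30):                        # backtracking line search
            cand = beta - step_size * step
            ll_new, g_new, h_new = _breslow_negloglik_grad_hess(
                cand, xs_o, order, last_idx, d_events, x_events_sum)
            if ll_new >= ll - 1e-12:
                beta, ll, grad, hess = cand, ll_new, g_new, h_new
                break
            step_size /= 2
        else:
            break
    else:
        converged = np.linalg.norm(grad) < grad_tol

    flags = []
    runaway = np.abs(beta) > 10       # on standardized scale
    if runaway.any():
        flags.append(
            "possible separation: runaway coefficient(s) "
            f"{list(x_df.columns[runaway])}"
        )
    try:
        cov_beta = np.linalg.inv(-hess)
    except np.linalg.LinAlgError:
        cov_beta = np.full((len(beta), len(beta)), np.nan)
    # back to the original covariate scale
    coef = beta / scale
    se = np.sqrt(np.maximum(np.diag(cov_beta), 0)) / scale
    z = np.divide(coef, se, out=np.full_like(coef, np.nan), where=se > 0)
    p = 2 * stats.norm.sf(np.abs(z))
    ci = stats.norm.ppf(0.975)
    with np.errstate(over="ignore"):
        table = pd.DataFrame(
            {
                "coef": coef,
                "hr": np.exp(coef),
                "se": se,
                "ci_low": np.exp(coef - ci * se),
                "ci_high": np.exp(coef + ci * se),
                "z": z,
                "p": p,
            },
            index=x_df.columns,
        )
    table.index.name = "covariate"
    return CoxResult(table, float(ll), bool(converged), int(t.size),
                     n_events, tuple(flags))


def encode_covariates(
    clinical: ClinicalTable,
    scores: ScoreTable | None = None,
    covariates: tuple[str, ...] = ("grade", "stage", "pam50"),
) -> pd.DataFrame:
    """Design matrix for Cox regression on a clinical table.

    hs_group enters as 1 for HS-high; grade/stage/pam50 are one-hot
    encoded with the most frequent category as the reference level.
    Samples with a missing covariate are dropped.
    """
    frames = []
    if scores is not None:
        shared = clinical.table.index.intersection(scores.table.index)
        frames.append(
            (scores.table.loc[shared, "group"] == "high")
            .astype(float).rename("hs_high").to_frame()
        )
    for col in covariates:
        if col not in clinical.table.columns:
            continue
        series = clinical.table[col].dropna()
        cats = series.value_counts()
        ref = cats.index[0]
        dummies = pd.get_dummies(series, prefix=col, dtype=float)
        dummies = dummies.drop(columns=f"{col}_{ref}")
        frames.append(dummies)
    if not frames:
        raise ValueError("no covariates available")
    design = pd.concat(frames, axis=1, join="inner").dropna()
    return design
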