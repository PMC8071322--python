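"""Kaplan-Meier estimation, logrank (plain and trend) tests, and Cox regression.

Disease-free survival enters in months with surgery as time zero; an event is
an observed relapse, censoring is the last relapse-free follow-up. The Cox
model is fitted by maximizing the partial likelihood with Breslow tie handling
(the default of the mainstream clinical-statistics packages; Efron optional),
giving HR = exp(beta) with two-sided 95% Wald intervals on the log scale. The
logrank machinery accumulates observed minus expected events over distinct
event times with the hypergeometric covariance; the trend variant contrasts
ordered groups with scores s_g and statistic [sum s_g (O_g - E_g)]^2 / s'Vs
on one degree of freedom.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats
from statsmodels.duration.hazard_regression import PHReg

__all__ = [
    "SurvivalRecord",
    "CoxFit",
    "LogrankResult",
    "km_curve",
    "logrank",
    "logrank_trend",
    "cox_fit",
    "circ_survival_screen",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SurvivalRecord:
    sample_id: str
    dfs_time: float  # months from surgery
    event: int  # 1 = relapse observed, 0 = censored

    def __post_init__(self) -> None:
        if self.dfs_time <= 0:
            raise ValueError(f"nonpositive DFS time for {self.sample_id}")
        if self.event not in (0, 1):
            raise ValueError(f"event must be 0/1, got {self.event}")


@dataclass
class CoxFit:
    coef: pd.Series  # beta per covariate
    se: pd.Series
    hr: pd.Series
    ci_lower: pd.Series
    ci_upper: pd.Series
    p: pd.Series  # Wald
    ties: str
    iterations: int
    converged: bool
    warnings_: list[str] = field(default_factory=list)


@dataclass
class LogrankResult:
    observed: pd.Series  # O_g per group
    expected: pd.Series  # E_g per group
    statistic: float
    df: int
    p: float
    scores: tuple | None = None


def _unpack(records) -> tuple[np.ndarray, np.ndarray, list[str]]:
    times = np.array([r.dfs_time for r in records], dtype=float)
    events = np.array([r.event for r in records], dtype=int)
    ids = [r.sample_id for r in records]
    if times.size == 0:
        raise ValueError("no survival records")
    return times, events, ids


def km_curve(records) -> pd.DataFrame:
    """Product-limit estimate: one row per distinct event time.

    Columns: time, at_risk, events, survival. Censorings tied with events are
    handled events-first (censored subjects remain at risk at that time).
    """
    times, events, _ = _unpack(records)
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    table = kmf.event_table
    surv = kmf.survival_function_["KM_estimate"]
    out = pd.DataFrame(
        {
            "time": table.index.to_numpy(dtype=float),
            "at_risk": table["at_risk"].to_numpy(dtype=int),
            "events": table["observed"].to_numpy(dtype=int),
            "survival": surv.reindex(table.index).to_numpy(dtype=float),
        }
    )
    return out[out["time"] > 0].reset_index(drop=True)


def _oe_and_covariance(times, events, groups) -> tuple[pd.Series, pd.Series, np.ndarray, list]:
    """Observed/expected events per group and the hypergeometric covariance."""
    labels = sorted(pd.unique(groups), key=str)
    g_index = {g: i for i, g in enumerate(labels)}
    gidx = np.array([g_index[g] for g in groups])
    n_groups = len(labels)
    observed = np.zeros(n_groups)
    expected = np.zeros(n_groups)
    cov = np.zeros((n_groups, n_groups))
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n_t = at_risk.sum()
        d_t = int(((times == t) & (events == 1)).sum())
        if n_t == 0 or d_t == 0:
            continue
        n_g = np.bincount(gidx[at_risk], minlength=n_groups).astype(float)
        d_g = np.bincount(gidx[(times == t) & (events == 1)], minlength=n_groups).astype(float)
        observed += d_g
        expected += d_t * n_g / n_t
        if n_t > 1:
            frac = n_g / n_t
            cov += d_t * (n_t - d_t) / (n_t - 1) * (np.diag(frac) - np.outer(frac, frac))
    return pd.Series(observed, index=labels), pd.Series(expected, index=labels), cov, labels


def logrank(records, groups) -> LogrankResult:
    """K-sample logrank test on df = K - 1."""
    times, events, ids = _unpack(records)
    groups = pd.Series(list(groups))
    if groups.size != times.size:
        raise ValueError("groups must align with records")
    counts = groups.value_counts()
    if counts.size < 2:
        raise ValueError("logrank needs at least 2 groups")
    if (counts == 0).any():
        raise ValueError("a group has zero subjects")
    obs, exp, cov, labels = _oe_and_covariance(times, events, groups.to_numpy())
    diff = (obs - exp).to_numpy()[:-1]
    v = cov[:-1, :-1]
    try:
        stat = float(diff @ np.linalg.solve(v, diff))
    except np.linalg.LinAlgError:
        stat = float(diff @ np.linalg.pinv(v) @ diff)
    stat = max(stat, 0.0)
    df = len(labels) - 1
    return LogrankResult(obs, exp, stat, df, float(stats.chi2.sf(stat, df)))


def logrank_trend(records, groups, scores=None) -> LogrankResult:
    """Logrank test for trend across ordered groups (1 df).

    ``groups`` must be ordered labels; ``scores`` (default 1..K in the order
    the distinct labels first appear sorted) must be strictly increasing.
    """
    times, events, _ = _unpack(records)
    groups = pd.Series(list(groups))
    obs, exp, cov, labels = _oe_and_covariance(times, events, groups.to_numpy())
    k = len(labels)
    if k < 2:
        raise ValueError("trend test needs at least 2 ordered groups")
    if scores is None:
        scores = tuple(range(1, k + 1))
    s = np.asarray(scores, dtype=float)
    if s.size != k:
        raise ValueError(f"{k} groups but {s.size} scores")
    if not np.all(np.diff(s) > 0):
        raise ValueError("scores must be strictly increasing")
    u = float(s @ (obs - exp).to_numpy())
    var = float(s @ cov @ s)
    stat = 0.0 if var <= 0 else u * u / var
    return LogrankResult(obs, exp, stat, 1, float(stats.chi2.sf(stat, 1)), scores=tuple(s))


def cox_fit(records, covariates, ties: str = "breslow", tol: float = 1e-9, max_iter: int = 200) -> CoxFit:
    """Cox proportional-hazards fit of DFS on the given covariates.

    ``covariates`` is a DataFrame (rows aligned with records) or dict/Series of
    one covariate. Reports beta, SE from the inverse observed information,
    HR = exp(beta), 95% Wald CI, and the Wald p-value. A monotone partial
    likelihood (complete separation) is flagged as non-converged; the CI is
    suppressed (NaN) in that case.
    """
    times, events, ids = _unpack(records)
    if events.sum() < 1:
        raise ValueError("Cox regression needs at least 1 event")
    if isinstance(covariates, (dict, pd.Series)):
        covariates = pd.DataFrame({"x": pd.Series(covariates)})
    x = covariates.loc[ids] if set(ids).issubset(covariates.index) else covariates
    x = x.apply(pd.to_numeric)
    if not np.isfinite(x.to_numpy()).all():
        raise ValueError("covariates must be finite")
    variation = x.nunique()
    if (variation < 2).any():
        bad = list(variation[variation < 2].index)
        raise ValueError(f"no variation in covariate(s): {bad}")

    model = PHReg(times, x.to_numpy(dtype=float), status=events, ties=ties)
    warns: list[str] = []
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        res = model.fit(method="newton", maxiter=max_iter, gtol=tol, disp=False)
        warns += [str(w.message) for w in caught]
    beta = np.asarray(res.params, dtype=float)
    score = model.score(beta)
    converged = bool(np.isfinite(beta).all() and np.max(np.abs(score)) < max(tol * 1e3, 1e-4)
                     and np.max(np.abs(beta)) < 15)
    se = np.asarray(res.bse, dtype=float)
    if not converged:
        warns.append("partial likelihood appears monotone (separation?); CI suppressed")
        se = np.full_like(se, np.nan)
    names = list(x.columns)
    coef = pd.Series(beta, index=names)
    se_s = pd.Series(se, index=names)
    z = 1.959963984540054
    return CoxFit(
        coef=coef,
        se=se_s,
        hr=np.exp(coef),
        ci_lower=np.exp(coef - z * se_s),
        ci_upper=np.exp(coef + z * se_s),
        p=pd.Series(2 * stats.norm.sf(np.abs(coef / se_s)), index=names),
        ties=ties,
        iterations=max_iter,
        converged=converged,
        warnings_=warns,
    )


def circ_survival_screen(presence_column, records) -> tuple[CoxFit, LogrankResult]:
    """Detected-vs-not survival analysis for one circRNA.

    ``presence_column`` maps sample id -> bool. Coding: detected = 1 with
    "not detected" as reference, so HR < 1 means detection is protective.
    Runs a two-group logrank and a single-covariate Cox fit.
    """
    presence = pd.Series(presence_column).astype(bool)
    ids = [r.sample_id for r in records]
    x = presence.reindex(ids)
    if x.isna().any():
        raise ValueError("presence column missing some samples")
    n_detected = int(x.sum())
    if n_detected == 0 or n_detected == len(ids):
        raise ValueError("one stratum is empty (all or none detected)")
    groups = np.where(x.to_numpy(), "detected", "not_detected")
    lr = logrank(records, groups)
    events = np.array([r.event for r in records])
    if (x.to_numpy().astype(int) == events).all() or (x.to_numpy().astype(int) == 1 - events).all():
        warnings.warn("presence coincides with event status: complete separation expected")
    fit = cox_fit(records, pd.DataFrame({"detected": x.astype(float).to_numpy()}, index=ids))
    return fit, lr
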