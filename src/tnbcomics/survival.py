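"""Survival analysis: Cox proportional hazards, Kaplan-Meier, logrank.

The Cox model has a single continuous covariate and maximises the Breslow
partial likelihood by Newton-Raphson with analytic score and information;
significance is the Wald test.  Breslow tie handling is used (rather than
Efron) so that with a binary covariate and untied event times the score test
at beta = 0 coincides exactly with the logrank statistic, a cross-check the
test suite exploits.  The Kaplan-Meier estimator carries Greenwood variance.
For illustration a continuous covariate can be dichotomised at the median
(low group: values <= median).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _sps

__all__ = [
    "CoxFit",
    "cox_fit",
    "cox_score_test",
    "km_curve",
    "logrank_test",
    "median_dichotomize",
    "prognosis_report",
]


@dataclass
class CoxFit:
    beta_hat: float
    se: float
    wald_z: float
    wald_p: float
    hazard_ratio: float
    ci95: tuple[float, float]
    n: int
    n_events: int
    loglik: float
    converged: bool
    iterations: int


def _prepare(time, event, covariate=None):
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if np.any(time < 0):
        raise ValueError("times must be non-negative")
    if not np.isin(event, (0, 1)).all():
        raise ValueError("event indicator must be 0/1")
    if covariate is None:
        return time, event
    covariate = np.asarray(covariate, dtype=float)
    if not np.all(np.isfinite(covariate)):
        raise ValueError("covariate must be finite")
    if len(covariate) != len(time):
        raise ValueError("length mismatch")
    return time, event, covariate


def _breslow_quantities(time, event, x, beta):
    """Breslow partial log-likelihood, score and information at beta.

    Works on ascending-time order; risk-set sums are suffix cumulative sums,
    with tied times sharing one risk set.
    """
    order = np.argsort(time, kind="stable")
    t, d, xs = time[order], event[order], x[order]
    e = np.exp(beta * xs)
    s0 = np.cumsum(e[::-1])[::-1]
    s1 = np.cumsum((xs * e)[::-1])[::-1]
    s2 = np.cumsum((xs * xs * e)[::-1])[::-1]
    ll = score = info = 0.0
    i = 0
    n = len(t)
    while i < n:
        j = i
        dsum = 0
        xsum = 0.0
        while j < n and t[j] == t[i]:
            if d[j]:
                dsum += 1
                xsum += xs[j]
            j += 1
        if dsum:
            r0, r1, r2 = s0[i], s1[i], s2[i]
            ll += beta * xsum - dsum * math.log(r0)
            m = r1 / r0
            score += xsum - dsum * m
            info += dsum * (r2 / r0 - m * m)
        i = j
    return ll, score, info


def cox_fit(time, event, covariate, max_iter: int = 50,
            score_tol: float = 1e-8, step_tol: float = 1e-10) -> CoxFit:
    """Fit the single-covariate Cox model by Newton-Raphson from beta = 0.

    Convergence when |score| < 1e-8 or the Newton step falls below 1e-10;
    monotone partial likelihood (the estimate diverging, e.g. a covariate
    that perfectly orders the events) is detected and flagged as
    non-converged rather than returned silently.
    """
    time, event, x = _prepare(time, event, covariate)
    n_events = int(event.sum())
    if n_events < 2:
        raise ValueError("Cox fit needs >= 2 events")
    if np.ptp(x) == 0 or np.ptp(x[event == 1]) == 0:
        raise ValueError("covariate is constant (among events); unidentifiable")
    beta = 0.0
    converged = False
    ll, score, info = _breslow_quantities(time, event, x, beta)
    it = 0
    for it in range(1, max_iter + 1):
        if info <= 0 or abs(beta) > 50:
            break
        step = score / info
        new_beta = beta + step
        new_ll, new_score, new_info = _breslow_quantities(time, event, x, new_beta)
        halvings = 0
        while new_ll < ll - 1e-12 and halvings < 10:
            step /= 2.0
            new_beta = beta + step
            new_ll, new_score, new_info = _breslow_quantities(time, event, x, new_beta)
            halvings += 1
        beta, ll, score, info = new_beta, new_ll, new_score, new_info
        if abs(score) < score_tol or abs(step) < step_tol:
            # a vanishing information with a huge |beta| is a flat (monotone)
            # likelihood saturating numerically, not a genuine optimum
            converged = abs(beta) <= 30 and info > 1e-6
            break
    se = 1.0 / math.sqrt(info) if info > 0 else float("nan")
    z = beta / se if se and not math.isnan(se) else float("nan")
    p = 2.0 * float(_sps.norm.sf(abs(z))) if not math.isnan(z) else float("nan")

    def _exp(v: float) -> float:
        try:
            return math.exp(v)
        except OverflowError:
            return float("inf")

    return CoxFit(
        beta_hat=beta, se=se, wald_z=z, wald_p=p,
        hazard_ratio=_exp(beta),
        ci95=(_exp(beta - 1.96 * se), _exp(beta + 1.96 * se))
        if not math.isnan(se) else (float("nan"), float("nan")),
        n=len(time), n_events=n_events, loglik=ll,
        converged=converged, iterations=it,
    )


def cox_score_test(time, event, covariate) -> tuple[float, float]:
    """Score (Rao) test of beta = 0: chi-square on 1 dof and p-value."""
    time, event, x = _prepare(time, event, covariate)
    _, score, info = _breslow_quantities(time, event, x, 0.0)
    if info <= 0:
        raise ValueError("zero information at beta = 0")
    chi2 = score * score / info
    return chi2, float(_sps.chi2.sf(chi2, 1))


def km_curve(time, event) -> pd.DataFrame:
    """Kaplan-Meier product-limit estimate with Greenwood variance.

    One row per distinct event time: time, number at risk, events, survival
    just after the time, and the Greenwood variance of the estimate.
    """
    time, event = _prepare(time, event)
    if len(time) == 0:
        raise ValueError("no records")
    order = np.argsort(time, kind="stable")
    t, d = time[order], event[order]
    rows = []
    surv = 1.0
    greenwood = 0.0
    n = len(t)
    i = 0
    while i < n:
        j = i
        deaths = 0
        while j < n and t[j] == t[i]:
            deaths += int(d[j])
            j += 1
        at_risk = n - i
        if deaths:
            surv *= 1.0 - deaths / at_risk
            if at_risk > deaths:
                greenwood += deaths / (at_risk * (at_risk - deaths))
            rows.append({
                "time": t[i], "n_at_risk": at_risk, "n_events": deaths,
                "survival": surv,
                "variance": surv * surv * greenwood,
            })
        i = j
    return pd.DataFrame(rows, columns=["time", "n_at_risk", "n_events",
                                       "survival", "variance"])


def logrank_test(time, event, group) -> tuple[float, float]:
    """Two-group logrank test: chi-square on 1 dof and p-value.

    At each distinct event time the observed-minus-expected event count in
    group 1 is accumulated with the hypergeometric variance.
    """
    time, event = _prepare(time, event)
    group = np.asarray(group).astype(bool)
    if group.all() or not group.any():
        raise ValueError("both groups need at least one subject")
    order = np.argsort(time, kind="stable")
    t, d, g = time[order], event[order], group[order]
    n = len(t)
    o_minus_e = 0.0
    var = 0.0
    i = 0
    while i < n:
        j = i
        deaths = d1 = 0
        while j < n and t[j] == t[i]:
            if d[j]:
                deaths += 1
                d1 += int(g[j])
            j += 1
        if deaths:
            at_risk = n - i
            n1 = int(g[i:].sum())
            e1 = deaths * n1 / at_risk
            o_minus_e += d1 - e1
            if at_risk > 1:
                var += (deaths * (n1 / at_risk) * (1 - n1 / at_risk)
                        * (at_risk - deaths) / (at_risk - 1))
        i = j
    if var <= 0:
        return 0.0, 1.0
    chi2 = o_minus_e * o_minus_e / var
    return chi2, float(_sps.chi2.sf(chi2, 1))


def median_dichotomize(covariate) -> np.ndarray:
    """Split at the median: low group = values <= median (returns high mask)."""
    x = np.asarray(covariate, dtype=float)
    if len(x) < 2:
        raise ValueError("need >= 2 values")
    med = float(np.median(x))
    high = x > med
    if not high.any() or high.all():
        raise ValueError("median split leaves one group empty (values too tied)")
    return high


def prognosis_report(expression: pd.Series, records: pd.DataFrame,
                     annotations: pd.Series | None = None,
                     subgroup: str | None = "TNBC",
                     exclude: pd.Series | None = None,
                     endpoints: list[str] | None = None) -> pd.DataFrame:
    """Per-endpoint prognosis table within one subgroup.

    For each endpoint present in ``records`` (columns sample_id, time, event,
    endpoint) the continuous-covariate Cox fit (Wald p, HR, CI) and the
    median-dichotomised logrank test are computed over samples shared with
    ``expression``.  ``exclude`` (boolean per sample, e.g. initial metastatic
    disease) is applied before analysis.  Endpoints with < 2 events or a
    degenerate median split are reported as not computed.
    """
    if endpoints is None:
        endpoints = list(pd.unique(records["endpoint"]))
    keep = set(expression.dropna().index)
    if subgroup is not None and annotations is not None:
        keep &= set(annotations.index[annotations == subgroup])
    if exclude is not None:
        keep -= set(exclude.index[exclude.astype(bool)])
    rows = []
    for ep in endpoints:
        sub = records[(records["endpoint"] == ep)
                      & records["sample_id"].isin(keep)]
        row = {"endpoint": ep, "n": len(sub),
               "n_events": int(sub["event"].sum()), "computed": False,
               "beta": np.nan, "hazard_ratio": np.nan, "ci_low": np.nan,
               "ci_high": np.nan, "wald_p": np.nan, "logrank_chi2": np.nan,
               "logrank_p": np.nan}
        x = expression[sub["sample_id"]].to_numpy()
        if row["n_events"] >= 2 and len(sub) >= 3 and np.ptp(x) > 0:
            try:
                fit = cox_fit(sub["time"].to_numpy(), sub["event"].to_numpy(), x)
                row.update(beta=fit.beta_hat, hazard_ratio=fit.hazard_ratio,
                           ci_low=fit.ci95[0], ci_high=fit.ci95[1],
                           wald_p=fit.wald_p, computed=fit.converged)
                high = median_dichotomize(x)
                chi2, p = logrank_test(sub["time"].to_numpy(),
                                       sub["event"].to_numpy(), high)
                row.update(logrank_chi2=chi2, logrank_p=p)
            except ValueError:
                row["computed"] = False
        rows.append(row)
    return pd.DataFrame(rows)
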