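"""All-cause mortality contrast: Cox proportional hazards on the matched cohort.

The model is the crude two-group contrast the matched design calls for: one
binary covariate (case vs control), partial likelihood maximized by
Newton–Raphson with Efron's (default) or Breslow's correction for tied death
days.  With a single binary covariate the risk-set sums reduce to at-risk
counts per group at each distinct death time, which keeps the fit exact and
fast at registry scale.  A pair-stratified variant (conditional on matched
pair) is available as a sensitivity analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

Z95 = 1.959964


@dataclass(frozen=True)
class CoxFit:
    log_hr: float
    se_log_hr: float
    hr: float
    ci95: tuple[float, float]
    n: int
    n_events: int
    ties_method: str
    converged: bool

    def summary(self) -> dict:
        return {"log_hr": self.log_hr, "se_log_hr": self.se_log_hr, "hr": self.hr,
                "ci95": list(self.ci95), "n": self.n, "n_events": self.n_events,
                "ties_method": self.ties_method, "converged": self.converged}


def survival_table(cohort: pd.DataFrame, min_time_days: float = 0.5) -> pd.DataFrame:
    """One survival record per matched individual (cases and their controls).

    ``time`` is days from index to the follow-up end; the event indicator is
    death as the censoring reason.  Zero-length follow-up (death on the index
    date) is clamped to ``min_time_days`` rather than dropped, so same-day
    deaths still contribute risk.
    """
    rows = []
    for i, r in enumerate(cohort.itertuples(index=False)):
        t = (r.follow_up_end - r.index_date).days
        rows.append({"person_id": r.case_id, "group": 1, "pair_id": i,
                     "time": max(float(t), min_time_days),
                     "event": r.censor_reason == "death"})
        if r.control_id is not None and pd.notna(r.control_follow_up_end):
            t = (r.control_follow_up_end - r.index_date).days
            rows.append({"person_id": r.control_id, "group": 0, "pair_id": i,
                         "time": max(float(t), min_time_days),
                         "event": r.control_censor_reason == "death"})
    return pd.DataFrame(rows, columns=["person_id", "group", "pair_id", "time", "event"])


def _tie_groups(time, event, group):
    """Sufficient statistics per distinct death time.

    Returns arrays (one entry per expanded tie slot) A, B such that the
    Efron-corrected risk-set denominator at slot l of death-time j is
    A + B·exp(beta), plus the total deaths in group 1.
    """
    order = np.argsort(time, kind="mergesort")
    t, e, g = time[order], event[order], group[order]
    death_times = np.unique(t[e])
    # at-risk counts: number with time >= t_j, by group
    n_tot = np.searchsorted(t, death_times, side="left")
    n_risk = len(t) - n_tot
    t1 = np.sort(t[g == 1])
    n1_risk = len(t1) - np.searchsorted(t1, death_times, side="left")
    n0_risk = n_risk - n1_risk
    # deaths at t_j, by group
    td = t[e]
    d_tot = np.searchsorted(td, death_times, side="right") - \
        np.searchsorted(td, death_times, side="left")
    td1 = np.sort(t[e & (g == 1)])
    d1 = np.searchsorted(td1, death_times, side="right") - \
        np.searchsorted(td1, death_times, side="left")
    d0 = d_tot - d1
    return n0_risk, n1_risk, d0, d1, d_tot


def _expand_efron(n0, n1, d0, d1, d, efron: bool):
    """Per-slot coefficients (A, B): denominator = A + B e^beta."""
    reps = d.astype(int)
    j = np.repeat(np.arange(len(d)), reps)
    l = np.concatenate([np.arange(k) for k in reps]) if len(reps) else np.array([])
    frac = (l / d[j]) if efron else np.zeros(len(j))
    A = n0[j] - frac * d0[j]
    B = n1[j] - frac * d1[j]
    return A, B


def fit_cox(records: pd.DataFrame, ties: str = "efron", tol: float = 1e-9,
            max_iter: int = 50) -> CoxFit:
    """Newton–Raphson fit of the two-group Cox partial likelihood.

    ``records`` needs columns ``time`` (days > 0), ``event`` (bool) and
    ``group`` (0/1).  Convergence when the log-likelihood change drops below
    ``tol``.  A monotone likelihood (all deaths in one group) is reported as
    a non-finite estimate with ``converged=False`` rather than an error.
    """
    if ties not in ("efron", "breslow"):
        raise ValueError("ties must be 'efron' or 'breslow'")
    time = np.asarray(records["time"], dtype=float)
    event = np.asarray(records["event"], dtype=bool)
    group = np.asarray(records["group"], dtype=int)
    n_events = int(event.sum())
    if n_events == 0:
        raise ValueError("no events: the hazard ratio is not identified")
    n0r, n1r, d0, d1, d = _tie_groups(time, event, group)
    D1 = float(d1.sum())
    if D1 == 0.0 or D1 == float(d.sum()):
        sign = -math.inf if D1 == 0.0 else math.inf
        return CoxFit(sign, math.inf, math.exp(sign) if sign < 0 else math.inf,
                      (0.0, math.inf), len(time), n_events, ties, False)
    A, B = _expand_efron(n0r, n1r, d0, d1, d, efron=(ties == "efron"))

    beta = 0.0
    prev_ll = -math.inf
    converged = False
    for _ in range(max_iter):
        r = math.exp(beta)
        denom = A + B * r
        p = B * r / denom
        ll = D1 * beta - float(np.log(denom).sum())
        U = D1 - float(p.sum())
        I = float((p * (1.0 - p)).sum())
        if I <= 0:
            break
        beta += U / I
        if abs(ll - prev_ll) < tol:
            converged = True
            break
        prev_ll = ll
    r = math.exp(beta)
    p = B * r / (A + B * r)
    info = float((p * (1.0 - p)).sum())
    se = 1.0 / math.sqrt(info)
    return CoxFit(log_hr=beta, se_log_hr=se, hr=math.exp(beta),
                  ci95=(math.exp(beta - Z95 * se), math.exp(beta + Z95 * se)),
                  n=len(time), n_events=n_events, ties_method=ties,
                  converged=converged)


def fit_cox_stratified(records: pd.DataFrame, ties: str = "efron",
                       tol: float = 1e-9, max_iter: int = 50) -> CoxFit:
    """Pair-stratified sensitivity variant: each matched pair is its own
    stratum, so the partial likelihood conditions on the matching."""
    parts = []
    n_events = 0
    for _, grp in records.groupby("pair_id"):
        time = grp["time"].to_numpy(dtype=float)
        event = grp["event"].to_numpy(dtype=bool)
        g = grp["group"].to_numpy(dtype=int)
        if not event.any():
            continue
        n_events += int(event.sum())
        stats = _tie_groups(time, event, g)
        parts.append(stats)
    if not parts:
        raise ValueError("no events in any stratum")
    n0r = np.concatenate([p[0] for p in parts])
    n1r = np.concatenate([p[1] for p in parts])
    d0 = np.concatenate([p[2] for p in parts])
    d1 = np.concatenate([p[3] for p in parts])
    d = np.concatenate([p[4] for p in parts])
    D1 = float(d1.sum())
    if D1 == 0.0 or D1 == float(d.sum()):
        sign = -math.inf if D1 == 0.0 else math.inf
        return CoxFit(sign, math.inf, math.exp(sign) if sign < 0 else math.inf,
                      (0.0, math.inf), len(records), n_events, ties, False)
    A, B = _expand_efron(n0r, n1r, d0, d1, d, efron=(ties == "efron"))
    # informative slots only (B in (0, A+B)); strata where the case is not at
    # risk contribute nothing
    beta, prev_ll, converged = 0.0, -math.inf, False
    for _ in range(max_iter):
        r = math.exp(beta)
        p = B * r / (A + B * r)
        ll = D1 * beta - float(np.log(A + B * r).sum())
        U = D1 - float(p.sum())
        I = float((p * (1.0 - p)).sum())
        if I <= 0:
            break
        beta += U / I
        if abs(ll - prev_ll) < tol:
            converged = True
            break
        prev_ll = ll
    r = math.exp(beta)
    p = B * r / (A + B * r)
    info = float((p * (1.0 - p)).sum())
    se = 1.0 / math.sqrt(info) if info > 0 else math.inf
    return CoxFit(beta, se, math.exp(beta),
                  (math.exp(beta - Z95 * se), math.exp(beta + Z95 * se)),
                  len(records), n_events, ties, converged)


def mortality_rate(records: pd.DataFrame, per: float = 1000.0,
                   year_days: float = 365.25) -> float:
    """Deaths per ``per`` person-years at risk."""
    total_time = float(records["time"].sum())
    if total_time <= 0:
        raise ValueError("no person-time at risk")
    return per * float(records["event"].sum()) / (total_time / year_days)


def mortality_analysis(cohort: pd.DataFrame, ties: str = "efron") -> dict:
    """End-to-end mortality contrast: survival table, Cox fit, group rates."""
    records = survival_table(cohort)
    fit = fit_cox(records, ties=ties)
    rates = {}
    for g, name in ((1, "mdd"), (0, "control")):
        sub = records[records["group"] == g]
        rates[name] = mortality_rate(sub) if len(sub) and sub["time"].sum() > 0 else None
    out = fit.summary()
    out["rate_per_1000py_by_group"] = rates
    out["rate_per_1000py_overall"] = mortality_rate(records)
    return out
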