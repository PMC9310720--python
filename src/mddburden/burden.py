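"""Healthcare-resource-utilization and work-loss burden.

Two conventions coexist deliberately: the monthly figures use whole calendar
months on the −12..+12 grid, while the annual summary uses day-based windows
pre = [index−365 d, index) and post = [index, index+365 d).  The annual
estimate is a follow-up-weighted ratio: each person contributes their outcome
total x_i over the part of the window they were followed, with weight
w_i = followed days / 365, and

    mean  = Σ x_i / Σ w_i
    SE    = sqrt( Σ (x_i − mean·w_i)² ) / Σ w_i      (linearized / sandwich)
    CI95  = mean ± 1.959964 · SE

which is the heteroskedasticity-robust intercept-only weighted regression,
accounting for the within-person clustering of events.  Work loss is
restricted to ages 20–64 at index and to sick-leave spells of at least 14
days (shorter spells are employer-paid and unobserved in insurance data).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd

from .registry import EventTables
from .trajectories import MONTHS, _month_ord

Z95 = 1.959964
OUTPATIENT_LEVELS = ("total", "primary", "psychiatric")
BEDDAY_WARDS = ("total", "psychiatric", "non_psychiatric")
WORKLOSS_KINDS = ("total", "sick_leave", "disability_pension")


@dataclass(frozen=True)
class BurdenEstimate:
    """One annualized weighted mean with robust CI (one summary-table cell)."""
    outcome: str
    group: str           # mdd | control
    window: str          # pre | post
    estimate: float
    se: float
    ci95: tuple[float, float]
    n: int
    sum_weights: float


def weighted_annual_mean(x, w, outcome: str = "", group: str = "",
                         window: str = "") -> BurdenEstimate:
    """Follow-up-weighted annualized mean with linearized robust SE."""
    x = np.asarray(x, dtype=float)
    w = np.asarray(w, dtype=float)
    if x.size < 1 or x.size != w.size:
        raise ValueError("x and w must be equal-length, non-empty")
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    sw = float(w.sum())
    if sw == 0:
        raise ValueError("sum of weights is zero")
    mu = float(x.sum()) / sw
    se = float(np.sqrt(np.sum((x - mu * w) ** 2))) / sw
    return BurdenEstimate(outcome=outcome, group=group, window=window,
                          estimate=mu, se=se,
                          ci95=(mu - Z95 * se, mu + Z95 * se),
                          n=int(x.size), sum_weights=sw)


def burden_ratio(a: BurdenEstimate | float, b: BurdenEstimate | float,
                 digits: int = 1) -> float:
    """Case/control ratio of two burden means, rounded half-up."""
    av = a.estimate if isinstance(a, BurdenEstimate) else float(a)
    bv = b.estimate if isinstance(b, BurdenEstimate) else float(b)
    if bv == 0:
        raise ValueError("cannot form a ratio against a zero mean")
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(av / bv)).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# event-counting primitives
# ---------------------------------------------------------------------------

def _overlap_days(starts, ends, lo, hi) -> np.ndarray:
    """Day counts of [starts, ends) ∩ [lo, hi), all half-open, vectorized."""
    s = np.maximum(np.asarray(starts, "datetime64[ns]"), np.asarray(lo, "datetime64[ns]"))
    e = np.minimum(np.asarray(ends, "datetime64[ns]"), np.asarray(hi, "datetime64[ns]"))
    d = (e - s) / np.timedelta64(1, "D")
    return np.maximum(d, 0.0)


def _visit_level(care_level: pd.Series) -> pd.Series:
    psych = care_level.isin(["psychiatric_outpatient", "psychiatric_inpatient"])
    return pd.Series(np.where(psych, "psychiatric",
                              np.where(care_level == "primary", "primary", "other")),
                     index=care_level.index)


def _month_start(ords: np.ndarray) -> pd.DatetimeIndex:
    return pd.to_datetime({"year": ords // 12, "month": ords % 12 + 1, "day": 1})


def _panel_monthly_mean(units: pd.DataFrame, contrib: pd.DataFrame,
                        measures: tuple) -> pd.DataFrame:
    """Average per-month contributions over at-risk panel units.

    ``contrib`` has columns unit, month, and one column per measure; missing
    (unit, month) pairs count as zero.
    """
    n = len(units)
    idx_ord = _month_ord(units["index_date"])
    fue_ord = _month_ord(units["follow_up_end"])
    at_risk = MONTHS[None, :] <= np.minimum(fue_ord - idx_ord, 12)[:, None]
    n_risk = at_risk.sum(axis=0)
    rows = []
    for meas in measures:
        total = np.zeros((n, len(MONTHS)))
        if len(contrib):
            sel = contrib[(contrib["month"] >= -12) & (contrib["month"] <= 12)]
            np.add.at(total, (sel["unit"].to_numpy(), sel["month"].to_numpy() + 12),
                      sel[meas].to_numpy(dtype=float))
        total[~at_risk] = 0.0
        mean = np.divide(total.sum(axis=0), n_risk, where=n_risk > 0,
                         out=np.zeros(len(MONTHS)))
        for m, v, nr in zip(MONTHS, mean, n_risk):
            rows.append({"month": int(m), "measure": meas, "mean": float(v),
                         "n_at_risk": int(nr)})
    return pd.DataFrame(rows)


def monthly_hru(panel: pd.DataFrame, tables: EventTables) -> pd.DataFrame:
    """Mean outpatient physician visits and inpatient bed days per month.

    Visits are split total / primary / psychiatric; bed days are the day
    overlap of each stay with the calendar month, split total / psychiatric /
    non-psychiatric.
    """
    units = panel.reset_index(drop=True)
    lookup = units[["person_id"]].reset_index(names="unit")
    idx_ord = _month_ord(units["index_date"])

    visits = tables.visits
    vrows = pd.DataFrame(columns=["unit", "month"])
    if len(visits):
        phys = visits[visits["physician"]]
        m = phys.merge(lookup, on="person_id")
        if len(m):
            month = _month_ord(m["date"]) - idx_ord[m["unit"].to_numpy()]
            lvl = _visit_level(m["care_level"]).to_numpy()
            vrows = pd.DataFrame({"unit": m["unit"].to_numpy(), "month": month,
                                  "visits_total": 1.0,
                                  "visits_primary": (lvl == "primary").astype(float),
                                  "visits_psychiatric": (lvl == "psychiatric").astype(float)})
    out_v = _panel_monthly_mean(units, vrows,
                                ("visits_total", "visits_primary", "visits_psychiatric"))

    stays = tables.stays
    srows = pd.DataFrame(columns=["unit", "month"])
    if len(stays):
        m = stays.merge(lookup, on="person_id")
        if len(m):
            parts = []
            a_ord = _month_ord(m["admission_date"])
            d_last = m["discharge_date"] - pd.Timedelta(days=1)
            # stays of zero length ([d, d)) contribute nothing
            nonzero = m["discharge_date"] > m["admission_date"]
            d_ord = np.where(nonzero, _month_ord(d_last), a_ord)
            for k in range(int((d_ord - a_ord).max()) + 1 if len(m) else 0):
                cur = a_ord + k
                live = cur <= d_ord
                if not live.any():
                    break
                mo_start = _month_start(cur[live])
                mo_end = _month_start(cur[live] + 1)
                days = _overlap_days(m.loc[live, "admission_date"],
                                     m.loc[live, "discharge_date"], mo_start, mo_end)
                psych = (m.loc[live, "ward"] == "psychiatric").to_numpy()
                parts.append(pd.DataFrame({
                    "unit": m.loc[live, "unit"].to_numpy(),
                    "month": cur[live] - idx_ord[m.loc[live, "unit"].to_numpy()],
                    "beddays_total": days,
                    "beddays_psychiatric": days * psych,
                    "beddays_non_psychiatric": days * ~psych}))
            if parts:
                srows = pd.concat(parts, ignore_index=True)
    out_s = _panel_monthly_mean(units, srows,
                                ("beddays_total", "beddays_psychiatric",
                                 "beddays_non_psychiatric"))
    return pd.concat([out_v, out_s], ignore_index=True)


def monthly_workloss(panel: pd.DataFrame, tables: EventTables,
                     min_sick_days: int = 14,
                     age_range: tuple[int, int] = (20, 64)) -> pd.DataFrame:
    """Mean net work-loss days per month (total / sick leave / disability).

    The panel is restricted to persons aged 20–64 at index; sick-leave spells
    shorter than ``min_sick_days`` are dropped; each spell contributes its
    day-overlap with the month times its extent.
    """
    units = panel.reset_index(drop=True)
    units = units[(units["age"] >= age_range[0]) & (units["age"] <= age_range[1])]
    units = units.reset_index(drop=True)
    lookup = units[["person_id"]].reset_index(names="unit")
    idx_ord = _month_ord(units["index_date"]) if len(units) else np.array([], dtype=int)

    wl = _filter_workloss(tables.workloss, min_sick_days)
    rows = pd.DataFrame(columns=["unit", "month"])
    if len(wl) and len(units):
        m = wl.merge(lookup, on="person_id")
        if len(m):
            parts = []
            a_ord = _month_ord(m["start"])
            d_ord = _month_ord(m["end"] - pd.Timedelta(days=1))
            for k in range(int((d_ord - a_ord).max()) + 1):
                cur = a_ord + k
                live = cur <= d_ord
                if not live.any():
                    break
                mo_start = _month_start(cur[live])
                mo_end = _month_start(cur[live] + 1)
                days = _overlap_days(m.loc[live, "start"], m.loc[live, "end"],
                                     mo_start, mo_end) * m.loc[live, "extent"].to_numpy()
                sick = (m.loc[live, "kind"] == "sick_leave").to_numpy()
                parts.append(pd.DataFrame({
                    "unit": m.loc[live, "unit"].to_numpy(),
                    "month": cur[live] - idx_ord[m.loc[live, "unit"].to_numpy()],
                    "workloss_total": days,
                    "workloss_sick_leave": days * sick,
                    "workloss_disability_pension": days * ~sick}))
            rows = pd.concat(parts, ignore_index=True)
    return _panel_monthly_mean(units, rows,
                               ("workloss_total", "workloss_sick_leave",
                                "workloss_disability_pension"))


def _filter_workloss(wl: pd.DataFrame, min_sick_days: int) -> pd.DataFrame:
    if not len(wl):
        return wl
    dur = (wl["end"] - wl["start"]).dt.days
    short_sick = (wl["kind"] == "sick_leave") & (dur < min_sick_days)
    return wl[~short_sick]


# ---------------------------------------------------------------------------
# annual weighted summary
# ---------------------------------------------------------------------------

def _annual_window(units: pd.DataFrame, window: str, year_days: int = 365):
    idx = pd.DatetimeIndex(units["index_date"])
    if window == "pre":
        lo, hi = idx - pd.Timedelta(days=year_days), idx
        w = np.ones(len(units))
    elif window == "post":
        lo = idx
        fue = pd.DatetimeIndex(units["follow_up_end"])
        hi = np.minimum(np.asarray(idx + pd.Timedelta(days=year_days)),
                        np.asarray(fue) + np.timedelta64(1, "D"))
        followed = np.maximum((hi - np.asarray(lo)) / np.timedelta64(1, "D"), 0.5)
        w = followed / year_days
    else:
        raise ValueError("window must be 'pre' or 'post'")
    return pd.DatetimeIndex(lo), pd.DatetimeIndex(hi), w


def _sum_by_unit(n, unit, values) -> np.ndarray:
    out = np.zeros(n)
    np.add.at(out, unit, values)
    return out


def person_outcomes(panel: pd.DataFrame, tables: EventTables, window: str,
                    year_days: int = 365, min_sick_days: int = 14) -> pd.DataFrame:
    """Per-person annual outcome totals x and follow-up weights w.

    Post-index windows are truncated at censoring (weight < 1); the pre-index
    window is fully observed by design (12 months of residency is an
    inclusion requirement).  Returns one row per panel unit with a column per
    outcome plus ``w``.
    """
    units = panel.reset_index(drop=True)
    n = len(units)
    lo, hi, w = _annual_window(units, window, year_days)
    bounds = units.assign(lo=lo, hi=hi).reset_index(names="unit")
    lookup = bounds[["person_id", "unit", "lo", "hi"]]
    out = {"person_id": units["person_id"], "group": units.get("group"),
           "age": units["age"], "w": w}

    visits = tables.visits
    vt = vp = vpsy = np.zeros(n)
    if len(visits):
        m = visits[visits["physician"]].merge(lookup, on="person_id")
        m = m[(m["date"] >= m["lo"]) & (m["date"] < m["hi"])]
        if len(m):
            lvl = _visit_level(m["care_level"]).to_numpy()
            u = m["unit"].to_numpy()
            vt = _sum_by_unit(n, u, np.ones(len(m)))
            vp = _sum_by_unit(n, u, (lvl == "primary").astype(float))
            vpsy = _sum_by_unit(n, u, (lvl == "psychiatric").astype(float))
    out["visits_total"], out["visits_primary"], out["visits_psychiatric"] = vt, vp, vpsy

    stays = tables.stays
    bt = bp = bn = np.zeros(n)
    if len(stays):
        m = stays.merge(lookup, on="person_id")
        if len(m):
            days = _overlap_days(m["admission_date"], m["discharge_date"],
                                 m["lo"], m["hi"])
            psych = (m["ward"] == "psychiatric").to_numpy()
            u = m["unit"].to_numpy()
            bt = _sum_by_unit(n, u, days)
            bp = _sum_by_unit(n, u, days * psych)
            bn = _sum_by_unit(n, u, days * ~psych)
    out["beddays_total"], out["beddays_psychiatric"] = bt, bp
    out["beddays_non_psychiatric"] = bn

    wl = _filter_workloss(tables.workloss, min_sick_days)
    wt = ws = wd = np.zeros(n)
    if len(wl):
        m = wl.merge(lookup, on="person_id")
        if len(m):
            days = _overlap_days(m["start"], m["end"], m["lo"], m["hi"]) \
                * m["extent"].to_numpy()
            sick = (m["kind"] == "sick_leave").to_numpy()
            u = m["unit"].to_numpy()
            wt = _sum_by_unit(n, u, days)
            ws = _sum_by_unit(n, u, days * sick)
            wd = _sum_by_unit(n, u, days * ~sick)
    out["workloss_total"], out["workloss_sick_leave"] = wt, ws
    out["workloss_disability_pension"] = wd
    return pd.DataFrame(out)


HRU_OUTCOMES = ("visits_total", "visits_primary", "visits_psychiatric",
                "beddays_total", "beddays_psychiatric", "beddays_non_psychiatric")
WORKLOSS_OUTCOMES = ("workloss_total", "workloss_sick_leave",
                     "workloss_disability_pension")


def annual_burden_table(panels: dict[str, pd.DataFrame], tables: EventTables,
                        year_days: int = 365,
                        age_range: tuple[int, int] = (20, 64)) -> pd.DataFrame:
    """The annual weighted summary: outcome × group × window.

    ``panels`` maps group name ('mdd', 'control') to its panel.  HRU outcomes
    use the full panel; work-loss outcomes the 20–64 subset.
    """
    rows = []
    for group, panel in panels.items():
        for window in ("pre", "post"):
            po = person_outcomes(panel, tables, window, year_days)
            wl_po = po[(po["age"] >= age_range[0]) & (po["age"] <= age_range[1])]
            for outcome in HRU_OUTCOMES + WORKLOSS_OUTCOMES:
                src = wl_po if outcome in WORKLOSS_OUTCOMES else po
                if not len(src):
                    continue
                est = weighted_annual_mean(src[outcome], src["w"], outcome,
                                           group, window)
                rows.append({"outcome": outcome, "group": group, "window": window,
                             "mean": est.estimate, "se": est.se,
                             "ci_lo": est.ci95[0], "ci_hi": est.ci95[1],
                             "n": est.n, "sum_weights": est.sum_weights})
    return pd.DataFrame(rows)


def ratio_table(table: pd.DataFrame, digits: int = 1) -> pd.DataFrame:
    """Case/control mean ratios per outcome and window from the annual table."""
    rows = []
    for (outcome, window), grp in table.groupby(["outcome", "window"]):
        g = grp.set_index("group")["mean"]
        if "mdd" in g and "control" in g and g["control"] > 0:
            rows.append({"outcome": outcome, "window": window,
                         "ratio": burden_ratio(float(g["mdd"]), float(g["control"]),
                                               digits)})
    return pd.DataFrame(rows)
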