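"""Monthly treatment-exposure and comorbidity trajectories around the index.

The month grid is calendar-anchored: month 0 is the calendar month containing
the index date, months −12..+12 are whole calendar months before/after it.
A drug therapy (antidepressants, add-on medication) counts as ongoing in a
month if any dispensation's supply window — days supplied plus a 25%
adherence buffer — intersects that month; a procedure therapy (ECT, rTMS,
psychotherapy) counts only in months with at least one recorded procedure.
Cumulative series carry a person forward from the first treated (or first
diagnosed, for comorbidity) month, with an at-risk denominator that drops
censored persons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .registry import Codebook, EventTables, PSYCHIATRIC_COMORBIDITIES

THERAPIES = ("ad", "addon", "ECT", "rTMS", "psychotherapy")
MONTHS = np.arange(-12, 13)


def _month_ord(dates) -> np.ndarray:
    """Calendar month as a single integer (year*12 + month-1)."""
    dates = pd.DatetimeIndex(dates)
    return (dates.year * 12 + dates.month - 1).to_numpy()


def supply_window(date, tablets, tablets_per_day: float = 1.0,
                  adherence_buffer: float = 0.25) -> tuple[pd.Timestamp, pd.Timestamp]:
    """Half-open interval of days covered by one dispensation.

    Days supplied = tablets / tablets_per_day, inflated by the adherence
    buffer and rounded up (coverage-favouring), e.g. 100 tablets → 125 days,
    30 tablets → 38 days.
    """
    if tablets < 1:
        raise ValueError("tablets must be >= 1")
    days = math.ceil(tablets / tablets_per_day * (1.0 + adherence_buffer))
    start = pd.Timestamp(date)
    return start, start + pd.Timedelta(days=days)


@dataclass
class ExposureGrid:
    """Person × month × therapy exposure booleans plus an at-risk mask.

    ``treated[therapy]`` and ``at_risk`` are (n_units, 25) boolean arrays on
    the month grid −12..+12; a unit is one panel row (a control matched to
    two cases appears twice, once per index date).
    """

    units: pd.DataFrame                   # person_id, index_date, follow_up_end
    months: np.ndarray
    treated: dict[str, np.ndarray]
    at_risk: np.ndarray

    def any_therapy(self) -> np.ndarray:
        out = np.zeros_like(self.at_risk)
        for arr in self.treated.values():
            out |= arr
        return out


def monthly_exposure(panel: pd.DataFrame, tables: EventTables, codebook: Codebook,
                     tablets_per_day: float = 1.0,
                     adherence_buffer: float = 0.25) -> ExposureGrid:
    """Build the exposure grid for a panel (person_id, index_date, follow_up_end)."""
    units = panel.reset_index(drop=True)
    n = len(units)
    idx_ord = _month_ord(units["index_date"])
    fue_ord = _month_ord(units["follow_up_end"])
    # at risk while the month starts on/before the follow-up end
    max_m = fue_ord - idx_ord
    at_risk = MONTHS[None, :] <= np.minimum(max_m, 12)[:, None]
    treated = {t: np.zeros((n, len(MONTHS)), dtype=bool) for t in THERAPIES}

    lookup = units[["person_id"]].reset_index(names="unit")

    disp = tables.dispensations
    if len(disp):
        ad_mask = disp["atc"].map(codebook["antidepressant"].matches)
        addon_mask = codebook.addon_mask(disp["atc"], disp["daily_dose_mg"]) & ~ad_mask
        for mask, therapy in ((ad_mask, "ad"), (addon_mask, "addon")):
            sub = disp.loc[mask, ["person_id", "date", "tablets"]]
            if sub.empty:
                continue
            m = sub.merge(lookup, on="person_id")
            if m.empty:
                continue
            days = np.ceil(m["tablets"].to_numpy() / tablets_per_day
                           * (1.0 + adherence_buffer)).astype(int)
            last_day = pd.DatetimeIndex(m["date"]) + pd.to_timedelta(days - 1, unit="D")
            m0 = _month_ord(m["date"]) - idx_ord[m["unit"].to_numpy()]
            m1 = _month_ord(last_day) - idx_ord[m["unit"].to_numpy()]
            _mark(treated[therapy], m["unit"].to_numpy(), m0, m1)

    proc = tables.procedures
    if len(proc):
        m = proc.merge(lookup, on="person_id")
        if not m.empty:
            mo = _month_ord(m["date"]) - idx_ord[m["unit"].to_numpy()]
            for therapy in ("ECT", "rTMS", "psychotherapy"):
                sel = (m["source"] == therapy).to_numpy() if "source" in m.columns \
                    else (m["procedure"] == therapy).to_numpy()
                _mark(treated[therapy], m.loc[sel, "unit"].to_numpy(),
                      mo[sel], mo[sel])

    for t in THERAPIES:
        treated[t] &= at_risk
    return ExposureGrid(units=units, months=MONTHS, treated=treated, at_risk=at_risk)


def _mark(grid: np.ndarray, unit: np.ndarray, m_from: np.ndarray, m_to: np.ndarray):
    """Set grid[unit, m] = True for m in [m_from, m_to] clipped to −12..+12."""
    lo = np.clip(m_from, -12, 13)
    hi = np.clip(m_to, -13, 12)
    span = hi - lo + 1
    keep = span > 0
    unit, lo, span = unit[keep], lo[keep], span[keep]
    rows = np.repeat(unit, span)
    cols = np.concatenate([np.arange(a, a + s) for a, s in zip(lo, span)]) + 12 \
        if len(lo) else np.array([], dtype=int)
    grid[rows, cols] = True


def proportion_series(grid: ExposureGrid, mode: str = "point",
                      denominator: str | None = None) -> pd.DataFrame:
    """Per-month treated proportions for each therapy and for any therapy.

    ``point``: treated that month / denominator.  ``cumulative``: treated in
    any month up to and including this one (carried forward even after
    stopping).  ``denominator`` is ``'at_risk'`` (drops censored persons) or
    ``'fixed'`` (everyone); the default is at-risk for the point series and
    fixed for the cumulative one, which keeps the cumulative curve monotone
    by construction.
    """
    if mode not in ("point", "cumulative"):
        raise ValueError("mode must be 'point' or 'cumulative'")
    if denominator is None:
        denominator = "at_risk" if mode == "point" else "fixed"
    if denominator not in ("at_risk", "fixed"):
        raise ValueError("denominator must be 'at_risk' or 'fixed'")
    rows = []
    series = dict(grid.treated)
    series["any"] = grid.any_therapy()
    n_units = grid.at_risk.shape[0]
    for therapy, arr in series.items():
        use = np.maximum.accumulate(arr, axis=1) if mode == "cumulative" else arr
        if denominator == "at_risk":
            use = use & grid.at_risk
            n_risk = grid.at_risk.sum(axis=0)
        else:
            n_risk = np.full(len(grid.months), n_units)
        n_treat = use.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            prop = np.where(n_risk > 0, n_treat / np.maximum(n_risk, 1), 0.0)
        for m, p, nr, nt in zip(grid.months, prop, n_risk, n_treat):
            rows.append({"month": int(m), "therapy": therapy, "mode": mode,
                         "proportion": float(p), "n_at_risk": int(nr),
                         "n_treated": int(nt)})
    return pd.DataFrame(rows)


def comorbidity_series(panel: pd.DataFrame, tables: EventTables, codebook: Codebook,
                       conditions=PSYCHIATRIC_COMORBIDITIES,
                       lookback_years: float = 5.0) -> pd.DataFrame:
    """Cumulative per-month proportion with each comorbid condition.

    A person counts from month ``max(-12, month of first qualifying
    diagnosis)`` onward; qualifying diagnoses are dated within
    ``lookback_years`` before index through the end of month +12.  Older
    diagnoses never qualify, so the month 0 value matches a baseline table
    built with the same lookback.
    """
    units = panel.reset_index(drop=True)
    n = len(units)
    idx_ord = _month_ord(units["index_date"])
    fue_ord = _month_ord(units["follow_up_end"])
    at_risk = MONTHS[None, :] <= np.minimum(fue_ord - idx_ord, 12)[:, None]
    lookup = units[["person_id", "index_date"]].reset_index(names="unit")
    lookback = pd.Timedelta(days=round(lookback_years * 365.25))
    dx = tables.diagnoses
    rows = []
    for cond in conditions:
        first_m = np.full(n, 99, dtype=int)
        if len(dx):
            sub = dx[dx["icd10"].map(codebook[cond].matches)]
            m = sub.merge(lookup, on="person_id")
            if len(m):
                mo = _month_ord(m["date"]) - idx_ord[m["unit"].to_numpy()]
                ok = (m["date"] >= m["index_date"] - lookback).to_numpy() & (mo <= 12)
                mo = np.maximum(mo, -12)
                sel = m.loc[ok, "unit"].to_numpy()
                np.minimum.at(first_m, sel, mo[ok])
        counted = first_m[:, None] <= MONTHS[None, :]
        counted &= at_risk
        n_risk = at_risk.sum(axis=0)
        n_with = counted.sum(axis=0)
        for mth, nw, nr in zip(MONTHS, n_with, n_risk):
            rows.append({"month": int(mth), "condition": cond,
                         "proportion": float(nw / nr) if nr else 0.0,
                         "n_at_risk": int(nr), "n_with": int(nw)})
    return pd.DataFrame(rows)
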