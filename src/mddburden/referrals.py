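"""Care-level states at quarterly timepoints and the mobility (flow) table.

Each case is classified at 0, 3, 6, 9 and 12 months after index by the care
level of the most recent depression-related event on or before the timepoint
(the index diagnosis included); recorded psychiatric outpatient/inpatient
levels collapse to ``psychiatric``.  Pharmacy dispensations carry no care
level and therefore never change the state.  A case censored before a
timepoint is ``censored`` there and at every later timepoint.  The flow
table counts state transitions between consecutive timepoints — the numbers
behind an alluvial diagram — and summarizes the share of primary-care-onset
cases with any psychiatric MDD contact within the first year.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import care_group

TIMEPOINTS = (0, 3, 6, 9, 12)
#: quarterly offsets in days (3 months ≈ 91.25 d, rounded)
TIMEPOINT_DAYS = {0: 0, 3: 91, 6: 182, 9: 273, 12: 365}
STATES = ("primary", "psychiatric", "other", "censored")


def state_at(events: pd.DataFrame, timepoint_date, follow_up_end) -> str:
    """Care-level state of one person at one timepoint.

    ``events`` is the person's depressive-event frame (sorted); only events
    with a recorded care level (diagnoses and procedures) are considered.
    """
    timepoint_date = pd.Timestamp(timepoint_date)
    if pd.Timestamp(follow_up_end) < timepoint_date:
        return "censored"
    leveled = events[events["care_level"].notna() & (events["date"] <= timepoint_date)]
    if leveled.empty:
        raise ValueError("no leveled event on or before the timepoint "
                         "(the index diagnosis should always qualify)")
    return care_group(leveled["care_level"].iloc[-1])


def state_table(cohort: pd.DataFrame, events_all: pd.DataFrame,
                timepoint_days: dict[int, int] = TIMEPOINT_DAYS) -> pd.DataFrame:
    """States for every case at every timepoint: case_id × {0,3,6,9,12}."""
    # canonical order makes states independent of input record order; the
    # (date, event_class, source) key breaks same-day ties deterministically
    events_all = events_all.sort_values(
        ["person_id", "date", "event_class", "source", "care_level"],
        kind="mergesort")
    grouped = dict(tuple(events_all.groupby("person_id", sort=False)))
    rows = []
    for r in cohort.itertuples(index=False):
        ev = grouped.get(r.case_id)
        ev = ev[ev["date"] >= r.index_date] if ev is not None else None
        row = {"case_id": r.case_id, "care_level_at_index": r.care_level}
        for tp, dd in timepoint_days.items():
            date = r.index_date + pd.Timedelta(days=dd)
            if r.follow_up_end < date or ev is None:
                row[f"m{tp}"] = "censored"
            else:
                row[f"m{tp}"] = state_at(ev, date, r.follow_up_end)
        rows.append(row)
    return pd.DataFrame(rows)


def flow_table(states: pd.DataFrame,
               timepoints=TIMEPOINTS) -> pd.DataFrame:
    """Transition counts between consecutive timepoints.

    Totals are conserved: the row sums at each origin timepoint equal the
    state counts there, censored included.
    """
    rows = []
    for a, b in zip(timepoints[:-1], timepoints[1:]):
        counts = states.groupby([f"m{a}", f"m{b}"]).size()
        for (sa, sb), n in counts.items():
            rows.append({"t_from": a, "t_to": b, "state_from": sa,
                         "state_to": sb, "n": int(n)})
    return pd.DataFrame(rows, columns=["t_from", "t_to", "state_from", "state_to", "n"])


def primary_to_psychiatric_share(cohort: pd.DataFrame, events_all: pd.DataFrame,
                                 states: pd.DataFrame | None = None,
                                 within_days: int = 365,
                                 basis: str = "events") -> float:
    """Share of primary-care-onset cases reaching psychiatric care in year 1.

    ``basis='events'`` (default): any psychiatric-level depressive event in
    (index, index + within_days].  ``basis='states'``: state ``psychiatric``
    at any of the quarterly timepoints 3–12.
    """
    primary = cohort[cohort["care_level"] == "primary"]
    if not len(primary):
        raise ValueError("no primary-care-onset cases")
    if basis == "states":
        if states is None:
            states = state_table(cohort, events_all)
        sub = states[states["care_level_at_index"] == "primary"]
        hit = (sub[[f"m{t}" for t in (3, 6, 9, 12)]] == "psychiatric").any(axis=1)
        return float(hit.mean())
    if basis != "events":
        raise ValueError("basis must be 'events' or 'states'")
    ev = events_all[events_all["care_level"].isin(
        ["psychiatric_outpatient", "psychiatric_inpatient"])]
    merged = primary[["case_id", "index_date"]].merge(
        ev[["person_id", "date"]], left_on="case_id", right_on="person_id")
    within = (merged["date"] > merged["index_date"]) & \
        (merged["date"] <= merged["index_date"] + pd.Timedelta(days=within_days))
    hit_ids = set(merged.loc[within, "case_id"])
    return float(np.mean([cid in hit_ids for cid in primary["case_id"]]))


def referral_summary(cohort: pd.DataFrame, events_all: pd.DataFrame) -> dict:
    """States, flows and the primary→psychiatric share in one call."""
    states = state_table(cohort, events_all)
    flows = flow_table(states)
    share = primary_to_psychiatric_share(cohort, events_all, states)
    return {"states": states, "flows": flows,
            "primary_to_psychiatric_share": share}
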