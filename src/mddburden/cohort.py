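"""Incident-case identification, exclusions, matched-control sampling and
censoring.

A case is a person whose *first-ever* MDD diagnosis (ICD-10 F32/F33) falls
inside the inclusion window.  Cases with a history of psychosis, bipolar
disorder, mania or dementia on or before the index date, or with 12 months or
less of prior residency, are excluded.  Each retained case draws, with
replacement, one control from the stratum of same-sex, same-municipality
persons within two whole years of age who have no depression diagnosis,
intentional self-harm code or antidepressant dispensation anywhere in the
data window and who pass the case exclusions at the index date.  Follow-up
ends at the first of death, emigration, a post-index exclusion diagnosis, or
the end of data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .registry import Codebook, EventTables

EXCLUSION_SETS = ("psychosis", "mania", "bipolar", "dementia")
#: same-day tie-break for the care level of the first diagnosis
CARE_PRIORITY = {"psychiatric": 0, "primary": 1, "other": 2}


def care_group(level: str) -> str:
    """Collapse recorded care levels to primary / psychiatric / other."""
    if level in ("psychiatric_outpatient", "psychiatric_inpatient"):
        return "psychiatric"
    return level


@dataclass(frozen=True)
class IndexEvent:
    person_id: object
    index_date: pd.Timestamp
    care_level_at_index: str      # primary | psychiatric | other
    age_at_index: int
    sex: str
    municipality: str


@dataclass(frozen=True)
class CensorInfo:
    person_id: object
    follow_up_end: pd.Timestamp
    reason: str                   # death | emigration | exclusion_dx | end_of_data


def age_at(birth_date, date) -> int:
    """Whole years between birth and ``date`` (floor of days/365.25)."""
    return int((pd.Timestamp(date) - pd.Timestamp(birth_date)).days // 365.25)


# ---------------------------------------------------------------------------
# person-level lookups
# ---------------------------------------------------------------------------

def _merged_residency(residency: pd.DataFrame) -> dict:
    """person_id -> (starts, ends) arrays of merged half-open intervals."""
    out = {}
    for pid, grp in residency.sort_values(["person_id", "start"]).groupby("person_id"):
        starts, ends = [], []
        for s, e in zip(grp["start"], grp["end"]):
            if starts and s <= ends[-1]:          # touching intervals merge
                ends[-1] = max(ends[-1], e)
            else:
                starts.append(s)
                ends.append(e)
        out[pid] = (np.array(starts, dtype="datetime64[ns]"),
                    np.array(ends, dtype="datetime64[ns]"))
    return out


def _residency_covers(intervals, start, end) -> bool:
    """True iff one merged interval covers [start, end] (end inclusive)."""
    if intervals is None:
        return False
    starts, ends = intervals
    i = np.searchsorted(starts, np.datetime64(start), side="right") - 1
    if i < 0:
        return False
    return bool(starts[i] <= np.datetime64(start) and np.datetime64(end) < ends[i])


def _first_code_dates(diagnoses: pd.DataFrame, codebook: Codebook, set_names) -> pd.Series:
    """Per person, earliest diagnosis date matching any of the named sets."""
    if diagnoses.empty:
        return pd.Series(dtype="datetime64[ns]")
    mask = pd.Series(False, index=diagnoses.index)
    for name in set_names:
        mask |= diagnoses["icd10"].map(codebook[name].matches)
    sub = diagnoses[mask]
    return sub.groupby("person_id")["date"].min()


class PersonIndex:
    """Precomputed per-person facts needed for eligibility and censoring."""

    def __init__(self, tables: EventTables, codebook: Codebook):
        self.persons = tables.persons.set_index("person_id")
        self.residency = _merged_residency(tables.residency)
        self.first_exclusion = _first_code_dates(tables.diagnoses, codebook, EXCLUSION_SETS)
        self.first_depression = _first_code_dates(tables.diagnoses, codebook, ("mdd",))
        self.first_self_harm = _first_code_dates(tables.diagnoses, codebook, ("self_harm",))
        disp = tables.dispensations
        if len(disp):
            ad = disp[disp["atc"].map(codebook["antidepressant"].matches)]
            self.has_ad = set(ad["person_id"].unique())
        else:
            self.has_ad = set()

    def death_date(self, pid):
        try:
            return self.persons.at[pid, "death_date"]
        except KeyError:
            return pd.NaT


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def find_incident_cases(tables: EventTables, codebook: Codebook,
                        inclusion_window: tuple) -> list[IndexEvent]:
    """Persons whose first-ever MDD diagnosis falls inside the window.

    A first diagnosis outside the window (before it) makes the person
    non-incident, not merely shifted.  When the first day carries diagnoses
    at several care levels the psychiatric > primary > other tie-break picks
    the index care level (specialist recording assumed authoritative).
    """
    lo, hi = pd.Timestamp(inclusion_window[0]), pd.Timestamp(inclusion_window[1])
    dx = tables.diagnoses
    if dx.empty:
        return []
    mdd = dx[dx["icd10"].map(codebook["mdd"].matches)]
    if mdd.empty:
        return []
    firsts = mdd.groupby("person_id")["date"].min()
    persons = tables.persons.set_index("person_id")
    out = []
    for pid, d0 in firsts.items():
        if not (lo <= d0 < hi):
            continue
        same_day = mdd[(mdd["person_id"] == pid) & (mdd["date"] == d0)]
        levels = sorted({care_group(lv) for lv in same_day["care_level"]},
                        key=CARE_PRIORITY.get)
        try:
            prow = persons.loc[pid]
        except KeyError:
            continue
        out.append(IndexEvent(person_id=pid, index_date=d0,
                              care_level_at_index=levels[0],
                              age_at_index=age_at(prow["birth_date"], d0),
                              sex=prow["sex"], municipality=prow["municipality"]))
    out.sort(key=lambda e: (e.index_date, str(e.person_id)))
    return out


def apply_exclusions(cases: list[IndexEvent], tables: EventTables, codebook: Codebook,
                     pindex: PersonIndex | None = None,
                     washout_days: int = 365) -> list[IndexEvent]:
    """Drop cases with a prior exclusion diagnosis or too little prior residency.

    History means any exclusion code dated on or before the index; residency
    must continuously cover ``[index - washout_days, index]``.
    """
    pindex = pindex or PersonIndex(tables, codebook)
    kept = []
    for case in cases:
        excl = pindex.first_exclusion.get(case.person_id, pd.NaT)
        if pd.notna(excl) and excl <= case.index_date:
            continue
        start = case.index_date - pd.Timedelta(days=washout_days)
        if not _residency_covers(pindex.residency.get(case.person_id), start, case.index_date):
            continue
        kept.append(case)
    return kept


def eligible_control(person_id, index_date, tables: EventTables, codebook: Codebook,
                     pindex: PersonIndex | None = None, washout_days: int = 365) -> bool:
    """Control eligibility at a case's index date.

    Controls must be clean of depression, self-harm and antidepressant
    dispensations over the whole data window (not just before index), and
    must pass the case exclusions at the index date: no prior psychosis /
    bipolar / mania / dementia, more than 12 months of prior residency, and
    alive and resident at index.
    """
    pindex = pindex or PersonIndex(tables, codebook)
    index_date = pd.Timestamp(index_date)
    if person_id in pindex.has_ad:
        return False
    if pd.notna(pindex.first_depression.get(person_id, pd.NaT)):
        return False
    if pd.notna(pindex.first_self_harm.get(person_id, pd.NaT)):
        return False
    excl = pindex.first_exclusion.get(person_id, pd.NaT)
    if pd.notna(excl) and excl <= index_date:
        return False
    death = pindex.death_date(person_id)
    if pd.notna(death) and death <= index_date:
        return False
    start = index_date - pd.Timedelta(days=washout_days)
    return _residency_covers(pindex.residency.get(person_id), start, index_date)


def match_controls(cases: list[IndexEvent], tables: EventTables, codebook: Codebook,
                   seed: int, pindex: PersonIndex | None = None,
                   age_caliper: int = 2) -> pd.DataFrame:
    """Sample one control per case, with replacement, within the
    (sex, municipality, age ± caliper) stratum; seeded and reproducible.

    Returns a frame with columns ``case_id, control_id, index_date``;
    ``control_id`` is None when the stratum is empty (the case is kept).
    """
    pindex = pindex or PersonIndex(tables, codebook)
    rng = np.random.default_rng(seed)
    persons = tables.persons
    # pre-screen on the any-time rules, which do not depend on the index date
    never_dep = ~persons["person_id"].isin(pindex.first_depression.index)
    never_sh = ~persons["person_id"].isin(pindex.first_self_harm.index)
    never_ad = ~persons["person_id"].isin(pindex.has_ad)
    pool = persons[never_dep & never_sh & never_ad]
    by_stratum: dict[tuple, pd.DataFrame] = {
        key: grp for key, grp in pool.groupby(["sex", "municipality"], sort=True)}

    rows = []
    for case in cases:
        grp = by_stratum.get((case.sex, case.municipality))
        control = None
        if grp is not None:
            ages = (case.index_date - grp["birth_date"]).dt.days // 365.25
            cand = grp.loc[(ages - case.age_at_index).abs() <= age_caliper, "person_id"]
            cand = [c for c in cand if c != case.person_id
                    and eligible_control(c, case.index_date, tables, codebook, pindex)]
            if cand:
                control = cand[int(rng.integers(len(cand)))]
        rows.append({"case_id": case.person_id, "control_id": control,
                     "index_date": case.index_date})
    return pd.DataFrame(rows, columns=["case_id", "control_id", "index_date"])


#: earlier-in-list wins when several censoring events share the first date
_REASON_PRIORITY = ("death", "emigration", "exclusion_dx", "end_of_data")


def censor(person_id, index_date, tables: EventTables, codebook: Codebook,
           end_of_data, pindex: PersonIndex | None = None) -> CensorInfo:
    """Follow-up end: first of death, emigration, post-index exclusion
    diagnosis, or the administrative end of data."""
    pindex = pindex or PersonIndex(tables, codebook)
    index_date = pd.Timestamp(index_date)
    end_of_data = pd.Timestamp(end_of_data)
    candidates: dict[str, pd.Timestamp] = {"end_of_data": end_of_data}

    death = pindex.death_date(person_id)
    if pd.notna(death):
        candidates["death"] = pd.Timestamp(death)
    intervals = pindex.residency.get(person_id)
    if intervals is not None:
        starts, ends = intervals
        i = np.searchsorted(starts, np.datetime64(index_date), side="right") - 1
        if i >= 0 and np.datetime64(index_date) < ends[i]:
            res_end = pd.Timestamp(ends[i])
            if res_end < end_of_data:
                candidates["emigration"] = res_end
    excl = pindex.first_exclusion.get(person_id, pd.NaT)
    if pd.notna(excl) and excl > index_date:
        candidates["exclusion_dx"] = pd.Timestamp(excl)

    best_date = max(min(candidates.values()), index_date)
    for reason in _REASON_PRIORITY:
        d = candidates.get(reason)
        if d is not None and max(d, index_date) == best_date:
            return CensorInfo(person_id, best_date, reason)
    raise AssertionError("unreachable: end_of_data always present")


def build_cohort(tables: EventTables, codebook: Codebook, inclusion_window: tuple,
                 end_of_data, seed: int) -> pd.DataFrame:
    """Full cohort assembly: incident cases, exclusions, matching, censoring.

    One row per case: ``case_id, control_id, index_date, care_level, age, sex,
    municipality, follow_up_end, censor_reason, control_follow_up_end,
    control_censor_reason`` (control columns empty for unmatched cases).
    """
    pindex = PersonIndex(tables, codebook)
    cases = find_incident_cases(tables, codebook, inclusion_window)
    cases = apply_exclusions(cases, tables, codebook, pindex)
    pairs = match_controls(cases, tables, codebook, seed, pindex)
    rows = []
    for case, pair in zip(cases, pairs.itertuples(index=False)):
        ci = censor(case.person_id, case.index_date, tables, codebook, end_of_data, pindex)
        row = {"case_id": case.person_id, "control_id": pair.control_id,
               "index_date": case.index_date, "care_level": case.care_level_at_index,
               "age": case.age_at_index, "sex": case.sex,
               "municipality": case.municipality,
               "follow_up_end": ci.follow_up_end, "censor_reason": ci.reason,
               "control_follow_up_end": pd.NaT, "control_censor_reason": None}
        if pair.control_id is not None:
            cci = censor(pair.control_id, case.index_date, tables, codebook,
                         end_of_data, pindex)
            row["control_follow_up_end"] = cci.follow_up_end
            row["control_censor_reason"] = cci.reason
        rows.append(row)
    cols = ["case_id", "control_id", "index_date", "care_level", "age", "sex",
            "municipality", "follow_up_end", "censor_reason",
            "control_follow_up_end", "control_censor_reason"]
    return pd.DataFrame(rows, columns=cols)


def case_panel(cohort: pd.DataFrame) -> pd.DataFrame:
    """One row per case: person_id, index_date, follow_up_end, age, group."""
    out = cohort[["case_id", "index_date", "follow_up_end", "age", "care_level"]].copy()
    out = out.rename(columns={"case_id": "person_id"})
    out["group"] = "mdd"
    return out.reset_index(drop=True)


def control_panel(cohort: pd.DataFrame, persons: pd.DataFrame) -> pd.DataFrame:
    """One row per matched control occurrence (with-replacement sampling means
    a person may appear several times, once per matched case)."""
    sub = cohort[cohort["control_id"].notna()]
    out = sub[["control_id", "index_date", "control_follow_up_end"]].copy()
    out = out.rename(columns={"control_id": "person_id",
                              "control_follow_up_end": "follow_up_end"})
    birth = persons.set_index("person_id")["birth_date"]
    out["age"] = [age_at(birth[p], d) for p, d in zip(out["person_id"], out["index_date"])]
    out["care_level"] = None
    out["group"] = "control"
    return out.reset_index(drop=True)
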