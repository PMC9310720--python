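"""Treatment-episode construction from depressive-event streams, plus
Kaplan–Meier estimation of episode duration.

An MDD treatment episode is a proxy for the span of healthcare activity
related to depression.  Starting from the first-ever MDD diagnosis, events
(diagnoses, antidepressant or add-on dispensations, ECT/rTMS/psychotherapy)
are stitched into one episode as long as consecutive events are at most
``gap_days`` apart (365 days by default; 180 in the sensitivity variant).
A gap larger than ``gap_days`` closes the episode at the last event; if that
last event was a dispensation, the episode end is extended by the number of
dispensed tablets at one tablet per day, capped at ``extension_cap_days``
(100).  After closure only a new MDD *diagnosis* — not a dispensation or
procedure — opens the next episode.  An episode whose last event lies within
``gap_days`` of the end of data cannot be distinguished from an ongoing one
and is flagged ``open_at_data_end``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.utils import median_survival_times


@dataclass(frozen=True)
class EpisodeParams:
    """Tuning knobs of the stitching algorithm.

    gap_days            maximum allowed event-to-event interval inside an episode
                        (365 d default; 180 d sensitivity variant)
    extension_cap_days  cap on the supply-based extension after a terminal
                        dispensation (100 d)
    tablets_per_day     tablets assumed consumed per day (1; converts a tablet
                        count into days of supply)
    extended_gap_checks if True, gap checks measure from the supply-extended
                        end of a dispensation rather than its fill date
                        (non-default variant; the literal reading uses raw
                        event dates)
    """

    gap_days: int = 365
    extension_cap_days: int = 100
    tablets_per_day: float = 1.0
    extended_gap_checks: bool = False

    def __post_init__(self):
        if self.gap_days <= 0 or self.extension_cap_days <= 0 or self.tablets_per_day <= 0:
            raise ValueError("gap_days, extension_cap_days and tablets_per_day must be positive")

    def supply_days(self, tablets: float) -> int:
        return int(math.ceil(tablets / self.tablets_per_day))


@dataclass(frozen=True)
class Episode:
    person_id: object
    ordinal: int            # 1 = the incident episode
    start_date: pd.Timestamp
    end_date: pd.Timestamp
    closure: str            # gap | extension_after_gap | open_at_data_end
    n_events: int


@dataclass(frozen=True)
class _DayEvent:
    """Same-day events collapsed to one record for the gap logic."""
    date: pd.Timestamp
    has_diagnosis: bool
    tablets: float | None   # largest same-day dispensation, if any


def _collapse_days(events: pd.DataFrame) -> list[_DayEvent]:
    out: list[_DayEvent] = []
    for date, grp in events.groupby("date", sort=True):
        is_disp = grp["event_class"] == "dispensation"
        tablets = float(grp.loc[is_disp, "tablets"].max()) if is_disp.any() else None
        out.append(_DayEvent(date=date,
                             has_diagnosis=bool((grp["event_class"] == "diagnosis").any()),
                             tablets=tablets))
    return out


def build_episodes(events: pd.DataFrame, first_dx_date, params: EpisodeParams,
                   data_end) -> list[Episode]:
    """Stitch one person's depressive events into ordered, disjoint episodes.

    ``events`` is a sorted frame as produced by
    :func:`mddburden.registry.depressive_events`; its first event must be the
    first-ever MDD diagnosis (the index date).  ``data_end`` is the last date
    with data coverage, used to flag episodes that cannot be closed yet.
    """
    if events is None or len(events) == 0:
        raise ValueError("no depressive events: cannot build episodes without an index diagnosis")
    first_dx_date = pd.Timestamp(first_dx_date)
    data_end = pd.Timestamp(data_end)
    person_id = events["person_id"].iloc[0] if "person_id" in events.columns else None
    days = _collapse_days(events)
    if days[0].date != first_dx_date or not days[0].has_diagnosis:
        raise ValueError("event stream must start with the first MDD diagnosis")

    G = pd.Timedelta(days=params.gap_days)
    episodes: list[Episode] = []

    def effective_end(ev: _DayEvent) -> pd.Timestamp:
        """Date from which the next gap is measured (raw by default)."""
        if params.extended_gap_checks and ev.tablets is not None:
            ext = min(params.supply_days(ev.tablets), params.extension_cap_days)
            return ev.date + pd.Timedelta(days=ext)
        return ev.date

    def close(start: pd.Timestamp, last: _DayEvent, n: int, reason: str) -> Episode:
        end = last.date
        closure = reason
        if reason == "gap" and last.tablets is not None:
            ext = min(params.supply_days(last.tablets), params.extension_cap_days)
            end = end + pd.Timedelta(days=ext)
            closure = "extension_after_gap"
        return Episode(person_id, len(episodes) + 1, start, min(end, data_end), closure, n)

    in_episode = True
    start, last, n_events = days[0].date, days[0], 1
    for ev in days[1:]:
        if in_episode:
            if ev.date - effective_end(last) <= G:
                last, n_events = ev, n_events + 1
            else:
                episodes.append(close(start, last, n_events, "gap"))
                in_episode = False
        if not in_episode and ev.has_diagnosis:
            in_episode, start, last, n_events = True, ev.date, ev, 1
    if in_episode:
        if data_end - effective_end(last) <= G:
            episodes.append(close(start, last, n_events, "open_at_data_end"))
        else:
            episodes.append(close(start, last, n_events, "gap"))
    return episodes


def episodes_frame(episodes: list[Episode]) -> pd.DataFrame:
    rows = [{"person_id": e.person_id, "ordinal": e.ordinal,
             "start": e.start_date, "end": e.end_date, "closure": e.closure,
             "n_events": e.n_events,
             "duration_days": int((e.end_date - e.start_date).days)}
            for e in episodes]
    cols = ["person_id", "ordinal", "start", "end", "closure", "n_events", "duration_days"]
    return pd.DataFrame(rows, columns=cols)


def episode_durations(episodes: list[Episode], follow_up_end,
                      min_follow_up_days: int = 365) -> tuple[float, bool] | None:
    """Duration of the incident (ordinal-1) episode for the KM analysis.

    Returns ``(duration_days, observed)`` or ``None`` when the person has
    less than ``min_follow_up_days`` of follow-up after the index and is
    excluded from the duration analysis.  The duration is censored
    (``observed=False``) when the episode is still open at the end of data or
    when censoring cuts it short.
    """
    if not episodes:
        return None
    ep = episodes[0]
    follow_up_end = pd.Timestamp(follow_up_end)
    if (follow_up_end - ep.start_date).days < min_follow_up_days:
        return None
    if ep.closure == "open_at_data_end" or follow_up_end < ep.end_date:
        return (float((min(follow_up_end, ep.end_date) - ep.start_date).days), False)
    return (float((ep.end_date - ep.start_date).days), True)


@dataclass(frozen=True)
class KMEstimate:
    """Product-limit estimate of episode duration with a log-log median CI."""
    times: np.ndarray
    survival: np.ndarray
    n_risk: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    median: float            # smallest t with S(t) <= 0.5; inf if not reached
    median_ci: tuple[float, float]
    n: int

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t": self.times, "S": self.survival, "n_risk": self.n_risk,
                             "ci_low": self.ci_low, "ci_high": self.ci_high})


def km_fit(durations, observed) -> KMEstimate:
    """Kaplan–Meier fit of episode durations (Greenwood variance, log-log
    pointwise bands, Brookmeyer–Crowley-style median CI)."""
    durations = np.asarray(durations, dtype=float)
    observed = np.asarray(observed, dtype=bool)
    if durations.size == 0:
        raise ValueError("km_fit requires at least one duration")
    kmf = KaplanMeierFitter()
    kmf.fit(durations, event_observed=observed)
    sf = kmf.survival_function_
    ci = kmf.confidence_interval_
    times = sf.index.to_numpy(dtype=float)
    surv = sf.iloc[:, 0].to_numpy()
    # event table gives at-risk counts on the same grid
    n_risk = kmf.event_table["at_risk"].reindex(sf.index).ffill().to_numpy(dtype=float)
    med = kmf.median_survival_time_
    med_ci_df = median_survival_times(ci)
    lo, hi = float(med_ci_df.iloc[0, 0]), float(med_ci_df.iloc[0, 1])
    return KMEstimate(times=times, survival=surv, n_risk=n_risk,
                      ci_low=ci.iloc[:, 0].to_numpy(), ci_high=ci.iloc[:, 1].to_numpy(),
                      median=float(med), median_ci=(lo, hi), n=int(durations.size))


def cohort_episodes(events_all: pd.DataFrame, cohort: pd.DataFrame,
                    params: EpisodeParams, data_end) -> pd.DataFrame:
    """Build episodes for every case in a cohort frame.

    ``cohort`` needs columns ``case_id`` and ``index_date``; ``events_all`` is
    the pooled output of :func:`mddburden.registry.depressive_events_all`.
    Events before the index date (prior dispensations, psychotherapy for other
    indications) do not belong to the incident episode and are dropped.
    """
    grouped = dict(tuple(events_all.groupby("person_id", sort=False)))
    frames = []
    for row in cohort.itertuples(index=False):
        ev = grouped.get(row.case_id)
        if ev is None:
            continue
        ev = ev[ev["date"] >= row.index_date]
        if len(ev) == 0:
            continue
        eps = build_episodes(ev, row.index_date, params, data_end)
        frames.append(episodes_frame(eps))
    if not frames:
        return episodes_frame([])
    return pd.concat(frames, ignore_index=True)
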