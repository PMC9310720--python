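"""Independent brute-force oracles used to cross-check the implementation.

The episode oracle reconstructs episode boundaries by flood-filling a day
grid (mark every day within G of an already-included event, starting from
the index) instead of the sequential scan the package uses.
"""

import numpy as np
import pandas as pd

BASE = pd.Timestamp("2012-01-01")


def day_events_frame(stream, person_id="X"):
    """Build a depressive-event frame from (day, kind, tablets) tuples.

    kind: 'dx' | 'disp' | 'proc'.
    """
    rows = []
    for day, kind, tablets in stream:
        rows.append({
            "person_id": person_id, "date": BASE + pd.Timedelta(days=day),
            "event_class": {"dx": "diagnosis", "disp": "dispensation",
                            "proc": "procedure"}[kind],
            "source": {"dx": "mdd_dx", "disp": "ad", "proc": "psychotherapy"}[kind],
            "care_level": None if kind == "disp" else "primary",
            "tablets": float(tablets) if kind == "disp" else np.nan})
    cols = ["person_id", "date", "event_class", "source", "care_level", "tablets"]
    if not rows:
        return pd.DataFrame(columns=cols)
    df = pd.DataFrame(rows)[cols].sort_values(["date", "event_class"], kind="mergesort")
    return df.reset_index(drop=True)


def daygrid_episodes(stream, gap_days, data_end_day, cap=100):
    """Flood-fill oracle: returns [(start_day, end_day, closure), ...]."""
    # collapse to day level: any diagnosis, max dispensed tablets
    days = {}
    for day, kind, tablets in stream:
        has_dx, tab = days.get(day, (False, None))
        if kind == "dx":
            has_dx = True
        if kind == "disp":
            tab = max(tab or 0, tablets)
        days[day] = (has_dx, tab)
    event_days = sorted(days)
    grid_len = max(event_days) + gap_days + 2
    episodes = []
    i = 0
    while i < len(event_days):
        start = event_days[i]
        if episodes and not days[start][0]:
            i += 1            # between episodes only a diagnosis can start one
            continue
        reach = np.zeros(grid_len + gap_days + 2, dtype=bool)
        reach[start:start + gap_days + 1] = True
        last = start
        j = i
        while j < len(event_days):
            e = event_days[j]
            if reach[e]:
                last = max(last, e)
                reach[e:e + gap_days + 1] = True
                j += 1
            elif e <= last:
                j += 1
            else:
                break
        has_dx, tab = days[last]
        if data_end_day - last <= gap_days:
            closure = "open_at_data_end"
            end = last
        else:
            closure = "gap"
            end = last
            if tab is not None:
                end = last + min(int(tab), cap)
                closure = "extension_after_gap"
        episodes.append((start, min(end, data_end_day), closure))
        i = j
    return episodes


def random_stream(rng, max_events=15, max_gap=500, max_tablets=150):
    """Random depressive-event stream starting with the index diagnosis."""
    n = int(rng.integers(1, max_events + 1))
    stream = [(0, "dx", None)]
    day = 0
    for _ in range(n - 1):
        day += int(rng.integers(0, max_gap + 1))
        kind = rng.choice(["dx", "disp", "proc"], p=[0.5, 0.3, 0.2])
        tablets = int(rng.integers(1, max_tablets + 1)) if kind == "disp" else None
        stream.append((day, kind, tablets))
    data_end = day + int(rng.integers(0, 600))
    return stream, data_end
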