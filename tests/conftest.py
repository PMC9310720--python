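import numpy as np
import pandas as pd
import pytest

import mddburden as mb
from mddburden.registry import SCHEMAS, empty_tables


@pytest.fixture(scope="session")
def codebook():
    return mb.default_codebook()


def make_tables(**rows) -> mb.EventTables:
    """Build a small EventTables from lists of dicts, filling typed defaults."""
    base = empty_tables()
    frames = {}
    for name in SCHEMAS:
        recs = rows.get(name, [])
        if not recs:
            frames[name] = base.table(name)
            continue
        df = pd.DataFrame(recs)
        for col in SCHEMAS[name]:
            if col not in df.columns:
                df[col] = None
        df = df[SCHEMAS[name]]
        for col in df.columns:
            if col in ("birth_date", "death_date", "date", "start", "end",
                       "admission_date", "discharge_date"):
                df[col] = pd.to_datetime(df[col])
        if name == "dispensations":
            df["tablets"] = df["tablets"].fillna(100).astype(int)
            df["daily_dose_mg"] = pd.to_numeric(df["daily_dose_mg"], errors="coerce")
        if name == "workloss":
            df["extent"] = pd.to_numeric(df["extent"]).fillna(1.0)
        if name == "visits":
            df["physician"] = df["physician"].fillna(True).astype(bool)
        frames[name] = df
    return mb.EventTables(**frames)


@pytest.fixture
def tables_factory():
    return make_tables


def person(pid="P1", sex="F", birth="1980-01-01", muni="M01", death=None,
           res=("2010-01-01", "2019-01-01")):
    """Convenience: one person plus one residency interval."""
    return ({"person_id": pid, "sex": sex, "birth_date": birth,
             "municipality": muni, "death_date": death},
            {"person_id": pid, "start": res[0], "end": res[1]})


@pytest.fixture(scope="session")
def sim_small():
    """A shared mid-size simulated registry with its cohort and events."""
    cfg = mb.SimConfig(seed=2, n_persons=4000)
    tables, truth = mb.generate(cfg)
    cb = mb.default_codebook()
    coh = mb.build_cohort(tables, cb, cfg.inclusion_window, "2018-12-31", seed=2)
    events = mb.depressive_events_all(tables, cb)
    return {"config": cfg, "tables": tables, "truth": truth, "cohort": coh,
            "events": events, "codebook": cb}


@pytest.fixture(scope="session")
def sim_large():
    """A 20k-person registry for law-of-large-numbers checks."""
    cfg = mb.SimConfig(seed=5, n_persons=20000)
    tables, truth = mb.generate(cfg)
    cb = mb.default_codebook()
    coh = mb.build_cohort(tables, cb, cfg.inclusion_window, "2018-12-31", seed=5)
    events = mb.depressive_events_all(tables, cb)
    return {"config": cfg, "tables": tables, "truth": truth, "cohort": coh,
            "events": events, "codebook": cb}
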