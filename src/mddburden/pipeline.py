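"""End-to-end orchestration: simulate → cohort → episodes → trajectories →
burden → mortality → referrals, with a manifest of seeds, row counts and
content hashes for reproducibility checks."""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .registry import Codebook, EventTables, default_codebook, load_tables, write_tables
from .registry import depressive_events_all
from .simulate import SimConfig, generate, truth_report
from .cohort import build_cohort, case_panel, control_panel
from .episodes import EpisodeParams, cohort_episodes, km_fit
from .trajectories import monthly_exposure, proportion_series, comorbidity_series
from .burden import annual_burden_table, monthly_hru, monthly_workloss, ratio_table
from .mortality import mortality_analysis
from .referrals import referral_summary

ALL_STAGES = ("simulate", "cohort", "episodes", "trajectories", "burden",
              "mortality", "referrals")


@dataclass
class RunConfig:
    out_dir: str = "out"
    seed: int = 0
    sim: dict = field(default_factory=dict)          # SimConfig overrides
    codebook: str | None = None                      # YAML path; default codebook if None
    inclusion_window: tuple[str, str] = ("2012-01-01", "2019-01-01")
    end_of_data: str = "2018-12-31"
    gap_days: int = 365
    stages: tuple = ALL_STAGES

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**doc)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> Path:
    out = df.copy()
    for c in out.columns:
        if pd.api.types.is_datetime64_any_dtype(out[c]):
            out[c] = out[c].dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False, lineterminator="\n")
    return path


def _write_json(obj, path: Path) -> Path:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
    return path


def _read_cohort(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for c in ("index_date", "follow_up_end", "control_follow_up_end"):
        df[c] = pd.to_datetime(df[c])
    df["control_id"] = df["control_id"].where(df["control_id"].notna(), None)
    return df


def run_all(config: RunConfig) -> dict:
    """Execute the enabled stages in dependency order; returns the manifest.

    Every output is a deterministic function of the config and seed, so two
    runs with identical settings produce byte-identical files.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if config.codebook is not None and not Path(config.codebook).exists():
        raise FileNotFoundError(f"codebook file not found: {config.codebook}")
    codebook = Codebook.from_yaml(config.codebook) if config.codebook \
        else default_codebook()
    manifest: dict = {"version": __version__, "seed": config.seed,
                      "stages": list(config.stages), "outputs": {}, "wall_time_s": {}}
    outputs: dict[str, Path] = {}

    def record(name: str, path: Path, t0: float):
        outputs[name] = path
        manifest["wall_time_s"][name] = round(time.perf_counter() - t0, 3)

    tables: EventTables | None = None
    truth = cohort = events_all = episodes = None

    if "simulate" in config.stages:
        t0 = time.perf_counter()
        sim_cfg = SimConfig(**{"seed": config.seed,
                               "inclusion_window": config.inclusion_window,
                               **config.sim})
        tables, truth = generate(sim_cfg)
        data_dir = out_dir / "data"
        write_tables(tables, data_dir)
        truth_report(truth, data_dir / "truth.csv")
        record("data", data_dir / "persons.csv", t0)
        manifest["n_persons"] = int(len(tables.persons))
    else:
        tables = load_tables(out_dir / "data")

    def ensure_cohort():
        nonlocal cohort, events_all
        if cohort is None:
            cohort = _read_cohort(out_dir / "cohort.csv")
        if events_all is None:
            events_all = depressive_events_all(tables, codebook)

    if "cohort" in config.stages:
        t0 = time.perf_counter()
        cohort = build_cohort(tables, codebook, config.inclusion_window,
                              config.end_of_data, seed=config.seed)
        record("cohort", _write_csv(cohort, out_dir / "cohort.csv"), t0)
        events_all = depressive_events_all(tables, codebook)

    if "episodes" in config.stages:
        t0 = time.perf_counter()
        ensure_cohort()
        params = EpisodeParams(gap_days=config.gap_days)
        episodes = cohort_episodes(events_all, cohort, params, config.end_of_data)
        record("episodes", _write_csv(episodes, out_dir / "episodes.csv"), t0)
        t0 = time.perf_counter()
        durations = _km_input(episodes, cohort)
        if len(durations):
            km = km_fit(durations["duration"], durations["observed"])
            _write_csv(km.frame(), out_dir / "km.csv")
            _write_json({"median_days": km.median, "median_ci95": list(km.median_ci),
                         "n": km.n}, out_dir / "km_summary.json")
            record("km", out_dir / "km.csv", t0)

    panels = None

    def ensure_panels():
        nonlocal panels
        ensure_cohort()
        if panels is None:
            panels = {"mdd": case_panel(cohort),
                      "control": control_panel(cohort, tables.persons)}

    if "trajectories" in config.stages:
        t0 = time.perf_counter()
        ensure_panels()
        grid = monthly_exposure(panels["mdd"], tables, codebook)
        _write_csv(proportion_series(grid, "point"), out_dir / "exposure_point.csv")
        _write_csv(proportion_series(grid, "cumulative"), out_dir / "exposure_cum.csv")
        _write_csv(comorbidity_series(panels["mdd"], tables, codebook),
                   out_dir / "comorbidity_cum.csv")
        record("trajectories", out_dir / "exposure_point.csv", t0)

    if "burden" in config.stages:
        t0 = time.perf_counter()
        ensure_panels()
        hru = pd.concat([monthly_hru(p, tables).assign(group=g)
                         for g, p in panels.items()], ignore_index=True)
        _write_csv(hru, out_dir / "monthly_hru.csv")
        wloss = pd.concat([monthly_workloss(p, tables).assign(group=g)
                           for g, p in panels.items()], ignore_index=True)
        _write_csv(wloss, out_dir / "monthly_workloss.csv")
        table2 = annual_burden_table(panels, tables)
        _write_csv(table2, out_dir / "table2.csv")
        _write_csv(ratio_table(table2), out_dir / "ratios.csv")
        record("burden", out_dir / "table2.csv", t0)

    if "mortality" in config.stages:
        t0 = time.perf_counter()
        ensure_cohort()
        result = mortality_analysis(cohort)
        record("mortality", _write_json(result, out_dir / "cox.json"), t0)

    if "referrals" in config.stages:
        t0 = time.perf_counter()
        ensure_cohort()
        summary = referral_summary(cohort, events_all)
        _write_csv(summary["flows"], out_dir / "flows.csv")
        _write_json({"primary_to_psychiatric_share":
                     summary["primary_to_psychiatric_share"]},
                    out_dir / "referral_summary.json")
        record("referrals", out_dir / "flows.csv", t0)

    for name, path in outputs.items():
        manifest["outputs"][name] = {"path": str(path.relative_to(out_dir)),
                                     "sha256": _sha256(path)}
    # hash every file in the output tree for the determinism contract
    manifest["files"] = {
        str(p.relative_to(out_dir)): _sha256(p)
        for p in sorted(out_dir.rglob("*"))
        if p.is_file() and p.name != "manifest.json"}
    _write_json(manifest, out_dir / "manifest.json")
    return manifest


def _km_input(episodes: pd.DataFrame, cohort: pd.DataFrame,
              min_follow_up_days: int = 365) -> pd.DataFrame:
    """Incident-episode durations for the KM analysis (≥1 y of follow-up)."""
    ep1 = episodes[episodes["ordinal"] == 1].merge(
        cohort[["case_id", "index_date", "follow_up_end"]],
        left_on="person_id", right_on="case_id")
    fup = (ep1["follow_up_end"] - ep1["index_date"]).dt.days
    ep1 = ep1[fup >= min_follow_up_days]
    open_ = (ep1["closure"] == "open_at_data_end") | (ep1["follow_up_end"] < ep1["end"])
    end = ep1[["end", "follow_up_end"]].min(axis=1)
    return pd.DataFrame({"person_id": ep1["person_id"],
                         "duration": (end - ep1["start"]).dt.days.astype(float),
                         "observed": ~open_})
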