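"""Synthetic registry generator.

Emulates the structure of a regional healthcare data warehouse linked to
social-insurance registries: per-person demographics, residency intervals,
ICD-10 diagnosis events with care levels, ATC dispensations with tablet
counts, neurostimulation/psychotherapy procedures, outpatient physician
visits, inpatient stays and work-loss spells over a configurable calendar
window.  A latent disease process drives everything: each person may have one
or two true depressive episodes; the episode interval generates diagnosis,
dispensation and procedure streams, elevated healthcare use, work loss and an
elevated mortality hazard, so every downstream estimator has a known ground
truth to recover.

Determinism: one master seed; each person draws from an independent
substream keyed by ``(seed, person_index)``, so enlarging the population
leaves existing persons' records unchanged.

The generator targets the *structure* of registry data plus configurable
marginals (onset rate, sex split of cases, care-level mix at onset, episode
duration distribution, mortality hazard ratio, utilization rates); it makes
no attempt to reproduce any particular region's joint distributions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .registry import EventTables, SCHEMAS

DAY = pd.Timedelta(days=1)


def _lognormal_from_median(rng, median, sigma, size=None):
    return np.exp(np.log(median) + sigma * rng.standard_normal(size))


@dataclass
class SimConfig:
    """Knobs of the synthetic registry.

    Rates are per person-year unless noted.  Defaults mirror the incident-MDD
    study population this package targets: onset rate ≈ 0.82%/yr (≈137.8k
    cases out of 2.4M over 7 years), 63.2% of cases female, onset care-level
    mix 68.2/27.3/4.6% primary/psychiatric/other, true episode duration
    log-normal with median 398 days, case mortality log-hazard-ratio
    log(2.2) over a baseline of 5.4 deaths/1000 person-years (pooling cases
    and controls at HR 2.2 yields ≈8.6/1000).
    """

    seed: int = 0
    n_persons: int = 10_000
    window: tuple[str, str] = ("2010-01-01", "2019-01-01")
    inclusion_window: tuple[str, str] = ("2012-01-01", "2019-01-01")
    n_municipalities: int = 10

    # demographics
    age_mean: float = 41.3
    age_sd: float = 19.4
    age_min: float = 5.0
    age_max: float = 95.0
    late_entry_fraction: float = 0.05      # residency starts after window start
    emigration_rate: float = 0.012

    # disease process
    annual_mdd_onset_rate: float = 0.0082
    sex_ratio_cases: float = 0.632         # fraction of cases female
    care_level_mix: dict = field(default_factory=lambda: {
        "primary": 0.682, "psychiatric": 0.273, "other": 0.046})
    episode_median_days: float = 398.0
    episode_sigma: float = 0.7
    recurrence_prob: float = 0.3
    recurrence_gap_min_days: int = 400     # keeps true episodes separable at G=365
    recurrence_gap_mean_days: float = 300.0
    max_event_gap_days: int = 300          # cap on in-episode event spacing
    dx_interval_days: float = 120.0        # renewal mean for repeat MDD diagnoses

    # therapy during the episode
    treatment_propensities: dict = field(default_factory=lambda: {
        "ad": 0.85, "addon": 0.02, "ECT": 0.005, "rTMS": 0.003, "psychotherapy": 0.25})
    dispensation_interval_days: float = 90.0
    tablets_per_fill: int = 100
    prior_ad_propensity: float = 0.262     # AD use in the year before onset
    prior_psychotherapy_propensity: float = 0.069
    background_ad_rate: float = 0.02       # non-cases ever using ADs (ineligible controls)
    index_treatment_propensity: float = 0.646  # treated in the index month itself
    referral_propensity: float = 0.138     # primary-onset cases with a psychiatric
                                           # MDD contact within year one

    # comorbidity (5-year pre-onset ramp for cases; flat background otherwise);
    # ramp density rises toward onset as (1 - back/5y)^power, so cumulative
    # recorded prevalence roughly doubles over the final pre-index year at the
    # default power of 2
    comorbidity_ramp_power: float = 2.0
    case_comorbidity_prev: dict = field(default_factory=lambda: {
        "anxiety": 0.269, "stress": 0.215, "sleep": 0.146, "substance": 0.035,
        "alcohol": 0.046, "ocd": 0.016, "hyperkinetic": 0.039, "autism": 0.014,
        "personality": 0.008, "self_harm": 0.014,
        "hypertension": 0.153, "diabetes_t2": 0.041, "hypothyroidism": 0.055,
        "ibd": 0.010, "ra": 0.007, "cardiovascular": 0.078})
    background_comorbidity_rate: dict = field(default_factory=lambda: {
        "anxiety": 0.005, "stress": 0.007, "sleep": 0.006, "substance": 0.003,
        "alcohol": 0.002, "ocd": 0.0003, "hyperkinetic": 0.002, "autism": 0.0006,
        "personality": 0.0001, "hypertension": 0.025, "diabetes_t2": 0.006,
        "hypothyroidism": 0.008, "ibd": 0.0015, "ra": 0.001, "cardiovascular": 0.010})

    # mortality
    baseline_mortality_rate: float = 5.4   # per 1000 person-years
    case_log_hr: float = math.log(2.2)

    # utilization
    visit_rate_control: float = 2.5        # physician visits / yr
    visit_rate_case_extra: float = 5.4     # additional, during the episode
    admission_rate_control: float = 0.055
    los_median_days: float = 6.0
    los_sigma: float = 0.8
    psych_admission_rate_case: float = 0.10  # during the episode

    # work loss (generated only for ages 20-64 at spell start)
    sick_spell_rate_control: float = 0.10
    sick_duration_median: float = 25.0
    sick_duration_sigma: float = 0.7
    sick_spell_rate_case_extra: float = 1.2  # during the episode
    sick_duration_median_case: float = 55.0
    dp_prevalence: float = 0.025
    dp_extent_choices: tuple = (0.5, 0.75, 1.0)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**doc)

    def to_yaml(self, path) -> None:
        doc = asdict(self)
        doc["window"] = list(self.window)
        doc["inclusion_window"] = list(self.inclusion_window)
        doc["dp_extent_choices"] = list(self.dp_extent_choices)
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


# ICD-10 codes the generator emits per concept (one representative per concept;
# the analysis is concept-driven so one code per set suffices structurally)
CONDITION_CODES = {
    "mdd": "F329", "anxiety": "F411", "stress": "F430", "sleep": "F510",
    "substance": "F121", "alcohol": "F102", "ocd": "F420", "hyperkinetic": "F900",
    "autism": "F840", "personality": "F603", "self_harm": "X78",
    "hypertension": "I10", "diabetes_t2": "E119", "hypothyroidism": "E039",
    "ibd": "K509", "ra": "M059", "cardiovascular": "I209",
}
AD_ATC = "N06AB10"       # escitalopram
ADDON_ATC = "N05AN01"    # lithium


class _Tally:
    """Column-wise accumulator for one output table."""

    def __init__(self, columns):
        self.columns = columns
        self.rows: list[tuple] = []

    def add(self, *row):
        self.rows.append(row)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=self.columns)


def _draw_death_day(rng, lam0: float, onset_day: float | None, lam_mult: float,
                    horizon: float) -> float | None:
    """Piecewise-exponential death time (days from window start), or None.

    Hazard is ``lam0`` per day until ``onset_day`` and ``lam0*lam_mult``
    afterwards; inversion of the cumulative hazard.
    """
    u = rng.random()
    target = -math.log(u)
    if onset_day is None or lam_mult == 1.0:
        t = target / lam0
    else:
        h_pre = lam0 * onset_day
        if target <= h_pre:
            t = target / lam0
        else:
            t = onset_day + (target - h_pre) / (lam0 * lam_mult)
    return t if t < horizon else None


def generate(config: SimConfig) -> tuple[EventTables, pd.DataFrame]:
    """Simulate the seven registry tables plus a per-person ground-truth frame.

    Returns ``(tables, truth)`` where ``truth`` has one row per person with the
    latent quantities (onset date, true episode intervals, hazard multiplier,
    therapy flags) that recovery tests check against.
    """
    cfg = config
    w0, w1 = pd.Timestamp(cfg.window[0]), pd.Timestamp(cfg.window[1])
    i0, i1 = pd.Timestamp(cfg.inclusion_window[0]), pd.Timestamp(cfg.inclusion_window[1])
    horizon = float((w1 - w0).days)
    incl_lo, incl_hi = float((i0 - w0).days), float((i1 - w0).days)
    lam0 = cfg.baseline_mortality_rate / 1000.0 / 365.25
    hr_mult = math.exp(cfg.case_log_hr)
    years_at_risk = (incl_hi - incl_lo) / 365.25
    p_onset = 1.0 - math.exp(-cfg.annual_mdd_onset_rate * years_at_risk)
    care_levels = list(cfg.care_level_mix)
    care_probs = np.array([cfg.care_level_mix[k] for k in care_levels], dtype=float)
    care_probs = care_probs / care_probs.sum()

    persons = _Tally(SCHEMAS["persons"])
    residency = _Tally(SCHEMAS["residency"])
    diagnoses = _Tally(SCHEMAS["diagnoses"])
    dispensations = _Tally(SCHEMAS["dispensations"])
    procedures = _Tally(SCHEMAS["procedures"])
    visits = _Tally(SCHEMAS["visits"])
    stays = _Tally(SCHEMAS["stays"])
    workloss = _Tally(SCHEMAS["workloss"])
    truth_rows = []

    def D(day: float) -> pd.Timestamp:
        return w0 + pd.Timedelta(days=int(round(day)))

    for idx in range(cfg.n_persons):
        rng = np.random.default_rng([cfg.seed, idx])
        pid = f"P{idx:06d}"
        sex = "F" if rng.random() < 0.5 else "M"
        age_ref = float(np.clip(cfg.age_mean + cfg.age_sd * rng.standard_normal(),
                                cfg.age_min, cfg.age_max))
        # age is anchored at the window midpoint
        birth = w0 + pd.Timedelta(days=int(horizon / 2 - age_ref * 365.25))
        municipality = f"M{rng.integers(cfg.n_municipalities):02d}"

        entry = 0.0
        if rng.random() < cfg.late_entry_fraction:
            entry = float(rng.uniform(0.0, horizon - 365.0))
        emig = rng.exponential(1.0 / cfg.emigration_rate) * 365.25 + entry \
            if cfg.emigration_rate > 0 else math.inf

        # latent onset
        onset = None
        p_sex = p_onset * 2.0 * (cfg.sex_ratio_cases if sex == "F" else 1 - cfg.sex_ratio_cases)
        if rng.random() < p_sex:
            onset = float(rng.uniform(incl_lo, min(incl_hi, horizon) - 1.0))
        # onset must fall inside residency to ever be observed
        if onset is not None and not (entry <= onset < emig):
            onset = None

        death = _draw_death_day(rng, lam0, onset, hr_mult if onset is not None else 1.0,
                                horizon)
        res_end = min(emig, horizon)
        if death is not None:
            res_end = min(res_end, death + 1.0)  # half-open: resident through death day
        cover_end = res_end                      # no events at/after this day
        if entry >= cover_end:
            continue

        persons.add(pid, sex, birth, municipality, D(death) if death is not None else None)
        residency.add(pid, D(entry), D(cover_end))
        # event days are emitted on an integer-day grid strictly inside the
        # person's (rounded) residency interval
        entry_i, cover_i = int(round(entry)), int(round(cover_end))

        def event_days(days):
            out = []
            for d in np.atleast_1d(days):
                di = int(round(float(d)))
                if entry_i <= di < cover_i:
                    out.append(di)
            return out

        age_entry = (D(entry) - birth).days / 365.25
        working = lambda day: 20.0 <= (D(day) - birth).days / 365.25 <= 64.0

        # ---- background processes (everyone) -------------------------------
        span_years = (cover_end - entry) / 365.25
        n_visits = rng.poisson(cfg.visit_rate_control * span_years)
        for day in event_days(rng.uniform(entry, cover_end, n_visits)):
            lvl = rng.choice(["primary", "other", "psychiatric_outpatient"],
                             p=[0.80, 0.15, 0.05])
            visits.add(pid, D(day), lvl, bool(rng.random() < 0.85))
        n_adm = rng.poisson(cfg.admission_rate_control * span_years)
        for day in event_days(rng.uniform(entry, cover_end, n_adm)):
            los = max(1, int(_lognormal_from_median(rng, cfg.los_median_days, cfg.los_sigma)))
            end = min(day + los, cover_i)
            if end > day:
                stays.add(pid, D(day), D(end), "non_psychiatric")
        for cond, rate in cfg.background_comorbidity_rate.items():
            n = rng.poisson(rate * span_years)
            for day in event_days(rng.uniform(entry, cover_end, n)):
                diagnoses.add(pid, D(day), CONDITION_CODES[cond], "primary")
        # background sick leave
        n_sick = rng.poisson(cfg.sick_spell_rate_control * span_years)
        for day in event_days(rng.uniform(entry, cover_end, n_sick)):
            if not working(day):
                continue
            dur = max(3, int(_lognormal_from_median(rng, cfg.sick_duration_median,
                                                    cfg.sick_duration_sigma)))
            end = min(day + dur, cover_i)
            if end > day:
                workloss.add(pid, D(day), D(end), "sick_leave", 1.0)
        # disability pension: a standing spell over the whole residency
        if rng.random() < cfg.dp_prevalence and working(entry):
            extent = float(rng.choice(cfg.dp_extent_choices))
            workloss.add(pid, D(entry), D(cover_end), "disability_pension", extent)
        # non-cases occasionally use ADs for other indications
        if onset is None and rng.random() < cfg.background_ad_rate:
            start = rng.uniform(entry, cover_end)
            for day in event_days(np.arange(start, start + 365.0,
                                            cfg.dispensation_interval_days)):
                dispensations.add(pid, D(day), AD_ATC, cfg.tablets_per_fill, None)

        if onset is None:
            truth_rows.append((pid, False, sex, birth, municipality, None, None, None,
                               np.nan, None, 1.0, False, False, False))
            continue

        # ---- the disease process (cases) -----------------------------------
        dur1 = float(_lognormal_from_median(rng, cfg.episode_median_days, cfg.episode_sigma))
        dur1 = max(1.0, dur1)
        episodes = [(onset, onset + dur1)]
        if rng.random() < cfg.recurrence_prob:
            gap = cfg.recurrence_gap_min_days + rng.exponential(cfg.recurrence_gap_mean_days)
            s2 = episodes[0][1] + gap
            if s2 < horizon - 30:
                d2 = max(1.0, float(_lognormal_from_median(
                    rng, cfg.episode_median_days, cfg.episode_sigma)))
                episodes.append((s2, s2 + d2))

        index_level = str(rng.choice(care_levels, p=care_probs))
        index_care = {"primary": "primary", "psychiatric": "psychiatric_outpatient",
                      "other": "other"}[index_level]
        referred = (index_level == "primary" and rng.random() < cfg.referral_propensity)

        treated = {t: rng.random() < p for t, p in cfg.treatment_propensities.items()}
        prior_ad = rng.random() < cfg.prior_ad_propensity
        prior_pt = rng.random() < cfg.prior_psychotherapy_propensity
        index_treated = rng.random() < cfg.index_treatment_propensity

        for ord_, (s, e) in enumerate(episodes, start=1):
            e_obs = min(e, horizon)
            if s >= cover_end:
                break
            # diagnosis stream: onset dx, interior renewals, terminal dx at the
            # last contact; gaps capped so the episode is reconstructable
            dx_days = [s]
            d = s
            while True:
                d = d + min(rng.exponential(cfg.dx_interval_days) + 1.0,
                            float(cfg.max_event_gap_days))
                if d >= e_obs - 1.0:
                    break
                dx_days.append(d)
            if e_obs - s >= 1.0:
                dx_days.append(e_obs - 1.0)
            dx_days = event_days(dx_days)
            for k, day in enumerate(dx_days):
                lvl = index_care if ord_ == 1 else "primary"
                if ord_ == 1 and referred and k > 0 and day <= s + 360 and lvl == "primary":
                    lvl = "psychiatric_outpatient"
                diagnoses.add(pid, D(day), CONDITION_CODES["mdd"], lvl)
            if ord_ == 1 and referred and len(dx_days) < 2:
                for day in event_days([min(s + float(rng.uniform(30, 330)),
                                           cover_end - 1)]):
                    if day > s:
                        diagnoses.add(pid, D(day), CONDITION_CODES["mdd"],
                                      "psychiatric_outpatient")

            # antidepressant dispensations at a steady refill interval; most
            # starters fill within the index month, the rest after a delay
            # fills stop a month before the terminal diagnosis so the episode's
            # last recorded contact is the closing diagnosis, not a refill
            if treated["ad"]:
                start = s + (float(rng.uniform(0, 15)) if (index_treated or ord_ > 1)
                             else float(rng.uniform(30, 90)))
                fills = np.arange(start, max(start + 1.0, e_obs - 35.0),
                                  cfg.dispensation_interval_days)
                for day in event_days(fills):
                    dispensations.add(pid, D(day), AD_ATC, cfg.tablets_per_fill, None)
            if treated["addon"]:
                start = s + float(rng.uniform(30, 90))
                fills = np.arange(start, max(start + 1.0, e_obs - 35.0),
                                  cfg.dispensation_interval_days)
                for day in event_days(fills):
                    dispensations.add(pid, D(day), ADDON_ATC, cfg.tablets_per_fill, None)
            for proc in ("ECT", "rTMS"):
                if treated[proc]:
                    n = 1 + rng.poisson(3)
                    base = s + float(rng.uniform(0, 60))
                    for day in event_days(base + 3.0 * np.arange(n)):
                        procedures.add(pid, D(day), proc, "psychiatric_inpatient")
            if treated["psychotherapy"]:
                n = 1 + rng.poisson(6)
                base = s + float(rng.uniform(0, 90))
                for day in event_days(base + 14.0 * np.arange(n)):
                    lvl = index_care if index_level != "other" else "primary"
                    procedures.add(pid, D(day), "psychotherapy", lvl)

            # elevated utilization during the episode
            ep_years = max(e_obs - s, 0.0) / 365.25
            n_extra = rng.poisson(cfg.visit_rate_case_extra * ep_years)
            extra_days = np.concatenate([[s], rng.uniform(s, max(e_obs, s + 1), n_extra)]) \
                if ord_ == 1 else rng.uniform(s, max(e_obs, s + 1), n_extra)
            for day in event_days(extra_days):
                lvl = "psychiatric_outpatient" if index_level == "psychiatric" \
                    else ("primary" if index_level == "primary" else "other")
                visits.add(pid, D(day), lvl, True)
            n_padm = rng.poisson(cfg.psych_admission_rate_case * ep_years)
            for day in event_days(rng.uniform(s, max(e_obs, s + 1), n_padm)):
                los = max(1, int(_lognormal_from_median(rng, 10.0, cfg.los_sigma)))
                end = min(day + los, cover_i)
                if end > day:
                    stays.add(pid, D(day), D(end), "psychiatric")
            n_csick = rng.poisson(cfg.sick_spell_rate_case_extra * ep_years)
            sick_days = np.concatenate([[s + 1.0], rng.uniform(s, max(e_obs, s + 1), n_csick)]) \
                if ord_ == 1 else rng.uniform(s, max(e_obs, s + 1), n_csick)
            for day in event_days(sick_days):
                if not working(day):
                    continue
                dur = max(5, int(_lognormal_from_median(rng, cfg.sick_duration_median_case,
                                                        cfg.sick_duration_sigma)))
                end = min(day + dur, cover_i)
                if end > day:
                    workloss.add(pid, D(day), D(end), "sick_leave", 1.0)

        # pre-index therapy in the year before onset
        if prior_ad:
            start = onset - float(rng.uniform(60, 365))
            fills = np.arange(start, onset, cfg.dispensation_interval_days)
            for day in event_days(fills):
                dispensations.add(pid, D(day), AD_ATC, cfg.tablets_per_fill, None)
        if prior_pt:
            base = onset - float(rng.uniform(30, 330))
            for day in event_days(base + 14.0 * np.arange(1 + rng.poisson(4))):
                procedures.add(pid, D(day), "psychotherapy", "primary")

        # comorbidity with a 5-year pre-onset ramp plus occasional post-index
        # recording
        ramp_exp = 1.0 / (cfg.comorbidity_ramp_power + 1.0)
        for cond, prev in cfg.case_comorbidity_prev.items():
            if rng.random() < prev:
                back = 5 * 365.25 * (1.0 - rng.random() ** ramp_exp)
                lvl = "other" if cond == "self_harm" else "primary"
                for day in event_days([onset - back]):
                    diagnoses.add(pid, D(day), CONDITION_CODES[cond], lvl)
            if rng.random() < prev * 0.15:
                for day in event_days([onset + float(rng.uniform(1, 365))]):
                    diagnoses.add(pid, D(day), CONDITION_CODES[cond], "primary")

        ep1 = episodes[0]
        truth_rows.append((
            pid, True, sex, birth, municipality, D(onset), D(ep1[0]),
            D(min(ep1[1], horizon)), float(min(ep1[1], horizon) - ep1[0]),
            index_level, hr_mult, treated["ad"], prior_ad, referred))

    tables = EventTables(
        persons=_finish(persons, "persons"),
        residency=_finish(residency, "residency"),
        diagnoses=_finish(diagnoses, "diagnoses"),
        dispensations=_finish(dispensations, "dispensations"),
        procedures=_finish(procedures, "procedures"),
        visits=_finish(visits, "visits"),
        stays=_finish(stays, "stays"),
        workloss=_finish(workloss, "workloss"),
    )
    truth = pd.DataFrame(truth_rows, columns=[
        "person_id", "is_case", "sex", "birth_date", "municipality", "onset_date",
        "episode1_start", "episode1_end", "episode1_duration_days",
        "index_care_level", "hazard_multiplier", "treated_ad", "prior_ad",
        "referred_psychiatric"])
    return tables, truth


def _finish(tally: _Tally, name: str) -> pd.DataFrame:
    df = tally.frame()
    if df.empty:
        from .registry import empty_tables
        return empty_tables().table(name)
    sort_cols = [c for c in ("person_id", "date", "start", "admission_date") if c in df.columns]
    df = df.sort_values(sort_cols, kind="mergesort").reset_index(drop=True)
    if name == "dispensations":
        df["tablets"] = df["tablets"].astype(int)
        df["daily_dose_mg"] = pd.to_numeric(df["daily_dose_mg"], errors="coerce")
    if name == "workloss":
        df["extent"] = df["extent"].astype(float)
    return df


def truth_report(truth: pd.DataFrame, path=None) -> pd.DataFrame:
    """Per-person ground truth as a flat CSV-ready table (one row per person)."""
    out = truth.copy()
    for c in ("birth_date", "onset_date", "episode1_start", "episode1_end"):
        out[c] = pd.to_datetime(out[c]).dt.strftime("%Y-%m-%d")
    if path is not None:
        out.to_csv(path, index=False, lineterminator="\n")
    return out


# ---------------------------------------------------------------------------
# Fast mortality-only path
# ---------------------------------------------------------------------------

def simulate_survival(n_pairs: int, log_hr: float, seed: int,
                      baseline_rate_per_1000py: float = 5.4,
                      accrual_years: float = 7.0,
                      emigration_rate: float = 0.02) -> pd.DataFrame:
    """Vectorized draw from the generator's mortality submodel alone.

    Simulates ``n_pairs`` case/control pairs: index dates accrue uniformly
    over ``accrual_years`` with administrative censoring at the end of the
    accrual window, emigration as an independent exponential, and exponential
    death times at the baseline rate (controls) times ``exp(log_hr)`` (cases).
    Uniform accrual with registry-realistic emigration gives a mean follow-up
    of about 3.3 years.
    Returns a frame with columns ``time`` (days), ``event``, ``group``
    (1=case), ``pair_id`` — the exact input shape of
    :func:`mddburden.mortality.fit_cox`.  Used for large-n hazard-ratio
    recovery where generating full event tables would be wasteful.
    """
    rng = np.random.default_rng(seed)
    n = 2 * n_pairs
    group = np.tile([1, 0], n_pairs)
    pair_id = np.repeat(np.arange(n_pairs), 2)
    admin = rng.uniform(0.0, accrual_years * 365.25, n_pairs)
    admin = np.repeat(accrual_years * 365.25 - admin, 2)  # same index date per pair
    lam = baseline_rate_per_1000py / 1000.0 / 365.25 * np.exp(log_hr * group)
    t_death = rng.exponential(1.0 / lam)
    t_emig = rng.exponential(365.25 / emigration_rate, n) if emigration_rate > 0 \
        else np.full(n, np.inf)
    time = np.minimum.reduce([t_death, t_emig, admin])
    event = t_death <= np.minimum(t_emig, admin)
    time = np.maximum(time, 0.5)
    return pd.DataFrame({"time": time, "event": event, "group": group, "pair_id": pair_id})
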