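"""Registry data model: event tables, schema validation, CSV I/O and the codebook.

The analysis consumes seven delimited tables shaped like a regional healthcare
data warehouse linked to social-insurance registries:

* ``persons``        -- demographics and death dates
* ``residency``      -- half-open intervals of residence in the region
* ``diagnoses``      -- ICD-10 coded diagnosis events with a care level
* ``dispensations``  -- ATC-coded pharmacy fills with tablet counts
* ``procedures``     -- ECT / rTMS / psychotherapy records
* ``visits``         -- outpatient visits (physician flag)
* ``stays``          -- inpatient admissions with ward type
* ``workloss``       -- sick-leave and disability-pension spells

All intervals are half-open ``[start, end)``; all dates are ISO-8601 calendar
dates without times.  Clinical concepts (depression, exclusion diagnoses,
antidepressants, add-on medication, comorbid conditions) are defined by a
configurable :class:`Codebook` of ICD-10 / ATC prefixes, so every downstream
algorithm is phrased in concepts rather than code strings.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

CARE_LEVELS = ("primary", "psychiatric_outpatient", "psychiatric_inpatient", "other")
PROCEDURES = ("ECT", "rTMS", "psychotherapy")
WARDS = ("psychiatric", "non_psychiatric")
WORKLOSS_KINDS = ("sick_leave", "disability_pension")

ICD10_RE = re.compile(r"^[A-Z][0-9]{2}[0-9A-Z]{0,2}$")
ATC_RE = re.compile(r"^[A-Z][0-9]{2}[A-Z]{0,2}([0-9]{2})?$")
_RANGE_RE = re.compile(r"^([A-Z])([0-9]{2})-([A-Z])([0-9]{2})$")

#: column layout of each table, in canonical write order
SCHEMAS: dict[str, list[str]] = {
    "persons": ["person_id", "sex", "birth_date", "municipality", "death_date"],
    "residency": ["person_id", "start", "end"],
    "diagnoses": ["person_id", "date", "icd10", "care_level"],
    "dispensations": ["person_id", "date", "atc", "tablets", "daily_dose_mg"],
    "procedures": ["person_id", "date", "procedure", "care_level"],
    "visits": ["person_id", "date", "care_level", "physician"],
    "stays": ["person_id", "admission_date", "discharge_date", "ward"],
    "workloss": ["person_id", "start", "end", "kind", "extent"],
}

_DATE_COLS: dict[str, list[str]] = {
    "persons": ["birth_date", "death_date"],
    "residency": ["start", "end"],
    "diagnoses": ["date"],
    "dispensations": ["date"],
    "procedures": ["date"],
    "visits": ["date"],
    "stays": ["admission_date", "discharge_date"],
    "workloss": ["start", "end"],
}


class SchemaError(ValueError):
    """A table's header or column types do not match the declared schema."""


class ValidationError(ValueError):
    """A row violates a table invariant (strict mode only)."""


# ---------------------------------------------------------------------------
# Codebook
# ---------------------------------------------------------------------------

def expand_range(spec: str) -> list[str]:
    """Expand a range like ``"F20-F29"`` into its 3-character prefixes.

    A bare prefix passes through unchanged, so code lists may freely mix
    ranges and plain prefixes.
    """
    m = _RANGE_RE.match(spec)
    if m is None:
        return [spec]
    lo_letter, lo_num, hi_letter, hi_num = m.groups()
    if lo_letter != hi_letter:
        raise ValueError(f"range endpoints must share the letter: {spec!r}")
    lo, hi = int(lo_num), int(hi_num)
    if lo > hi:
        raise ValueError(f"empty code range: {spec!r}")
    return [f"{lo_letter}{i:02d}" for i in range(lo, hi + 1)]


@dataclass(frozen=True)
class CodeSet:
    """A clinical concept: codes matching any ``include`` prefix and no
    ``exclude`` prefix (e.g. stress reactions F43 excluding PTSD F431)."""

    include: tuple[str, ...]
    exclude: tuple[str, ...] = ()

    def __post_init__(self):
        if not self.include:
            raise ValueError("code set must have at least one include prefix")

    def matches(self, code: str) -> bool:
        return match_code(code, self.include) and not match_code(code, self.exclude)


def match_code(code: str, prefixes) -> bool:
    """True iff any prefix in ``prefixes`` is a prefix of ``code``.

    Prefix semantics mirror hierarchical ICD-10/ATC coding: ``F32`` matches
    ``F32``, ``F329``, ``F3201`` and so on.
    """
    if not code:
        raise ValueError("empty code")
    return any(code.startswith(p) for p in prefixes)


def _cs(*include: str, exclude: tuple[str, ...] = ()) -> CodeSet:
    expanded: list[str] = []
    for spec in include:
        expanded.extend(expand_range(spec))
    ex: list[str] = []
    for spec in exclude:
        ex.extend(expand_range(spec))
    return CodeSet(tuple(expanded), tuple(ex))


#: psychiatric comorbid conditions tracked in the baseline table / monthly curves
PSYCHIATRIC_COMORBIDITIES = (
    "anxiety", "stress", "sleep", "substance", "alcohol", "ocd",
    "hyperkinetic", "autism", "personality", "self_harm",
)
#: non-psychiatric comorbid conditions
SOMATIC_COMORBIDITIES = (
    "cardiovascular", "hypertension", "diabetes_t2", "hypothyroidism", "ibd", "ra",
)


@dataclass(frozen=True)
class Codebook:
    """Named code sets driving every clinical definition in the pipeline.

    ``dose_constrained`` maps an ATC prefix within ``addon_med`` to a minimum
    prescribed daily dose in mg (exclusive threshold): quetiapine counts as
    depression add-on therapy only above 100 mg/day, the antipsychotic dose
    range being higher than the augmentation range.
    """

    sets: dict[str, CodeSet] = field(default_factory=dict)
    dose_constrained: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        required = {"mdd", "psychosis", "mania", "bipolar", "dementia", "antidepressant",
                    "addon_med"}
        missing = required - set(self.sets)
        if missing:
            raise ValueError(f"codebook missing required sets: {sorted(missing)}")
        mdd = set(self.sets["mdd"].include)
        for name in ("psychosis", "mania", "bipolar", "dementia"):
            if mdd & set(self.sets[name].include):
                raise ValueError(f"mdd codes overlap exclusion set {name!r}")

    def __getitem__(self, name: str) -> CodeSet:
        return self.sets[name]

    def matches(self, name: str, code: str) -> bool:
        return self.sets[name].matches(code)

    def addon_mask(self, atc: pd.Series, daily_dose_mg: pd.Series) -> pd.Series:
        """Vectorized membership in the add-on set, honouring dose thresholds.

        Dose-constrained codes with a missing ``daily_dose_mg`` are excluded
        (we cannot establish the augmentation dose, so we stay conservative).
        """
        cs = self.sets["addon_med"]
        mask = atc.map(cs.matches)
        for prefix, min_dose in self.dose_constrained.items():
            constrained = atc.str.startswith(prefix)
            ok_dose = daily_dose_mg.notna() & (daily_dose_mg > min_dose)
            mask &= ~constrained | ok_dose
        return mask

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "sets": {
                name: {"include": list(cs.include), **({"exclude": list(cs.exclude)} if cs.exclude else {})}
                for name, cs in self.sets.items()
            },
            "dose_constrained": dict(self.dose_constrained),
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Codebook":
        doc = yaml.safe_load(Path(path).read_text())
        sets = {
            name: _cs(*entry["include"], exclude=tuple(entry.get("exclude", ())))
            for name, entry in doc["sets"].items()
        }
        return cls(sets=sets, dose_constrained={k: float(v) for k, v in
                                                doc.get("dose_constrained", {}).items()})


def default_codebook() -> Codebook:
    """Editable defaults: body-text definitions for the depression concepts,
    conventional ICD-10 choices for the comorbidity lists."""
    sets = {
        # depression and exclusion concepts
        "mdd": _cs("F32", "F33"),
        "psychosis": _cs("F20-F29"),
        "mania": _cs("F30"),
        "bipolar": _cs("F31"),
        "dementia": _cs("F00-F03"),
        # pharmacotherapy
        "antidepressant": _cs("N06A"),
        # lithium, risperidone, olanzapine, aripiprazole, quetiapine
        "addon_med": _cs("N05AN01", "N05AX08", "N05AH03", "N05AX12", "N05AH04"),
        # psychiatric comorbid conditions
        "anxiety": _cs("F40-F41"),
        "stress": _cs("F43", exclude=("F431",)),  # excl. PTSD
        "sleep": _cs("F51", "G47"),
        "substance": _cs("F10-F19"),
        "alcohol": _cs("F10"),
        "ocd": _cs("F42"),
        "hyperkinetic": _cs("F90"),
        "autism": _cs("F84"),
        "personality": _cs("F60-F61"),
        "self_harm": _cs("X60-X84"),
        # non-psychiatric comorbid conditions
        "hypertension": _cs("I10-I15"),
        "diabetes_t2": _cs("E11"),
        "hypothyroidism": _cs("E03"),
        "ibd": _cs("K50-K51"),
        "ra": _cs("M05-M06"),
        "cardiovascular": _cs("I20-I25", "I60-I69"),
    }
    return Codebook(sets=sets, dose_constrained={"N05AH04": 100.0})


# ---------------------------------------------------------------------------
# Event tables
# ---------------------------------------------------------------------------

@dataclass
class EventTables:
    """The seven validated registry tables as pandas DataFrames.

    ``dropped`` records, per table, how many rows lenient-mode validation
    discarded; strict-mode loading guarantees it is all zeros.
    """

    persons: pd.DataFrame
    residency: pd.DataFrame
    diagnoses: pd.DataFrame
    dispensations: pd.DataFrame
    procedures: pd.DataFrame
    visits: pd.DataFrame
    stays: pd.DataFrame
    workloss: pd.DataFrame
    dropped: dict[str, int] = field(default_factory=dict)

    def table(self, name: str) -> pd.DataFrame:
        return getattr(self, name)

    def copy(self) -> "EventTables":
        return replace(self, **{n: self.table(n).copy() for n in SCHEMAS})


def empty_tables() -> EventTables:
    frames = {}
    for name, cols in SCHEMAS.items():
        df = pd.DataFrame({c: pd.Series(dtype=object) for c in cols})
        for c in _DATE_COLS[name]:
            df[c] = pd.Series(dtype="datetime64[ns]")
        frames[name] = df
    return EventTables(**frames)


def _check_rows(name: str, df: pd.DataFrame) -> pd.Series:
    """Boolean mask of valid rows plus per-row reasons attached via attrs."""
    ok = pd.Series(True, index=df.index)
    reasons: dict[int, str] = {}

    def flag(bad: pd.Series, reason: str):
        nonlocal ok
        for i in df.index[bad & ok]:
            reasons[i] = reason
        ok &= ~bad

    if name == "persons":
        flag(~df["sex"].isin(["F", "M"]), "sex must be F or M")
        both = df["death_date"].notna()
        flag(both & (df["death_date"] < df["birth_date"]), "death_date before birth_date")
    elif name == "residency":
        flag(df["end"] <= df["start"], "empty residency interval")
    elif name == "diagnoses":
        flag(~df["icd10"].astype(str).str.match(ICD10_RE), "icd10 must match [A-Z][0-9]{2}[0-9A-Z]{0,2}")
        flag(~df["care_level"].isin(CARE_LEVELS), "unknown care_level")
    elif name == "dispensations":
        flag(~df["atc"].astype(str).str.match(ATC_RE), "atc must match [A-Z][0-9]{2}[A-Z]{0,2}([0-9]{2})?")
        flag(df["tablets"] < 1, "tablets must be >= 1")
        dose = df["daily_dose_mg"]
        flag(dose.notna() & (dose <= 0), "daily_dose_mg must be positive")
    elif name == "procedures":
        flag(~df["procedure"].isin(PROCEDURES), "unknown procedure")
        flag(~df["care_level"].isin(CARE_LEVELS), "unknown care_level")
    elif name == "visits":
        flag(~df["care_level"].isin(CARE_LEVELS), "unknown care_level")
    elif name == "stays":
        flag(df["discharge_date"] < df["admission_date"], "discharge before admission")
        flag(~df["ward"].isin(WARDS), "unknown ward")
    elif name == "workloss":
        flag(df["end"] <= df["start"], "end must be after start")
        flag(~df["kind"].isin(WORKLOSS_KINDS), "unknown work-loss kind")
        flag((df["extent"] <= 0) | (df["extent"] > 1), "extent must be in (0, 1]")
    ok.attrs["reasons"] = reasons
    return ok


def _load_one(name: str, path: str | Path, strict: bool) -> tuple[pd.DataFrame, int]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    expected = SCHEMAS[name]
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise SchemaError(f"{name}: missing column(s) {missing} in {path}")
    df = df[expected].replace({"": None})

    for col in _DATE_COLS[name]:
        parsed = pd.to_datetime(df[col], format="%Y-%m-%d", errors="coerce")
        bad = parsed.isna() & df[col].notna()
        if bad.any():
            line = int(df.index[bad][0]) + 2  # header + 1-based
            msg = f"{name}: unparseable date in column {col!r} at line {line}"
            if strict:
                raise ValidationError(msg)
            logger.warning("%s; dropping %d row(s)", msg, int(bad.sum()))
            df = df[~bad]
            parsed = parsed[~bad]
        df[col] = parsed
    # required (non-nullable) dates
    nullable = {("persons", "death_date")}
    for col in _DATE_COLS[name]:
        if (name, col) not in nullable:
            req = df[col].isna()
            if req.any():
                msg = f"{name}: missing date in column {col!r}"
                if strict:
                    raise ValidationError(msg)
                df = df[~req]

    if name == "dispensations":
        df["tablets"] = pd.to_numeric(df["tablets"], errors="coerce")
        df["daily_dose_mg"] = pd.to_numeric(df["daily_dose_mg"], errors="coerce")
        bad = df["tablets"].isna() | (df["tablets"] != df["tablets"].round())
        if bad.any():
            if strict:
                raise ValidationError("dispensations: tablets must be a positive integer")
            df = df[~bad]
        df["tablets"] = df["tablets"].astype(int)
    if name == "visits":
        df["physician"] = df["physician"].map({"True": True, "False": False,
                                               "true": True, "false": False, "1": True, "0": False})
        if df["physician"].isna().any():
            raise SchemaError("visits: physician must be boolean")
        df["physician"] = df["physician"].astype(bool)
    if name == "workloss":
        df["extent"] = pd.to_numeric(df["extent"], errors="coerce").fillna(1.0)

    ok = _check_rows(name, df)
    n_bad = int((~ok).sum())
    if n_bad:
        first = next(iter(ok.attrs["reasons"].values()))
        if strict:
            raise ValidationError(f"{name}: {n_bad} invalid row(s); first: {first}")
        logger.warning("%s: dropped %d invalid row(s); first reason: %s", name, n_bad, first)
        df = df[ok]
    return df.reset_index(drop=True), n_bad


def load_tables(paths: dict[str, str | Path] | str | Path,
                schema_strict: bool = True) -> EventTables:
    """Read and validate the seven registry CSVs.

    ``paths`` is either a directory containing ``<table>.csv`` files or an
    explicit table→path mapping.  In strict mode any invariant violation
    raises; in lenient mode offending rows are dropped and counted in
    :attr:`EventTables.dropped`.
    """
    if isinstance(paths, (str, Path)):
        base = Path(paths)
        paths = {name: base / f"{name}.csv" for name in SCHEMAS}
    frames, dropped = {}, {}
    for name in SCHEMAS:
        frames[name], dropped[name] = _load_one(name, paths[name], schema_strict)
    tables = EventTables(**frames, dropped=dropped)
    _warn_orphan_events(tables)
    return tables


def _warn_orphan_events(tables: EventTables) -> None:
    """Warn about events dated outside any residency interval of their person."""
    res = tables.residency
    for name in ("diagnoses", "dispensations", "procedures", "visits"):
        df = tables.table(name)
        if df.empty or res.empty:
            continue
        ev = df[["person_id", "date"]].reset_index(names="_row")
        merged = ev.merge(res, on="person_id", how="left")
        inside = (merged["date"] >= merged["start"]) & (merged["date"] < merged["end"])
        covered = inside.groupby(merged["_row"]).any()
        n_out = int((~covered).sum())
        if n_out:
            logger.warning("%s: %d event(s) dated outside the person's residency", name, n_out)


def write_tables(tables: EventTables, out_dir: str | Path) -> dict[str, Path]:
    """Write the seven tables in canonical form (ISO dates, fixed column order).

    Canonical output round-trips: ``write_tables(load_tables(d))`` reproduces
    the files in ``d`` byte-identically when they are already canonical.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = {}
    for name, cols in SCHEMAS.items():
        df = tables.table(name)[cols].copy()
        for c in _DATE_COLS[name]:
            df[c] = df[c].dt.strftime("%Y-%m-%d")
        if name == "workloss":
            df["extent"] = df["extent"].map(lambda v: format(float(v), "g"))
        if name == "dispensations":
            df["daily_dose_mg"] = df["daily_dose_mg"].map(
                lambda v: "" if pd.isna(v) else format(float(v), "g"))
        path = out_dir / f"{name}.csv"
        df.to_csv(path, index=False, lineterminator="\n")
        written[name] = path
    return written


# ---------------------------------------------------------------------------
# Depressive events
# ---------------------------------------------------------------------------

EVENT_COLUMNS = ["person_id", "date", "event_class", "source", "care_level", "tablets"]


def depressive_events_all(tables: EventTables, codebook: Codebook) -> pd.DataFrame:
    """Union of depression-related events for every person, sorted.

    Depressive events are: MDD diagnoses at any care level, antidepressant
    dispensations (ATC N06A), add-on medication dispensations (dose rule for
    quetiapine), and ECT / rTMS / psychotherapy procedure records.  The result
    has one row per event with columns ``person_id, date, event_class
    ('diagnosis'|'dispensation'|'procedure'), source, care_level, tablets``;
    sort order is (person_id, date, event_class) so the output is stable under
    arbitrary shuffling of the input tables.
    """
    parts: list[pd.DataFrame] = []

    dx = tables.diagnoses
    if len(dx):
        m = dx["icd10"].map(codebook["mdd"].matches)
        sub = dx.loc[m, ["person_id", "date", "care_level"]].copy()
        sub["event_class"] = "diagnosis"
        sub["source"] = "mdd_dx"
        sub["tablets"] = np.nan
        parts.append(sub)

    disp = tables.dispensations
    if len(disp):
        ad = disp["atc"].map(codebook["antidepressant"].matches)
        addon = codebook.addon_mask(disp["atc"], disp["daily_dose_mg"])
        for mask, src in ((ad, "ad"), (addon & ~ad, "addon")):
            sub = disp.loc[mask, ["person_id", "date", "tablets"]].copy()
            sub["event_class"] = "dispensation"
            sub["source"] = src
            sub["care_level"] = None
            parts.append(sub)

    proc = tables.procedures
    if len(proc):
        sub = proc[["person_id", "date", "procedure", "care_level"]].copy()
        sub["event_class"] = "procedure"
        sub = sub.rename(columns={"procedure": "source"})
        sub["tablets"] = np.nan
        parts.append(sub)

    if not parts:
        return pd.DataFrame(columns=EVENT_COLUMNS)
    out = pd.concat([p[EVENT_COLUMNS] for p in parts], ignore_index=True)
    out = out.sort_values(["person_id", "date", "event_class", "source"],
                          kind="mergesort").reset_index(drop=True)
    return out


def depressive_events(tables: EventTables, person_id, codebook: Codebook) -> pd.DataFrame:
    """Chronologically sorted depressive events for one person (may be empty)."""
    sub = EventTables(**{n: (tables.table(n)[tables.table(n)["person_id"] == person_id]
                             if "person_id" in tables.table(n).columns else tables.table(n))
                         for n in SCHEMAS})
    return depressive_events_all(sub, codebook).reset_index(drop=True)
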