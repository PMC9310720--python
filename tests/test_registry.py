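"""Codebook semantics, table validation, round-trip I/O, depressive events."""

import itertools
import string

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import mddburden as mb
from mddburden.registry import (SchemaError, ValidationError, expand_range,
                                load_tables, match_code, write_tables)
from conftest import make_tables, person


class TestCodebook:
    def test_range_expansion(self):
        assert expand_range("F20-F29") == [f"F2{i}" for i in range(10)]
        assert expand_range("F32") == ["F32"]
        with pytest.raises(ValueError):
            expand_range("F29-F20")

    @pytest.mark.parametrize("code,prefixes,expected", [
        ("F329", ("F32", "F33"), True),
        ("F20", tuple(f"F2{i}" for i in range(10)), True),   # psychosis range
        ("F34", ("F32", "F33"), False),
        ("F3", ("F32",), False),
    ])
    def test_match_code(self, code, prefixes, expected):
        assert match_code(code, prefixes) is expected

    @given(st.sampled_from([("F20", "F29"), ("I60", "I69"), ("X60", "X84")]))
    @settings(derandomize=True)
    def test_expansion_consistent_with_enumeration(self, endpoints):
        lo, hi = endpoints
        prefixes = expand_range(f"{lo}-{hi}")
        # every 3-character stem of the alphabet-digit-digit space
        for letter, d1, d2 in itertools.product(lo[0], string.digits, string.digits):
            stem = f"{letter}{d1}{d2}"
            in_range = lo <= stem <= hi
            assert match_code(stem, prefixes) is in_range

    def test_stress_excludes_ptsd(self, codebook):
        assert codebook.matches("stress", "F430")
        assert not codebook.matches("stress", "F431")

    def test_mdd_disjoint_from_exclusions_enforced(self, codebook):
        from mddburden.registry import Codebook, CodeSet
        bad = dict(codebook.sets)
        bad["bipolar"] = CodeSet(("F32",))
        with pytest.raises(ValueError):
            Codebook(sets=bad, dose_constrained={})

    def test_yaml_round_trip(self, codebook, tmp_path):
        path = tmp_path / "codebook.yaml"
        codebook.to_yaml(path)
        loaded = mb.Codebook.from_yaml(path)
        assert loaded.sets == codebook.sets
        assert loaded.dose_constrained == codebook.dose_constrained


class TestLoadValidate:
    def write_min(self, tmp_path, **overrides):
        p, r = person()
        tables = make_tables(persons=[p], residency=[r], **overrides)
        return write_tables(tables, tmp_path)

    def test_identity_three_persons(self, tmp_path):
        rows = [person(pid=f"P{i}")[0] for i in range(3)]
        res = [person(pid=f"P{i}")[1] for i in range(3)]
        write_tables(make_tables(persons=rows, residency=res), tmp_path)
        tables = load_tables(tmp_path)
        assert len(tables.persons) == 3

    def test_bad_icd10_rejected_naming_pattern(self, tmp_path):
        self.write_min(tmp_path, diagnoses=[
            {"person_id": "P1", "date": "2013-01-01", "icd10": "32F",
             "care_level": "primary"}])
        with pytest.raises(ValidationError, match=r"\[A-Z\]\[0-9\]"):
            load_tables(tmp_path, schema_strict=True)

    def test_lenient_drops_backwards_stay_with_count(self, tmp_path):
        self.write_min(tmp_path, stays=[
            {"person_id": "P1", "admission_date": "2013-05-10",
             "discharge_date": "2013-05-01", "ward": "psychiatric"},
            {"person_id": "P1", "admission_date": "2013-06-01",
             "discharge_date": "2013-06-05", "ward": "psychiatric"}])
        tables = load_tables(tmp_path, schema_strict=False)
        assert tables.dropped["stays"] == 1
        assert len(tables.stays) == 1

    def test_missing_column_names_it(self, tmp_path):
        paths = self.write_min(tmp_path)
        df = pd.read_csv(paths["diagnoses"])
        df.drop(columns=["icd10"], errors="ignore").assign(x=1).to_csv(
            paths["diagnoses"], index=False)
        with pytest.raises(SchemaError, match="icd10"):
            load_tables(tmp_path)

    def test_round_trip_byte_identical(self, tmp_path, sim_small):
        d1 = tmp_path / "a"
        d2 = tmp_path / "b"
        write_tables(sim_small["tables"], d1)
        write_tables(load_tables(d1), d2)
        for f in d1.iterdir():
            assert (d2 / f.name).read_bytes() == f.read_bytes()


class TestDepressiveEvents:
    def base(self, **overrides):
        p, r = person()
        return make_tables(persons=[p], residency=[r], **overrides)

    def test_diagnosis_and_fill_in_date_order(self, codebook):
        t = self.base(
            diagnoses=[{"person_id": "P1", "date": "2013-03-01", "icd10": "F320",
                        "care_level": "primary"}],
            dispensations=[{"person_id": "P1", "date": "2013-01-15",
                            "atc": "N06AB10", "tablets": 100}])
        ev = mb.depressive_events(t, "P1", codebook)
        assert list(ev["event_class"]) == ["dispensation", "diagnosis"]
        assert ev["date"].is_monotonic_increasing

    @pytest.mark.parametrize("dose,included", [(100.0, False), (150.0, True),
                                               (None, False)])
    def test_quetiapine_dose_threshold_strict(self, codebook, dose, included):
        t = self.base(dispensations=[{"person_id": "P1", "date": "2013-01-15",
                                      "atc": "N05AH04", "tablets": 30,
                                      "daily_dose_mg": dose}])
        ev = mb.depressive_events(t, "P1", codebook)
        assert (len(ev) == 1) is included
        if included:
            assert ev["source"].iloc[0] == "addon"

    def test_lithium_needs_no_dose(self, codebook):
        t = self.base(dispensations=[{"person_id": "P1", "date": "2013-01-15",
                                      "atc": "N05AN01", "tablets": 30}])
        assert len(mb.depressive_events(t, "P1", codebook)) == 1

    def test_unknown_person_empty(self, codebook):
        assert mb.depressive_events(self.base(), "nobody", codebook).empty

    def test_stable_under_input_shuffling(self, codebook, sim_large):
        tables = sim_large["tables"]
        rng = np.random.default_rng(0)
        pid = sim_large["truth"].query("is_case").person_id.iloc[3]
        ref = mb.depressive_events(tables, pid, codebook)
        shuffled = tables.copy()
        for name in ("diagnoses", "dispensations", "procedures"):
            df = shuffled.table(name)
            setattr(shuffled, name,
                    df.sample(frac=1, random_state=rng.integers(2**31)).reset_index(drop=True))
        got = mb.depressive_events(shuffled, pid, codebook)
        pd.testing.assert_frame_equal(ref, got)
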