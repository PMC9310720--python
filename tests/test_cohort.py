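"""Incident cases, exclusions, control eligibility, matching and censoring."""

import numpy as np
import pandas as pd
import pytest

import mddburden as mb
from conftest import make_tables, person

WINDOW = ("2012-01-01", "2019-01-01")
END = "2018-12-31"


def dx(pid, date, icd10="F320", care_level="primary"):
    return {"person_id": pid, "date": date, "icd10": icd10, "care_level": care_level}


class TestIncidentCases:
    def test_first_ever_outside_window_is_not_incident(self, codebook):
        p, r = person()
        t = make_tables(persons=[p], residency=[r],
                        diagnoses=[dx("P1", "2011-06-01"), dx("P1", "2013-02-01", "F331")])
        assert mb.find_incident_cases(t, codebook, WINDOW) == []

    def test_boundary_first_day_included(self, codebook):
        p, r = person()
        t = make_tables(persons=[p], residency=[r],
                        diagnoses=[dx("P1", "2012-01-01", "F331")])
        cases = mb.find_incident_cases(t, codebook, WINDOW)
        assert len(cases) == 1
        assert cases[0].index_date == pd.Timestamp("2012-01-01")
        assert cases[0].age_at_index == 32

    def test_same_day_tie_break_prefers_psychiatric(self, codebook):
        p, r = person()
        t = make_tables(persons=[p], residency=[r],
                        diagnoses=[dx("P1", "2013-02-01", care_level="primary"),
                                   dx("P1", "2013-02-01",
                                      care_level="psychiatric_outpatient")])
        cases = mb.find_incident_cases(t, codebook, WINDOW)
        assert len(cases) == 1
        assert cases[0].care_level_at_index == "psychiatric"


class TestExclusions:
    def run(self, codebook, extra_dx=(), res=("2010-01-01", "2019-01-01")):
        p, r = person(res=res)
        t = make_tables(persons=[p], residency=[r],
                        diagnoses=[dx("P1", "2013-02-01"), *extra_dx])
        cases = mb.find_incident_cases(t, codebook, WINDOW)
        return mb.apply_exclusions(cases, t, codebook)

    def test_bipolar_history_excludes(self, codebook):
        assert self.run(codebook, [dx("P1", "2011-02-01", "F319")]) == []

    def test_psychosis_after_index_retained(self, codebook):
        kept = self.run(codebook, [dx("P1", "2014-02-01", "F200")])
        assert len(kept) == 1

    def test_short_residency_excludes(self, codebook):
        # residency starts 100 days before index: fails the 12-month washout
        assert self.run(codebook, res=("2012-10-24", "2019-01-01")) == []


class TestControlEligibility:
    def build(self, **overrides):
        rows = [person(pid="P1"), person(pid="C1", sex="F", birth="1980-06-01")]
        t = make_tables(persons=[r[0] for r in rows], residency=[r[1] for r in rows],
                        **overrides)
        return t

    def test_any_time_ad_fill_makes_ineligible(self, codebook):
        t = self.build(dispensations=[{"person_id": "C1", "date": "2017-05-01",
                                       "atc": "N06AX16", "tablets": 30}])
        assert not mb.eligible_control("C1", "2013-01-01", t, codebook)

    def test_dead_before_index_ineligible(self, codebook):
        rows = [person(pid="C1", death="2012-06-01", res=("2010-01-01", "2012-06-02"))]
        t = make_tables(persons=[r[0] for r in rows], residency=[r[1] for r in rows])
        assert not mb.eligible_control("C1", "2013-01-01", t, codebook)

    def test_clean_resident_eligible(self, codebook):
        assert mb.eligible_control("C1", "2013-01-01", self.build(), codebook)

    def test_self_harm_any_time_ineligible(self, codebook):
        t = self.build(diagnoses=[dx("C1", "2018-03-01", "X780")])
        assert not mb.eligible_control("C1", "2013-01-01", t, codebook)


class TestMatching:
    def cohort_tables(self, n_controls=1, control_muni="M01"):
        rows = [person(pid="CASE", sex="F", birth="1980-01-01", muni="M01")]
        for i in range(n_controls):
            rows.append(person(pid=f"C{i}", sex="F", birth="1981-03-01",
                               muni=control_muni))
        t = make_tables(persons=[r[0] for r in rows],
                        residency=[r[1] for r in rows],
                        diagnoses=[dx("CASE", "2013-02-01")])
        return t

    def test_singleton_stratum_chosen(self, codebook):
        t = self.cohort_tables(1)
        cases = mb.find_incident_cases(t, codebook, WINDOW)
        pairs = mb.match_controls(cases, t, codebook, seed=0)
        assert list(pairs["control_id"]) == ["C0"]

    def test_no_same_municipality_candidate_unmatched(self, codebook):
        t = self.cohort_tables(1, control_muni="M99")
        cases = mb.find_incident_cases(t, codebook, WINDOW)
        pairs = mb.match_controls(cases, t, codebook, seed=0)
        assert pairs["control_id"].iloc[0] is None
        assert len(pairs) == 1  # unmatched case kept

    def test_seed_reproducible(self, codebook, sim_small):
        t, cb = sim_small["tables"], sim_small["codebook"]
        cases = mb.apply_exclusions(
            mb.find_incident_cases(t, cb, WINDOW), t, cb)
        p1 = mb.match_controls(cases, t, cb, seed=42)
        p2 = mb.match_controls(cases, t, cb, seed=42)
        pd.testing.assert_frame_equal(p1, p2)

    def test_matching_balance(self, sim_large):
        """Matched controls mirror cases on sex exactly and age within the
        2-year caliper; the match rate is high in an adequate population."""
        coh = sim_large["cohort"]
        matched = coh[coh["control_id"].notna()]
        assert len(matched) / len(coh) > 0.95
        persons = sim_large["tables"].persons.set_index("person_id")
        ctrl = persons.loc[matched["control_id"]]
        assert (ctrl["sex"].to_numpy() == matched["sex"].to_numpy()).all()
        ctrl_age = ((matched["index_date"].to_numpy()
                     - ctrl["birth_date"].to_numpy())
                    / np.timedelta64(1, "D")) // 365.25
        diff = np.abs(ctrl_age - matched["age"].to_numpy())
        assert diff.max() <= 2
        assert diff.mean() <= 2

    def test_no_duplicate_cases_and_follow_up_after_index(self, sim_small):
        coh = sim_small["cohort"]
        assert coh["case_id"].is_unique
        assert (coh["follow_up_end"] >= coh["index_date"]).all()


class TestCensoring:
    def censored(self, codebook, extra_dx=(), death=None,
                 res=("2010-01-01", "2019-01-01")):
        p, r = person(death=death, res=res)
        t = make_tables(persons=[p], residency=[r],
                        diagnoses=[dx("P1", "2013-02-01"), *extra_dx])
        return mb.censor("P1", "2013-02-01", t, codebook, END)

    def test_no_terminating_events_end_of_data(self, codebook):
        ci = self.censored(codebook)
        assert (ci.follow_up_end, ci.reason) == (pd.Timestamp(END), "end_of_data")

    def test_exclusion_dx_before_death_wins(self, codebook):
        ci = self.censored(codebook, extra_dx=[dx("P1", "2013-05-02", "F200")],
                           death="2013-08-20")
        assert ci.reason == "exclusion_dx"
        assert ci.follow_up_end == pd.Timestamp("2013-05-02")

    def test_same_day_tie_break_death_over_emigration(self, codebook):
        ci = self.censored(codebook, death="2014-03-01",
                           res=("2010-01-01", "2014-03-01"))
        assert ci.reason == "death"
        assert ci.follow_up_end == pd.Timestamp("2014-03-01")

    def test_emigration(self, codebook):
        ci = self.censored(codebook, res=("2010-01-01", "2015-06-01"))
        assert (ci.follow_up_end, ci.reason) == (pd.Timestamp("2015-06-01"),
                                                 "emigration")
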