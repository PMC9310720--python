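"""Weighted annual estimator, ratios and monthly HRU / work-loss series."""

import numpy as np
import pandas as pd
import pytest

import mddburden as mb
from mddburden.burden import monthly_hru, monthly_workloss, person_outcomes
from conftest import make_tables, person


class TestWeightedAnnualMean:
    def test_closed_form_two_observations(self):
        est = mb.weighted_annual_mean([2.0, 4.0], [1.0, 1.0])
        assert est.estimate == pytest.approx(3.0)
        assert est.se == pytest.approx(np.sqrt(2) / 2, abs=1e-6)
        assert est.ci95[0] == pytest.approx(1.614, abs=1e-3)
        assert est.ci95[1] == pytest.approx(4.386, abs=1e-3)

    def test_exact_fit_zero_se(self):
        w = np.array([0.3, 0.7, 1.0])
        est = mb.weighted_annual_mean(5.0 * w, w)
        assert est.estimate == pytest.approx(5.0)
        assert est.se == 0.0

    def test_unit_weights_match_sample_moments(self):
        rng = np.random.default_rng(3)
        x = rng.poisson(4.0, 500).astype(float)
        est = mb.weighted_annual_mean(x, np.ones_like(x))
        n = len(x)
        assert est.estimate == pytest.approx(x.mean())
        expect_se = np.sqrt((n - 1) / n) * x.std(ddof=1) / np.sqrt(n)
        assert est.se == pytest.approx(expect_se, rel=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            mb.weighted_annual_mean([1.0], [0.0])
        with pytest.raises(ValueError):
            mb.weighted_annual_mean([], [])


class TestBurdenRatio:
    @pytest.mark.parametrize("a,b,expected", [
        (7.90, 2.48, 3.2), (5.68, 2.58, 2.2), (3.0, 3.0, 1.0)])
    def test_rounded_ratios(self, a, b, expected):
        assert mb.burden_ratio(a, b) == expected

    def test_round_half_up_not_bankers(self):
        assert mb.burden_ratio(2.25, 1.0) == 2.3

    def test_zero_denominator_error(self):
        with pytest.raises(ValueError):
            mb.burden_ratio(1.0, 0.0)


def one_person_panel(index="2014-06-15", fue="2018-12-31", age=40):
    return pd.DataFrame([{"person_id": "P1", "index_date": pd.Timestamp(index),
                          "follow_up_end": pd.Timestamp(fue), "age": age,
                          "group": "mdd"}])


def series_of(df, measure):
    return df[df["measure"] == measure].set_index("month")["mean"]


class TestMonthlyHRU:
    def test_stay_spanning_month_boundary_splits_days(self, codebook):
        p, r = person()
        t = make_tables(persons=[p], residency=[r], stays=[
            {"person_id": "P1", "admission_date": "2014-07-22",
             "discharge_date": "2014-08-06", "ward": "psychiatric"}])
        out = monthly_hru(one_person_panel(), t)
        total = series_of(out, "beddays_total")
        assert total[1] == 10.0   # Jul 22..31
        assert total[2] == 5.0    # Aug 1..5
        psych = series_of(out, "beddays_psychiatric")
        assert psych[1] == 10.0 and psych[2] == 5.0

    def test_non_physician_visit_not_counted(self, codebook):
        p, r = person()
        t = make_tables(persons=[p], residency=[r], visits=[
            {"person_id": "P1", "date": "2014-06-20", "care_level": "primary",
             "physician": False},
            {"person_id": "P1", "date": "2014-06-21", "care_level": "primary",
             "physician": True}])
        out = monthly_hru(one_person_panel(), t)
        assert series_of(out, "visits_total")[0] == 1.0
        assert series_of(out, "visits_primary")[0] == 1.0

    def test_zero_events_all_zero(self, codebook):
        p, r = person()
        t = make_tables(persons=[p], residency=[r])
        out = monthly_hru(one_person_panel(), t)
        assert (out["mean"] == 0).all()

    def test_bedday_decomposition_exact(self, sim_small):
        panel = mb.case_panel(sim_small["cohort"])
        out = monthly_hru(panel, sim_small["tables"])
        total = series_of(out, "beddays_total")
        parts = series_of(out, "beddays_psychiatric") + \
            series_of(out, "beddays_non_psychiatric")
        assert np.allclose(total.to_numpy(), parts.to_numpy())


class TestMonthlyWorkloss:
    def spells(self, codebook, spells, age=40):
        p, r = person()
        t = make_tables(persons=[p], residency=[r], workloss=spells)
        return monthly_workloss(one_person_panel(age=age), t)

    def test_short_sick_spell_dropped(self, codebook):
        out = self.spells(codebook, [{"person_id": "P1", "start": "2014-07-01",
                                      "end": "2014-07-14", "kind": "sick_leave",
                                      "extent": 1.0}])
        assert (out["mean"] == 0).all()

    def test_extent_scales_days(self, codebook):
        out = self.spells(codebook, [{"person_id": "P1", "start": "2014-07-01",
                                      "end": "2014-07-31", "kind": "sick_leave",
                                      "extent": 0.5}])
        assert series_of(out, "workloss_total")[1] == 15.0
        assert series_of(out, "workloss_sick_leave")[1] == 15.0

    def test_under_20_excluded_from_denominator(self, codebook):
        out = self.spells(codebook, [{"person_id": "P1", "start": "2014-07-01",
                                      "end": "2014-07-31", "kind": "sick_leave",
                                      "extent": 1.0}], age=19)
        assert (out["n_at_risk"] == 0).all()

    def test_short_disability_spell_kept(self, codebook):
        out = self.spells(codebook, [{"person_id": "P1", "start": "2014-07-01",
                                      "end": "2014-07-08", "kind": "disability_pension",
                                      "extent": 1.0}])
        assert series_of(out, "workloss_disability_pension")[1] == 7.0


class TestAnnualConsistency:
    def test_monthly_sum_equals_annual_totals_for_fully_followed(self, codebook):
        """With the index on Jan 1, calendar months 0..11 tile the post-index
        day window exactly, so the Fig-3 and Table-2 machinery agree."""
        rng = np.random.default_rng(8)
        persons_, res, visits = [], [], []
        for i in range(30):
            p, r = person(pid=f"P{i}")
            persons_.append(p)
            res.append(r)
            for day in rng.integers(0, 365, rng.poisson(6)):
                visits.append({"person_id": f"P{i}",
                               "date": pd.Timestamp("2014-01-01")
                               + pd.Timedelta(days=int(day)),
                               "care_level": "primary", "physician": True})
        t = make_tables(persons=persons_, residency=res, visits=visits)
        panel = pd.DataFrame([{"person_id": f"P{i}",
                               "index_date": pd.Timestamp("2014-01-01"),
                               "follow_up_end": pd.Timestamp("2018-12-31"),
                               "age": 40, "group": "mdd"} for i in range(30)])
        out = monthly_hru(panel, t)
        monthly = out[(out["measure"] == "visits_total") & (out["month"] >= 0)
                      & (out["month"] <= 11)]
        monthly_total = (monthly["mean"] * monthly["n_at_risk"]).sum()
        po = person_outcomes(panel, t, "post")
        assert monthly_total == pytest.approx(po["visits_total"].sum())
        assert (po["w"] == 1.0).all()

    def test_post_weights_censoring_aware(self, codebook):
        p, r = person()
        t = make_tables(persons=[p], residency=[r])
        panel = one_person_panel(index="2014-06-15", fue="2014-12-15")
        po = person_outcomes(panel, t, "post")
        # followed [index, fue] inclusive = 184 of 365 days
        assert po["w"].iloc[0] == pytest.approx(184 / 365)
        pre = person_outcomes(panel, t, "pre")
        assert pre["w"].iloc[0] == 1.0
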