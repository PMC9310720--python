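"""Episode stitching: hand-traced fixtures, oracle equivalence, KM."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import mddburden as mb
from mddburden.episodes import EpisodeParams, build_episodes

from oracle import BASE, day_events_frame, daygrid_episodes, random_stream

P365 = EpisodeParams(gap_days=365)
P180 = EpisodeParams(gap_days=180)


def run(stream, params, data_end_day):
    events = day_events_frame(stream)
    eps = build_episodes(events, BASE, params, BASE + pd.Timedelta(days=data_end_day))
    return [((e.start_date - BASE).days, (e.end_date - BASE).days, e.closure)
            for e in eps]


class TestHandTraces:
    def test_single_diagnosis_degenerate(self):
        assert run([(0, "dx", None)], P365, 2000) == [(0, 0, "gap")]

    def test_terminal_dispensation_extends_by_tablets(self):
        # dx d0, AD fill d200 with 100 tablets: gap 200 keeps the episode
        # ongoing; the fill is the last event, so the end moves 100 days out
        got = run([(0, "dx", None), (200, "disp", 100)], P365, 2000)
        assert got == [(0, 300, "extension_after_gap")]

    def test_extension_capped_at_100_days(self):
        got = run([(0, "dx", None), (200, "disp", 130)], P365, 2000)
        assert got == [(0, 300, "extension_after_gap")]

    def test_multi_episode_trace(self):
        # d0 dx; d300 dx; d700 dx; d1200 fill(30); d1300 dx, far data end:
        # d300->d700 gap 400 closes ep1 at d300; d700 dx opens ep2, closed at
        # d700 by the 500-day gap; the d1200 dispensation cannot start an
        # episode; d1300 dx opens ep3
        stream = [(0, "dx", None), (300, "dx", None), (700, "dx", None),
                  (1200, "disp", 30), (1300, "dx", None)]
        got = run(stream, P365, 3000)
        assert got == [(0, 300, "gap"), (700, 700, "gap"), (1300, 1300, "gap")]

    def test_sensitivity_gap_splits_more(self):
        stream = [(0, "dx", None), (300, "dx", None), (700, "dx", None),
                  (1200, "disp", 30), (1300, "dx", None)]
        got365 = run(stream, P365, 3000)
        got180 = run(stream, P180, 3000)
        assert len(got180) > len(got365)
        assert got180 == [(0, 0, "gap"), (300, 300, "gap"), (700, 700, "gap"),
                          (1300, 1300, "gap")]

    def test_open_at_data_end(self):
        got = run([(0, "dx", None), (100, "dx", None)], P365, 300)
        assert got == [(0, 100, "open_at_data_end")]

    def test_same_day_mixed_classes_keep_dispensation_for_extension(self):
        got = run([(0, "dx", None), (50, "dx", None), (50, "disp", 40)], P365, 2000)
        assert got == [(0, 90, "extension_after_gap")]

    def test_empty_stream_raises(self):
        with pytest.raises(ValueError):
            build_episodes(day_events_frame([]).iloc[0:0], BASE, P365, BASE)


class TestOracleEquivalence:
    @pytest.mark.parametrize("gap_days", [180, 365])
    def test_random_streams_match_daygrid(self, gap_days):
        rng = np.random.default_rng(314)
        params = EpisodeParams(gap_days=gap_days)
        for _ in range(300):
            stream, data_end = random_stream(rng)
            expect = daygrid_episodes(stream, gap_days, data_end)
            assert run(stream, params, data_end) == expect

    @given(st.data())
    @settings(max_examples=120, deadline=None, derandomize=True)
    def test_property_daygrid_agreement(self, data):
        gaps = data.draw(st.lists(st.integers(0, 450), min_size=0, max_size=8))
        kinds = data.draw(st.lists(
            st.tuples(st.sampled_from(["dx", "disp", "proc"]), st.integers(1, 140)),
            min_size=len(gaps), max_size=len(gaps)))
        stream = [(0, "dx", None)]
        day = 0
        for g, (kind, tabs) in zip(gaps, kinds):
            day += g
            stream.append((day, kind, tabs if kind == "disp" else None))
        data_end = day + data.draw(st.integers(0, 500))
        for G in (180, 365):
            assert run(stream, EpisodeParams(gap_days=G), data_end) == \
                daygrid_episodes(stream, G, data_end)


class TestEpisodeInvariants:
    def test_gap_invariants_on_random_streams(self):
        rng = np.random.default_rng(99)
        for _ in range(200):
            stream, data_end = random_stream(rng)
            eps = run(stream, P365, data_end)
            days = sorted({d for d, _, _ in stream})
            for k, (s, e, closure) in enumerate(eps):
                inside = [d for d in days if s <= d <= min(e, data_end)]
                gaps = np.diff([s] + inside)
                assert (gaps <= 365).all()
                if closure == "extension_after_gap":
                    last_event = max(d for d in days if d <= e)
                    assert e - last_event <= 100
                if k + 1 < len(eps):
                    assert eps[k + 1][0] - max(d for d in days if d <= e) > 365

    def test_shorter_gap_never_lengthens_first_episode(self):
        # open episodes run to the data end in the duration analysis, so the
        # comparison uses that effective end
        rng = np.random.default_rng(7)
        for _ in range(200):
            stream, data_end = random_stream(rng)
            e180 = run(stream, P180, data_end)[0]
            e365 = run(stream, P365, data_end)[0]
            eff = lambda ep: data_end if ep[2] == "open_at_data_end" else ep[1]
            assert eff(e180) - e180[0] <= eff(e365) - e365[0]


class TestDurations:
    def make(self, start_day, end_day, closure):
        return [mb.Episode("X", 1, BASE + pd.Timedelta(days=start_day),
                           BASE + pd.Timedelta(days=end_day), closure, 2)]

    def test_short_follow_up_excluded(self):
        eps = self.make(0, 100, "gap")
        assert mb.episode_durations(eps, BASE + pd.Timedelta(days=200)) is None

    def test_closed_episode_observed(self):
        eps = self.make(0, 398, "gap")
        got = mb.episode_durations(eps, BASE + pd.Timedelta(days=3 * 365))
        assert got == (398.0, True)

    def test_open_episode_censored_at_follow_up_end(self):
        eps = self.make(0, 500, "open_at_data_end")
        got = mb.episode_durations(eps, BASE + pd.Timedelta(days=450))
        assert got == (450.0, False)


class TestKaplanMeier:
    def test_product_limit_by_hand(self):
        km = mb.km_fit([1, 2, 3, 4, 5], [True] * 5)
        steps = dict(zip(km.times, km.survival))
        for t, s in [(1, 0.8), (2, 0.6), (3, 0.4), (4, 0.2), (5, 0.0)]:
            assert steps[t] == pytest.approx(s)
        assert km.median == 3

    def test_no_censoring_median_is_sample_median(self):
        rng = np.random.default_rng(1)
        x = rng.integers(1, 1000, 201).astype(float)
        km = mb.km_fit(x, np.ones_like(x, dtype=bool))
        assert km.median == np.sort(x)[100]  # smallest t with S(t) <= 0.5

    def test_survival_non_increasing_from_one(self):
        rng = np.random.default_rng(2)
        x = rng.exponential(100, 400)
        obs = rng.random(400) < 0.7
        km = mb.km_fit(x, obs)
        assert km.survival[0] <= 1.0
        assert (np.diff(km.survival) <= 1e-12).all()


def test_duration_recovery_from_generator_truth():
    """KM median of stitched incident episodes recovers the generator's
    log-normal truth (median 398 d) under light censoring."""
    cfg = mb.SimConfig(seed=11, n_persons=6000, annual_mdd_onset_rate=0.12,
                       inclusion_window=("2012-01-01", "2015-01-01"))
    tables, truth = mb.generate(cfg)
    cb = mb.default_codebook()
    coh = mb.build_cohort(tables, cb, cfg.inclusion_window, "2018-12-31", seed=11)
    events = mb.depressive_events_all(tables, cb)
    from mddburden.pipeline import _km_input
    eps = mb.cohort_episodes(events, coh, P365, "2018-12-31")
    km_in = _km_input(eps, coh)
    km = mb.km_fit(km_in["duration"], km_in["observed"])
    assert km.n > 1000
    assert abs(km.median - 398) / 398 < 0.03
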