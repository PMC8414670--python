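import numpy as np
import pytest

from sptconfine.confinement import (ConfinementConfig, classify_track,
                                    confinement_radius, detect_dwell_events,
                                    detect_transitions, dwell_survival,
                                    fit_dwell_decay)
from sptconfine.msd import LocalizationError

from .conftest import TAU, make_track
from .oracles import oracle_dwell_events


def random_track(rng, n_points, step_scale=0.08, gap_prob=0.1):
    """Random walk with occasional single-frame gaps and occasional large
    excursions, exercising every branch of the dwell rules."""
    steps = rng.standard_normal((n_points - 1, 2)) * step_scale
    big = rng.random(n_points - 1) < 0.15
    steps[big] *= 5
    xy = np.vstack([[0, 0], np.cumsum(steps, axis=0)])
    frames = [0]
    for _ in range(n_points - 1):
        frames.append(frames[-1] + (2 if rng.random() < gap_prob else 1))
    return make_track(xy, frames=frames)


class TestRadius:
    def test_factor_scaling(self):
        loc = LocalizationError(np.array([0.04]), 0.04)
        assert confinement_radius(loc) == pytest.approx(0.10)
        assert confinement_radius(loc, factor=1.0) == pytest.approx(0.04)

    def test_zero_error_rejected(self):
        with pytest.raises(ValueError):
            confinement_radius(LocalizationError(np.array([0.0]), 0.0))


class TestDetector:
    def test_stationary_track_single_event(self):
        t = make_track(np.zeros((10, 2)))
        cfg = ConfinementConfig(radius=0.1, min_steps=5)
        events = detect_dwell_events(t, cfg, tau=TAU)
        assert len(events) == 1
        ev = events[0]
        assert (ev.start, ev.end, ev.n_steps) == (0, 9, 9)
        assert ev.dwell_time == pytest.approx(9 * TAU)

    def test_spread_out_track_no_events(self):
        R = 0.1
        xy = np.column_stack([np.arange(10) * 2 * R, np.zeros(10)])
        events = detect_dwell_events(make_track(xy), ConfinementConfig(radius=R, min_steps=3))
        assert events == []

    def test_dwell_then_escape(self):
        rng = np.random.default_rng(5)
        inside = rng.standard_normal((11, 2)) * 0.02
        run_out = np.column_stack([np.arange(1, 10) * 0.5, np.zeros(9)])
        xy = np.vstack([inside, inside[-1] + run_out])
        cfg = ConfinementConfig(radius=0.08, min_steps=5)
        t = make_track(xy)
        events = detect_dwell_events(t, cfg)
        assert len(events) == 1
        oracle = oracle_dwell_events(t, cfg)
        assert (events[0].start, events[0].end) == oracle[0][:2]

    def test_single_outlier_bridged(self):
        xy = np.zeros((10, 2))
        xy[4] = (1.0, 0.0)  # one excursion that returns
        cfg = ConfinementConfig(radius=0.1, min_steps=5)
        events = detect_dwell_events(make_track(xy), cfg)
        assert len(events) == 1
        assert events[0].outliers_used == 1
        assert events[0].n_steps == 9

    def test_two_outliers_split_event(self):
        xy = np.zeros((12, 2))
        xy[3] = (1.0, 0.0)
        xy[8] = (1.0, 0.0)
        cfg = ConfinementConfig(radius=0.1, min_steps=3)
        events = detect_dwell_events(make_track(xy), cfg)
        # strict mode: only one irregularity per event
        assert all(ev.outliers_used + ev.gaps_bridged <= 1 for ev in events)

    def test_single_frame_gap_bridged(self):
        t = make_track(np.zeros((9, 2)), frames=[0, 1, 2, 3, 5, 6, 7, 8, 9])
        cfg = ConfinementConfig(radius=0.1, min_steps=5)
        events = detect_dwell_events(t, cfg)
        assert len(events) == 1
        assert events[0].gaps_bridged == 1
        assert events[0].n_steps == 9

    @pytest.mark.parametrize("strict", [True, False])
    def test_greedy_equals_exhaustive_oracle(self, strict):
        rng = np.random.default_rng(99)
        cfg = ConfinementConfig(radius=0.15, min_steps=3,
                                combine_gap_outlier=not strict)
        for i in range(120):
            t = random_track(rng, int(rng.integers(5, 26)))
            got = sorted((ev.start, ev.end, ev.n_steps)
                         for ev in detect_dwell_events(t, cfg))
            assert got == oracle_dwell_events(t, cfg), f"track {i}"

    def test_events_never_overlap_and_min_steps_monotone(self):
        rng = np.random.default_rng(77)
        for _ in range(40):
            t = random_track(rng, 25)
            prev = None
            for ms in (3, 4, 5, 6, 9):
                cfg = ConfinementConfig(radius=0.15, min_steps=ms)
                events = detect_dwell_events(t, cfg)
                spans = sorted((ev.start, ev.end) for ev in events)
                for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                    assert e1 < s2
                if prev is not None:
                    assert len(events) <= prev
                prev = len(events)

    def test_radius_monotonicity_in_covered_steps(self):
        rng = np.random.default_rng(55)
        for _ in range(20):
            t = random_track(rng, 20)
            covered = []
            for R in (0.05, 0.1, 0.2, 0.4):
                cfg = ConfinementConfig(radius=R, min_steps=3)
                covered.append(sum(ev.n_steps
                                   for ev in detect_dwell_events(t, cfg)))
            assert covered == sorted(covered)


class TestVerdicts:
    def test_free_mixed_confined(self):
        t_free = make_track(np.column_stack([np.arange(16) * 0.5, np.zeros(16)]))
        cfg = ConfinementConfig(radius=0.1, min_steps=5)
        assert classify_track(t_free, detect_dwell_events(t_free, cfg)).category == "free"

        t_conf = make_track(np.zeros((16, 2)))
        v = classify_track(t_conf, detect_dwell_events(t_conf, cfg))
        assert v.category == "confined" and v.confined_fraction == 1.0

        dwell = np.zeros((7, 2))
        out = dwell[-1] + np.column_stack([np.arange(1, 10) * 0.5, np.zeros(9)])
        t_mix = make_track(np.vstack([dwell, out]))
        v = classify_track(t_mix, detect_dwell_events(t_mix, cfg))
        assert v.category == "mixed"
        assert v.confined_fraction == pytest.approx(6 / 15)


class TestDwellTimes:
    def test_single_event_survival(self):
        t, s = dwell_survival(np.array([0.05]))
        assert t[0] == 0.05 and s[0] == 0.0

    def test_equal_times_single_step(self):
        t, s = dwell_survival(np.full(10, 0.2))
        assert np.all(t == 0.2)
        assert s[-1] == 0.0

    def test_exponential_sample_within_dkw_band(self):
        rng = np.random.default_rng(1)
        rate = 20.0
        times = rng.exponential(1 / rate, 10_000)
        t, s = dwell_survival(times)
        eps = np.sqrt(np.log(2 / 0.001) / (2 * len(times)))
        assert np.max(np.abs(s - np.exp(-rate * t))) < eps

    def test_single_exponential_recovery(self):
        rng = np.random.default_rng(2)
        times = rng.exponential(0.05, 4000)
        fit = fit_dwell_decay(dwell_survival(times))
        assert fit.n_components == 1
        assert fit.taus[0] == pytest.approx(0.05, rel=0.1)

    def test_two_exponential_recovery(self):
        rng = np.random.default_rng(3)
        times = np.concatenate([rng.exponential(0.03, 5000),
                                rng.exponential(0.3, 5000)])
        fit = fit_dwell_decay(dwell_survival(times))
        assert fit.n_components == 2
        assert fit.taus[0] == pytest.approx(0.03, rel=0.2)
        assert fit.taus[1] == pytest.approx(0.3, rel=0.2)
        assert fit.amplitudes.sum() == pytest.approx(1.0)

    def test_constant_sample_flagged_degenerate(self):
        fit = fit_dwell_decay(dwell_survival(np.full(20, 0.1)))
        assert fit.degenerate


class TestTransitions:
    def test_free_track_has_none(self):
        t = make_track(np.column_stack([np.arange(16) * 0.5, np.zeros(16)]))
        cfg = ConfinementConfig(radius=0.1, min_steps=5)
        counts = detect_transitions(t, detect_dwell_events(t, cfg), cfg.radius)
        assert counts.confined_to_free == 0 and counts.free_to_confined == 0

    def test_dwell_then_fast_exit_counts_one(self):
        dwell = np.zeros((8, 2))
        exit_run = np.column_stack([np.arange(1, 5) * 0.5, np.zeros(4)])
        t = make_track(np.vstack([dwell, dwell[-1] + exit_run]))
        cfg = ConfinementConfig(radius=0.1, min_steps=5)
        events = detect_dwell_events(t, cfg)
        counts = detect_transitions(t, events, cfg.radius)
        assert counts.confined_to_free == 1
        assert counts.free_to_confined == 0

    def test_slow_exit_below_radius_does_not_count(self):
        dwell = np.zeros((8, 2))
        exit_run = np.column_stack([np.arange(1, 5) * 0.01, np.zeros(4)])
        t = make_track(np.vstack([dwell, dwell[-1] + exit_run]))
        cfg = ConfinementConfig(radius=0.1, min_steps=5)
        events = detect_dwell_events(t, cfg)
        counts = detect_transitions(t, events, cfg.radius)
        assert counts.confined_to_free == 0
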