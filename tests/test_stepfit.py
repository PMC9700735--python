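from itertools import combinations

import numpy as np
import pytest

from nucleoforce import synth
from nucleoforce.stepfit import (
    ForceClampTrace,
    Segment,
    StretchCurve,
    classify_events,
    count_ruptures,
    fit_steps,
)


def exhaustive_changepoints(x: np.ndarray, n_breaks: int) -> tuple:
    """Exact least-squares change-point search by enumeration.

    Independent oracle for the binary-segmentation detector: evaluates
    the residual sum of squares of every breakpoint combination.
    """
    c = np.concatenate([[0.0], np.cumsum(x)])
    c2 = np.concatenate([[0.0], np.cumsum(x * x)])

    def rss(a, b):
        s, s2 = c[b] - c[a], c2[b] - c2[a]
        return s2 - s * s / (b - a)

    best, best_rss = (), rss(0, len(x))
    for combo in combinations(range(1, len(x)), n_breaks):
        bounds = (0, *combo, len(x))
        r = sum(rss(a, b) for a, b in zip(bounds[:-1], bounds[1:]))
        if r < best_rss - 1e-12:
            best, best_rss = combo, r
    return best


def make_staircase(levels, dwell_s, rate=50.0, noise_sd=0.0, seed=0):
    rng = np.random.default_rng(seed)
    per = int(dwell_s * rate)
    d = np.concatenate([np.full(per, lv, dtype=float) for lv in levels])
    if noise_sd:
        d = d + noise_sd * rng.standard_normal(d.size)
    t = np.arange(d.size) / rate
    return ForceClampTrace(time=t, distance=d, force_setpoint=10.0)


class TestFitSteps:
    def test_noiseless_staircase_exact(self, noiseless_staircase):
        segs = fit_steps(noiseless_staircase)
        assert len(segs) == 3
        assert [round(s.level, 6) for s in segs] == [0.0, 26.0, 52.0]
        assert segs[1].start == pytest.approx(100.0, abs=0.02)
        assert segs[2].start == pytest.approx(200.0, abs=0.02)

    def test_flat_noisy_trace_single_segment(self):
        trace = make_staircase([0.0], 60.0, noise_sd=3.0, seed=1)
        assert len(fit_steps(trace)) == 1

    def test_short_trace_returns_single_segment(self):
        trace = make_staircase([0, 26], 0.2)  # shorter than 2x min_dwell
        assert len(fit_steps(trace)) == 1

    @pytest.mark.parametrize("n_breaks", [1, 2, 3])
    def test_matches_exhaustive_search_on_noiseless_traces(self, n_breaks):
        """On clean staircases the detector equals exact LS enumeration."""
        levels = [26.0 * i for i in range(n_breaks + 1)]
        trace = make_staircase(levels, dwell_s=1.0, rate=20.0)
        segs = fit_steps(trace, min_dwell=0.5)
        found = [int(round(s.start * 20.0)) for s in segs[1:]]
        oracle = list(exhaustive_changepoints(trace.distance, n_breaks))
        assert found == oracle

    def test_recall_on_noisy_staircases(self):
        """>=95% of 26-nm steps with >=2 s dwells found within 0.1 s."""
        rng = np.random.default_rng(99)
        hits = total = 0
        for rep in range(25):
            n_steps = 5
            dwells = rng.uniform(2.0, 20.0, n_steps + 1)
            true_times = np.cumsum(dwells)[:-1]
            t = np.arange(0, dwells.sum(), 0.02)
            d = np.zeros_like(t)
            for tt in true_times:
                d[t >= tt] += 26.0
            d += 3.0 * rng.standard_normal(t.size)
            trace = ForceClampTrace(t, d, 10.0)
            segs = fit_steps(trace)
            found_times = np.array([s.start for s in segs[1:]])
            for tt in true_times:
                total += 1
                if found_times.size and np.min(np.abs(found_times - tt)) <= 0.1:
                    hits += 1
        assert hits / total >= 0.95

    def test_idempotent_on_fitted_signal(self):
        trace = make_staircase([0, 26, 52], 10.0, noise_sd=3.0, seed=5)
        segs = fit_steps(trace)
        # rebuild the piecewise-constant fit and refit it
        d = np.concatenate(
            [
                np.full(int(round((s.end - s.start) * 50)), s.level)
                for s in segs
            ]
        )
        refit = fit_steps(
            ForceClampTrace(np.arange(d.size) / 50.0, d, 10.0)
        )
        assert [round(s.level, 9) for s in refit] == [
            round(s.level, 9) for s in segs
        ]


class TestClassifyEvents:
    def seg(self, levels, dwell=100.0):
        return [
            Segment(start=i * dwell, end=(i + 1) * dwell, level=lv)
            for i, lv in enumerate(levels)
        ]

    def test_single_step(self):
        (ev,) = classify_events(self.seg([0, 26]))
        assert ev.size == pytest.approx(26)
        assert ev.multiplicity == 1

    def test_double_step_counted_twice(self):
        (ev,) = classify_events(self.seg([0, 52]))
        assert ev.multiplicity == 2
        assert not ev.anomalous

    def test_loop_excursion_excluded_by_net_increase_filter(self):
        # transient shortening and recovery contribute no events
        events = classify_events(self.seg([0, -30, 0, 26]))
        assert len(events) == 1
        assert events[0].size == pytest.approx(26)

    def test_triple_step_flagged_anomalous(self):
        (ev,) = classify_events(self.seg([0, 80]))
        assert ev.anomalous
        assert ev.implied_multiplicity == 3

    def test_empty_segments_rejected(self):
        with pytest.raises(ValueError):
            classify_events([])


class TestCountRuptures:
    @pytest.mark.parametrize("n_remaining", [0, 5, 9])
    def test_round_trip_with_generator(self, n_remaining):
        curve, _ = synth.simulate_stretch_curve(n_remaining, seed=n_remaining + 7)
        assert count_ruptures(curve) == n_remaining

    def test_rupture_contour_shifts_average_26nm(self):
        _, truth = synth.simulate_stretch_curve(40, seed=3)
        shifts = [sh for _, sh in truth.segment_plan]
        assert np.mean(shifts) == pytest.approx(26.0, abs=1.0)

    def test_requires_35pN(self):
        curve = StretchCurve(
            distance=np.linspace(100, 200, 50), force=np.linspace(1, 20, 50)
        )
        with pytest.raises(ValueError, match="35"):
            count_ruptures(curve)

    def test_non_monotone_force_rejected(self):
        f = np.linspace(2, 40, 50)
        f[10] = f[9]
        with pytest.raises(ValueError, match="increasing"):
            count_ruptures(StretchCurve(distance=np.linspace(100, 200, 50), force=f))


class TestConservation:
    @pytest.mark.parametrize("seed", range(6))
    def test_events_plus_ruptures_equals_nucleosome_count(self, seed):
        """Clamp events (with multiplicity) + stretch ruptures = array size."""
        cfg = synth.SimulationConfig(
            n_nucleosomes=15, condition="NO_PROTEIN", seed=seed
        )
        trace, truth = synth.simulate_force_clamp(cfg, 10.0)
        events = classify_events(fit_steps(trace))
        detected = sum(e.implied_multiplicity for e in events)
        curve, _ = synth.simulate_stretch_curve(truth.n_censored, seed=seed + 500)
        assert detected + count_ruptures(curve) == cfg.n_nucleosomes
        assert not any(e.anomalous for e in events)

    def test_event_count_never_exceeds_array_size(self):
        for seed in range(4):
            cfg = synth.SimulationConfig(
                n_nucleosomes=12, condition="PICH_ATP", seed=seed
            )
            trace, truth = synth.simulate_force_clamp(cfg, 12.5)
            events = classify_events(fit_steps(trace))
            assert sum(e.implied_multiplicity for e in events) <= 12
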