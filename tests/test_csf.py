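"""Staircase mechanics, log-parabola fitting and simulated-observer checks."""

import numpy as np
import pytest

from prismadapt.csf import (
    CSFModel,
    STAIRCASE_P_TARGET,
    fit_csf,
    make_contrast_ladder,
    make_frequency_ladder,
    match_csf,
    measure_csf,
    run_contrast_staircase,
    run_frequency_staircase,
    simulate_csf_observer,
)


class TestLadders:
    def test_frequency_ladder(self):
        lad = make_frequency_ladder()
        assert lad.size == 9
        assert lad[0] == pytest.approx(0.042)
        assert lad[-1] == pytest.approx(10.75)
        ratios = lad[1:] / lad[:-1]
        assert np.all(np.abs(ratios - 2.0) < 1e-2 * 2.0)

    def test_contrast_ladder(self):
        lad = make_contrast_ladder()
        assert lad.size == 8
        assert lad[0] == 100.0
        assert lad[-1] == pytest.approx(0.78, abs=5e-3)
        ratios = lad[:-1] / lad[1:]
        assert np.allclose(ratios, 2.0)


class TestFrequencyStaircase:
    def test_step_function_observer(self):
        """Observer correct iff f <= 2.688: threshold within one rung."""
        thr, trace = run_frequency_staircase(lambda f, c: f <= 2.688)
        assert trace.termination == "reversals"
        assert trace.n_reversals == 6
        assert 2.688 / 2 <= thr <= 2.688 * 2

    def test_always_correct_terminates_at_top(self):
        thr, trace = run_frequency_staircase(lambda f, c: True)
        assert trace.termination == "boundary"
        assert thr == pytest.approx(10.75)

    def test_reversal_flags_match_direction_changes(self):
        rng = np.random.default_rng(0)
        _, trace = run_frequency_staircase(lambda f, c: rng.random() < 0.7)
        # recount reversals independently from the level trace + outcomes
        directions = []
        sweep, run = True, 0
        for correct in trace.correct:
            if sweep:
                step = 1 if correct else -1
                if not correct:
                    sweep = False
                    run = 0
            else:
                if correct:
                    run += 1
                    step = 1 if run == 3 else 0
                    if run == 3:
                        run = 0
                else:
                    step, run = -1, 0
            directions.append(step)
        moves = [d for d in directions if d != 0]
        expected = sum(1 for a, b in zip(moves, moves[1:]) if a != b)
        assert trace.n_reversals == expected

    def test_levels_stay_on_ladder(self):
        rng = np.random.default_rng(1)
        _, trace = run_frequency_staircase(lambda f, c: rng.random() < 0.5)
        assert min(trace.levels) >= 0
        assert max(trace.levels) <= 8

    def test_equilibrium_near_79_percent_point(self):
        """Mean threshold over 200 runs sits within one rung of the
        frequency whose p(correct) equals 0.5**(1/3)."""
        fstar = 0.672
        assert STAIRCASE_P_TARGET == pytest.approx(0.794, abs=1e-3)

        def make_obs(seed):
            rng = np.random.default_rng(seed)

            def obs(f, c):
                if f < fstar * 0.99:
                    p = 0.97
                elif f > fstar * 1.01:
                    p = 0.40
                else:
                    p = STAIRCASE_P_TARGET
                return rng.random() < p

            return obs

        thresholds = [run_frequency_staircase(make_obs(s))[0] for s in range(200)]
        geo_mean = float(np.exp(np.mean(np.log(thresholds))))
        assert fstar / 2 <= geo_mean <= fstar * 2


class TestContrastStaircase:
    def test_step_function_observer(self):
        thr, trace = run_contrast_staircase(lambda f, c: c >= 12.5, frequency_cpd=1.0)
        assert 12.5 / 2 <= thr <= 12.5 * 2

    def test_always_correct_reaches_floor(self):
        thr, trace = run_contrast_staircase(lambda f, c: True, frequency_cpd=1.0)
        assert trace.termination == "boundary"
        assert thr == pytest.approx(0.78125)

    def test_seeded_trace_reproducible(self):
        def make_obs(seed):
            rng = np.random.default_rng(seed)
            return lambda f, c: rng.random() < (0.9 if c > 6 else 0.5)

        t1 = run_contrast_staircase(make_obs(5), 1.0)
        t2 = run_contrast_staircase(make_obs(5), 1.0)
        assert t1 == t2


class TestCSFFit:
    def test_noiseless_recovery_of_constructed_parabola(self):
        """Peak log10 S = 2 at 1 cpd with upper zero at 10 cpd."""
        model = CSFModel.from_cutoff(2.0, 1.0, 10.0)
        freqs = np.logspace(np.log10(0.15), np.log10(9.5), 9)
        points = [(float(f), float(model.threshold_pct(f))) for f in freqs]
        fit = fit_csf(points)
        assert not fit.degenerate
        assert fit.cutoff_cpd == pytest.approx(10.0, abs=1e-6)
        assert fit.peak_log_sensitivity == pytest.approx(2.0, rel=1e-6)
        assert fit.peak_frequency_cpd == pytest.approx(1.0, rel=1e-6)
        assert fit.cutoff_cpd > fit.peak_frequency_cpd

    def test_all_ceiling_thresholds_flagged_degenerate(self):
        points = [(f, 100.0) for f in (0.5, 1.0, 2.0, 4.0)]
        fit = fit_csf(points)
        assert fit.degenerate
        assert fit.cutoff_cpd == pytest.approx(4.0)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            fit_csf([(1.0, 10.0), (2.0, 20.0)])

    def test_upward_curvature_flagged(self):
        points = [(0.5, 10.0), (1.0, 50.0), (2.0, 10.0)]
        fit = fit_csf(points)
        assert fit.degenerate


class TestMatchCSF:
    def test_identical_models_match(self):
        m = CSFModel.from_cutoff(1.5, 1.0, 6.0)
        ok, diag = match_csf(m, m)
        assert ok
        assert diag["cutoff_diff_octaves"] == 0.0

    def test_grossly_different_cutoffs_fail(self):
        a = CSFModel.from_cutoff(1.5, 1.0, 5.0)
        b = CSFModel.from_cutoff(1.5, 1.0, 14.0)
        ok, diag = match_csf(a, b)
        assert not ok
        assert diag["cutoff_diff_octaves"] > 1.0

    def test_small_peak_offset_within_default_tolerance(self):
        a = CSFModel.from_cutoff(1.50, 1.0, 6.0)
        b = CSFModel(
            peak_log_sensitivity=1.55,
            peak_frequency_cpd=1.0,
            curvature=a.curvature,
        )
        ok, diag = match_csf(a, b)
        assert ok
        assert diag["max_shape_diff_log10"] == pytest.approx(0.05, abs=1e-6)


class TestSimulatedObserver:
    def test_probability_at_threshold_is_75_percent(self):
        model = CSFModel.from_cutoff(1.5, 1.0, 6.0)
        obs = simulate_csf_observer(model, lapse=0.0, seed=0)
        thr = float(model.threshold_pct(1.0))
        assert obs.p_correct(1.0, thr) == pytest.approx(0.75, abs=1e-9)

    def test_chance_floor_far_below_threshold(self):
        model = CSFModel.from_cutoff(1.5, 1.0, 6.0)
        obs = simulate_csf_observer(model, seed=0)
        assert obs.p_correct(1.0, 1e-6) == pytest.approx(0.5, abs=1e-6)

    def test_empirical_rate_matches_analytic(self):
        model = CSFModel.from_cutoff(1.5, 1.0, 6.0)
        obs = simulate_csf_observer(model, seed=12)
        f, c = 2.0, 20.0
        p = obs.p_correct(f, c)
        n = 10_000
        hits = sum(obs(f, c) for _ in range(n))
        se = np.sqrt(p * (1 - p) / n)
        assert abs(hits / n - p) < 2 * se + 1e-9

    def test_invalid_parameters_rejected(self):
        model = CSFModel.from_cutoff(1.5, 1.0, 6.0)
        with pytest.raises(ValueError):
            simulate_csf_observer(model, slope=-1)
        with pytest.raises(ValueError):
            simulate_csf_observer(model, lapse=0.5)


class TestEndToEnd:
    def test_cutoff_recovery_within_15_percent(self):
        """Full staircase pipeline recovers a 5 cpd cutoff (median of 100 runs)."""
        true = CSFModel.from_cutoff(1.3, 0.3, 5.0)
        cutoffs = []
        for s in range(100):
            obs = simulate_csf_observer(true, seed=s)
            res = measure_csf(obs)
            if not res.model.degenerate:
                cutoffs.append(res.model.cutoff_cpd)
        assert len(cutoffs) >= 80
        median = float(np.median(cutoffs))
        assert abs(median - 5.0) / 5.0 <= 0.15

    def test_round_trip_noiseless_thresholds(self):
        """Thresholds read off a known parabola refit to the same curve."""
        true = CSFModel.from_cutoff(1.4, 0.8, 6.0)
        freqs = np.logspace(np.log10(0.2), np.log10(5.0), 7)
        fit = fit_csf([(float(f), float(true.threshold_pct(f))) for f in freqs])
        assert fit.peak_log_sensitivity == pytest.approx(1.4, rel=1e-6)
        assert fit.peak_frequency_cpd == pytest.approx(0.8, rel=1e-6)
        assert fit.cutoff_cpd == pytest.approx(6.0, rel=1e-6)
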