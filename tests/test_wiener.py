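"""Diffusion primitives: density normalization, closed-form choice
probabilities, simulator agreement, likelihood bookkeeping."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from scipy.integrate import quad

from effort_ddm.wiener import (
    WienerParams,
    choice_probability,
    fpt_density,
    log_likelihood,
    simulate_trial,
    simulate_trials,
)

GRID = [
    WienerParams(a=a, v=v, z=z, t0=0.0)
    for a in (1.0, 2.0, 3.0)
    for v in (-1.0, 0.0, 1.0)
    for z in (0.3, 0.5, 0.7)
]


def _integral(params, boundary, upper_limit=80.0):
    return quad(
        lambda t: fpt_density(t, params, boundary), params.t0, upper_limit, limit=300
    )[0]


class TestDensity:
    def test_zero_before_nondecision_time(self):
        p = WienerParams(a=2.0, v=0.5, z=0.5, t0=0.3)
        assert fpt_density(0.3, p, "upper") == 0.0
        assert fpt_density(0.1, p, "lower") == 0.0
        assert fpt_density(0.301, p, "upper") >= 0.0

    @pytest.mark.parametrize("params", GRID)
    def test_normalizes_over_both_boundaries(self, params):
        total = _integral(params, "upper") + _integral(params, "lower")
        assert total == pytest.approx(1.0, abs=1e-4)

    @pytest.mark.parametrize("params", GRID[::4])
    def test_upper_integral_matches_choice_probability(self, params):
        assert _integral(params, "upper") == pytest.approx(
            choice_probability(params), abs=1e-4
        )

    def test_symmetry_under_reflection(self):
        """Swapping z -> 1-z and v -> -v exchanges the two boundaries."""
        t = np.linspace(0.05, 5.0, 40)
        p = WienerParams(a=1.7, v=0.8, z=0.35, t0=0.0)
        q = WienerParams(a=1.7, v=-0.8, z=0.65, t0=0.0)
        np.testing.assert_allclose(
            fpt_density(t, p, "upper"), fpt_density(t, q, "lower"), rtol=1e-10
        )

    def test_matches_simulated_histogram(self, rng):
        """Euler-simulated RT histogram agrees with the analytic density
        (sup-norm over 50 bins), pooled over both boundaries. A fine step
        keeps the scheme's own discretization bias below the tolerance."""
        p = WienerParams(a=2.0, v=0.5, z=0.5, t0=0.0)
        n = 100_000
        choice, rt, cens = simulate_trials(
            np.full(n, p.a), p.v, p.z, p.t0, rng, dt=2.5e-4
        )
        assert not cens.any()
        bins = np.linspace(0.0, np.quantile(rt, 0.995), 51)
        mids = 0.5 * (bins[:-1] + bins[1:])
        width = bins[1] - bins[0]
        for boundary, sel in (("upper", choice == 1), ("lower", choice == 0)):
            hist = np.histogram(rt[sel], bins=bins)[0] / (n * width)
            dens = fpt_density(mids, p, boundary)
            assert np.max(np.abs(hist - dens)) < 0.05

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            WienerParams(a=0.0, v=0.0, z=0.5, t0=0.0)
        with pytest.raises(ValueError):
            WienerParams(a=1.0, v=0.0, z=1.0, t0=0.0)
        with pytest.raises(ValueError):
            WienerParams(a=1.0, v=0.0, z=0.5, t0=-0.1)
        with pytest.raises(ValueError):
            fpt_density(1.0, WienerParams(a=1.0, v=0.0, z=0.5), boundary="sideways")


class TestChoiceProbability:
    @pytest.mark.parametrize(
        "params,expected",
        [
            (WienerParams(a=2.0, v=0.0, z=0.5), 0.5),
            (WienerParams(a=2.0, v=0.0, z=0.52), 0.52),
            (WienerParams(a=2.0, v=0.5, z=0.5), (1 - np.exp(-1)) / (1 - np.exp(-2))),
        ],
    )
    def test_closed_form(self, params, expected):
        assert choice_probability(params) == pytest.approx(expected, abs=1e-9)

    @given(
        st.floats(min_value=0.5, max_value=4.0),
        st.floats(min_value=-3.0, max_value=3.0),
        st.floats(min_value=0.1, max_value=0.9),
    )
    @settings(deadline=None, max_examples=200)
    def test_is_a_probability_and_monotone_in_drift(self, a, v, z):
        p = choice_probability(WienerParams(a=a, v=v, z=z))
        p_hi = choice_probability(WienerParams(a=a, v=v + 0.25, z=z))
        assert 0.0 <= p <= 1.0
        assert p_hi >= p - 1e-12


class TestSimulator:
    def test_rt_at_least_nondecision_time(self, rng):
        _, rt, _ = simulate_trials(np.full(500, 1.5), 0.5, 0.5, 0.4, rng)
        assert (rt >= 0.4).all()

    def test_unbiased_zero_drift_splits_evenly(self, rng):
        choice, _, _ = simulate_trials(np.full(100_000, 1.0), 0.0, 0.5, 0.0, rng)
        assert choice.mean() == pytest.approx(0.5, abs=0.006)

    def test_upper_fraction_matches_analytic(self, rng):
        p = WienerParams(a=2.0, v=0.5, z=0.5)
        choice, _, _ = simulate_trials(np.full(100_000, p.a), p.v, p.z, p.t0, rng)
        assert choice.mean() == pytest.approx(choice_probability(p), abs=0.006)

    def test_distribution_matches_inverse_cdf_draws(self, rng):
        """Two-sample KS between simulated upper-boundary RTs and draws
        from the analytic conditional density via inverse CDF."""
        p = WienerParams(a=1.5, v=1.0, z=0.5)
        choice, rt, _ = simulate_trials(np.full(10_000, p.a), p.v, p.z, p.t0, rng, dt=1e-4)
        sim = rt[choice == 1]
        grid = np.linspace(1e-4, 15.0, 4000)
        dens = fpt_density(grid, p, "upper")
        cdf = np.cumsum(dens) * (grid[1] - grid[0])
        cdf /= cdf[-1]
        u = rng.random(10_000)
        analytic = np.interp(u, cdf, grid)
        assert stats.ks_2samp(sim, analytic).pvalue > 0.01

    def test_reproducible_under_fixed_seed(self):
        p = WienerParams(a=2.0, v=0.3, z=0.45, t0=0.2)
        assert simulate_trial(p, 7) == simulate_trial(p, 7)

    def test_censoring_flagged_for_slow_process(self, rng):
        # enormous boundary, no drift: nothing absorbs within the cap
        choice, rt, cens = simulate_trials(np.full(4, 80.0), 0.0, 0.5, 0.0, rng, t_max=0.05)
        assert cens.all()
        assert (rt == pytest.approx(0.05)) or np.allclose(rt, 0.05)


class TestLogLikelihood:
    def test_empty_sum_is_zero(self):
        assert log_likelihood([], WienerParams(a=2.0, v=0.0, z=0.5)) == 0.0

    def test_single_trial_equals_log_density(self):
        p = WienerParams(a=2.0, v=0.4, z=0.55, t0=0.2)
        ll = log_likelihood([("upper", 1.0)], p)
        assert ll == pytest.approx(np.log(fpt_density(1.0, p, "upper")))

    def test_invariant_under_reordering(self, rng):
        p = WienerParams(a=2.0, v=0.4, z=0.55, t0=0.2)
        trials = [("upper" if rng.random() < 0.6 else "lower", float(t))
                  for t in rng.uniform(0.5, 3.0, 25)]
        shuffled = list(trials)
        rng.shuffle(shuffled)
        assert log_likelihood(trials, p) == pytest.approx(log_likelihood(shuffled, p))

    def test_rt_below_nondecision_time_is_minus_inf(self):
        p = WienerParams(a=2.0, v=0.4, z=0.5, t0=0.5)
        assert log_likelihood([("upper", 0.4)], p) == -np.inf
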