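"""Hierarchical fitting machinery: trimming, convergence diagnostics,
HDIs, DIC bookkeeping, sampler reproducibility."""

import numpy as np
import pandas as pd
import pytest

from effort_ddm.hierarchical import (
    McmcConfig,
    dic,
    fit_hierarchical,
    hdi,
    paper_budget,
    posterior_predictive,
    rhat,
    trim_rts,
)


def _trials(n, pid=0, rng=None, rt=None):
    rng = rng or np.random.default_rng(0)
    return pd.DataFrame(
        {
            "participant_id": pid,
            "condition": "sham",
            "miniblock": 1,
            "trial_in_series": 1,
            "low_effort": 1,
            "high_effort": 2,
            "low_reward": 2.0,
            "high_reward": 4.0,
            "choice": rng.choice(["low", "high"], n),
            "rt_s": rt if rt is not None else rng.uniform(0.8, 3.0, n),
        }
    )


class TestTrimRts:
    def test_removes_five_percent_each_tail(self):
        out = trim_rts(_trials(100))
        assert len(out) == 90

    def test_extremes_are_what_is_removed(self):
        df = _trials(100)
        out = trim_rts(df)
        ranked = np.sort(df["rt_s"].to_numpy())
        assert out["rt_s"].min() == ranked[5]
        assert out["rt_s"].max() == ranked[-6]
        assert sorted(out["rt_s"]) == list(ranked[5:-5])

    def test_identical_rts_trimmed_deterministically(self):
        df = _trials(20, rt=np.ones(20))
        out = trim_rts(df)
        assert len(out) == 18
        pd.testing.assert_frame_equal(out, trim_rts(df))

    def test_per_participant_never_cross(self):
        df = pd.concat(
            [_trials(100, pid=0), _trials(100, pid=1, rng=np.random.default_rng(5))],
            ignore_index=True,
        )
        out = trim_rts(df)
        assert (out.groupby("participant_id").size() == 90).all()

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            trim_rts(_trials(0))


class TestRhat:
    def test_identical_iid_chains_converged(self, rng):
        draws = rng.standard_normal((4, 2000))
        assert rhat(draws) < 1.01

    def test_disjoint_chains_flagged(self):
        draws = np.stack([np.zeros(100), np.ones(100)])
        assert rhat(draws) > 1.1

    def test_matches_textbook_hand_computation(self):
        draws = np.array([[1.0, 2.0, 3.0, 4.0], [1.5, 2.5, 3.5, 4.5]])
        # split each chain in half -> 4 chains of 2 draws
        chains = draws.reshape(4, 2)
        n = 2
        w = chains.var(axis=1, ddof=1).mean()
        b = n * chains.mean(axis=1).var(ddof=1)
        expected = np.sqrt(((n - 1) / n * w + b / n) / w)
        assert rhat(draws) == pytest.approx(expected, rel=1e-12)

    def test_single_or_short_chains_rejected(self):
        with pytest.raises(ValueError):
            rhat(np.zeros((1, 100)))
        with pytest.raises(ValueError):
            rhat(np.zeros((2, 3)))


class TestHdi:
    def test_constant_samples_zero_width(self):
        lo, hi, mean = hdi(np.full(500, 3.3))
        assert lo == hi == mean == 3.3

    def test_uniform_width(self, rng):
        lo, hi, _ = hdi(rng.random(1_000_000), 0.95)
        assert hi - lo == pytest.approx(0.95, abs=0.01)

    def test_normal_quantiles(self, rng):
        lo, hi, mean = hdi(rng.standard_normal(1_000_000), 0.95)
        assert lo == pytest.approx(-1.96, abs=0.02)
        assert hi == pytest.approx(1.96, abs=0.02)
        assert mean == pytest.approx(0.0, abs=0.01)

    def test_invalid_mass_or_sample_size_rejected(self):
        with pytest.raises(ValueError):
            hdi(np.zeros(500), mass=1.0)
        with pytest.raises(ValueError):
            hdi(np.zeros(50))


class TestFitMachinery:
    """Small-budget fits exercising the sampler contract; statistical
    recovery at scale lives in the acceptance suite."""

    @pytest.fixture(scope="class")
    @staticmethod
    def small_fit(small_study):
        _, _, trials = small_study
        trimmed = trim_rts(trials)
        cfg = McmcConfig(n_chains=4, n_draws=250, n_burn=400, seed=9)
        return trimmed, fit_hierarchical(trimmed, "attribute", cfg)

    def test_reproducible_under_fixed_seed(self, small_study):
        _, _, trials = small_study
        trimmed = trim_rts(trials)
        cfg = McmcConfig(n_chains=4, n_draws=60, n_burn=80, seed=21)
        a = fit_hierarchical(trimmed, "attribute", cfg)
        b = fit_hierarchical(trimmed, "attribute", cfg)
        pd.testing.assert_frame_equal(a.summary, b.summary)
        assert a.dic == b.dic

    def test_summary_structure(self, small_fit):
        _, fit = small_fit
        assert (fit.summary["hdi_lower"] <= fit.summary["mean"] + 1e-12).all()
        assert (fit.summary["mean"] <= fit.summary["hdi_upper"] + 1e-12).all()
        assert {"mu_a", "sigma_a", "mu_z_theta", "mu_beta_reward_alpha"} <= set(fit.summary.index)
        assert fit.draws.individual.shape[2:] == (6, 15)

    def test_effective_parameters_positive(self, small_fit):
        _, fit = small_fit
        assert fit.pd_eff > 0

    def test_dic_recomputation_matches(self, small_fit):
        trimmed, fit = small_fit
        d, dbar, pd_eff = dic(fit, trimmed)
        assert d == pytest.approx(fit.dic)
        assert dbar == pytest.approx(fit.dbar)

    def test_posterior_predictive_covers_design(self, small_fit):
        trimmed, fit = small_fit
        sim = posterior_predictive(fit, seed=3)
        assert len(sim) == len(trimmed)
        assert ((sim["choice"] == "high") == (sim["signed_rt"] > 0)).all()
        assert (sim["rt_s"] > 0).all()

    def test_posterior_predictive_empty_design(self, small_fit):
        _, fit = small_fit
        out = posterior_predictive(fit, fit.trials.iloc[:0], seed=0)
        assert len(out) == 0

    def test_unknown_model_rejected(self, small_study):
        _, _, trials = small_study
        with pytest.raises(ValueError):
            fit_hierarchical(trim_rts(trials), "exponential")

    def test_nonpositive_rts_rejected(self):
        df = _trials(50)
        df.loc[0, "rt_s"] = 0.0
        with pytest.raises(ValueError):
            fit_hierarchical(df, "attribute", McmcConfig(n_draws=10, n_burn=10, seed=0))

    def test_single_participant_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            fit_hierarchical(_trials(50), "attribute", McmcConfig(n_draws=10, n_burn=10, seed=0))


class TestLikelihoodPaths:
    @pytest.mark.parametrize("model", ["attribute", "hyperbolic", "parabolic", "linear"])
    def test_jit_kernel_matches_numpy_reference(self, small_study, model, rng):
        """The fused JIT likelihood kernel and the vectorized numpy path
        agree to floating-point accuracy for every model variant."""
        import effort_ddm._fastlik as fastlik
        from effort_ddm.hierarchical import _FitData

        if not fastlik.HAVE_NUMBA:
            pytest.skip("numba not installed; only the numpy path exists")
        _, _, trials = small_study
        data = _FitData(trials, model)
        theta = np.stack(
            [
                np.column_stack(
                    [
                        rng.uniform(1.5, 2.5, data.n_part),  # a
                        rng.uniform(0.4, 0.6, data.n_part),  # z
                        rng.uniform(0.2, 0.5, data.n_part),  # t0
                    ]
                    + [rng.uniform(0.0, 0.4, data.n_part) for _ in range(data.n_base - 3)]
                    + [rng.normal(0, 0.05, data.n_part) for _ in range(2 * data.n_base)]
                )
                for _ in range(2)
            ]
        )
        for c in range(3):
            fast = data.loglik_cond(theta, c)
            fastlik.HAVE_NUMBA = False
            try:
                slow = data.loglik_cond(theta, c)
            finally:
                fastlik.HAVE_NUMBA = True
            np.testing.assert_allclose(fast, slow, rtol=1e-9, atol=1e-9)


class TestBudgets:
    def test_paper_budget_matches_reference_protocol(self):
        cfg = paper_budget()
        assert cfg.n_chains == 2
        assert cfg.n_burn == 40_000
        assert cfg.thin == 5
        assert cfg.n_burn + cfg.n_draws * cfg.thin == 50_000

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            McmcConfig(n_chains=1)
        with pytest.raises(ValueError):
            McmcConfig(thin=0)
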