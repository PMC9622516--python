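"""Synthetic-study generator: design counts, population sampling, agent
behavior, round-tripping."""

import numpy as np
import pandas as pd
import pytest

from effort_ddm import io
from effort_ddm.simulate import (
    EFFORT_PAIRS,
    GroundTruth,
    PopulationParams,
    build_design,
    sample_population,
    simulate_nback,
    simulate_participant,
    simulate_study,
    reference_population,
)
from effort_ddm.titration import replay_choices
from effort_ddm.wiener import choice_probability, WienerParams, simulate_trials


class TestBuildDesign:
    def test_trial_counts(self):
        design = build_design(7, seed=0)
        assert design.trials_per_participant == 180
        for plist in design.series:
            assert len(plist) == 36  # 6 pairs x 2 rewards x 3 conditions
            per_cond = pd.Series([s.condition.value for s in plist]).value_counts()
            assert set(per_cond) == {12}  # 12 series = 60 decisions per condition

    def test_effort_pairs_exclude_degenerate(self):
        assert len(EFFORT_PAIRS) == 6
        assert all(lo < hi for lo, hi in EFFORT_PAIRS)

    def test_condition_order_counterbalanced(self):
        design = build_design(6, seed=0)
        assert len({o for o in design.condition_orders}) == 3

    def test_miniblocks_hold_twenty_trials(self):
        design = build_design(3, seed=1)
        for plist in design.series:
            counts = pd.Series([s.miniblock for s in plist]).value_counts()
            assert sorted(counts.index) == list(range(1, 10))
            assert set(counts) == {4}  # 4 series x 5 trials = 20


class TestSamplePopulation:
    def test_zero_sds_give_identical_participants(self):
        pop = reference_population(sd_frac=0.0)
        truth = sample_population(pop, 5, seed=0)
        assert (truth.participants.nunique() == 1).all()
        assert truth.participants["a"].iloc[0] == 2.09

    def test_default_means_match_preset(self):
        pop = reference_population()
        assert pop.means["a"] == 2.09
        assert pop.means["z"] == 0.52
        assert pop.means["t0"] == 0.66
        assert pop.means["z_theta"] == 0.03
        assert pop.sds["z"] == pytest.approx(0.052)

    def test_reproducible_under_fixed_seed(self):
        pop = reference_population()
        a = sample_population(pop, 8, seed=42).participants
        b = sample_population(pop, 8, seed=42).participants
        pd.testing.assert_frame_equal(a, b)

    def test_draws_center_on_group_means(self):
        pop = reference_population()
        truth = sample_population(pop, 400, seed=7)
        assert truth.participants["a"].mean() == pytest.approx(2.09, abs=0.05)
        assert truth.participants["z"].mean() == pytest.approx(0.52, abs=0.01)


class TestSimulateParticipant:
    @pytest.fixture(scope="class")
    @staticmethod
    def design():
        return build_design(3, seed=5)

    def _truth(self, **overrides):
        pop = reference_population(sd_frac=0.0)
        means = dict(pop.means)
        means.update(overrides)
        return sample_population(
            PopulationParams(model="attribute", means=means, sds={}), 3, seed=0
        )

    def test_reward_seeker_titrates_offers_down(self, design):
        """With strong reward sensitivity and no effort cost the agent
        keeps choosing high, so low offers drift toward the high reward
        (high relative SV)."""
        truth = self._truth(beta_reward=3.0, beta_effort=0.0, z=0.5, z_theta=0.0)
        trials = simulate_participant(truth, design, 0, seed=1)
        # early trials are near-certain high choices; late trials sit at the
        # titrated indifference point by construction
        assert (trials["choice"] == "high").mean() > 0.8
        last = trials[trials["trial_in_series"] == 5]
        assert (last["low_reward"] / last["high_reward"]).mean() > 0.85

    def test_effort_averse_agent_prefers_low(self, design):
        truth = self._truth(beta_reward=0.0, beta_effort=1.5, z=0.5, z_theta=0.0)
        trials = simulate_participant(truth, design, 0, seed=2)
        assert (trials["choice"] == "high").mean() < 0.5

    def test_theta_bias_raises_theta_subjective_values(self, design):
        """A positive theta shift of the starting bias raises mean
        relative SV under theta relative to sham across agents."""
        from effort_ddm.metrics import sv_table

        truth = sample_population(reference_population(sd_frac=0.0), 10, seed=3)
        big = build_design(10, seed=6)
        frames = [simulate_participant(truth, big, p, seed=100 + p) for p in range(10)]
        svs = sv_table(pd.concat(frames, ignore_index=True))
        means = svs.groupby("condition")["relative_sv"].mean()
        assert means["theta"] > means["sham"]

    def test_offers_follow_staircase_rule(self, design):
        """Recorded low offers are re-derivable from the choices alone."""
        truth = self._truth()
        trials = simulate_participant(truth, design, 1, seed=4)
        for _, grp in trials.groupby(["condition", "low_effort", "high_effort", "high_reward"]):
            grp = grp.sort_values("trial_in_series")
            state = replay_choices([], grp["high_reward"].iloc[0])
            from effort_ddm.titration import update_offer

            for _, row in grp.iterrows():
                assert row["low_reward"] == pytest.approx(state.current_offer)
                state = update_offer(state, row["choice"])

    def test_choice_fraction_approaches_analytic(self, rng):
        """Across many replicates of one fixed pair the empirical
        high-effort fraction matches the analytic absorption probability."""
        params = WienerParams(a=2.09, v=0.32, z=0.52, t0=0.66)
        n = 10_000
        choice, _, _ = simulate_trials(np.full(n, params.a), params.v, params.z, params.t0, rng)
        p = choice_probability(params)
        assert choice.mean() == pytest.approx(p, abs=3.5 * np.sqrt(p * (1 - p) / n))


class TestStudyTables:
    def test_round_trip_through_trial_table(self, small_study, tmp_path):
        _, _, trials = small_study
        path = tmp_path / "trials.tsv"
        io.write_trial_table(trials, path)
        back = io.read_trial_table(path)
        pd.testing.assert_frame_equal(back, trials, check_exact=False, rtol=1e-12)

    def test_ground_truth_round_trip(self, small_study, tmp_path):
        _, truth, _ = small_study
        path = tmp_path / "truth.json"
        io.write_ground_truth(truth, path)
        back = io.read_ground_truth(path)
        assert back.population.model == truth.population.model
        pd.testing.assert_frame_equal(
            back.participants, truth.participants, check_exact=False, rtol=1e-12
        )

    def test_study_is_reproducible(self, small_study):
        design, truth, trials = small_study
        again = simulate_study(truth, design, seed=13)
        pd.testing.assert_frame_equal(trials, again)


class TestSimulateNback:
    def test_null_design_has_no_condition_effect(self):
        design = build_design(30, seed=9)
        nback = simulate_nback(design, seed=10)
        from effort_ddm.metrics import nback_summary

        summ = nback_summary(nback)
        d = summ.groupby("condition")["d_prime"].mean()
        assert abs(d["theta"] - d["sham"]) < 0.25
        assert abs(d["alpha"] - d["sham"]) < 0.25

    def test_reproducible_and_rates_respected(self):
        design = build_design(5, seed=9)
        a = simulate_nback(design, seed=11)
        b = simulate_nback(design, seed=11)
        pd.testing.assert_frame_equal(a, b)
        targets = a[a["is_target"]]
        assert targets["responded"].mean() == pytest.approx(0.85, abs=0.06)

    def test_invalid_rates_rejected(self):
        design = build_design(2, seed=0)
        with pytest.raises(ValueError):
            simulate_nback(design, seed=0, hit_rate=1.2)
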