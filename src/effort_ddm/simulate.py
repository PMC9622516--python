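"""Synthetic studies: diffusion-model agents in the titration task.

Reproduces the study structure end-to-end with known ground truth:
participants drawn from truncated-normal group distributions interact with
the adaptive titration staircase, choosing on every trial via a Wiener
diffusion whose drift is recomputed from the current (titrated) offer.
Each participant contributes 3 stimulation conditions x 6 effort pairs x
2 high rewards x 5 titration choices = 180 decisions, organized in 9
miniblocks of 20 trials (3 miniblocks per condition, condition order
counterbalanced by Latin square), plus one 40-trial 2-back block per
condition.

The default population preset places the group means at the fitted values
this kind of task yields (boundary 2.09, bias 0.52, non-decision time
0.66 s, reward coefficient 0.22 per euro, effort coefficient 0.12 per
level, and a +0.03 theta-condition shift of the starting bias; all other
condition offsets zero), with between-subject SDs at 10% of each mean.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .drift import ChoicePair, Condition, ConditionParams, DiscountForm, resolve_condition, subjective_value
from .titration import N_TITRATION_CHOICES, TitrationState, update_offer
from .wiener import simulate_trials

__all__ = [
    "CONDITIONS",
    "EFFORT_PAIRS",
    "HIGH_REWARDS",
    "StudyDesign",
    "PopulationParams",
    "GroundTruth",
    "reference_population",
    "build_design",
    "sample_population",
    "simulate_participant",
    "simulate_study",
    "simulate_nback",
]

CONDITIONS = (Condition.SHAM, Condition.THETA, Condition.ALPHA)
#: All (low, high) N-back pairs with low in 1-3, high in 2-4, low < high.
EFFORT_PAIRS = tuple(
    (lo, hi) for lo, hi in itertools.product((1, 2, 3), (2, 3, 4)) if lo < hi
)
HIGH_REWARDS = (2.0, 4.0)
TRIALS_PER_MINIBLOCK = 20
MINIBLOCKS_PER_CONDITION = 3
NBACK_TRIALS_PER_BLOCK = 40
NBACK_TARGET_RATE = 0.3

#: Plausible ranges used to truncate the group distributions when drawing
#: participants (matching the uniform prior ranges of the fit).
TRUNCATION_RANGES = {
    "a": (0.3, 5.0),
    "z": (0.05, 0.95),
    "t0": (0.05, 3.0),
    "beta_reward": (-5.0, 5.0),
    "beta_effort": (-5.0, 5.0),
    "beta_discount": (0.0, 5.0),
}
OFFSET_RANGE = (-2.0, 2.0)

_BASE_NAMES = {
    "attribute": ("a", "z", "t0", "beta_reward", "beta_effort"),
    "hyperbolic": ("a", "z", "t0", "beta_discount"),
    "parabolic": ("a", "z", "t0", "beta_discount"),
    "linear": ("a", "z", "t0", "beta_discount"),
}


@dataclass(frozen=True)
class SeriesSpec:
    """One five-trial titration series within a miniblock."""

    condition: Condition
    low_effort: int
    high_effort: int
    high_reward: float
    miniblock: int


@dataclass(frozen=True)
class StudyDesign:
    """Session layout for every participant.

    ``series[p]`` lists participant p's 36 series in session order;
    miniblocks are numbered 1-9 in session order, four contiguous series
    (20 trials) per miniblock.
    """

    n_participants: int
    condition_orders: tuple
    series: tuple
    nback_trials_per_block: int = NBACK_TRIALS_PER_BLOCK

    @property
    def trials_per_participant(self) -> int:
        return len(self.series[0]) * N_TITRATION_CHOICES


def build_design(n_participants: int, seed: int = 0) -> StudyDesign:
    """Enumerate all decision series, counterbalancing condition order.

    Condition order follows a 3x3 Latin square cycled over participants;
    ``seed`` shuffles the order of the 12 series within each condition
    (their assignment to the condition's 3 miniblocks is contiguous).
    """
    if n_participants < 1:
        raise ValueError("n_participants must be >= 1")
    latin = (
        (Condition.SHAM, Condition.THETA, Condition.ALPHA),
        (Condition.THETA, Condition.ALPHA, Condition.SHAM),
        (Condition.ALPHA, Condition.SHAM, Condition.THETA),
    )
    rng = np.random.default_rng(seed)
    orders = []
    all_series = []
    combos = [
        (lo, hi, r) for (lo, hi) in EFFORT_PAIRS for r in HIGH_REWARDS
    ]  # 12 series per condition
    for p in range(n_participants):
        order = latin[p % 3]
        orders.append(order)
        plist = []
        block = 0
        for cond in order:
            idx = rng.permutation(len(combos))
            for j, ci in enumerate(idx):
                if j % (len(combos) // MINIBLOCKS_PER_CONDITION) == 0:
                    block += 1
                lo, hi, r = combos[ci]
                plist.append(SeriesSpec(cond, lo, hi, r, block))
        all_series.append(tuple(plist))
    return StudyDesign(n_participants, tuple(orders), tuple(all_series))


@dataclass(frozen=True)
class PopulationParams:
    """Group-level means and SDs for every base parameter and its
    theta/alpha offsets. Keys: base names plus ``{name}_theta`` and
    ``{name}_alpha``."""

    model: str = "attribute"
    means: dict = field(default_factory=dict)
    sds: dict = field(default_factory=dict)

    def param_names(self) -> list:
        base = _BASE_NAMES[self.model]
        return list(base) + [f"{n}_theta" for n in base] + [f"{n}_alpha" for n in base]


def reference_population(sd_frac: float = 0.1, model: str = "attribute") -> PopulationParams:
    """Default study conditions: group means at the reference fitted
    values with a +0.03 theta shift of the starting bias, between-subject
    SDs at ``sd_frac`` of each mean (zero-mean offsets get SD 0)."""
    if model == "attribute":
        means = {"a": 2.09, "z": 0.52, "t0": 0.66, "beta_reward": 0.22, "beta_effort": 0.12}
    else:
        means = {"a": 2.09, "z": 0.52, "t0": 0.66, "beta_discount": 0.5}
    pop_means = dict(means)
    for n in means:
        pop_means[f"{n}_theta"] = 0.0
        pop_means[f"{n}_alpha"] = 0.0
    pop_means["z_theta"] = 0.03
    sds = {k: sd_frac * abs(v) for k, v in pop_means.items()}
    return PopulationParams(model=model, means=pop_means, sds=sds)


@dataclass(frozen=True)
class GroundTruth:
    """Generating population, the per-participant parameter draws, and the
    seed; stored alongside every generated dataset."""

    population: PopulationParams
    participants: pd.DataFrame  # one row per participant, one column per parameter
    seed: int

    def condition_params(self, participant: int) -> ConditionParams:
        row = self.participants.iloc[participant]
        base_names = _BASE_NAMES[self.population.model]
        return ConditionParams(
            base={n: float(row[n]) for n in base_names},
            theta={n: float(row[f"{n}_theta"]) for n in base_names},
            alpha={n: float(row[f"{n}_alpha"]) for n in base_names},
        )


def _param_range(name: str):
    if name.endswith("_theta") or name.endswith("_alpha"):
        return OFFSET_RANGE
    return TRUNCATION_RANGES[name]


def sample_population(
    population: PopulationParams, n_participants: int, seed: int, max_redraws: int = 1000
) -> GroundTruth:
    """Draw per-participant parameters from truncated normal group
    distributions; draws whose condition-resolved parameters are
    infeasible are redrawn (up to ``max_redraws``, then rejected)."""
    rng = np.random.default_rng(seed)
    names = population.param_names()
    base_names = _BASE_NAMES[population.model]
    rows = []
    for _ in range(n_participants):
        for attempt in range(max_redraws):
            draw = {}
            for name in names:
                mu = population.means.get(name, 0.0)
                sd = population.sds.get(name, 0.0)
                lo, hi = _param_range(name)
                if sd == 0.0:
                    val = mu
                else:
                    val = rng.normal(mu, sd)
                    for _ in range(max_redraws):
                        if lo <= val <= hi:
                            break
                        val = rng.normal(mu, sd)
                draw[name] = float(np.clip(val, lo, hi))
            cp = ConditionParams(
                base={n: draw[n] for n in base_names},
                theta={n: draw[f"{n}_theta"] for n in base_names},
                alpha={n: draw[f"{n}_alpha"] for n in base_names},
            )
            if all(resolve_condition(cp, c)[1] for c in CONDITIONS):
                rows.append(draw)
                break
        else:
            raise RuntimeError("could not draw a feasible participant")
    return GroundTruth(population, pd.DataFrame(rows), int(seed))


def _series_drift(spec: SeriesSpec, offer: float, resolved: dict, model: str) -> float:
    pair = ChoicePair(spec.low_effort, spec.high_effort, min(offer, spec.high_reward), spec.high_reward, spec.condition)
    if model == "attribute":
        return resolved["beta_reward"] * pair.reward_diff - resolved["beta_effort"] * pair.effort_diff
    form = DiscountForm(model)
    beta = max(resolved["beta_discount"], 0.0)
    sv_h = subjective_value(pair.high_reward, pair.high_effort_level, form, beta)
    sv_l = subjective_value(pair.low_reward, pair.low_effort_level, form, beta)
    return float(sv_h - sv_l)


def simulate_participant(
    truth: GroundTruth, design: StudyDesign, participant: int, seed
) -> pd.DataFrame:
    """Simulate one participant's 180 decisions.

    Within each series the staircase and the diffusion agent alternate:
    the drift is recomputed from the current offer before every trial,
    the simulated boundary (upper = high effort) feeds the staircase
    update. Boundary/bias/non-decision time are constant within a
    condition. The rare censored trials (no absorption within the 20 s
    cap) are re-simulated; a persistent flag is recorded.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    model = truth.population.model
    cp = truth.condition_params(participant)
    resolved = {}
    for cond in CONDITIONS:
        res, feasible = resolve_condition(cp, cond, strict=True)
        resolved[cond] = res
    series = design.series[participant]
    states = [TitrationState.start(s.high_reward) for s in series]
    rows = []
    for trial_k in range(N_TITRATION_CHOICES):
        a = np.array([resolved[s.condition]["a"] for s in series])
        z = np.array([resolved[s.condition]["z"] for s in series])
        t0 = np.array([resolved[s.condition]["t0"] for s in series])
        offers = np.array([st.current_offer for st in states])
        v = np.array(
            [_series_drift(s, st.current_offer, resolved[s.condition], model) for s, st in zip(series, states)]
        )
        choice, rt, cens = simulate_trials(a, v, z, t0, rng)
        if cens.any():  # retry censored paths a few times
            for _ in range(5):
                idx = np.where(cens)[0]
                if idx.size == 0:
                    break
                c2, r2, cz2 = simulate_trials(a[idx], v[idx], z[idx], t0[idx], rng)
                choice[idx], rt[idx], cens[idx] = c2, r2, cz2
        for i, (s, st) in enumerate(zip(series, states)):
            ch = "high" if choice[i] == 1 else "low"
            rows.append(
                {
                    "_series": i,
                    "participant_id": participant,
                    "condition": s.condition.value,
                    "miniblock": s.miniblock,
                    "trial_in_series": trial_k + 1,
                    "low_effort": s.low_effort,
                    "high_effort": s.high_effort,
                    "low_reward": float(st.current_offer),
                    "high_reward": float(s.high_reward),
                    "choice": ch,
                    "rt_s": float(rt[i]),
                    "censored": bool(cens[i]),
                }
            )
            states[i] = update_offer(st, ch)
    df = pd.DataFrame(rows)
    # the five choices of a series are consecutive within its miniblock
    df = df.sort_values(["_series", "trial_in_series"], kind="stable").reset_index(drop=True)
    return df.drop(columns="_series")


def simulate_study(truth: GroundTruth, design: StudyDesign, seed) -> pd.DataFrame:
    """Simulate all participants; returns the long-format trial table."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(design.n_participants)
    frames = [
        simulate_participant(truth, design, p, np.random.default_rng(children[p]))
        for p in range(design.n_participants)
    ]
    return pd.concat(frames, ignore_index=True)


def simulate_nback(
    design: StudyDesign,
    seed,
    hit_rate: float = 0.85,
    fa_rate: float = 0.08,
    rt_median_ms: float = 550.0,
    rt_sigma_log: float = 0.25,
    condition_effects: dict | None = None,
) -> pd.DataFrame:
    """Simulate the 2-back control blocks (40 trials per condition).

    Responses are Bernoulli at the configured hit / false-alarm rates and
    hit RTs are lognormal; by default no condition differences (the
    working-memory null). ``condition_effects`` may map a condition name
    to ``(hit_rate, fa_rate)`` overrides. These generator settings are
    plumbing defaults, not fitted quantities.
    """
    if not (0.0 <= hit_rate <= 1.0 and 0.0 <= fa_rate <= 1.0):
        raise ValueError("hit_rate and fa_rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n = design.nback_trials_per_block
    n_targets = int(round(NBACK_TARGET_RATE * n))
    rows = []
    for p in range(design.n_participants):
        for cond in design.condition_orders[p]:
            hr, fr = hit_rate, fa_rate
            if condition_effects and cond.value in condition_effects:
                hr, fr = condition_effects[cond.value]
                if not (0.0 <= hr <= 1.0 and 0.0 <= fr <= 1.0):
                    raise ValueError("condition-effect rates must lie in [0, 1]")
            targets = np.zeros(n, dtype=bool)
            targets[rng.choice(n, size=n_targets, replace=False)] = True
            responded = np.where(
                targets, rng.random(n) < hr, rng.random(n) < fr
            )
            rt_ms = np.where(
                responded,
                np.exp(rng.normal(np.log(rt_median_ms), rt_sigma_log, size=n)),
                np.nan,
            )
            for t in range(n):
                rows.append(
                    {
                        "participant_id": p,
                        "condition": cond.value,
                        "trial": t + 1,
                        "is_target": bool(targets[t]),
                        "responded": bool(responded[t]),
                        "rt_ms": float(rt_ms[t]) if responded[t] else np.nan,
                    }
                )
    return pd.DataFrame(rows)
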