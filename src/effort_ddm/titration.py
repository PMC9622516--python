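"""Adaptive titration staircase for the effort-based decision task.

On every trial the participant chooses between a low effort-low reward
option and a high effort-high reward option. The high option's reward is
fixed (2 or 4 euro) while the low option's reward starts at half the high
amount and is adjusted after each choice so that the next decision is as
hard as possible: choosing the high option raises the low offer by the
current step, choosing the low option lowers it, and the step is halved
after every choice. Five choices per effort pair bisect the participant's
indifference point; the hypothetical sixth-trial offer is the indifference
estimate, with a resolution of ``high_reward / 64`` (0.0625 euro for the
4-euro pairs).

Dividing the indifference point by the fixed high reward gives the
*relative subjective value* of the high effort option, a dimensionless
number in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Hashable, Sequence

__all__ = [
    "N_TITRATION_CHOICES",
    "TitrationState",
    "SubjectiveValueRecord",
    "initial_offer",
    "initial_step",
    "update_offer",
    "indifference_point",
    "relative_subjective_value",
    "replay_choices",
    "run_staircase",
]

#: Number of choices per (low effort, high effort, high reward) series.
N_TITRATION_CHOICES = 5


def initial_offer(high_reward: float) -> float:
    """First low-effort offer: half the fixed high-effort reward."""
    if not high_reward > 0:
        raise ValueError(f"high_reward must be positive, got {high_reward!r}")
    return high_reward / 2.0


def initial_step(high_reward: float) -> float:
    """First titration step: a quarter of the fixed high-effort reward."""
    if not high_reward > 0:
        raise ValueError(f"high_reward must be positive, got {high_reward!r}")
    return high_reward / 4.0


@dataclass(frozen=True)
class TitrationState:
    """Staircase state for one effort pair.

    ``current_offer`` is the low-effort reward that the *next* trial would
    present; after the fifth recorded choice it is the hypothetical
    sixth-trial offer, i.e. the indifference-point estimate.
    """

    high_reward: float
    current_offer: float
    step: float
    choices_made: int = 0
    history: tuple[str, ...] = ()
    pair_key: Hashable = None

    @classmethod
    def start(cls, high_reward: float, pair_key: Hashable = None) -> "TitrationState":
        return cls(
            high_reward=float(high_reward),
            current_offer=initial_offer(high_reward),
            step=initial_step(high_reward),
            pair_key=pair_key,
        )

    @property
    def complete(self) -> bool:
        return self.choices_made >= N_TITRATION_CHOICES


def update_offer(state: TitrationState, choice: str) -> TitrationState:
    """Record one choice and return the updated staircase state.

    ``choice`` is ``"high"`` (the high effort-high reward option was taken;
    the low offer must rise to stay competitive) or ``"low"`` (the low
    offer falls). The applied step is then halved. Offers are clamped to
    ``[0, high_reward]``.
    """
    if choice not in ("low", "high"):
        raise ValueError(f"choice must be 'low' or 'high', got {choice!r}")
    if state.complete:
        raise ValueError(
            f"titration series exhausted after {N_TITRATION_CHOICES} choices"
        )
    sign = 1.0 if choice == "high" else -1.0
    offer = state.current_offer + sign * state.step
    offer = min(max(offer, 0.0), state.high_reward)
    return replace(
        state,
        current_offer=offer,
        step=state.step / 2.0,
        choices_made=state.choices_made + 1,
        history=state.history + (choice,),
    )


def indifference_point(state: TitrationState) -> float:
    """Indifference-point estimate after a complete five-choice series.

    Equals the offer a hypothetical sixth trial would present (the final
    signed half-step is already applied), so the estimate has resolution
    ``high_reward / 64``.
    """
    if not state.complete:
        raise ValueError(
            f"series incomplete: {state.choices_made} of {N_TITRATION_CHOICES} choices"
        )
    return state.current_offer


def relative_subjective_value(indifference: float, high_reward: float) -> float:
    """Indifference point normalized by the fixed high reward, in [0, 1]."""
    if not high_reward > 0:
        raise ValueError(f"high_reward must be positive, got {high_reward!r}")
    if not 0.0 <= indifference <= high_reward:
        raise ValueError(
            f"indifference point {indifference!r} outside [0, {high_reward}]"
        )
    return indifference / high_reward


def replay_choices(
    choices: Sequence[str], high_reward: float, pair_key: Hashable = None
) -> TitrationState:
    """Re-run the staircase from a recorded choice sequence.

    The offers presented on each trial are fully determined by the choices,
    so a stored trial table can be checked or re-derived from this replay.
    """
    state = TitrationState.start(high_reward, pair_key=pair_key)
    for choice in choices:
        state = update_offer(state, choice)
    return state


def run_staircase(
    agent: Callable[[float], str], high_reward: float, pair_key: Hashable = None
) -> TitrationState:
    """Run a full five-choice series against a choice function.

    ``agent`` maps the current low-effort offer to ``"low"`` or ``"high"``.
    A deterministic agent with true indifference point ``p`` (choose high
    iff the offer is below ``p``, ties toward high) ends within
    ``high_reward / 64`` of ``p`` for any ``p`` inside the reachable
    bracket.
    """
    state = TitrationState.start(high_reward, pair_key=pair_key)
    for _ in range(N_TITRATION_CHOICES):
        state = update_offer(state, agent(state.current_offer))
    return state


@dataclass(frozen=True)
class SubjectiveValueRecord:
    """Indifference point and relative subjective value for one series."""

    pair_key: Hashable
    indifference_point: float
    relative_sv: float

    def __post_init__(self):
        if not 0.0 <= self.relative_sv <= 1.0:
            raise ValueError(f"relative_sv {self.relative_sv!r} outside [0, 1]")

    @classmethod
    def from_series(cls, state: TitrationState) -> "SubjectiveValueRecord":
        ip = indifference_point(state)
        return cls(state.pair_key, ip, relative_subjective_value(ip, state.high_reward))
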