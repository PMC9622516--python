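"""Trial-wise drift rates under the four model variants.

The attribute-comparison model builds the drift from separate reward and
effort comparisons between the two options,

    v = beta_reward * (R_high - R_low) - beta_effort * (E_high - E_low),

with condition-specific coefficients: each coefficient is a sham baseline
plus additive offsets for the theta and alpha stimulation conditions
(dummy coding, sham as reference).

The effort-discounting variants first collapse each option to a subjective
value SV under a hyperbolic (R / (1 + beta*E)), parabolic (R - beta*E^2) or
linear (R - beta*E) discount function, and accumulate the SV difference:

    v = drift_scale * (SV_high - SV_low).

``drift_scale`` defaults to 1, i.e. the SV difference is the drift; a free
scale would make the linear form an exact reparameterization of the
attribute model and void any comparison between them.

Predictors enter raw (euros, N-back levels), so coefficients are
interpretable as drift per euro and drift per N-back level. Effort is the
integer N-back level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

__all__ = [
    "Condition",
    "DiscountForm",
    "ChoicePair",
    "AttributeCoefficients",
    "DiscountingCoefficients",
    "ConditionParams",
    "drift_attribute",
    "subjective_value",
    "drift_discounting",
    "resolve_condition",
]


class Condition(str, Enum):
    """Within-subject stimulation condition (sham is the dummy-coded reference)."""

    SHAM = "sham"
    THETA = "theta"
    ALPHA = "alpha"


class DiscountForm(str, Enum):
    HYPERBOLIC = "hyperbolic"
    PARABOLIC = "parabolic"
    LINEAR = "linear"


def _as_condition(condition) -> Condition:
    try:
        return Condition(condition)
    except ValueError:
        raise ValueError(f"unknown condition {condition!r}") from None


@dataclass(frozen=True)
class ChoicePair:
    """One decision's offer structure.

    The low option requires ``low_effort_level`` (1-3-back) for
    ``low_reward`` euro; the high option requires ``high_effort_level``
    (2-4-back) for a fixed ``high_reward`` of 2 or 4 euro.
    """

    low_effort_level: int
    high_effort_level: int
    low_reward: float
    high_reward: float
    condition: Condition = Condition.SHAM

    def __post_init__(self):
        object.__setattr__(self, "condition", _as_condition(self.condition))
        if not 1 <= self.low_effort_level < self.high_effort_level <= 4:
            raise ValueError(
                "effort levels must satisfy 1 <= low < high <= 4, got "
                f"({self.low_effort_level}, {self.high_effort_level})"
            )
        if not self.high_reward > 0:
            raise ValueError(f"high_reward must be positive, got {self.high_reward!r}")
        if not 0.0 <= self.low_reward <= self.high_reward:
            raise ValueError(
                f"low_reward {self.low_reward!r} outside [0, {self.high_reward}]"
            )

    @property
    def reward_diff(self) -> float:
        """High-minus-low reward difference, euro."""
        return self.high_reward - self.low_reward

    @property
    def effort_diff(self) -> int:
        """High-minus-low effort difference, N-back levels."""
        return self.high_effort_level - self.low_effort_level


@dataclass(frozen=True)
class AttributeCoefficients:
    """Drift coefficients of the attribute-comparison model.

    ``*_theta`` / ``*_alpha`` are additive offsets relative to sham.
    """

    beta_reward_sham: float = 0.0
    beta_reward_theta: float = 0.0
    beta_reward_alpha: float = 0.0
    beta_effort_sham: float = 0.0
    beta_effort_theta: float = 0.0
    beta_effort_alpha: float = 0.0

    def resolved(self, condition) -> tuple[float, float]:
        """(beta_reward, beta_effort) in the given condition."""
        cond = _as_condition(condition)
        is_t = cond is Condition.THETA
        is_a = cond is Condition.ALPHA
        br = self.beta_reward_sham + is_t * self.beta_reward_theta + is_a * self.beta_reward_alpha
        be = self.beta_effort_sham + is_t * self.beta_effort_theta + is_a * self.beta_effort_alpha
        return br, be


def drift_attribute(pair: ChoicePair, coeffs: AttributeCoefficients) -> float:
    """Drift of the attribute-comparison model for one choice pair."""
    br, be = coeffs.resolved(pair.condition)
    return br * pair.reward_diff - be * pair.effort_diff


def subjective_value(reward, effort, form, beta_discount):
    """Discounted subjective value of an option (vectorized over inputs).

    hyperbolic: R / (1 + beta*E); parabolic: R - beta*E^2;
    linear: R - beta*E. ``beta_discount`` must be >= 0.
    """
    form = DiscountForm(form)
    reward = np.asarray(reward, dtype=float)
    effort = np.asarray(effort, dtype=float)
    beta = np.asarray(beta_discount, dtype=float)
    if np.any(beta < 0):
        raise ValueError("beta_discount must be >= 0")
    if np.any(reward < 0) or np.any(effort < 0):
        raise ValueError("reward and effort must be >= 0")
    if form is DiscountForm.HYPERBOLIC:
        sv = reward / (1.0 + beta * effort)
    elif form is DiscountForm.PARABOLIC:
        sv = reward - beta * effort**2
    else:
        sv = reward - beta * effort
    return float(sv) if sv.ndim == 0 else sv


@dataclass(frozen=True)
class DiscountingCoefficients:
    """Discounting-model coefficients with condition offsets on the
    discount rate. ``drift_scale`` converts SV-difference units to drift;
    it is fixed at 1 unless explicitly freed."""

    discount_form: DiscountForm = DiscountForm.HYPERBOLIC
    beta_discount_sham: float = 0.0
    beta_discount_theta: float = 0.0
    beta_discount_alpha: float = 0.0
    drift_scale: float = 1.0

    def __post_init__(self):
        object.__setattr__(self, "discount_form", DiscountForm(self.discount_form))
        if self.beta_discount_sham < 0:
            raise ValueError("beta_discount_sham must be >= 0")

    def resolved_beta(self, condition) -> float:
        cond = _as_condition(condition)
        beta = self.beta_discount_sham
        if cond is Condition.THETA:
            beta += self.beta_discount_theta
        elif cond is Condition.ALPHA:
            beta += self.beta_discount_alpha
        return beta


def drift_discounting(pair: ChoicePair, coeffs: DiscountingCoefficients) -> float:
    """Drift of an effort-discounting model: scaled SV difference."""
    beta = coeffs.resolved_beta(pair.condition)
    if beta < 0:
        raise ValueError(
            f"resolved beta_discount is negative ({beta!r}) under {pair.condition}"
        )
    sv_high = subjective_value(pair.high_reward, pair.high_effort_level, coeffs.discount_form, beta)
    sv_low = subjective_value(pair.low_reward, pair.low_effort_level, coeffs.discount_form, beta)
    return coeffs.drift_scale * (sv_high - sv_low)


@dataclass(frozen=True)
class ConditionParams:
    """A participant's full parameter set: sham baselines plus additive
    theta/alpha offsets for every parameter (diffusion parameters and
    drift coefficients alike)."""

    base: dict = field(default_factory=dict)
    theta: dict = field(default_factory=dict)
    alpha: dict = field(default_factory=dict)


def _feasible(resolved: dict) -> bool:
    ok = True
    if "a" in resolved:
        ok &= resolved["a"] > 0
    if "z" in resolved:
        ok &= 0.0 < resolved["z"] < 1.0
    if "t0" in resolved:
        ok &= resolved["t0"] >= 0.0
    if "beta_discount" in resolved:
        ok &= resolved["beta_discount"] >= 0.0
    return bool(ok)


def resolve_condition(params: ConditionParams, condition, strict: bool = False):
    """Apply the condition's additive offsets to the sham baselines.

    Returns ``(resolved, feasible)``; with ``strict=True`` an infeasible
    resolution (a <= 0, z outside (0, 1), t0 < 0, negative discount rate)
    raises instead. Infeasible parameter sets receive likelihood ``-inf``
    in the hierarchical fit rather than being clamped.
    """
    cond = _as_condition(condition)
    offsets = (
        {} if cond is Condition.SHAM else params.theta if cond is Condition.THETA else params.alpha
    )
    resolved = {k: v + offsets.get(k, 0.0) for k, v in params.base.items()}
    feasible = _feasible(resolved)
    if strict and not feasible:
        raise ValueError(f"infeasible parameters under {cond.value}: {resolved}")
    return resolved, feasible
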