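"""Model-free behavioral metrics.

Subjective-value tables from the titration series, descriptive paired
condition contrasts (theta - sham, alpha - sham) with bootstrap intervals,
and 2-back signal-detection performance (d' and hit RTs). The contrasts
are deliberately descriptive companions to the model-based analysis:
regression-of-record inference is out of scope here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .titration import (
    N_TITRATION_CHOICES,
    indifference_point,
    relative_subjective_value,
    replay_choices,
)

__all__ = [
    "sv_table",
    "dprime",
    "nback_summary",
    "condition_contrasts",
    "ConditionContrast",
]

log = logging.getLogger(__name__)

_SERIES_KEYS = ["participant_id", "condition", "low_effort", "high_effort", "high_reward"]


def sv_table(trials: pd.DataFrame) -> pd.DataFrame:
    """Indifference points and relative subjective values per series.

    One row per (participant, condition, effort pair, high reward),
    obtained by replaying the recorded five-choice sequence through the
    staircase. Incomplete series are skipped with a logged warning.
    """
    rows = []
    for key, grp in trials.groupby(_SERIES_KEYS, sort=True):
        grp = grp.sort_values("trial_in_series", kind="stable")
        if len(grp) != N_TITRATION_CHOICES or list(grp["trial_in_series"]) != list(
            range(1, N_TITRATION_CHOICES + 1)
        ):
            log.warning("skipping incomplete titration series %s (%d trials)", key, len(grp))
            continue
        high_reward = float(key[-1])
        state = replay_choices(list(grp["choice"]), high_reward)
        ip = indifference_point(state)
        rows.append(
            dict(
                zip(_SERIES_KEYS, key),
                indifference_point=ip,
                relative_sv=relative_subjective_value(ip, high_reward),
            )
        )
    return pd.DataFrame(
        rows, columns=_SERIES_KEYS + ["indifference_point", "relative_sv"]
    )


def dprime(hits: int, misses: int, false_alarms: int, correct_rejections: int) -> float:
    """Signal-detection sensitivity: z(hit rate) - z(false-alarm rate).

    Extreme rates are pulled in by the 1/(2N) rule (N = targets for the
    hit rate, non-targets for the false-alarm rate) so the normal
    quantiles stay finite.
    """
    for name, v in (("hits", hits), ("misses", misses),
                    ("false_alarms", false_alarms), ("correct_rejections", correct_rejections)):
        if v < 0:
            raise ValueError(f"{name} must be non-negative, got {v}")
    n_targets = hits + misses
    n_lures = false_alarms + correct_rejections
    if n_targets == 0 or n_lures == 0:
        raise ValueError("need at least one target and one non-target trial")
    hr = np.clip(hits / n_targets, 1 / (2 * n_targets), 1 - 1 / (2 * n_targets))
    far = np.clip(false_alarms / n_lures, 1 / (2 * n_lures), 1 - 1 / (2 * n_lures))
    return float(stats.norm.ppf(hr) - stats.norm.ppf(far))


def nback_summary(nback: pd.DataFrame) -> pd.DataFrame:
    """Per participant and condition: hit rate, false-alarm rate, d' and
    mean hit RT (ms) from a 2-back trial table."""
    rows = []
    for (pid, cond), grp in nback.groupby(["participant_id", "condition"], sort=True):
        targets = grp[grp["is_target"]]
        lures = grp[~grp["is_target"]]
        hits = int(targets["responded"].sum())
        fas = int(lures["responded"].sum())
        d = dprime(hits, len(targets) - hits, fas, len(lures) - fas)
        hit_rt = targets.loc[targets["responded"], "rt_ms"].mean()
        rows.append(
            {
                "participant_id": pid,
                "condition": cond,
                "hit_rate": hits / len(targets),
                "fa_rate": fas / len(lures),
                "d_prime": d,
                "mean_hit_rt_ms": float(hit_rt) if np.isfinite(hit_rt) else np.nan,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ConditionContrast:
    """Within-participant condition means of relative subjective value and
    paired contrasts against sham with bootstrap 95% intervals."""

    participant_means: pd.DataFrame  # participants x conditions
    theta_minus_sham: float
    theta_ci: tuple
    alpha_minus_sham: float
    alpha_ci: tuple
    n_participants: int
    n_boot: int
    seed: int | None

    def to_dict(self) -> dict:
        return {
            "theta_minus_sham": self.theta_minus_sham,
            "theta_ci_95": list(self.theta_ci),
            "alpha_minus_sham": self.alpha_minus_sham,
            "alpha_ci_95": list(self.alpha_ci),
            "n_participants": self.n_participants,
            "n_boot": self.n_boot,
            "seed": self.seed,
        }


def condition_contrasts(
    sv_records: pd.DataFrame, seed: int | None = None, n_boot: int = 2000
) -> ConditionContrast:
    """Paired theta - sham and alpha - sham contrasts of mean relative
    subjective value, with seeded bootstrap-over-participants intervals.

    Participants missing any condition are dropped with a warning; at
    least two complete participants are required.
    """
    wide = (
        sv_records.groupby(["participant_id", "condition"])["relative_sv"]
        .mean()
        .unstack("condition")
    )
    complete = wide.dropna()
    dropped = set(wide.index) - set(complete.index)
    if dropped:
        log.warning("dropping participants without all conditions: %s", sorted(dropped))
    missing_conds = {"sham", "theta", "alpha"} - set(complete.columns)
    if missing_conds or len(complete) < 2:
        raise ValueError("need >= 2 participants with sham, theta and alpha data")
    d_theta = (complete["theta"] - complete["sham"]).to_numpy()
    d_alpha = (complete["alpha"] - complete["sham"]).to_numpy()
    rng = np.random.default_rng(seed)
    n = len(complete)
    idx = rng.integers(0, n, size=(n_boot, n))
    boot_t = d_theta[idx].mean(axis=1)
    boot_a = d_alpha[idx].mean(axis=1)
    return ConditionContrast(
        participant_means=complete,
        theta_minus_sham=float(d_theta.mean()),
        theta_ci=(float(np.quantile(boot_t, 0.025)), float(np.quantile(boot_t, 0.975))),
        alpha_minus_sham=float(d_alpha.mean()),
        alpha_ci=(float(np.quantile(boot_a, 0.025)), float(np.quantile(boot_a, 0.975))),
        n_participants=n,
        n_boot=n_boot,
        seed=seed,
    )
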