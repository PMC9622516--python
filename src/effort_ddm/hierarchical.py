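"""Hierarchical Bayesian estimation of the drift-diffusion models.

Every participant contributes a full parameter vector: sham baselines for
the diffusion parameters (boundary ``a``, bias ``z``, non-decision time
``t0``) and the model's drift coefficients, plus additive theta- and
alpha-condition offsets on each. Participant vectors are exchangeable
draws from normal group distributions whose means and SDs are the group
parameters; priors are non-informative uniforms over plausible ranges
(group means over the same ranges as individuals, group SDs over
(0.001, 2)).

Sampling is Metropolis-within-Gibbs over a small population of chains so
that differential-evolution proposals can use cross-chain differences
(chains are split into two halves; each half proposes with differences
drawn from the other). Three kinds of move are combined:

* participant-block moves -- all participants' values in a sub-block are
  proposed in parallel and accepted per participant; the sampler
  alternates between condition sub-blocks (sham baselines / theta
  offsets / alpha offsets) and per-parameter triples (base, theta
  offset, alpha offset), which covers both within-condition and
  base-offset posterior correlations;
* translation moves -- one group-level component and every participant's
  corresponding value shift by a common delta, which keeps the sampler
  mobile when a group SD is small (the usual hierarchical funnel);
  offset translations touch only that condition's trials;
* exact Gibbs draws for the group means (truncated normal) and group
  variances (truncated inverse-gamma), available in closed form under
  the uniform priors.

Per-condition likelihood contributions are cached so that moves touching
only the theta (or alpha) offsets re-evaluate a third of the data.

Convergence is summarized by split-chain R-hat (< 1.01 clean, 1.01-1.05
warned, >= 1.05 flagged as non-converged), inference by posterior means
with 95% highest-density intervals, and model comparison by the deviance
information criterion focused on the individual-level parameters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import arviz as az
import numpy as np
import pandas as pd
from scipy import stats

from . import _fastlik
from .drift import DiscountForm
from .wiener import simulate_trials, wfpt_logpdf

_MODEL_ID = {"attribute": 0, "hyperbolic": 1, "parabolic": 2, "linear": 3}

__all__ = [
    "McmcConfig",
    "paper_budget",
    "PosteriorDraws",
    "FitResult",
    "MODEL_NAMES",
    "trim_rts",
    "fit_hierarchical",
    "rhat",
    "hdi",
    "dic",
    "posterior_predictive",
]

log = logging.getLogger(__name__)

MODEL_NAMES = ("attribute", "hyperbolic", "parabolic", "linear")

_BASE_NAMES = {
    "attribute": ("a", "z", "t0", "beta_reward", "beta_effort"),
    "hyperbolic": ("a", "z", "t0", "beta_discount"),
    "parabolic": ("a", "z", "t0", "beta_discount"),
    "linear": ("a", "z", "t0", "beta_discount"),
}

#: Uniform prior ranges; the t0 upper bound is the participant's minimum
#: observed RT (group mean: the study-wide minimum).
PRIOR_RANGES = {
    "a": (0.3, 5.0),
    "z": (0.05, 0.95),
    "t0": (0.05, None),
    "beta_reward": (-5.0, 5.0),
    "beta_effort": (-5.0, 5.0),
    "beta_discount": (0.0, 5.0),
}
OFFSET_RANGE = (-2.0, 2.0)
SIGMA_RANGE = (1e-3, 2.0)

#: Baseline random-walk proposal scales per parameter kind (multiplied by
#: an adaptive per-block factor during burn-in).
_PROPOSAL_SD = {
    "a": 0.10,
    "z": 0.02,
    "t0": 0.02,
    "beta_reward": 0.03,
    "beta_effort": 0.03,
    "beta_discount": 0.05,
}
_OFFSET_PROPOSAL_SD = 0.02
_LL_FLOOR = -1e15


@dataclass(frozen=True)
class McmcConfig:
    """Sampler budget. ``n_draws`` is the number of retained draws per
    chain; the sampler runs ``n_burn + n_draws * thin`` sweeps."""

    n_chains: int = 4
    n_draws: int = 2000
    n_burn: int = 3000
    thin: int = 1
    seed: int | None = None
    rhat_warn: float = 1.01
    rhat_fail: float = 1.05

    def __post_init__(self):
        if self.n_chains < 2:
            raise ValueError("need at least 2 chains for convergence diagnostics")
        if self.n_draws < 1 or self.n_burn < 0 or self.thin < 1:
            raise ValueError("invalid sampler budget")


def paper_budget(seed: int | None = None) -> McmcConfig:
    """The reference study's budget: 2 chains of 50,000 sweeps each with a
    40,000-sweep burn-in and thinning 5 (2,000 retained draws/chain)."""
    return McmcConfig(n_chains=2, n_draws=2000, n_burn=40000, thin=5, seed=seed)


# ---------------------------------------------------------------------------
# RT trimming

def trim_rts(trials: pd.DataFrame, fraction: float = 0.05) -> pd.DataFrame:
    """Drop each participant's 5% fastest and 5% slowest trials.

    Applied per participant, pooled over conditions; ``floor(fraction*n)``
    trials are removed from each end of a stable sort on RT, so ties break
    deterministically by original trial order.
    """
    if len(trials) == 0:
        raise ValueError("empty trial table")
    if not 0.0 <= fraction < 0.5:
        raise ValueError(f"fraction must be in [0, 0.5), got {fraction!r}")
    keep_parts = []
    for _, grp in trials.groupby("participant_id", sort=False):
        n = len(grp)
        k = int(np.floor(fraction * n))
        order = np.argsort(grp["rt_s"].to_numpy(), kind="stable")
        keep = np.sort(order[k : n - k]) if k > 0 else np.arange(n)
        keep_parts.append(grp.iloc[keep])
    return pd.concat(keep_parts).sort_index().reset_index(drop=True)


# ---------------------------------------------------------------------------
# Data preparation and likelihood

_COND_INDEX = {"sham": 0, "theta": 1, "alpha": 2}


class _FitData:
    """Flat trial arrays grouped by condition, ready for vectorized
    likelihood evaluation with per-condition caching."""

    def __init__(self, trials: pd.DataFrame, model: str):
        required = {"participant_id", "condition", "rt_s", "choice",
                    "low_effort", "high_effort", "low_reward", "high_reward"}
        missing = required - set(trials.columns)
        if missing:
            raise ValueError(f"trial table lacks columns: {sorted(missing)}")
        if (trials["rt_s"] <= 0).any():
            raise ValueError("all rt_s must be positive")
        self.model = model
        self.participant_ids = sorted(trials["participant_id"].unique())
        if len(self.participant_ids) < 2:
            raise ValueError("hierarchical fit requires at least 2 participants")
        pid_map = {pid: i for i, pid in enumerate(self.participant_ids)}
        cond = trials["condition"].astype(str).map(_COND_INDEX)
        if cond.isna().any():
            bad = sorted(trials.loc[cond.isna(), "condition"].unique())
            raise ValueError(f"unknown condition labels in trial table: {bad}")
        part_idx = trials["participant_id"].map(pid_map).to_numpy(np.int64)
        cond_idx = cond.to_numpy(np.int64)
        self.n_trials = len(trials)
        self.n_part = len(self.participant_ids)
        rt = trials["rt_s"].to_numpy(float)
        upper = (trials["choice"] == "high").to_numpy(bool)
        r_high = trials["high_reward"].to_numpy(float)
        r_low = trials["low_reward"].to_numpy(float)
        e_high = trials["high_effort"].to_numpy(float)
        e_low = trials["low_effort"].to_numpy(float)
        self.cond = []
        for c in range(3):
            ix = np.where(cond_idx == c)[0]
            self.cond.append(
                {
                    "part": part_idx[ix],
                    "rt": rt[ix],
                    "upper": upper[ix],
                    "r_high": r_high[ix],
                    "r_low": r_low[ix],
                    "e_high": e_high[ix],
                    "e_low": e_low[ix],
                }
            )
        self.min_rt = np.full(self.n_part, np.inf)
        np.minimum.at(self.min_rt, part_idx, rt)

        self.base_names = _BASE_NAMES[model]
        self.n_base = len(self.base_names)
        self.n_ind = 3 * self.n_base
        self.param_names = (
            list(self.base_names)
            + [f"{n}_theta" for n in self.base_names]
            + [f"{n}_alpha" for n in self.base_names]
        )
        # per-component uniform ranges; t0 upper bound is per participant
        lo, hi = [], []
        for j, name in enumerate(self.param_names):
            if j < self.n_base:
                lo_j, hi_j = PRIOR_RANGES[self.base_names[j]]
                if self.base_names[j] == "t0":
                    hi_j = np.inf  # participant-specific, handled below
            else:
                lo_j, hi_j = OFFSET_RANGE
            lo.append(lo_j)
            hi.append(hi_j)
        self.range_lo = np.array(lo)
        self.range_hi_base = np.array(hi)
        self.t0_col = self.base_names.index("t0")
        self.range_hi = np.tile(self.range_hi_base, (self.n_part, 1))
        self.range_hi[:, self.t0_col] = self.min_rt
        self.mu_lo = self.range_lo.copy()
        self.mu_hi = self.range_hi_base.copy()
        # the group mean may exceed the fastest participant's own bound;
        # only the per-participant t0 values are capped by their min RT
        self.mu_hi[self.t0_col] = float(self.min_rt.max())
        self.prop_sd = np.array(
            [
                _PROPOSAL_SD[self.base_names[j]] if j < self.n_base else _OFFSET_PROPOSAL_SD
                for j in range(self.n_ind)
            ]
        )
        # two alternating block partitions: condition sub-blocks capture
        # within-condition correlations, per-parameter triples capture the
        # base-offset correlations
        b = self.n_base
        self.block_sets = [
            [np.arange(0, b), np.arange(b, 2 * b), np.arange(2 * b, 3 * b)],
            [np.array([j, j + b, j + 2 * b]) for j in range(b)],
        ]
        # conditions whose likelihood a block touches
        self.block_conds = [
            [(0, 1, 2), (1,), (2,)],
            [(0, 1, 2)] * b,
        ]
        self.n_blocks = max(len(bs) for bs in self.block_sets)

    def comp_conds(self, j: int):
        """Conditions whose likelihood component ``j`` touches."""
        if j < self.n_base:
            return (0, 1, 2)
        return (1,) if j < 2 * self.n_base else (2,)

    # -- likelihood ---------------------------------------------------------

    def loglik_cond(self, theta: np.ndarray, c: int) -> np.ndarray:
        """Per-participant log-likelihood of condition ``c``'s trials.

        ``theta`` has shape (N, d) or (K, N, d); returns (N,) or (K, N).
        Infeasible resolved parameter sets get the large negative
        sentinel.
        """
        single = theta.ndim == 2
        th = theta[None] if single else theta
        K = th.shape[0]
        b = self.n_base
        base = th[:, :, :b]
        if c == 0:
            res = base
        else:
            res = base + th[:, :, c * b : (c + 1) * b]
        names = self.base_names
        ia, iz, it0 = names.index("a"), names.index("z"), names.index("t0")
        a_r, z_r, t0_r = res[:, :, ia], res[:, :, iz], res[:, :, it0]
        feas = (a_r > 1e-3) & (z_r > 1e-4) & (z_r < 1 - 1e-4) & (t0_r >= 0.0)
        if self.model != "attribute":
            feas &= res[:, :, names.index("beta_discount")] >= 0.0

        d = self.cond[c]
        part = d["part"]
        if _fastlik.HAVE_NUMBA:
            a_m = np.ascontiguousarray(np.clip(a_r, 1e-3, None))
            z_m = np.ascontiguousarray(np.clip(z_r, 1e-4, 1 - 1e-4))
            t0_m = np.ascontiguousarray(t0_r)
            if self.model == "attribute":
                c1 = np.ascontiguousarray(res[:, :, names.index("beta_reward")])
                c2 = np.ascontiguousarray(res[:, :, names.index("beta_effort")])
            else:
                c1 = np.ascontiguousarray(
                    np.clip(res[:, :, names.index("beta_discount")], 0.0, None)
                )
                c2 = c1
            sums = np.zeros((K, self.n_part))
            _fastlik.loglik_sums(
                d["rt"], d["upper"], part, d["r_high"], d["r_low"], d["e_high"],
                d["e_low"], a_m, z_m, t0_m, c1, c2, _MODEL_ID[self.model],
                1e-10, -1e13, sums,
            )
            sums = np.where(feas, sums, _LL_FLOOR)
            sums = np.maximum(sums, _LL_FLOOR)
            return sums[0] if single else sums
        a_t = np.clip(a_r[:, part], 1e-3, None)
        z_t = np.clip(z_r[:, part], 1e-4, 1 - 1e-4)
        t0_t = t0_r[:, part]
        if self.model == "attribute":
            br = res[:, :, names.index("beta_reward")][:, part]
            be = res[:, :, names.index("beta_effort")][:, part]
            v_t = br * (d["r_high"] - d["r_low"]) - be * (d["e_high"] - d["e_low"])
        else:
            beta = np.clip(res[:, :, names.index("beta_discount")][:, part], 0.0, None)
            if self.model == "hyperbolic":
                sv_h = d["r_high"] / (1.0 + beta * d["e_high"])
                sv_l = d["r_low"] / (1.0 + beta * d["e_low"])
            elif self.model == "parabolic":
                sv_h = d["r_high"] - beta * d["e_high"] ** 2
                sv_l = d["r_low"] - beta * d["e_low"] ** 2
            else:
                sv_h = d["r_high"] - beta * d["e_high"]
                sv_l = d["r_low"] - beta * d["e_low"]
            v_t = sv_h - sv_l
        lp = wfpt_logpdf(d["rt"], d["upper"], a_t, v_t, z_t, t0_t)
        lp = np.where(np.isfinite(lp), lp, _LL_FLOOR)
        sums = np.empty((K, self.n_part))
        for k in range(K):
            sums[k] = np.bincount(part, weights=lp[k], minlength=self.n_part)
        sums = np.where(feas, sums, _LL_FLOOR)
        sums = np.maximum(sums, _LL_FLOOR)
        return sums[0] if single else sums

    def loglik_per_participant(self, theta: np.ndarray) -> np.ndarray:
        """Total per-participant log-likelihood over all conditions."""
        return sum(self.loglik_cond(theta, c) for c in range(3))

    def in_range(self, theta: np.ndarray) -> np.ndarray:
        """Per-participant indicator that every component is inside its
        uniform prior range; broadcasts over leading chain axes."""
        return ((theta >= self.range_lo) & (theta <= self.range_hi)).all(axis=-1)


# ---------------------------------------------------------------------------
# Posterior containers

@dataclass(frozen=True)
class PosteriorDraws:
    """Retained MCMC draws: group-level arrays of shape (chain, draw) per
    parameter, individual-level draws of shape (chain, draw, participant,
    component), and the sampler metadata."""

    group: dict
    individual: np.ndarray
    individual_names: tuple
    participant_ids: tuple
    n_chains: int
    n_draws: int
    burn_in: int
    thinning: int
    seed: int | None

    def names(self) -> list:
        return list(self.group)

    def to_dataset(self):
        return az.convert_to_dataset({k: v for k, v in self.group.items()})


@dataclass(frozen=True)
class FitResult:
    """Posterior draws plus convergence diagnostics, HDI summaries, DIC
    and the data the model was fit to."""

    model: str
    draws: PosteriorDraws
    summary: pd.DataFrame
    rhat: dict
    max_rhat: float
    dic: float
    dbar: float
    pd_eff: float
    deviance_draws: np.ndarray
    trials: pd.DataFrame = field(repr=False)
    warnings: tuple = ()

    @property
    def converged(self) -> bool:
        return self.max_rhat < 1.05

    def group_mean(self, name: str) -> float:
        return float(self.summary.loc[name, "mean"])

    def group_sd(self, name: str) -> float:
        return float(self.summary.loc[name, "sd"])

    def individual_posterior_means(self) -> pd.DataFrame:
        m = self.draws.individual.mean(axis=(0, 1))
        return pd.DataFrame(
            m, columns=list(self.draws.individual_names),
            index=list(self.draws.participant_ids),
        )


# ---------------------------------------------------------------------------
# Sampler

class _Sampler:
    def __init__(self, data: _FitData, cfg: McmcConfig, rng: np.random.Generator):
        self.data = data
        self.cfg = cfg
        self.rng = rng
        d, N, C = data.n_ind, data.n_part, cfg.n_chains
        self.theta = np.empty((C, N, d))
        self.mu = np.empty((C, d))
        self.sigma = np.empty((C, d))
        self.ll = np.empty((C, N, 3))  # per-condition cache
        idx = np.arange(C)
        self.halves = (idx[: C // 2], idx[C // 2 :])
        self.block_scale = np.ones((len(data.block_sets), data.n_blocks))
        self.trans_scale = np.full(d, 0.5)
        self._init_state()

    def _init_state(self):
        data, rng = self.data, self.rng
        N = data.n_part
        for c in range(self.cfg.n_chains):
            for attempt in range(200):
                th = np.empty((N, data.n_ind))
                for j, name in enumerate(data.param_names):
                    if j >= data.n_base:
                        th[:, j] = rng.uniform(-0.08, 0.08, N)
                        continue
                    base = data.base_names[j]
                    if base == "a":
                        th[:, j] = rng.uniform(1.0, 3.2, N)
                    elif base == "z":
                        th[:, j] = rng.uniform(0.35, 0.65, N)
                    elif base == "t0":
                        th[:, j] = rng.uniform(0.25, 0.7, N) * data.min_rt
                    elif base == "beta_discount":
                        th[:, j] = rng.uniform(0.05, 1.5, N)
                    else:
                        th[:, j] = rng.uniform(-0.5, 0.8, N)
                th = np.clip(th, data.range_lo, data.range_hi)
                ll = np.stack([data.loglik_cond(th, c_) for c_ in range(3)], axis=-1)
                if (ll.sum(axis=-1) > _LL_FLOOR / 2).all():
                    break
            else:
                raise RuntimeError("could not initialize feasible chain state")
            self.theta[c] = th
            self.mu[c] = th.mean(axis=0)
            self.sigma[c] = np.clip(th.std(axis=0) + 0.02, *SIGMA_RANGE)
            self.ll[c] = ll

    # -- prior pieces -------------------------------------------------------

    def _logprior_block(self, theta, mu, sigma, cols):
        """Hierarchical log-density of the block components, per (chain,
        participant). ``theta`` is (K, N, d); ``mu``/``sigma`` are (K, d)."""
        zs = (theta[:, :, cols] - mu[:, None, cols]) / sigma[:, None, cols]
        return -0.5 * (zs * zs).sum(axis=-1) - np.log(sigma[:, cols]).sum(axis=-1)[:, None]

    # -- moves --------------------------------------------------------------

    def _move_individual(self, sel, comp, si, bi, sweep):
        data, rng = self.data, self.rng
        cols = data.block_sets[si][bi]
        aff = data.block_conds[si][bi]
        K, N, n_cols = len(sel), data.n_part, len(cols)
        prop = self.theta[sel].copy()
        use_rw = rng.random() < 0.3 or len(comp) < 2
        if use_rw:
            step = self.block_scale[si, bi] * data.prop_sd[cols]
            prop[:, :, cols] += step * rng.standard_normal((K, N, n_cols))
        else:
            gamma = 1.0 if sweep % 10 == 0 else 2.38 / np.sqrt(2.0 * n_cols)
            r1 = comp[rng.integers(len(comp), size=K)]
            r2 = comp[rng.integers(len(comp), size=K)]
            redraw = r1 == r2
            while redraw.any():
                r2[redraw] = comp[rng.integers(len(comp), size=int(redraw.sum()))]
                redraw = r1 == r2
            diff = self.theta[r1][:, :, cols] - self.theta[r2][:, :, cols]
            prop[:, :, cols] += gamma * diff + 1e-4 * data.prop_sd[cols] * rng.standard_normal(
                (K, N, n_cols)
            )
        ok = (
            (prop[:, :, cols] >= data.range_lo[cols])
            & (prop[:, :, cols] <= data.range_hi[:, cols])
        ).all(axis=-1)
        ll_prop = {c: data.loglik_cond(prop, c) for c in aff}
        ll_new = sum(ll_prop.values())
        ll_old = self.ll[sel][:, :, list(aff)].sum(axis=-1)
        mu_s, sg_s = self.mu[sel], self.sigma[sel]
        pr_new = self._logprior_block(prop, mu_s, sg_s, cols)
        pr_old = self._logprior_block(self.theta[sel], mu_s, sg_s, cols)
        delta = np.where(ok, (ll_new + pr_new) - (ll_old + pr_old), -np.inf)
        accept = np.log(rng.random((K, N))) < delta
        for k, ch in enumerate(sel):
            rows = np.where(accept[k])[0]
            if rows.size:
                self.theta[ch][np.ix_(rows, cols)] = prop[k][np.ix_(rows, cols)]
                for c in aff:
                    self.ll[ch][rows, c] = ll_prop[c][k][rows]
        return use_rw, float(accept.mean())

    def _move_translation(self, sel, comp, j):
        """Shift group-mean component ``j`` and every participant's value
        by a common delta; the hierarchical prior is invariant, so
        acceptance involves only the affected condition's likelihood and
        the uniform bounds."""
        data, rng = self.data, self.rng
        aff = data.comp_conds(j)
        K = len(sel)
        if len(comp) >= 2 and rng.random() < 0.5:
            r1 = comp[rng.integers(len(comp), size=K)]
            r2 = comp[rng.integers(len(comp), size=K)]
            redraw = r1 == r2
            while redraw.any():
                r2[redraw] = comp[rng.integers(len(comp), size=int(redraw.sum()))]
                redraw = r1 == r2
            delta = 0.6 * (self.mu[r1, j] - self.mu[r2, j])
            delta += 0.1 * self.trans_scale[j] * data.prop_sd[j] * rng.standard_normal(K)
            rw = False
        else:
            delta = self.trans_scale[j] * data.prop_sd[j] * rng.standard_normal(K)
            rw = True
        mu_prop = self.mu[sel, j] + delta
        th_j = self.theta[sel][:, :, j] + delta[:, None]
        ok = (
            (mu_prop >= data.mu_lo[j])
            & (mu_prop <= data.mu_hi[j])
            & (th_j >= data.range_lo[j]).all(axis=1)
            & (th_j <= data.range_hi[:, j]).all(axis=1)
        )
        prop = self.theta[sel].copy()
        prop[:, :, j] = th_j
        ll_prop = {c: data.loglik_cond(prop, c) for c in aff}
        delta_ll = sum((ll_prop[c] - self.ll[sel][:, :, c]).sum(axis=1) for c in aff)
        accept = ok & (np.log(rng.random(K)) < delta_ll)
        for k, ch in enumerate(sel):
            if accept[k]:
                self.theta[ch][:, j] = prop[k][:, j]
                self.mu[ch, j] = mu_prop[k]
                for c in aff:
                    self.ll[ch][:, c] = ll_prop[c][k]
        return rw, float(accept.mean())

    def _update_group(self):
        """Exact Gibbs draws for group means and SDs, all chains at once."""
        data, rng = self.data, self.rng
        N = data.n_part
        xbar = self.theta.mean(axis=1)  # (C, d)
        se = self.sigma / np.sqrt(N)
        lo_u = stats.norm.cdf((data.mu_lo - xbar) / se)
        hi_u = stats.norm.cdf((data.mu_hi - xbar) / se)
        u = np.clip(lo_u + (hi_u - lo_u) * rng.random(xbar.shape), 1e-12, 1 - 1e-12)
        self.mu = xbar + se * stats.norm.ppf(u)
        s2 = np.maximum(((self.theta - self.mu[:, None, :]) ** 2).sum(axis=1), 1e-12)
        alpha = (N - 1) / 2.0
        lo_t, hi_t = SIGMA_RANGE[0] ** 2, SIGMA_RANGE[1] ** 2
        cdf_lo = stats.invgamma.cdf(lo_t, alpha, scale=s2 / 2.0)
        cdf_hi = stats.invgamma.cdf(hi_t, alpha, scale=s2 / 2.0)
        u = np.clip(cdf_lo + (cdf_hi - cdf_lo) * rng.random(s2.shape), 1e-12, 1 - 1e-12)
        tau = stats.invgamma.ppf(u, alpha, scale=s2 / 2.0)
        self.sigma = np.clip(np.sqrt(tau), *SIGMA_RANGE)

    # -- main loop ----------------------------------------------------------

    def run(self):
        cfg, data = self.cfg, self.data
        n_sweeps = cfg.n_burn + cfg.n_draws * cfg.thin
        C, N, d = cfg.n_chains, data.n_part, data.n_ind
        group_mu = np.empty((C, cfg.n_draws, d))
        group_sigma = np.empty((C, cfg.n_draws, d))
        ind = np.empty((C, cfg.n_draws, N, d))
        deviance = np.empty((C, cfg.n_draws))
        rw_acc = np.zeros((len(data.block_sets), data.n_blocks))
        rw_cnt = np.zeros_like(rw_acc)
        tr_acc = np.zeros(d)
        tr_cnt = np.zeros(d)
        kept = 0
        offset_comps = list(range(data.n_base, d))
        base_comps = list(range(data.n_base))
        for sweep in range(n_sweeps):
            si = sweep % len(data.block_sets)
            for bi in range(len(data.block_sets[si])):
                for h in (0, 1):
                    was_rw, acc = self._move_individual(
                        self.halves[h], self.halves[1 - h], si, bi, sweep
                    )
                    if was_rw:
                        rw_acc[si, bi] += acc
                        rw_cnt[si, bi] += 1
            comps = offset_comps + (base_comps if sweep % 5 == 0 else [])
            for j in comps:
                for h in (0, 1):
                    was_rw, acc = self._move_translation(
                        self.halves[h], self.halves[1 - h], j
                    )
                    if was_rw:
                        tr_acc[j] += acc
                        tr_cnt[j] += 1
            self._update_group()

            in_burn = sweep < cfg.n_burn
            if in_burn and sweep % 50 == 49:
                frac_rw = np.where(rw_cnt > 0, rw_acc / np.maximum(rw_cnt, 1), 0.25)
                frac_tr = np.where(tr_cnt > 0, tr_acc / np.maximum(tr_cnt, 1), 0.25)
                self.block_scale = np.clip(
                    self.block_scale * np.exp(0.4 * (frac_rw - 0.25)), 1e-2, 1e2
                )
                self.trans_scale = np.clip(
                    self.trans_scale * np.exp(0.4 * (frac_tr - 0.25)), 1e-2, 1e2
                )
                rw_acc[:] = rw_cnt[:] = 0.0
                tr_acc[:] = tr_cnt[:] = 0.0
            if not in_burn and (sweep - cfg.n_burn) % cfg.thin == cfg.thin - 1:
                group_mu[:, kept] = self.mu
                group_sigma[:, kept] = self.sigma
                ind[:, kept] = self.theta
                deviance[:, kept] = -2.0 * self.ll.sum(axis=(1, 2))
                kept += 1
        assert kept == cfg.n_draws
        return group_mu, group_sigma, ind, deviance


# ---------------------------------------------------------------------------
# Public operations

def rhat(draws, parameter: str | None = None, method: str = "split") -> float:
    """Split-chain potential-scale-reduction statistic.

    ``draws`` is either an array of shape (chain, draw) or a
    :class:`PosteriorDraws` together with a ``parameter`` name. Requires
    at least 2 chains and 10 draws per chain.
    """
    if isinstance(draws, PosteriorDraws):
        if parameter is None:
            raise ValueError("parameter name required with PosteriorDraws input")
        arr = np.asarray(draws.group[parameter])
    else:
        arr = np.asarray(draws, dtype=float)
    if arr.ndim != 2:
        raise ValueError("draws must have shape (chain, draw)")
    if arr.shape[0] < 2 or arr.shape[1] < 4:
        raise ValueError("need >= 2 chains with >= 4 draws each (2 per split half)")
    return float(az.rhat(az.convert_to_dataset(arr), method=method)["x"].values)


def hdi(samples, mass: float = 0.95):
    """Shortest interval holding ``mass`` of the samples, plus their mean.

    Returns ``(lower, upper, mean)``; requires at least 100 samples.
    """
    if not 0.0 < mass < 1.0:
        raise ValueError(f"mass must be in (0, 1), got {mass!r}")
    arr = np.asarray(samples, dtype=float).ravel()
    if arr.size < 100:
        raise ValueError("need at least 100 samples for an HDI")
    if np.ptp(arr) == 0.0:
        return float(arr[0]), float(arr[0]), float(arr[0])
    lo, hi = az.hdi(arr, hdi_prob=mass)
    return float(lo), float(hi), float(arr.mean())


def _summarize(group: dict, mass: float = 0.95) -> tuple[pd.DataFrame, dict]:
    rows = {}
    rhats = {}
    for name, arr in group.items():
        flat = arr.ravel()
        if np.ptp(flat) == 0.0:
            lo = hi = float(flat[0])
        else:
            lo, hi = az.hdi(flat, hdi_prob=mass)
        rhats[name] = rhat(arr)
        rows[name] = {
            "mean": float(flat.mean()),
            "sd": float(flat.std(ddof=1)),
            "hdi_lower": float(lo),
            "hdi_upper": float(hi),
            "rhat": rhats[name],
        }
    return pd.DataFrame(rows).T, rhats


def fit_hierarchical(
    trials: pd.DataFrame,
    model: str = "attribute",
    mcmc: McmcConfig | None = None,
    seed: int | None = None,
) -> FitResult:
    """Fit one hierarchical DDM variant to a trial table and return
    draws, diagnostics, HDIs and DIC.

    ``model`` is one of ``attribute``, ``hyperbolic``, ``parabolic``,
    ``linear``. Reproducible given ``seed`` (or ``mcmc.seed``).
    Non-convergence (any R-hat >= 1.05) is flagged in
    ``FitResult.warnings`` and ``converged``, never silent.
    """
    if model not in MODEL_NAMES:
        raise ValueError(f"model must be one of {MODEL_NAMES}, got {model!r}")
    cfg = mcmc or McmcConfig()
    if seed is not None:
        cfg = replace(cfg, seed=seed)
    rng = np.random.default_rng(cfg.seed)
    data = _FitData(trials, model)
    sampler = _Sampler(data, cfg, rng)
    group_mu, group_sigma, ind, deviance = sampler.run()

    group = {}
    for j, name in enumerate(data.param_names):
        group[f"mu_{name}"] = group_mu[:, :, j]
        group[f"sigma_{name}"] = group_sigma[:, :, j]
    draws = PosteriorDraws(
        group=group,
        individual=ind,
        individual_names=tuple(data.param_names),
        participant_ids=tuple(data.participant_ids),
        n_chains=cfg.n_chains,
        n_draws=cfg.n_draws,
        burn_in=cfg.n_burn,
        thinning=cfg.thin,
        seed=cfg.seed,
    )
    summary, rhats = _summarize(group)
    # individual-level R-hats enter the convergence gate too
    ind_rhat = az.rhat(
        az.convert_to_dataset(ind.reshape(cfg.n_chains, cfg.n_draws, -1)), method="split"
    )["x"].values
    max_rhat = float(max(np.nanmax(list(rhats.values())), np.nanmax(ind_rhat)))
    warnings = []
    if max_rhat >= cfg.rhat_fail:
        warnings.append(f"non-convergence: max split R-hat {max_rhat:.3f} >= {cfg.rhat_fail}")
        log.warning(warnings[-1])
    elif max_rhat >= cfg.rhat_warn:
        warnings.append(f"max split R-hat {max_rhat:.3f} in warn band >= {cfg.rhat_warn}")
        log.info(warnings[-1])

    dbar = float(deviance.mean())
    theta_hat = ind.mean(axis=(0, 1))
    d_hat = float(-2.0 * data.loglik_per_participant(theta_hat).sum())
    pd_eff = dbar - d_hat
    dic_val = dbar + pd_eff
    return FitResult(
        model=model,
        draws=draws,
        summary=summary,
        rhat=rhats,
        max_rhat=max_rhat,
        dic=dic_val,
        dbar=dbar,
        pd_eff=pd_eff,
        deviance_draws=deviance,
        trials=trials,
        warnings=tuple(warnings),
    )


def dic(fit: FitResult, trials: pd.DataFrame | None = None):
    """Deviance information criterion focused on the individual-level
    parameters: ``DIC = Dbar + pD`` with ``pD = Dbar - D(theta_hat)``.

    With ``trials`` given, the plug-in deviance is recomputed on that
    table (it must cover the same participants); otherwise the stored
    value is returned.
    """
    if trials is None:
        return fit.dic, fit.dbar, fit.pd_eff
    data = _FitData(trials, fit.model)
    if tuple(data.participant_ids) != fit.draws.participant_ids:
        raise ValueError("trial table does not match the fitted participants")
    theta_hat = fit.draws.individual.mean(axis=(0, 1))
    d_hat = float(-2.0 * data.loglik_per_participant(theta_hat).sum())
    if d_hat >= -2.0 * _LL_FLOOR / 1e3:
        raise ValueError("deviance undefined at the posterior mean (infeasible parameters)")
    dbar = float(fit.deviance_draws.mean())
    pd_eff = dbar - d_hat
    return dbar + pd_eff, dbar, pd_eff


def posterior_predictive(
    fit: FitResult, design: pd.DataFrame | None = None, seed: int | None = None
) -> pd.DataFrame:
    """Simulate choices and RTs from the individual posterior means over
    an observed design.

    Returns the design rows with simulated ``choice``, ``rt_s`` and
    ``signed_rt`` (negative = low-effort choice), the usual overlay for
    comparing simulated against observed RT distributions.
    """
    design = fit.trials if design is None else design
    out = design.copy()
    if len(design) == 0:
        for col in ("choice", "rt_s", "signed_rt"):
            out[col] = pd.Series(dtype=float if col != "choice" else object)
        return out
    rng = np.random.default_rng(seed)
    means = fit.individual_posterior_means()
    base_names = _BASE_NAMES[fit.model]
    pid_map = {pid: i for i, pid in enumerate(fit.draws.participant_ids)}
    pi = design["participant_id"].map(pid_map)
    if pi.isna().any():
        raise ValueError("design contains participants absent from the fit")
    pi = pi.to_numpy(np.int64)
    ci = design["condition"].astype(str).map(_COND_INDEX).to_numpy(np.int64)
    theta = means.to_numpy()  # (N, d)
    b = len(base_names)
    resolved = np.stack(
        [theta[:, :b], theta[:, :b] + theta[:, b : 2 * b], theta[:, :b] + theta[:, 2 * b :]],
        axis=1,
    )

    def col(name):
        return resolved[:, :, base_names.index(name)][pi, ci]

    r_high = design["high_reward"].to_numpy(float)
    r_low = design["low_reward"].to_numpy(float)
    e_high = design["high_effort"].to_numpy(float)
    e_low = design["low_effort"].to_numpy(float)
    if fit.model == "attribute":
        v = col("beta_reward") * (r_high - r_low) - col("beta_effort") * (e_high - e_low)
    else:
        beta = np.clip(col("beta_discount"), 0.0, None)
        form = DiscountForm(fit.model)
        if form is DiscountForm.HYPERBOLIC:
            v = r_high / (1 + beta * e_high) - r_low / (1 + beta * e_low)
        elif form is DiscountForm.PARABOLIC:
            v = (r_high - beta * e_high**2) - (r_low - beta * e_low**2)
        else:
            v = (r_high - beta * e_high) - (r_low - beta * e_low)
    choice, rt, _ = simulate_trials(col("a"), v, col("z"), col("t0"), rng)
    out["choice"] = np.where(choice == 1, "high", "low")
    out["rt_s"] = rt
    out["signed_rt"] = np.where(choice == 1, rt, -rt)
    return out
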