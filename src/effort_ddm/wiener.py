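"""Two-boundary Wiener diffusion primitives.

Choice and response time are modelled as the first passage of a drifting
Brownian motion (unit diffusion coefficient) between an absorbing lower
boundary at 0 and an upper boundary at ``a``, started at ``z * a``. The
upper boundary codes a high-effort choice, the lower boundary a low-effort
choice. Observed RT is the absorption time plus a non-decision time ``t0``.

The first-passage-time density uses the classic dual-series evaluation: a
small-time expansion (sum over image charges) and a large-time expansion
(sine series), switching per evaluation point to whichever needs fewer
terms for a requested truncation error (1e-10 by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "WienerParams",
    "fpt_density",
    "wfpt_logpdf",
    "choice_probability",
    "simulate_trial",
    "simulate_trials",
    "log_likelihood",
    "SIM_DT",
    "SIM_TMAX",
]

#: Truncation tolerance for the series evaluation (on the normalized scale).
SERIES_ERR = 1e-10
#: Euler-Maruyama step for the trial simulator, in seconds.
SIM_DT = 1e-3
#: Absorption cap for the simulator, in seconds; paths alive beyond this
#: are flagged as censored.
SIM_TMAX = 20.0


@dataclass(frozen=True)
class WienerParams:
    """Diffusion parameters: boundary ``a`` > 0 (evidence units), drift
    ``v`` (evidence/s), relative start ``z`` in (0, 1), non-decision time
    ``t0`` >= 0 s. The diffusion coefficient is fixed at 1, so ``a`` is in
    noise units."""

    a: float
    v: float
    z: float
    t0: float = 0.0

    def __post_init__(self):
        if not (np.isfinite(self.a) and self.a > 0):
            raise ValueError(f"boundary a must be finite and > 0, got {self.a!r}")
        if not np.isfinite(self.v):
            raise ValueError(f"drift v must be finite, got {self.v!r}")
        if not (np.isfinite(self.z) and 0.0 < self.z < 1.0):
            raise ValueError(f"relative start z must be in (0, 1), got {self.z!r}")
        if not (np.isfinite(self.t0) and self.t0 >= 0.0):
            raise ValueError(f"non-decision time t0 must be >= 0, got {self.t0!r}")


def _f0_lower(u, w, err=SERIES_ERR):
    """Density of first passage through 0 at normalized time ``u`` for a
    zero-drift, unit-diffusion process on [0, 1] started at ``w``.

    Vectorized; entries with ``u <= 0`` return 0. Term counts follow the
    standard small-time / large-time bounds for truncation error ``err``;
    within each regime the batch uses the largest required count (extra
    terms only shrink the truncation error).
    """
    u = np.asarray(u, dtype=float)
    w = np.asarray(w, dtype=float)
    u, w = np.broadcast_arrays(u, w)
    out = np.zeros(u.shape, dtype=float)
    ok = u > 0
    if not ok.any():
        return out
    uu = np.ascontiguousarray(u[ok])
    ww = np.ascontiguousarray(w[ok])

    with np.errstate(over="ignore", under="ignore", divide="ignore", invalid="ignore"):
        sq = np.sqrt(2.0 * np.pi * uu)
        ks = np.where(
            2.0 * sq * err < 1.0,
            2.0 + np.sqrt(np.maximum(-2.0 * uu * np.log(np.minimum(2.0 * sq * err, 1.0)), 0.0)),
            2.0,
        )
        ks = np.maximum(ks, np.sqrt(uu) + 1.0)
        kl = np.where(
            np.pi * uu * err < 1.0,
            np.sqrt(
                np.maximum(-2.0 * np.log(np.minimum(np.pi * uu * err, 1.0)), 0.0)
                / (np.pi**2 * uu)
            ),
            0.0,
        )
        kl = np.maximum(kl, 1.0 / (np.pi * np.sqrt(uu)))

    res = np.empty_like(uu)
    small = ks < kl
    if small.any():
        us = uu[small]
        wsv = ww[small]
        K = int(np.ceil(ks[small].max()))
        acc = np.zeros_like(us)
        with np.errstate(under="ignore"):
            for k in range(-((K - 1) // 2), (K - 1) - (K - 1) // 2 + 1):
                wk = wsv + 2.0 * k
                acc += wk * np.exp(-(wk * wk) / (2.0 * us))
            res[small] = acc / np.sqrt(2.0 * np.pi * us**3)
    large = ~small
    if large.any():
        ul = uu[large]
        wl = ww[large]
        K = int(np.ceil(kl[large].max()))
        acc = np.zeros_like(ul)
        with np.errstate(under="ignore"):
            for k in range(1, K + 1):
                acc += k * np.exp(-(k * k) * (np.pi**2) * ul / 2.0) * np.sin(k * np.pi * wl)
        res[large] = np.pi * acc

    out[ok] = np.maximum(res, 0.0)
    return out


def wfpt_logpdf(t, upper, a, v, z, t0, err=SERIES_ERR):
    """Log of the defective first-passage density, broadcast over inputs.

    ``upper`` selects the boundary per element (True = upper). Entries with
    ``t <= t0`` or zero density return ``-inf``; no parameter validation is
    done here (callers in the sampler gate feasibility themselves).
    """
    t, upper, a, v, z, t0 = np.broadcast_arrays(
        np.asarray(t, float),
        np.asarray(upper, bool),
        np.asarray(a, float),
        np.asarray(v, float),
        np.asarray(z, float),
        np.asarray(t0, float),
    )
    v_eff = np.where(upper, -v, v)
    w = np.where(upper, 1.0 - z, z)
    td = t - t0
    with np.errstate(divide="ignore", invalid="ignore", over="ignore", under="ignore"):
        u = np.where(td > 0, td / (a * a), -1.0)
        f0 = _f0_lower(u, w, err)
        good = (td > 0) & (f0 > 0)
        logf = np.where(
            good,
            np.log(np.where(good, f0, 1.0))
            - v_eff * a * w
            - 0.5 * v_eff * v_eff * td
            - 2.0 * np.log(a),
            -np.inf,
        )
    return logf


def fpt_density(t, params: WienerParams, boundary: str = "upper", err=SERIES_ERR):
    """Defective density of absorption at ``boundary`` at time ``t`` (s).

    Integrates over t to the probability of that choice; the two
    boundaries together integrate to 1. Zero for ``t <= t0``.
    """
    if boundary not in ("upper", "lower"):
        raise ValueError(f"boundary must be 'upper' or 'lower', got {boundary!r}")
    t_arr = np.asarray(t, dtype=float)
    lp = wfpt_logpdf(t_arr, boundary == "upper", params.a, params.v, params.z, params.t0, err)
    with np.errstate(under="ignore"):
        dens = np.exp(lp)
    return float(dens) if np.isscalar(t) or t_arr.ndim == 0 else dens


def choice_probability(params: WienerParams) -> float:
    """Probability of absorption at the upper (high effort) boundary.

    Closed form ``(1 - exp(-2 v a z)) / (1 - exp(-2 v a))``; the zero-drift
    limit is ``z``.
    """
    a, v, z = params.a, params.v, params.z
    x = -2.0 * v * a
    if abs(x) < 1e-9:
        return float(z)
    x = float(np.clip(x, -700.0, 700.0))
    return float(np.expm1(x * z) / np.expm1(x))


def simulate_trials(a, v, z, t0, rng, dt: float = SIM_DT, t_max: float = SIM_TMAX):
    """Euler-Maruyama simulation of many independent trials.

    Parameters broadcast to a common shape; returns ``(choice, rt, censored)``
    with ``choice`` 1 for upper / 0 for lower, ``rt`` in seconds (absorption
    time + t0), and ``censored`` True where no boundary was hit by ``t_max``
    (such trials report ``rt = t_max + t0`` and choice by the nearer
    boundary).
    """
    a, v, z, t0 = np.broadcast_arrays(
        np.asarray(a, float), np.asarray(v, float), np.asarray(z, float), np.asarray(t0, float)
    )
    shape = a.shape
    a = a.ravel().copy()
    v = v.ravel()
    z = z.ravel()
    t0 = t0.ravel()
    n = a.size
    x = z * a
    choice = np.zeros(n, dtype=np.int64)
    steps = np.zeros(n, dtype=np.int64)
    active = np.arange(n)
    sdt = np.sqrt(dt)
    n_max = int(round(t_max / dt))
    k = 0
    while active.size and k < n_max:
        k += 1
        xa = x[active] + v[active] * dt + sdt * rng.standard_normal(active.size)
        x[active] = xa
        up = xa >= a[active]
        lo = xa <= 0.0
        done = up | lo
        if done.any():
            idx = active[done]
            choice[idx] = up[done].astype(np.int64)
            steps[idx] = k
            active = active[~done]
    censored = np.zeros(n, dtype=bool)
    if active.size:
        censored[active] = True
        steps[active] = n_max
        choice[active] = (x[active] >= a[active] / 2.0).astype(np.int64)
    rt = steps * dt + t0
    return choice.reshape(shape), rt.reshape(shape), censored.reshape(shape)


def simulate_trial(params: WienerParams, seed):
    """Simulate one trial; returns ``(choice, rt_s, censored)`` with choice
    ``"upper"`` or ``"lower"``. ``seed`` may be an int or a Generator."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    c, rt, cens = simulate_trials(params.a, params.v, params.z, params.t0, rng)
    return ("upper" if int(c) == 1 else "lower", float(rt), bool(cens))


def log_likelihood(trials, params: WienerParams) -> float:
    """Sum of log first-passage densities over ``(choice, rt_s)`` tuples.

    ``choice`` accepts ``"upper"``/``"high"`` vs ``"lower"``/``"low"``.
    Empty input returns 0. A trial with ``rt <= t0`` contributes ``-inf``
    (infeasible non-decision time).
    """
    trials = list(trials)
    if not trials:
        return 0.0
    upper = np.array([c in ("upper", "high", 1, True) for c, _ in trials], dtype=bool)
    rt = np.array([float(t) for _, t in trials])
    lp = wfpt_logpdf(rt, upper, params.a, params.v, params.z, params.t0)
    return float(np.sum(lp))
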