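"""JIT-compiled likelihood kernel for the hierarchical sampler.

Implements the same dual-series first-passage density as
:mod:`effort_ddm.wiener` in a fused per-trial loop (parameter gather,
drift construction, density, per-participant accumulation), which is what
the Metropolis-within-Gibbs sampler spends essentially all its time on.
The vectorized numpy path remains the reference implementation; this
module is optional and the sampler falls back to numpy when numba is
unavailable.

Model ids: 0 attribute, 1 hyperbolic, 2 parabolic, 3 linear.
"""

from __future__ import annotations

import math

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is an optional accelerator
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def deco(f):
            return f

        return deco if not (args and callable(args[0])) else args[0]


@njit(cache=False)
def _log_f0(u: float, w: float, err: float) -> float:
    """Log density of first passage through 0 at normalized time ``u`` for
    a zero-drift unit-diffusion on [0, 1] started at ``w``; small-time /
    large-time series chosen by required term count."""
    sq = math.sqrt(2.0 * math.pi * u)
    if 2.0 * sq * err < 1.0:
        ks = 2.0 + math.sqrt(-2.0 * u * math.log(2.0 * sq * err))
        if ks < math.sqrt(u) + 1.0:
            ks = math.sqrt(u) + 1.0
    else:
        ks = 2.0
    if math.pi * u * err < 1.0:
        kl = math.sqrt(-2.0 * math.log(math.pi * u * err) / (math.pi * math.pi * u))
        if kl < 1.0 / (math.pi * math.sqrt(u)):
            kl = 1.0 / (math.pi * math.sqrt(u))
    else:
        kl = 1.0 / (math.pi * math.sqrt(u))
    acc = 0.0
    if ks < kl:
        K = int(math.ceil(ks))
        lo = -((K - 1) // 2)
        hi = (K - 1) - (K - 1) // 2
        for k in range(lo, hi + 1):
            wk = w + 2.0 * k
            acc += wk * math.exp(-(wk * wk) / (2.0 * u))
        f = acc / math.sqrt(2.0 * math.pi * u * u * u)
    else:
        K = int(math.ceil(kl))
        for k in range(1, K + 1):
            acc += k * math.exp(-(k * k) * (math.pi * math.pi) * u / 2.0) * math.sin(
                k * math.pi * w
            )
        f = math.pi * acc
    if f > 0.0:
        return math.log(f)
    return -np.inf


@njit(cache=False)
def loglik_sums(
    rt, upper, part, r_high, r_low, e_high, e_low,
    a2, z2, t02, c1, c2, model_id, err, floor, out,
):
    """Accumulate per-(chain, participant) trial log-likelihoods into
    ``out`` (must be zero-initialized, shape (K, n_participants)).

    ``a2``/``z2``/``t02``/``c1``/``c2`` are condition-resolved per-chain,
    per-participant parameter matrices; ``c1``/``c2`` are the drift
    coefficients (reward/effort for the attribute model; discount rate in
    ``c1`` otherwise). Infeasible evaluations contribute ``floor``.
    """
    K = a2.shape[0]
    T = rt.shape[0]
    for k in range(K):
        for t in range(T):
            p = part[t]
            a = a2[k, p]
            z = z2[k, p]
            t0 = t02[k, p]
            if model_id == 0:
                v = c1[k, p] * (r_high[t] - r_low[t]) - c2[k, p] * (e_high[t] - e_low[t])
            elif model_id == 1:
                b = c1[k, p]
                v = r_high[t] / (1.0 + b * e_high[t]) - r_low[t] / (1.0 + b * e_low[t])
            elif model_id == 2:
                b = c1[k, p]
                v = (r_high[t] - b * e_high[t] * e_high[t]) - (
                    r_low[t] - b * e_low[t] * e_low[t]
                )
            else:
                b = c1[k, p]
                v = (r_high[t] - b * e_high[t]) - (r_low[t] - b * e_low[t])
            if upper[t]:
                ve = -v
                w = 1.0 - z
            else:
                ve = v
                w = z
            td = rt[t] - t0
            if td <= 0.0:
                lp = floor
            else:
                u = td / (a * a)
                lf0 = _log_f0(u, w, err)
                if lf0 == -np.inf:
                    lp = floor
                else:
                    lp = lf0 - ve * a * w - 0.5 * ve * ve * td - 2.0 * math.log(a)
                    if not math.isfinite(lp) or lp < floor:
                        lp = floor
            out[k, p] += lp
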