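# Methods

## The task and the staircase

The effort-based decision task offers, on every trial, a low effort-low
reward option against a high effort-high reward option. Effort is an
N-back working-memory level (low option 1-3-back, high option 2-4-back,
always strictly harder); the high reward is fixed at 2 or 4 euro. The low
offer starts at half the high amount and is titrated: choosing the high
option raises it by the current step, choosing the low option lowers it,
and the step — initially a quarter of the high amount — halves after every
choice. Five choices per (low effort, high effort, high reward) series
bisect the indifference point; the estimate is the offer a hypothetical
sixth trial would present, so its resolution is `high_reward / 64`
(0.0625 euro for 4-euro pairs, 0.03125 euro for 2-euro pairs — the
halving rule makes the resolution proportional to the high amount).
Dividing by the high reward gives the relative subjective value (RSV) of
the high option in [0, 1]. Offers are clamped to `[0, high_reward]` and an
exactly indifferent agent is counted as choosing the high option, so
degenerate inputs cannot stall the staircase. Each series is independent;
nothing carries over between stimulation conditions.

A session comprises 9 miniblocks of 20 trials (3 miniblocks per
stimulation condition: sham, theta, alpha; order counterbalanced by Latin
square), i.e. 6 effort pairs x 2 high rewards x 5 choices = 60 decisions
per condition and 180 per participant, plus one 40-trial 2-back block per
condition.

## Diffusion model

Choices and response times are modelled as a two-boundary Wiener process
with unit diffusion coefficient: evidence starts at `z * a` (bias
`z` in (0, 1)), drifts at rate `v`, and absorbs at `a` (choose high
effort) or 0 (choose low effort); RT is absorption time plus a
non-decision time `t0`. The first-passage density is evaluated with the
standard dual-series expansion — a small-time image-charge sum and a
large-time sine series — switching per evaluation point to whichever
regime needs fewer terms for truncation error 1e-10. The analytic
absorption probability `(1 - e^{-2vaz}) / (1 - e^{-2va})` (limit `z` at
`v = 0`) serves as an internal cross-check: the integrated upper-boundary
density must match it, and both densities together must integrate to 1
(verified to 1e-4 over a 27-point parameter grid).

Trials are simulated by Euler-Maruyama with step 1 ms and a 20 s
absorption cap (censoring flagged). At study-typical parameters the
discretization inflates RTs by roughly the step-size-order boundary
overshoot; this is far below the recovery tolerances, and the oracle
tests that compare simulator against analytic density use a finer step so
the scheme's own bias stays below the test tolerance. There are no
across-trial variability parameters (none are in the models considered).

Four drift-rate constructions are supported:

* **attribute comparison** — `v = beta_reward * (R_high - R_low) -
  beta_effort * (E_high - E_low)`, with rewards in euro and efforts in
  N-back levels, entered raw so the coefficients are interpretable as
  drift per euro and per level;
* **effort discounting** (hyperbolic `R/(1 + beta*E)`, parabolic
  `R - beta*E^2`, linear `R - beta*E`) — each option is collapsed to a
  subjective value and `v = SV_high - SV_low`. The drift scale is fixed
  at 1 (a `drift_scale` field exists for experimentation): with a free
  scale the linear form is an exact reparameterization of the attribute
  model and the comparison between them would be vacuous.

Stimulation enters by dummy coding: every parameter (a, z, t0 and the
drift coefficients) has a sham baseline plus additive theta and alpha
offsets on the natural scale. Infeasible resolved combinations (a <= 0,
z outside (0, 1), t0 < 0, negative discount rate) receive zero
likelihood rather than being clamped.

## Hierarchical estimation

Participant-level parameter vectors (5 base + 10 offsets for the
attribute model; 4 + 8 for discounting) are normal draws from group
distributions; group means and SDs are the quantities of interest.
Priors are non-informative uniforms: a in (0.3, 5), z in (0.05, 0.95),
t0 in (0.05, min observed RT — per participant for individual values, the
study-wide minimum for the group mean), drift coefficients in (-5, 5),
discount rates in (0, 5), condition offsets in (-2, 2), group SDs in
(0.001, 2). The truncation of the group-level normal by the individual
ranges is ignored in the group conditionals (it is negligible at the SDs
these data produce).

The sampler is Metropolis-within-Gibbs over a small population of
chains, so differential-evolution proposals can use cross-chain
differences (chains are split in two halves; each half proposes with
scaled differences of two states from the other half, 30% adaptive
random-walk moves, occasional mode-jump steps). Three move families:

1. **participant blocks** — all participants in parallel, accepted per
   participant; the sweep alternates between condition sub-blocks (sham
   baselines / theta offsets / alpha offsets) and per-parameter triples
   (base, theta offset, alpha offset). The two partitions cover the two
   dominant correlation structures: within-condition parameter trade-offs
   and base-offset anticorrelation.
2. **translation moves** — one group-level component and every
   participant's corresponding value shift by a common delta. Because the
   hierarchical prior is invariant under this shift, acceptance involves
   only the trial likelihood; these moves keep the group mean mobile when
   a group SD is near zero (the usual hierarchical funnel, acute here
   because condition offsets are generated with tiny between-subject
   spread). Offset translations touch only that condition's trials.
3. **exact group-level Gibbs** — under the uniform priors the group-mean
   conditional is a truncated normal and the group-variance conditional a
   truncated inverse-gamma, both sampled in closed form.

Per-condition likelihood contributions are cached so moves touching only
the theta (or alpha) offsets re-evaluate a third of the data. The
likelihood inner loop is JIT-compiled (numba) with the vectorized numpy
implementation kept as reference and fallback; the two paths agree to
1e-13 and this equality is unit-tested.

Adaptive proposal scales target 25% acceptance and adapt only during
burn-in. Default budget: 4 chains, 3,000 burn-in sweeps, 2,000 retained
draws, thinning 1 — deliberately smaller than the reference protocol of
2 chains x 50,000 samples (burn-in 40,000, thinning 5), which remains
available via `paper_budget()`. Convergence is monitored by split-chain
R-hat on every group-level and individual-level parameter: below 1.01 is
clean, 1.01-1.05 produces a warning, at or above 1.05 the fit is flagged
as non-converged (never silently). Inference uses posterior means and
95% highest-density intervals.

## Model comparison and checks

DIC is computed focused on the individual-level parameters:
`Dbar` is the posterior mean deviance of the trial likelihood given
individual parameters, `pD = Dbar - D(posterior mean of the individual
parameters)`, `DIC = Dbar + pD`. The alternative group-focused deviance
would require integrating out individual parameters; the individual
focus matches how these models are compared in practice and is what the
implementation reports.

Posterior-predictive checks simulate every observed trial from the
individual posterior means and compare signed-RT distributions (negative
RT = low-effort choice) via the two-sample KS distance, plus the
high-effort choice fraction.

## RT trimming

`trim_rts` removes each participant's 5% fastest and 5% slowest trials
(pooled over conditions, `floor(0.05 n)` per tail, stable sort so ties
break by trial order). It is the pipeline default for empirical data,
where it guards against contaminant RTs. The recovery analyses and the
acceptance script fit the full synthetic dataset instead: simulated
agents produce no contaminants, and deleting genuine distribution tails
while fitting an untruncated likelihood measurably biases the boundary
(about -0.13) and non-decision time (about +0.04) at study scale. This
is a property of trim-then-fit generally, not of this implementation.

## Synthetic data generator

The generator is the package's study stand-in: participants are drawn
from truncated-normal group distributions (infeasible draws rejected and
redrawn), and each agent interacts with the staircase — the drift is
recomputed from the current offer before every trial, so choices feed
back into the offers exactly as in the task. The default population
(`reference_population()`) places the group means at the reference fitted
values — a = 2.09, z = 0.52, t0 = 0.66 s, beta_reward = 0.22/euro,
beta_effort = 0.12/level — with a +0.03 theta offset on the bias, all
other condition offsets 0, and between-subject SDs at 10% of each mean
(offsets with zero mean get SD 0). These are the study conditions every
recovery test runs under.

The 2-back generator is deliberately simple plumbing: 40 trials per
condition with a 30% target rate, hit probability 0.85, false-alarm
probability 0.08, lognormal hit RTs (median 550 ms, log-SD 0.25), no
condition effect by default (the working-memory null); all configurable.
d' is computed as the difference of normal quantiles of hit and
false-alarm rates with the 1/(2N) extreme-rate correction.

What the generator does **not** emulate: sequential effects and
learning, RT contaminants and lapses, within-condition parameter drift,
discomfort/flicker covariates, or any electrophysiology. Passing
recovery tests therefore demonstrates that the estimation machinery is
correct and calibrated under the model's own assumptions — not that the
model is true of human data.

## Scale choices and known limitations

Statistical checks run at sizes chosen to keep a full suite in the tens
of minutes on one core: recovery at 20 participants x 180 trials with
the default reduced budget; DIC model selection at 6 participants across
5 replicates; density/simulator calibration at 10^4-10^5 draws. At
these scales the group-mean posterior SDs are close to the reference
study's published standard errors, so tolerances are meaningful.

Known limitations:

* The theta bias offset is weakly identified at study scale: its
  realization noise across simulated datasets is of order 0.01 around
  the generating 0.03, so single-dataset recoveries scatter accordingly
  (the likelihood-profile check in the test suite documents this).
* Group SDs generated at or near zero sit against the prior boundary;
  their posteriors (and R-hats) are the slowest-moving quantities, and
  short budgets may flag them even when group means are stable.
* DIC conditions on point estimates and is reported with its usual
  caveats; no WAIC/LOO is provided.
* The Euler simulator is the only trial-level data source; its
  discretization bias, while small, is inherited by every synthetic
  dataset.
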