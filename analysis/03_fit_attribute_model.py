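"""Fit the hierarchical attribute-comparison DDM to the simulated study
and compare the group-level posteriors against the generating values.

Uses the reduced default budget (4 chains, 3,000 burn-in sweeps, 2,000
retained draws). Writes the fit summary to results/fit_attribute.json.
Run 01_simulate_study.py first.
"""

import time
from pathlib import Path

from effort_ddm import io
from effort_ddm.hierarchical import McmcConfig, fit_hierarchical

SEED = 22
DATA = Path(__file__).resolve().parents[1] / "scratch" / "study"
ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    ROOT.mkdir(exist_ok=True)
    trials = io.read_trial_table(DATA / "trials.tsv")
    truth = io.read_ground_truth(DATA / "ground_truth.json")

    t0 = time.time()
    fit = fit_hierarchical(trials, "attribute", McmcConfig(seed=SEED))
    print(f"fit {len(trials)} trials in {time.time() - t0:.0f} s; "
          f"max split R-hat {fit.max_rhat:.3f} "
          f"({'converged' if fit.converged else 'NOT converged'})")
    io.write_json(io.fit_summary_dict(fit), ROOT / "fit_attribute.json")

    print(f"{'parameter':24s} {'generating':>10s} {'posterior':>10s} {'95% HDI':>20s}")
    for name in ("mu_a", "mu_z", "mu_t0", "mu_beta_reward", "mu_beta_effort", "mu_z_theta"):
        gen = truth.population.means.get(name[3:], 0.0)
        row = fit.summary.loc[name]
        print(f"{name:24s} {gen:10.3f} {row['mean']:10.3f} "
              f"[{row['hdi_lower']:8.3f}, {row['hdi_upper']:8.3f}]")
    print(f"DIC {fit.dic:.1f} (Dbar {fit.dbar:.1f}, pD {fit.pd_eff:.1f})")


if __name__ == "__main__":
    main()
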