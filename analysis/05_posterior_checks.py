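"""Posterior-predictive check of the attribute-model fit.

Simulates choices and RTs from the individual posterior means over the
observed design and compares signed-RT distributions (negative = low
effort choice) against the data: KS distance, choice fractions, and an
overlay figure written to scratch/ (binary output stays out of
results/). Run 01 and 03 first.
"""

import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from effort_ddm import io
from effort_ddm.hierarchical import McmcConfig, fit_hierarchical, posterior_predictive
from effort_ddm.pipeline import ppc_statistics

SEED = 24
DATA = Path(__file__).resolve().parents[1] / "scratch" / "study"
ROOT = Path(__file__).resolve().parents[1] / "results"
SCRATCH = Path(__file__).resolve().parents[1] / "scratch"


def main() -> None:
    trials = io.read_trial_table(DATA / "trials.tsv")
    # refit (draws are not persisted to disk); same budget as 03
    fit = fit_hierarchical(trials, "attribute", McmcConfig(seed=22))
    sim = posterior_predictive(fit, trials, seed=SEED)
    ppc = ppc_statistics(trials, sim)
    io.write_json(ppc, ROOT / "ppc.json")
    print(json.dumps(ppc, indent=2))

    SCRATCH.mkdir(exist_ok=True)
    obs = np.where(trials["choice"] == "high", trials["rt_s"], -trials["rt_s"])
    bins = np.linspace(-8, 8, 81)
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.hist(obs, bins=bins, density=True, color="0.7", label="generated data")
    ax.hist(sim["signed_rt"], bins=bins, density=True, histtype="step",
            color="k", lw=1.5, label="posterior predictive")
    ax.set_xlabel("signed RT (s; negative = low-effort choice)")
    ax.set_ylabel("density")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(SCRATCH / "ppc_overlay.png", dpi=150)
    print(f"overlay figure: {SCRATCH / 'ppc_overlay.png'}")


if __name__ == "__main__":
    main()
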