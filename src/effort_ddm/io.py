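"""Delimited-table and JSON I/O for trial data, ground truth and fits.

All on-disk formats are plain text: tab-separated tables for trials,
2-back records and subjective values; JSON for ground truth sidecars,
fit summaries and pipeline reports.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import GroundTruth, PopulationParams

__all__ = [
    "TRIAL_COLUMNS",
    "read_trial_table",
    "write_trial_table",
    "read_nback_table",
    "write_nback_table",
    "write_ground_truth",
    "read_ground_truth",
    "fit_summary_dict",
    "write_json",
]

TRIAL_COLUMNS = [
    "participant_id",
    "condition",
    "miniblock",
    "trial_in_series",
    "low_effort",
    "high_effort",
    "low_reward",
    "high_reward",
    "choice",
    "rt_s",
]


def write_trial_table(trials: pd.DataFrame, path) -> None:
    missing = set(TRIAL_COLUMNS) - set(trials.columns)
    if missing:
        raise ValueError(f"trial table lacks columns: {sorted(missing)}")
    trials.to_csv(path, sep="\t", index=False)


def read_trial_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trial table lacks columns: {sorted(missing)}")
    return df


def write_nback_table(nback: pd.DataFrame, path) -> None:
    nback.to_csv(path, sep="\t", index=False)


def read_nback_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_ground_truth(truth: GroundTruth, path) -> None:
    payload = {
        "model": truth.population.model,
        "means": truth.population.means,
        "sds": truth.population.sds,
        "seed": truth.seed,
        "participant_columns": list(truth.participants.columns),
        "participants": truth.participants.to_dict(orient="list"),
    }
    write_json(payload, path)


def read_ground_truth(path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    pop = PopulationParams(
        model=payload["model"], means=payload["means"], sds=payload["sds"]
    )
    participants = pd.DataFrame(payload["participants"])
    if "participant_columns" in payload:
        participants = participants[payload["participant_columns"]]
    return GroundTruth(population=pop, participants=participants, seed=payload["seed"])


def fit_summary_dict(fit) -> dict:
    """JSON-ready summary of a hierarchical fit: posterior means, HDIs,
    R-hat per group parameter, DIC decomposition and sampler metadata."""
    return {
        "model": fit.model,
        "parameters": {
            name: {k: _scrub(v) for k, v in row.items()}
            for name, row in fit.summary.to_dict(orient="index").items()
        },
        "max_rhat": _scrub(fit.max_rhat),
        "converged": bool(fit.converged),
        "warnings": list(fit.warnings),
        "dic": _scrub(fit.dic),
        "dbar": _scrub(fit.dbar),
        "pd": _scrub(fit.pd_eff),
        "mcmc": {
            "n_chains": fit.draws.n_chains,
            "n_draws": fit.draws.n_draws,
            "burn_in": fit.draws.burn_in,
            "thinning": fit.draws.thinning,
            "seed": fit.draws.seed,
        },
        "n_trials": int(len(fit.trials)),
        "n_participants": len(fit.draws.participant_ids),
    }


def _scrub(v):
    if isinstance(v, (np.floating, float)):
        v = float(v)
        return v if np.isfinite(v) else None
    if isinstance(v, np.integer):
        return int(v)
    return v


def write_json(payload: dict, path) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
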