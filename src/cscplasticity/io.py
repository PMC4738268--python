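"""Delimited-text readers and writers for the pipeline artifacts."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .gridfit import FitData, FitResult
from .model import ModelParameters, Trajectory
from .ssa import EnsembleResult

__all__ = [
    "write_trajectory",
    "read_trajectory",
    "write_ensemble",
    "write_fit_result",
    "write_params",
    "read_params",
]


def write_trajectory(traj: Trajectory, path) -> None:
    """Write a trajectory as CSV with header ``t,S,D,f``."""
    traj.to_frame().to_csv(path, index=False)


def read_trajectory(path) -> Trajectory:
    df = pd.read_csv(path)
    return Trajectory(df["t"].to_numpy(), df["S"].to_numpy(), df["D"].to_numpy())


def write_ensemble(ens: EnsembleResult, summary_path, finals_path=None) -> None:
    """Write grid summaries (`t,mean_S,mean_D,mean_f,var_S,var_D`) and finals."""
    ens.to_frame().to_csv(summary_path, index=False)
    if finals_path is not None:
        finals = ens.finals.copy()
        finals.insert(1, "seed", [f"{ens.master_seed}:{r}" for r in finals["run"]])
        finals.to_csv(finals_path, index=False)


def write_fit_result(res: FitResult, accepted_path, summary_path) -> None:
    """Serialise a grid-fit result: accepted-sets table + summary block."""
    res.accepted.to_csv(accepted_path, index=False)
    summary: dict = {
        "success": bool(res.success),
        "tolerance": float(res.tolerance),
        "n_grid": int(res.n_grid),
        "n_accepted": int(len(res.accepted)),
        "min_loss": float(res.min_loss),
        "means": res.means,
        "sds": res.sds,
    }
    for extra in ("k_DS_early_mean", "k_DS_late_mean", "ratio_late_early", "switch_day"):
        if hasattr(res, extra):
            summary[extra] = float(getattr(res, extra))
    Path(summary_path).write_text(yaml.safe_dump(summary, sort_keys=False))


def write_params(params: ModelParameters, path) -> None:
    Path(path).write_text(yaml.safe_dump(params.as_dict(), sort_keys=False))


def read_params(path) -> ModelParameters:
    return ModelParameters.from_dict(yaml.safe_load(Path(path).read_text()))
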