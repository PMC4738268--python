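"""End-to-end orchestration: synth -> simulate -> mammosphere -> fit -> overlap.

The pipeline is a plain function over a :class:`RunConfig`; the CLI is a
thin wrapper.  Every produced file is recorded in a manifest (path,
stage, seed, sha256) and every stochastic stage derives its seed from
the master seed, so re-running an identical config reproduces identical
outputs byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import io as pio
from .gridfit import FitData, GridSpec, brute_force_search, fit_two_phase_dedifferentiation
from .mammosphere import compare_conditions, simulate_mammosphere_rate
from .model import PopulationState, solve_deterministic
from .signatures import derive_signature, overlap_report
from .ssa import SSAConfig, simulate_ensemble
from .synth import (
    Scenario,
    SyntheticExpressionSpec,
    generate_expression,
    generate_mammosphere_counts,
    generate_timecourse,
    load_scenario,
)

log = logging.getLogger("cscplasticity")

STAGES = ("synth", "simulate", "mammosphere", "fit", "overlap")


@dataclass
class RunConfig:
    """Pipeline configuration (see ``RunConfig.from_yaml``)."""

    outdir: Path
    seed: int = 0
    scenarios: tuple[str, ...] = ("normoxia", "hypoxia")
    stages: tuple[str, ...] = STAGES
    wells: int = 96
    n_runs_ensemble: int = 100
    ensemble_init: int = 50
    fit: dict = field(default_factory=dict)
    expression: dict = field(default_factory=dict)
    alpha: float = 0.05

    def __post_init__(self):
        self.outdir = Path(self.outdir)
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(
            outdir=raw.get("outdir", "pipeline_out"),
            seed=int(raw.get("seed", 0)),
            scenarios=tuple(raw.get("scenarios", ("normoxia", "hypoxia"))),
            stages=tuple(raw.get("stages", STAGES)),
            wells=int(raw.get("wells", 96)),
            n_runs_ensemble=int(raw.get("n_runs_ensemble", 100)),
            ensemble_init=int(raw.get("ensemble_init", 50)),
            fit=raw.get("fit", {}) or {},
            expression=raw.get("expression", {}) or {},
            alpha=float(raw.get("alpha", 0.05)),
        )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class _Manifest:
    def __init__(self, outdir: Path, seed: int):
        self.outdir = outdir
        self.seed = seed
        self.entries: list[dict] = []

    def add(self, path: Path, stage: str) -> None:
        self.entries.append(
            {
                "path": str(path.relative_to(self.outdir)),
                "stage": stage,
                "seed": self.seed,
                "sha256": _sha256(path),
            }
        )

    def write(self) -> Path:
        path = self.outdir / "manifest.json"
        path.write_text(json.dumps({"seed": self.seed, "artifacts": self.entries}, indent=2))
        return path


def _default_fit_grid(cfg_fit: dict, scn: Scenario, two_phase: bool) -> GridSpec:
    axes = cfg_fit.get("axes")
    switch_day = float(cfg_fit.get("switch_day", 3.0))
    if axes:
        return GridSpec(axes=axes, fixed=cfg_fit.get("fixed", {}), switch_day=switch_day)
    p = scn.params
    k_axis = [0.0005, 0.001, 0.002, 0.004, 0.008]
    k_axis_late = [0.005, 0.01, 0.02, 0.04, 0.08]
    fixed = {
        "alpha_S": p.alpha_S,
        "delta_S": p.delta_S,
        "alpha_D": p.alpha_D,
        "delta_D": p.delta_D,
    }
    if two_phase:
        axes = {"k_SD": [0.05, 0.1, 0.2], "k_DS_early": k_axis, "k_DS_late": k_axis_late}
    else:
        axes = {"k_SD": [0.05, 0.1, 0.2], "k_DS": k_axis}
    return GridSpec(axes=axes, fixed=fixed, switch_day=switch_day)


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute the requested stages in dependency order; return manifest path."""
    out = cfg.outdir
    out.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(out, cfg.seed)
    scenarios = {name: load_scenario(name, seed=cfg.seed) for name in cfg.scenarios}
    timecourses: dict[str, FitData] = {}
    sphere_counts: dict[str, tuple[int, int]] = {}

    if "synth" in cfg.stages:
        for name, scn in scenarios.items():
            log.info("[synth] %s: time course and mammosphere counts", name)
            data = generate_timecourse(scn)
            path = out / f"timecourse_{name}.csv"
            data.to_csv(path)
            manifest.add(path, "synth")
            timecourses[name] = data
            pos, wells = generate_mammosphere_counts(scn, cfg.wells)
            sphere_counts[name] = (pos, wells)
        counts_path = out / "mammosphere_counts.csv"
        pd.DataFrame(
            [
                {"condition": k, "positives": v[0], "wells": v[1]}
                for k, v in sphere_counts.items()
            ]
        ).to_csv(counts_path, index=False)
        manifest.add(counts_path, "synth")
        spec = SyntheticExpressionSpec(**cfg.expression)
        table, _ = generate_expression(spec, seed=cfg.seed)
        expr_path = out / "expression.tsv"
        table.to_csv(expr_path)
        manifest.add(expr_path, "synth")

    if "simulate" in cfg.stages:
        for name, scn in scenarios.items():
            log.info("[simulate] %s: ODE trajectory + SSA ensemble", name)
            init = PopulationState(t=0.0, S=0.0, D=float(scn.n_initial_negative))
            days = np.asarray(scn.observation_days, dtype=float)
            grid = np.arange(days[0], days[-1] + 1e-9, 0.1)
            traj = solve_deterministic(init, scn.params, grid)
            tpath = out / f"trajectory_{name}.csv"
            pio.write_trajectory(traj, tpath)
            manifest.add(tpath, "simulate")
            init_i = PopulationState(t=0.0, S=0, D=cfg.ensemble_init)
            ens = simulate_ensemble(
                init_i,
                scn.params,
                SSAConfig(t_end=float(days[-1]), seed=cfg.seed, record_dt=0.1),
                n_runs=cfg.n_runs_ensemble,
            )
            epath = out / f"ensemble_{name}.csv"
            fpath = out / f"ensemble_finals_{name}.csv"
            pio.write_ensemble(ens, epath, fpath)
            manifest.add(epath, "simulate")
            manifest.add(fpath, "simulate")

    if "mammosphere" in cfg.stages:
        results = {}
        for name, scn in scenarios.items():
            log.info("[mammosphere] %s", name)
            res = simulate_mammosphere_rate(scn.params, scn.mammosphere)
            results[name] = res
            rpath = out / f"mammosphere_runs_{name}.csv"
            per_run = res.per_run.copy()
            per_run.insert(1, "seed", [f"{res.seed}:{r}" for r in per_run["run"]])
            per_run.to_csv(rpath, index=False)
            manifest.add(rpath, "mammosphere")
        spath = out / "mammosphere_summary.csv"
        pd.DataFrame(
            [
                {
                    "condition": k,
                    "rate": v.rate,
                    "ci_low": v.ci_low,
                    "ci_high": v.ci_high,
                    "n_positive": v.n_positive,
                    "n_runs": v.n_runs,
                }
                for k, v in results.items()
            ]
        ).to_csv(spath, index=False)
        manifest.add(spath, "mammosphere")
        if len(scenarios) == 2:
            a, b = (scenarios[n].params for n in cfg.scenarios)
            comp = compare_conditions(a, b, scenarios[cfg.scenarios[0]].mammosphere)
            cpath = out / "mammosphere_comparison.yaml"
            cpath.write_text(
                yaml.safe_dump(
                    {
                        "condition_a": cfg.scenarios[0],
                        "condition_b": cfg.scenarios[1],
                        "rate_a": comp.result_a.rate,
                        "rate_b": comp.result_b.rate,
                        "odds_ratio": float(comp.odds_ratio),
                        "p_value": float(comp.p_value),
                    },
                    sort_keys=False,
                )
            )
            manifest.add(cpath, "mammosphere")

    if "fit" in cfg.stages:
        tolerance = float(cfg.fit.get("tolerance", 0.01))
        for name, scn in scenarios.items():
            data = timecourses.get(name)
            if data is None:
                path = out / f"timecourse_{name}.csv"
                if not path.exists():
                    raise FileNotFoundError(
                        f"fit stage needs {path}; run the synth stage first"
                    )
                data = FitData.from_csv(path, condition=name)
            two_phase = not scn.params.k_DS_constant
            grid = _default_fit_grid(cfg.fit, scn, two_phase)
            log.info("[fit] %s: %d grid points", name, grid.size)
            if two_phase:
                res = fit_two_phase_dedifferentiation(
                    grid, data, tolerance=tolerance, seed=cfg.seed
                )
            else:
                res = brute_force_search(grid, data, tolerance=tolerance, seed=cfg.seed)
            apath = out / f"fit_accepted_{name}.csv"
            ypath = out / f"fit_summary_{name}.yaml"
            pio.write_fit_result(res, apath, ypath)
            manifest.add(apath, "fit")
            manifest.add(ypath, "fit")

    if "overlap" in cfg.stages:
        expr_path = out / "expression.tsv"
        if not expr_path.exists():
            raise FileNotFoundError(
                f"overlap stage needs {expr_path}; run the synth stage first"
            )
        from .signatures import ExpressionTable

        spec = SyntheticExpressionSpec(**cfg.expression)
        table = ExpressionTable.from_csv(expr_path, reference=spec.reference)
        conds = table.conditions
        sigs = {
            (c, d): derive_signature(table, c, d) for c in conds for d in ("up", "down")
        }
        for (c, d), sig in sigs.items():
            sp = out / f"signature_{c}_{d}.txt"
            sp.write_text("\n".join(sorted(sig.probes)) + "\n")
            manifest.add(sp, "overlap")
        pairs = [
            (sigs[(c1, d)], sigs[(c2, d)])
            for i, c1 in enumerate(conds)
            for c2 in conds[i + 1 :]
            for d in ("up", "down")
        ]
        report = overlap_report(pairs, table.universe_size, alpha=cfg.alpha)
        rpath = out / "overlap_report.csv"
        report.to_csv(rpath, index=False)
        manifest.add(rpath, "overlap")

    mpath = manifest.write()
    log.info("wrote manifest with %d artifacts to %s", len(manifest.entries), mpath)
    return mpath
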