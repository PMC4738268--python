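"""Exact stochastic simulation of the two-compartment reaction network.

The six first-order channels of the deterministic model are sampled with
the direct-method Gillespie algorithm (two uniform variates per event).
The piecewise-constant dedifferentiation schedule is handled exactly:
each waiting time is capped at the next *effective* rate switch (a switch
where the rate actually changes value) and redrawn there, which is exact
for piecewise-constant propensities.  A schedule whose segments carry the
same rate therefore reproduces the constant-rate sample path for the same
seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

from .model import ModelParameters, PopulationState, Trajectory, solve_deterministic

__all__ = [
    "ReactionChannel",
    "CHANNELS",
    "SSAConfig",
    "SSATrajectory",
    "EnsembleResult",
    "propensities",
    "simulate_trajectory",
    "simulate_ensemble",
    "run_seed",
]


class ReactionChannel(NamedTuple):
    """One elementary reaction: label, state change, and rate accessor."""

    label: str
    dS: int
    dD: int


CHANNELS: tuple[ReactionChannel, ...] = (
    ReactionChannel("S_birth", +1, 0),
    ReactionChannel("S_death", -1, 0),
    ReactionChannel("S_to_D", -1, +1),
    ReactionChannel("D_birth", 0, +1),
    ReactionChannel("D_death", 0, -1),
    ReactionChannel("D_to_S", +1, -1),
)

_DS = np.array([c.dS for c in CHANNELS])
_DD = np.array([c.dD for c in CHANNELS])


def propensities(state: PopulationState, params: ModelParameters, t: float | None = None) -> np.ndarray:
    """Per-channel event rates at the given state and time.

    Order matches :data:`CHANNELS`:
    (alpha_S*S, delta_S*S, k_SD*S, alpha_D*D, delta_D*D, k_DS(t)*D).
    """
    if state.S < 0 or state.D < 0:
        raise ValueError("cell counts must be non-negative")
    tt = state.t if t is None else t
    k_ds = params.k_DS_at(tt)
    S, D = state.S, state.D
    return np.array(
        [
            params.alpha_S * S,
            params.delta_S * S,
            params.k_SD * S,
            params.alpha_D * D,
            params.delta_D * D,
            k_ds * D,
        ]
    )


@dataclass(frozen=True)
class SSAConfig:
    """Settings for a single stochastic run.

    ``record_dt`` sets the fixed output grid (last-event carry-forward);
    ``stop_above`` optionally terminates a run early once the total cell
    count reaches that ceiling (used by the mammosphere assay, where only
    the exceed-threshold indicator matters).
    """

    t_end: float
    seed: int | np.random.SeedSequence | None = None
    max_events: int = 10_000_000
    record_dt: float = 0.1
    stop_above: int | None = None

    def __post_init__(self):
        if self.t_end <= 0:
            raise ValueError("t_end must be > 0")
        if self.max_events <= 0:
            raise ValueError("max_events must be > 0")
        if self.record_dt <= 0:
            raise ValueError("record_dt must be > 0")
        if self.stop_above is not None and self.stop_above < 1:
            raise ValueError("stop_above must be >= 1")


@dataclass
class SSATrajectory:
    """One sample path recorded on a fixed grid, plus run diagnostics."""

    t: np.ndarray
    S: np.ndarray
    D: np.ndarray
    final: PopulationState
    n_events: int
    truncated: bool = False
    capped: bool = False
    seed_key: tuple = ()

    @property
    def total(self) -> np.ndarray:
        return self.S + self.D

    def fraction(self) -> np.ndarray:
        total = self.total
        with np.errstate(invalid="ignore"):
            return np.where(total > 0, self.S / np.where(total > 0, total, 1), np.nan)


def run_seed(master_seed: int, run_index: int) -> np.random.SeedSequence:
    """Per-run seed derived from a master seed by a splittable scheme."""
    return np.random.SeedSequence(entropy=master_seed, spawn_key=(run_index,))


def _record_grid(t0: float, t_end: float, dt: float) -> np.ndarray:
    n = int(math.floor((t_end - t0) / dt + 1e-9))
    grid = t0 + dt * np.arange(n + 1)
    if grid[-1] < t_end - 1e-9:
        grid = np.append(grid, t_end)
    else:
        grid[-1] = t_end
    return grid


def simulate_trajectory(
    init: PopulationState, params: ModelParameters, cfg: SSAConfig
) -> SSATrajectory:
    """Draw one exact sample path of the reaction network."""
    S = int(init.S)
    D = int(init.D)
    if S != init.S or D != init.D:
        raise ValueError("stochastic simulation requires integer initial counts")

    seed = cfg.seed
    if isinstance(seed, np.random.SeedSequence):
        seed_key = (seed.entropy, tuple(seed.spawn_key))
    else:
        seed_key = (seed,)
    rng = np.random.default_rng(seed)

    t = init.t
    t_end = cfg.t_end
    grid = _record_grid(t, t_end, cfg.record_dt)
    gS = np.empty(grid.size, dtype=np.int64)
    gD = np.empty(grid.size, dtype=np.int64)
    gi = 0

    # only switches where the rate actually changes interrupt waiting times
    boundaries = [s for s in params.switch_times() if t < s < t_end]
    bi = 0
    k_ds = params.k_DS_at(t)
    aS, dS_, kSD = params.alpha_S, params.delta_S, params.k_SD
    aD, dD_ = params.alpha_D, params.delta_D

    n_events = 0
    truncated = False
    capped = False

    while True:
        p = (aS * S, dS_ * S, kSD * S, aD * D, dD_ * D, k_ds * D)
        a0 = p[0] + p[1] + p[2] + p[3] + p[4] + p[5]
        next_cut = boundaries[bi] if bi < len(boundaries) else t_end

        if a0 == 0.0:
            t_next = next_cut  # absorbing (0,0) or frozen state: jump ahead
        else:
            u1 = rng.random()
            t_next = t - math.log(u1) / a0

        if t_next >= next_cut:
            # cap at the boundary (or the end) and redraw there
            while gi < grid.size and grid[gi] < next_cut:
                gS[gi], gD[gi] = S, D
                gi += 1
            t = next_cut
            if bi < len(boundaries):
                bi += 1
                k_ds = params.k_DS_at(t)
                continue
            break

        # fire one reaction at t_next
        u2 = rng.random() * a0
        acc = 0.0
        ch = 5
        for i in range(6):
            acc += p[i]
            if u2 < acc:
                ch = i
                break
        while gi < grid.size and grid[gi] < t_next:
            gS[gi], gD[gi] = S, D
            gi += 1
        t = t_next
        S += CHANNELS[ch].dS
        D += CHANNELS[ch].dD
        n_events += 1

        if cfg.stop_above is not None and S + D >= cfg.stop_above:
            capped = True
            break
        if n_events >= cfg.max_events:
            truncated = True
            break

    while gi < grid.size:
        gS[gi], gD[gi] = S, D
        gi += 1

    return SSATrajectory(
        t=grid,
        S=gS,
        D=gD,
        final=PopulationState(t=t_end if not (truncated or capped) else t, S=S, D=D),
        n_events=n_events,
        truncated=truncated,
        capped=capped,
        seed_key=seed_key,
    )


@dataclass
class EnsembleResult:
    """Per-grid-time ensemble summaries over repeated stochastic runs."""

    t: np.ndarray
    mean_S: np.ndarray
    mean_D: np.ndarray
    mean_f: np.ndarray
    var_S: np.ndarray
    var_D: np.ndarray
    finals: "object"  # pandas.DataFrame: run, S_final, D_final
    n_runs: int
    master_seed: int
    runs: list = field(default_factory=list, repr=False)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "t": self.t,
                "mean_S": self.mean_S,
                "mean_D": self.mean_D,
                "mean_f": self.mean_f,
                "var_S": self.var_S,
                "var_D": self.var_D,
            }
        )


def simulate_ensemble(
    init: PopulationState,
    params: ModelParameters,
    cfg: SSAConfig,
    n_runs: int,
    keep_runs: bool = False,
) -> EnsembleResult:
    """Repeat :func:`simulate_trajectory` with per-run derived seeds.

    Run ``i`` uses ``run_seed(master, i)``; rerunning with the same
    master seed reproduces the ensemble exactly.  ``mean_f`` averages the
    per-run positive fraction over runs whose population is non-extinct
    at that grid time.
    """
    import pandas as pd

    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    master = cfg.seed
    if master is None:
        master = 0
    if isinstance(master, np.random.SeedSequence):
        raise TypeError("ensemble master seed must be an integer")

    allS, allD, finals, kept = [], [], [], []
    for i in range(n_runs):
        run_cfg = SSAConfig(
            t_end=cfg.t_end,
            seed=run_seed(int(master), i),
            max_events=cfg.max_events,
            record_dt=cfg.record_dt,
            stop_above=cfg.stop_above,
        )
        traj = simulate_trajectory(init, params, run_cfg)
        allS.append(traj.S)
        allD.append(traj.D)
        finals.append((i, int(traj.final.S), int(traj.final.D)))
        if keep_runs:
            kept.append(traj)
        grid = traj.t

    Sm = np.asarray(allS, dtype=float)
    Dm = np.asarray(allD, dtype=float)
    total = Sm + Dm
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, Sm / np.where(total > 0, total, 1.0), np.nan)
    ddof = 1 if n_runs > 1 else 0
    return EnsembleResult(
        t=grid,
        mean_S=Sm.mean(axis=0),
        mean_D=Dm.mean(axis=0),
        mean_f=np.nanmean(frac, axis=0),
        var_S=Sm.var(axis=0, ddof=ddof),
        var_D=Dm.var(axis=0, ddof=ddof),
        finals=pd.DataFrame(finals, columns=["run", "S_final", "D_final"]),
        n_runs=n_runs,
        master_seed=int(master),
        runs=kept,
    )


def ensemble_vs_ode(
    init: PopulationState, params: ModelParameters, cfg: SSAConfig, n_runs: int
) -> "object":
    """Convenience table comparing ensemble means with the ODE solution."""
    import pandas as pd

    ens = simulate_ensemble(init, params, cfg, n_runs)
    det = solve_deterministic(init, params, ens.t)
    se_S = np.sqrt(ens.var_S / n_runs)
    se_D = np.sqrt(ens.var_D / n_runs)
    return pd.DataFrame(
        {
            "t": ens.t,
            "mean_S": ens.mean_S,
            "ode_S": det.S,
            "se_S": se_S,
            "mean_D": ens.mean_D,
            "ode_D": det.D,
            "se_D": se_D,
        }
    )
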