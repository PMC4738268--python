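"""Deterministic core of the two-compartment stem-cell plasticity model.

Two phenotypic compartments are tracked: stem-like, biomarker-positive
cells ``S`` (in the motivating system, GD2(+) breast cancer stem cells)
and differentiated, biomarker-negative cells ``D``.  Each compartment
self-replicates, dies, and converts into the other through first-order
channels, giving the linear system

    dS/dt = (alpha_S - delta_S) S - k_SD * S + k_DS(t) * D
    dD/dt = (alpha_D - delta_D) D - k_DS(t) * D + k_SD * S

All rates are per day and time is measured in days.  The
dedifferentiation rate ``k_DS`` — conversion of non-stem to stem cells,
the parameter through which an oxygen-poor microenvironment acts in this
model — may be a piecewise-constant schedule so that plasticity can jump
at a fixed switch day.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "ModelParameters",
    "PopulationState",
    "Trajectory",
    "ode_rhs",
    "solve_deterministic",
    "fraction_positive",
    "steady_state_fraction",
]

#: integrator undershoot below this magnitude is treated as exact zero
NEGATIVE_CLAMP = 1e-12

_RATE_FIELDS = ("alpha_S", "delta_S", "alpha_D", "delta_D", "k_SD")


def _as_schedule(k_DS) -> tuple[tuple[float, float], ...]:
    """Normalise ``k_DS`` to a tuple of (start_day, rate) segments."""
    if isinstance(k_DS, (int, float)):
        return ((0.0, float(k_DS)),)
    segs = tuple((float(s), float(r)) for s, r in k_DS)
    if not segs:
        raise ValueError("k_DS schedule must contain at least one segment")
    return segs


@dataclass(frozen=True)
class ModelParameters:
    """First-order rates of the two-compartment model (per day).

    Parameters
    ----------
    alpha_S, delta_S
        Division and death rate of stem-like (biomarker-positive) cells.
    alpha_D, delta_D
        Division and death rate of differentiated (negative) cells.
    k_SD
        Differentiation rate, S -> D.
    k_DS
        Dedifferentiation rate, D -> S.  A plain float encodes a constant
        rate; a sequence of ``(start_day, rate)`` pairs encodes a
        piecewise-constant schedule whose start times strictly increase
        and begin at day 0.
    """

    alpha_S: float
    delta_S: float
    alpha_D: float
    delta_D: float
    k_SD: float
    k_DS: tuple[tuple[float, float], ...] = ((0.0, 0.0),)

    def __post_init__(self):
        object.__setattr__(self, "k_DS", _as_schedule(self.k_DS))
        for name in _RATE_FIELDS:
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")
        starts = [s for s, _ in self.k_DS]
        rates = [r for _, r in self.k_DS]
        if starts[0] != 0.0:
            raise ValueError("k_DS schedule must begin at day 0")
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise ValueError("k_DS segment start times must strictly increase")
        if any(not math.isfinite(r) or r < 0 for r in rates):
            raise ValueError("k_DS rates must be finite and >= 0")

    # -- schedule helpers -------------------------------------------------
    @property
    def k_DS_constant(self) -> bool:
        return len(self.k_DS) == 1

    def k_DS_at(self, t: float) -> float:
        """Dedifferentiation rate in effect at time ``t`` (days)."""
        if t < 0:
            raise ValueError("t must be >= 0")
        rate = self.k_DS[0][1]
        for start, r in self.k_DS:
            if t >= start:
                rate = r
            else:
                break
        return rate

    def switch_times(self) -> tuple[float, ...]:
        """Times at which the dedifferentiation rate actually changes."""
        out = []
        prev = self.k_DS[0][1]
        for start, r in self.k_DS[1:]:
            if r != prev:
                out.append(start)
            prev = r
        return tuple(out)

    def with_k_DS(self, k_DS) -> "ModelParameters":
        return replace(self, k_DS=_as_schedule(k_DS))

    def net_growth(self) -> tuple[float, float]:
        """Net growth rates (alpha - delta) of the S and D compartments."""
        return (self.alpha_S - self.delta_S, self.alpha_D - self.delta_D)

    def as_dict(self) -> dict:
        d = {name: getattr(self, name) for name in _RATE_FIELDS}
        d["k_DS"] = [list(seg) for seg in self.k_DS]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParameters":
        return cls(**d)


@dataclass(frozen=True)
class PopulationState:
    """Cell counts of both compartments at a time point (days)."""

    t: float
    S: float
    D: float

    def __post_init__(self):
        if self.t < 0 or not math.isfinite(self.t):
            raise ValueError("t must be finite and >= 0")
        if self.S < 0 or self.D < 0:
            raise ValueError("cell counts must be non-negative")
        if not (math.isfinite(self.S) and math.isfinite(self.D)):
            raise ValueError("cell counts must be finite")

    @property
    def total(self) -> float:
        return self.S + self.D


@dataclass
class Trajectory:
    """Compartment counts sampled at strictly increasing output times."""

    t: np.ndarray
    S: np.ndarray
    D: np.ndarray
    params: ModelParameters | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.S = np.asarray(self.S, dtype=float)
        self.D = np.asarray(self.D, dtype=float)
        if not (self.t.shape == self.S.shape == self.D.shape):
            raise ValueError("t, S, D must have identical shapes")
        if self.t.size and np.any(np.diff(self.t) <= 0):
            raise ValueError("trajectory times must strictly increase")

    @property
    def total(self) -> np.ndarray:
        return self.S + self.D

    def fraction(self) -> np.ndarray:
        return fraction_positive(self)

    def state_at(self, i: int) -> PopulationState:
        return PopulationState(float(self.t[i]), float(self.S[i]), float(self.D[i]))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"t": self.t, "S": self.S, "D": self.D, "f": self.fraction()}
        )


def ode_rhs(state: PopulationState, params: ModelParameters) -> tuple[float, float]:
    """Time derivatives (dS/dt, dD/dt) of the two-compartment system."""
    k_ds = params.k_DS_at(state.t)
    dS = (params.alpha_S - params.delta_S) * state.S - params.k_SD * state.S + k_ds * state.D
    dD = (params.alpha_D - params.delta_D) * state.D - k_ds * state.D + params.k_SD * state.S
    return (dS, dD)


def _rate_matrix(params: ModelParameters, k_ds: float) -> np.ndarray:
    gS, gD = params.net_growth()
    return np.array(
        [[gS - params.k_SD, k_ds], [params.k_SD, gD - k_ds]], dtype=float
    )


def _segment_spans(params: ModelParameters, t0: float, t1: float):
    """Yield (start, end, k_DS) spans covering [t0, t1], split at switches."""
    cuts = [s for s in params.switch_times() if t0 < s < t1]
    edges = [t0, *cuts, t1]
    for a, b in zip(edges, edges[1:]):
        yield a, b, params.k_DS_at(a)


def solve_deterministic(
    init: PopulationState,
    params: ModelParameters,
    output_times: Sequence[float],
    rtol: float = 3e-14,
    atol: float = 1e-30,
) -> Trajectory:
    """Integrate the rate equations at requested output times.

    Uses an adaptive high-order integrator (DOP853; the system is linear
    with eigenvalues on the order of the rates, so it is never stiff)
    with hard breakpoints wherever the piecewise dedifferentiation
    schedule switches, so no step straddles a rate discontinuity.  The
    default tolerances keep the solution within ~1e-11 relative error of
    the exact matrix-exponential solution even over 20 days of
    exponential growth.  The first output time must equal ``init.t``;
    the returned trajectory starts at the initial condition exactly.
    """
    times = np.asarray(output_times, dtype=float)
    if times.ndim != 1 or times.size < 1:
        raise ValueError("output_times must be a non-empty 1-D sequence")
    if np.any(np.diff(times) <= 0):
        raise ValueError("output_times must strictly increase")
    if not math.isclose(times[0], init.t, rel_tol=0.0, abs_tol=1e-12):
        raise ValueError("output_times must start at the initial time")

    S = np.empty_like(times)
    D = np.empty_like(times)
    S[0], D[0] = init.S, init.D
    if times.size > 1:
        y = np.array([init.S, init.D], dtype=float)
        filled = 1
        for a, b, k_ds in _segment_spans(params, float(times[0]), float(times[-1])):
            A = _rate_matrix(params, k_ds)
            inside = times[(times > a) & (times <= b)]
            t_eval = np.unique(np.concatenate([inside, [b]]))
            sol = solve_ivp(
                lambda t, y, A=A: A @ y,
                (a, b),
                y,
                method="DOP853",
                t_eval=t_eval,
                rtol=rtol,
                atol=atol,
            )
            if not sol.success:  # pragma: no cover - LSODA on linear systems
                raise RuntimeError(f"integration failed: {sol.message}")
            n_req = inside.size
            if n_req:
                idx = np.searchsorted(sol.t, inside)
                S[filled : filled + n_req] = sol.y[0, idx]
                D[filled : filled + n_req] = sol.y[1, idx]
                filled += n_req
            y = sol.y[:, -1].copy()

    for arr, name in ((S, "S"), (D, "D")):
        neg = arr < 0
        if np.any(neg):
            worst = arr[neg].min()
            if worst < -NEGATIVE_CLAMP:
                raise RuntimeError(
                    f"integrator produced {name}={worst!r} below the clamp threshold"
                )
            arr[neg] = 0.0

    return Trajectory(
        times,
        S,
        D,
        params=params,
        meta={"solver": "DOP853", "rtol": rtol, "atol": atol},
    )


def fraction_positive(traj: Trajectory) -> np.ndarray:
    """Biomarker-positive fraction f = S/(S+D) along a trajectory.

    Extinct time points (S+D == 0) yield NaN and a warning rather than a
    silent division error.
    """
    total = traj.total
    extinct = total == 0
    if np.any(extinct):
        warnings.warn(
            "population extinct at some output times; fraction set to NaN",
            RuntimeWarning,
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(extinct, np.nan, traj.S / np.where(extinct, 1.0, total))
    return f


def steady_state_fraction(params: ModelParameters) -> float:
    """Equilibrium biomarker-positive fraction f* of the fraction ODE.

    With constant dedifferentiation rate the fraction obeys the Riccati
    equation f' = k_DS (1-f) - k_SD f + dg f(1-f), where
    dg = (alpha_S - delta_S) - (alpha_D - delta_D).  f* is the stable
    root in [0, 1] of dg f^2 + (k_SD + k_DS - dg) f - k_DS = 0; when
    dg == 0 this reduces to f* = k_DS / (k_SD + k_DS).
    """
    if not params.k_DS_constant:
        raise ValueError(
            "steady_state_fraction requires a constant (single-segment) k_DS; "
            "pass the per-regime rate explicitly"
        )
    k_ds = params.k_DS[0][1]
    k_sd = params.k_SD
    gS, gD = params.net_growth()
    dg = gS - gD
    if dg == 0.0:
        if k_sd + k_ds == 0.0:
            raise ValueError("degenerate parameters: no interconversion and dg == 0")
        return k_ds / (k_sd + k_ds)
    # g(f) = dg f^2 + (k_sd + k_ds - dg) f - k_ds; f' = -g(f); stable where g' > 0
    b = k_sd + k_ds - dg
    disc = b * b + 4.0 * dg * k_ds
    sq = math.sqrt(max(disc, 0.0))
    candidates = [(-b + sq) / (2.0 * dg), (-b - sq) / (2.0 * dg)]
    eps = 1e-12
    in_unit = [f for f in candidates if -eps <= f <= 1.0 + eps]
    if not in_unit:  # pragma: no cover - excluded by g(0)<=0<=g(1)
        raise RuntimeError("no equilibrium fraction in [0, 1]")
    stable = [f for f in in_unit if 2.0 * dg * f + b >= 0.0]
    f_star = (stable or in_unit)[0]
    return min(max(f_star, 0.0), 1.0)
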