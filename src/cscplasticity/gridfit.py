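"""Brute-force grid-search estimation of the interconversion rates.

Every point of a Cartesian parameter grid is evaluated against the data;
all points whose loss falls within a tolerance are accepted, and the
estimate is the per-parameter mean (with SD) over the accepted set —
no single best point is selected.  The loss is the Chebyshev (max-abs)
residual over the observed biomarker-positive fractions, optionally
combined (again by max) with the absolute mammosphere-rate residual
simulated under common random numbers so the search is deterministic.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .mammosphere import MammosphereProtocol, simulate_mammosphere_rate
from .model import ModelParameters, PopulationState, fraction_positive, solve_deterministic

__all__ = [
    "GridSpec",
    "FitData",
    "FitResult",
    "TwoPhaseFitResult",
    "loss",
    "brute_force_search",
    "fit_two_phase_dedifferentiation",
    "default_grid",
]

_PARAM_AXES = (
    "alpha_S",
    "delta_S",
    "alpha_D",
    "delta_D",
    "k_SD",
    "k_DS",
    "k_DS_early",
    "k_DS_late",
)


@dataclass(frozen=True)
class GridSpec:
    """Cartesian search space over the model rates.

    ``axes`` maps parameter names to sorted candidate lists; ``fixed``
    pins the remaining rates.  The dedifferentiation rate is searched
    either as a single ``k_DS`` axis (constant rate) or as the pair
    ``k_DS_early``/``k_DS_late`` with the change at ``switch_day``.
    """

    axes: Mapping[str, Sequence[float]]
    fixed: Mapping[str, float] = field(default_factory=dict)
    switch_day: float = 3.0

    def __post_init__(self):
        names = set(self.axes) | set(self.fixed)
        unknown = names - set(_PARAM_AXES)
        if unknown:
            raise ValueError(f"unknown parameter axes: {sorted(unknown)}")
        overlap = set(self.axes) & set(self.fixed)
        if overlap:
            raise ValueError(f"parameters both searched and fixed: {sorted(overlap)}")
        two_phase = {"k_DS_early", "k_DS_late"} & names
        if two_phase and "k_DS" in names:
            raise ValueError("specify either k_DS or k_DS_early/k_DS_late, not both")
        if len(two_phase) == 1:
            raise ValueError("k_DS_early and k_DS_late must both be given")
        if not two_phase and "k_DS" not in names:
            raise ValueError("a dedifferentiation axis (k_DS or early/late) is required")
        missing = {"alpha_S", "delta_S", "alpha_D", "delta_D", "k_SD"} - names
        if missing:
            raise ValueError(f"rates neither searched nor fixed: {sorted(missing)}")
        for name, values in self.axes.items():
            v = list(values)
            if not v:
                raise ValueError(f"axis {name} is empty")
            if any(x < 0 or not math.isfinite(x) for x in v):
                raise ValueError(f"axis {name} must be non-negative and finite")
            if v != sorted(v):
                raise ValueError(f"axis {name} must be sorted ascending")

    @property
    def two_phase(self) -> bool:
        return "k_DS_early" in self.axes or "k_DS_early" in self.fixed

    @property
    def axis_names(self) -> tuple[str, ...]:
        return tuple(self.axes)

    @property
    def size(self) -> int:
        n = 1
        for values in self.axes.values():
            n *= len(values)
        return n

    def points(self):
        """Yield (value-dict, ModelParameters) for every grid point."""
        names = self.axis_names
        for combo in itertools.product(*(self.axes[n] for n in names)):
            values = dict(self.fixed)
            values.update(zip(names, combo))
            yield dict(zip(names, combo)), self._to_params(values)

    def _to_params(self, values: Mapping[str, float]) -> ModelParameters:
        base = {
            k: values[k] for k in ("alpha_S", "delta_S", "alpha_D", "delta_D", "k_SD")
        }
        if "k_DS" in values:
            k_ds = values["k_DS"]
        else:
            k_ds = [
                [0.0, values["k_DS_early"]],
                [self.switch_day, values["k_DS_late"]],
            ]
        return ModelParameters(k_DS=k_ds, **base)


def default_grid(switch_day: float = 3.0, two_phase: bool = True) -> GridSpec:
    """Biologically plausible logarithmic default grid.

    Interconversion rates span 1e-4 to 1 per day; division rates span
    0.1 to 1.5 per day; death rates are pinned at 0.1 per day.
    """
    switching = list(np.geomspace(1e-4, 1.0, 9).round(12))
    division = list(np.geomspace(0.1, 1.5, 5).round(12))
    axes: dict[str, Sequence[float]] = {
        "alpha_S": division,
        "alpha_D": division,
        "k_SD": switching,
    }
    if two_phase:
        axes["k_DS_early"] = switching
        axes["k_DS_late"] = switching
    else:
        axes["k_DS"] = switching
    return GridSpec(axes=axes, fixed={"delta_S": 0.1, "delta_D": 0.1}, switch_day=switch_day)


@dataclass
class FitData:
    """Observations the grid search fits.

    ``fractions`` holds the biomarker-positive fraction time series
    (columns ``time``, ``fraction`` and the FACS events-per-timepoint
    column ``n``); ``mammosphere`` optionally holds observed sphere
    counts as ``(positives, wells)``.
    """

    fractions: pd.DataFrame
    mammosphere: tuple[int, int] | None = None
    condition: str = ""

    def __post_init__(self):
        required = {"time", "fraction"}
        if not required <= set(self.fractions.columns):
            raise ValueError("fractions table needs 'time' and 'fraction' columns")
        f = self.fractions["fraction"].to_numpy()
        if np.any((f < 0) | (f > 1)):
            raise ValueError("fractions must lie in [0, 1]")
        if np.any(self.fractions["time"].to_numpy() < 0):
            raise ValueError("times must be >= 0")
        if self.mammosphere is not None:
            pos, wells = self.mammosphere
            if not (0 <= pos <= wells):
                raise ValueError("mammosphere counts need 0 <= positives <= wells")

    @classmethod
    def from_csv(cls, path, mammosphere=None, condition="") -> "FitData":
        return cls(pd.read_csv(path), mammosphere=mammosphere, condition=condition)

    def to_csv(self, path) -> None:
        self.fractions.to_csv(path, index=False)


def _model_fractions(params: ModelParameters, times: np.ndarray) -> np.ndarray:
    """Deterministic positive fraction at observation times, S0 = 0.

    The system is linear, so the fraction is independent of the initial
    population size; one biomarker-negative unit is used.
    """
    t = np.asarray(times, dtype=float)
    order = np.argsort(t)
    uniq, inv = np.unique(t[order], return_inverse=True)
    if uniq[0] > 0:
        solve_times = np.concatenate([[0.0], uniq])
        offset = 1
    else:
        solve_times = uniq
        offset = 0
    init = PopulationState(t=0.0, S=0.0, D=1.0)
    # fractions are compared at ~1e-2 tolerances; a looser integrator
    # setting keeps the grid sweep fast without touching the acceptance
    traj = solve_deterministic(init, params, solve_times, rtol=1e-10, atol=1e-14)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        f = fraction_positive(traj)
    out = np.empty_like(t)
    out[order] = f[offset:][inv]
    return out


def loss(
    params: ModelParameters,
    data: FitData,
    proto: MammosphereProtocol | None = None,
    seed: int = 0,
    norm: str = "max",
) -> float:
    """Scalar misfit of a parameter set against the observations.

    ``norm='max'`` (default) is the Chebyshev residual: the maximum
    absolute deviation over fraction observations, combined by max with
    the mammosphere-rate residual when a protocol and sphere counts are
    supplied.  ``norm='sse'`` sums squared residuals instead.  The
    mammosphere term reuses ``seed`` for every call (common random
    numbers), making the loss deterministic.
    """
    if norm not in ("max", "sse"):
        raise ValueError("norm must be 'max' or 'sse'")
    times = data.fractions["time"].to_numpy(dtype=float)
    obs = data.fractions["fraction"].to_numpy(dtype=float)
    try:
        model = _model_fractions(params, times)
    except (RuntimeError, OverflowError):
        return math.inf
    if not np.all(np.isfinite(model)):
        return math.inf
    res = np.abs(model - obs)

    sphere_res = None
    if proto is not None and data.mammosphere is not None:
        pos, wells = data.mammosphere
        proto_cr = MammosphereProtocol(
            n_initial_negative=proto.n_initial_negative,
            t_end=proto.t_end,
            threshold=proto.threshold,
            n_runs=proto.n_runs,
            seed=seed,
            ceiling=proto.ceiling,
            max_events=proto.max_events,
        )
        rate = simulate_mammosphere_rate(params, proto_cr).rate
        sphere_res = abs(rate - pos / wells)

    if norm == "max":
        value = float(res.max()) if res.size else 0.0
        if sphere_res is not None:
            value = max(value, sphere_res)
    else:
        value = float(np.sum(res**2))
        if sphere_res is not None:
            value += sphere_res**2
    return value


@dataclass
class FitResult:
    """Accepted parameter sets and their mean/SD summary."""

    accepted: pd.DataFrame  # one row per accepted grid point (+ loss column)
    means: dict | None
    sds: dict | None
    tolerance: float
    n_grid: int
    min_loss: float
    success: bool

    def summary(self) -> str:
        if not self.success:
            return (
                f"no fit within tolerance {self.tolerance:g} "
                f"({self.n_grid} grid points; minimum loss {self.min_loss:.4g})"
            )
        lines = [
            f"accepted {len(self.accepted)}/{self.n_grid} grid points "
            f"at tolerance {self.tolerance:g}"
        ]
        for name, m in self.means.items():
            lines.append(f"  {name}: {m:.6g} +/- {self.sds[name]:.3g}")
        return "\n".join(lines)


def brute_force_search(
    grid: GridSpec,
    data: FitData,
    tolerance: float,
    proto: MammosphereProtocol | None = None,
    seed: int = 0,
    norm: str = "max",
) -> FitResult:
    """Exhaustively evaluate the grid and accept all points within tolerance.

    Every point is visited; the result is independent of enumeration
    order.  An empty accepted set is returned as an explicit failure
    carrying the minimum loss encountered.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be > 0")
    rows = []
    min_loss = math.inf
    for values, params in grid.points():
        value = loss(params, data, proto=proto, seed=seed, norm=norm)
        min_loss = min(min_loss, value)
        if value <= tolerance:
            rows.append({**values, "loss": value})
    axis_cols = list(grid.axis_names)
    accepted = pd.DataFrame(rows, columns=axis_cols + ["loss"])
    if rows:
        means = {c: float(accepted[c].mean()) for c in axis_cols}
        sds = {c: float(accepted[c].std(ddof=0)) for c in axis_cols}
        success = True
    else:
        means = sds = None
        success = False
    return FitResult(
        accepted=accepted,
        means=means,
        sds=sds,
        tolerance=tolerance,
        n_grid=grid.size,
        min_loss=min_loss,
        success=success,
    )


@dataclass
class TwoPhaseFitResult(FitResult):
    """Grid-fit result with early/late dedifferentiation summaries."""

    k_DS_early_mean: float = math.nan
    k_DS_late_mean: float = math.nan
    ratio_late_early: float = math.nan
    switch_day: float = 3.0


def fit_two_phase_dedifferentiation(
    grid: GridSpec,
    data: FitData,
    tolerance: float,
    switch_day: float | None = None,
    proto: MammosphereProtocol | None = None,
    seed: int = 0,
    norm: str = "max",
) -> TwoPhaseFitResult:
    """Joint search over early/late dedifferentiation rates.

    Reports the mean accepted rate in each phase and their ratio
    late/early — the model's measure of how strongly plasticity rises
    after the switch day.  A zero mean early rate yields an infinite
    ratio with a warning.
    """
    if not grid.two_phase:
        raise ValueError("grid must carry k_DS_early and k_DS_late axes")
    if switch_day is not None and switch_day != grid.switch_day:
        grid = GridSpec(axes=grid.axes, fixed=grid.fixed, switch_day=switch_day)
    res = brute_force_search(grid, data, tolerance, proto=proto, seed=seed, norm=norm)
    early = late = ratio = math.nan
    if res.success:
        early = res.means.get("k_DS_early", grid.fixed.get("k_DS_early", math.nan))
        late = res.means.get("k_DS_late", grid.fixed.get("k_DS_late", math.nan))
        if early == 0.0:
            warnings.warn(
                "mean early dedifferentiation rate is 0; ratio reported as inf",
                RuntimeWarning,
                stacklevel=2,
            )
            ratio = math.inf
        else:
            ratio = late / early
    return TwoPhaseFitResult(
        accepted=res.accepted,
        means=res.means,
        sds=res.sds,
        tolerance=res.tolerance,
        n_grid=res.n_grid,
        min_loss=res.min_loss,
        success=res.success,
        k_DS_early_mean=early,
        k_DS_late_mean=late,
        ratio_late_early=ratio,
        switch_day=grid.switch_day,
    )
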