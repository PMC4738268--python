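"""Synthetic inputs emulating the study's assays.

Three generators cover everything the pipeline consumes:

* biomarker-positive fraction time courses with binomial FACS sampling
  noise, from a pure-negative start;
* mammosphere well counts, binomially drawn around the simulated
  in-silico formation rate;
* probe-by-condition expression tables with planted fold-changes and
  controlled overlap between the planted signatures of different
  conditions.

Two named scenarios ship with the package (``normoxia`` and
``hypoxia``); the hypoxic one carries a ten-fold jump of the
dedifferentiation rate at day 3 and halved division rates.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .gridfit import FitData
from .mammosphere import MammosphereProtocol, simulate_mammosphere_rate
from .model import ModelParameters, PopulationState, fraction_positive, solve_deterministic
from .signatures import ExpressionTable

__all__ = [
    "Scenario",
    "SyntheticExpressionSpec",
    "load_scenario",
    "scenario_names",
    "generate_timecourse",
    "generate_mammosphere_counts",
    "generate_expression",
]


@dataclass(frozen=True)
class Scenario:
    """Named bundle of generating parameters and observation design."""

    name: str
    params: ModelParameters
    facs_sample_size: int | None = 10_000
    observation_days: tuple[float, ...] = (0, 1, 2, 3, 4, 5, 6, 7, 8)
    n_initial_negative: int = 1000
    mammosphere: MammosphereProtocol = field(default_factory=MammosphereProtocol)
    seed: int = 0

    def __post_init__(self):
        if self.facs_sample_size is not None and self.facs_sample_size < 1:
            raise ValueError("facs_sample_size must be >= 1 (or None for noiseless)")
        if self.n_initial_negative < 1:
            raise ValueError("n_initial_negative must be >= 1")

    def with_seed(self, seed: int) -> "Scenario":
        return replace(self, seed=seed)

    def without_noise(self) -> "Scenario":
        return replace(self, facs_sample_size=None)


def _packaged_config() -> dict:
    text = (
        importlib.resources.files("cscplasticity")
        .joinpath("data/scenarios.yaml")
        .read_text()
    )
    return yaml.safe_load(text)


def scenario_names() -> list[str]:
    return sorted(_packaged_config())


def load_scenario(name: str, seed: int = 0) -> Scenario:
    """Load a packaged scenario (``normoxia`` or ``hypoxia``) by name."""
    cfg = _packaged_config()
    if name not in cfg:
        raise KeyError(f"unknown scenario {name!r}; packaged: {sorted(cfg)}")
    c = cfg[name]
    proto = MammosphereProtocol(seed=seed, **c.get("mammosphere", {}))
    return Scenario(
        name=name,
        params=ModelParameters.from_dict(c["params"]),
        facs_sample_size=c.get("facs_sample_size", 10_000),
        observation_days=tuple(c.get("observation_days", range(9))),
        n_initial_negative=c.get("n_initial_negative", 1000),
        mammosphere=proto,
        seed=seed,
    )


def generate_timecourse(scn: Scenario, seed: int | None = None) -> FitData:
    """FACS-style fraction time course from a pure biomarker-negative start.

    The true fraction comes from the deterministic solution with S0 = 0;
    each observation draws Binomial(n, f_true)/n with n the FACS events
    per time point.  ``facs_sample_size=None`` disables the noise and
    returns the deterministic fractions exactly.
    """
    if seed is None:
        seed = scn.seed
    days = np.asarray(scn.observation_days, dtype=float)
    init = PopulationState(t=float(days[0]), S=0.0, D=float(scn.n_initial_negative))
    traj = solve_deterministic(init, scn.params, days)
    f_true = fraction_positive(traj)
    if scn.facs_sample_size is None:
        observed = f_true
        n_col = np.full(days.size, np.inf)
    else:
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(0,)))
        n = scn.facs_sample_size
        observed = rng.binomial(n, f_true) / n
        n_col = np.full(days.size, float(n))
    frame = pd.DataFrame({"time": days, "fraction": observed, "n": n_col})
    return FitData(fractions=frame, condition=scn.name)


def generate_mammosphere_counts(
    scn: Scenario, wells: int, seed: int | None = None
) -> tuple[int, int]:
    """Observed sphere counts: Binomial(wells, simulated formation rate)."""
    if wells < 1:
        raise ValueError("wells must be >= 1")
    if seed is None:
        seed = scn.seed
    proto = replace(scn.mammosphere, seed=seed)
    rate = simulate_mammosphere_rate(scn.params, proto).rate
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(1,)))
    return int(rng.binomial(wells, rate)), wells


@dataclass(frozen=True)
class SyntheticExpressionSpec:
    """Design of a planted-signature expression table.

    ``conditions`` lists the non-reference condition names.  Each gets a
    planted up- and down-set of ``signature_size`` probes, multiplied or
    divided by ``fold`` before log-normal noise of dispersion ``sigma``
    (sdlog).  Consecutive conditions share ``overlap`` of their planted
    sets; unshared probes are drawn fresh and disjoint.
    """

    n_probes: int = 20_000
    conditions: tuple[str, ...] = ("hypoxia_d6", "hypoxia_d8")
    signature_size: int = 200
    fold: float = 4.0
    sigma: float = 0.1
    overlap: float = 0.5
    baseline: float = 100.0
    reference: str = "reference"

    def __post_init__(self):
        if not 0.0 <= self.overlap <= 1.0:
            raise ValueError("overlap fraction must lie in [0, 1]")
        if self.fold < 2.0:
            raise ValueError("planted fold must be >= 2 to survive thresholding")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        need = 2 * self.signature_size * len(self.conditions)
        if need > self.n_probes:
            raise ValueError("planted sets exceed the probe universe")


def _planted_sets(spec: SyntheticExpressionSpec, rng: np.random.Generator):
    """Planted up/down probe-index sets with chained pairwise overlap."""
    size = spec.signature_size
    n_shared = int(round(spec.overlap * size))
    pool = rng.permutation(spec.n_probes)
    cursor = 0

    def take(k):
        nonlocal cursor
        out = pool[cursor : cursor + k]
        cursor += k
        return out

    sets: dict[str, dict[str, np.ndarray]] = {}
    prev = None
    for cond in spec.conditions:
        if prev is None:
            up = take(size)
            down = take(size)
        else:
            up = np.concatenate([prev["up"][:n_shared], take(size - n_shared)])
            down = np.concatenate([prev["down"][:n_shared], take(size - n_shared)])
        sets[cond] = {"up": up, "down": down}
        prev = sets[cond]
    return sets


def generate_expression(
    spec: SyntheticExpressionSpec, seed: int = 0
) -> tuple[ExpressionTable, dict]:
    """Expression table with planted two-fold-plus signatures.

    Returns the table and the planted probe-ID sets per condition (for
    recovery checks).  Reference intensities are log-normal around the
    baseline; each condition multiplies its planted up-probes by
    ``fold`` and divides its down-probes likewise before multiplicative
    log-normal noise.
    """
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(2,)))
    probes = np.array([f"probe_{i:05d}" for i in range(spec.n_probes)])
    base = spec.baseline * rng.lognormal(mean=0.0, sigma=0.5, size=spec.n_probes)
    columns = {spec.reference: base}
    planted = _planted_sets(spec, rng)
    planted_ids = {}
    for cond in spec.conditions:
        mult = np.ones(spec.n_probes)
        up_idx = planted[cond]["up"]
        down_idx = planted[cond]["down"]
        mult[up_idx] = spec.fold
        mult[down_idx] = 1.0 / spec.fold
        noise = (
            rng.lognormal(mean=0.0, sigma=spec.sigma, size=spec.n_probes)
            if spec.sigma > 0
            else 1.0
        )
        columns[cond] = base * mult * noise
        planted_ids[cond] = {
            "up": frozenset(probes[up_idx]),
            "down": frozenset(probes[down_idx]),
        }
    table = ExpressionTable(
        data=pd.DataFrame(columns, index=pd.Index(probes, name="probe")),
        reference=spec.reference,
    )
    return table, planted_ids
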