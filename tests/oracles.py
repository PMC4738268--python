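"""Independent reference computations used to validate the package.

Each oracle takes a route disjoint from the implementation it checks:
the ODE solver is checked against segment-wise matrix exponentials, the
stochastic simulator against direct exponentiation of the truncated
master-equation generator and against branching-process closed forms,
and the exact test against full enumeration in rational arithmetic.
"""

from __future__ import annotations

import math
from fractions import Fraction
from math import comb

import numpy as np
from scipy.linalg import expm
from scipy.sparse import lil_matrix
from scipy.sparse.linalg import expm_multiply

from cscplasticity.model import ModelParameters, PopulationState, _rate_matrix, _segment_spans


def expm_solution(
    init: PopulationState, params: ModelParameters, times
) -> np.ndarray:
    """Exact (S, D) at each time via matrix exponentials per rate segment."""
    out = np.empty((len(times), 2))
    for i, t in enumerate(times):
        y = np.array([init.S, init.D], dtype=float)
        if t > init.t:
            for a, b, k in _segment_spans(params, init.t, float(t)):
                y = expm(_rate_matrix(params, k) * (b - a)) @ y
        out[i] = y
    return out


def fisher_two_sided_enum(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p by full enumeration in exact arithmetic.

    Sums, over all tables with the observed margins, the hypergeometric
    probabilities no larger than the observed table's (exact integer
    comparison, so ties are unambiguous).
    """
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    c2 = n - c1
    if min(r1, r2, c1, c2) == 0 or n == 0:
        return 1.0
    lo, hi = max(0, c1 - r2), min(r1, c1)
    weights = {x: comb(r1, x) * comb(r2, c1 - x) for x in range(lo, hi + 1)}
    w_obs = weights[a]
    return float(
        Fraction(sum(w for w in weights.values() if w <= w_obs), comb(n, c1))
    )


def yule_pmf(n: int, alpha: float, t: float) -> float:
    """P(N(t) = n) for a pure-birth process started from a single cell."""
    if n < 1:
        return 0.0
    e = math.exp(-alpha * t)
    return e * (1.0 - e) ** (n - 1)


def yule_exceed(n: int, alpha: float, t: float) -> float:
    """P(N(t) > n) for the pure-birth process from one cell."""
    return (1.0 - math.exp(-alpha * t)) ** n


def cme_final_distribution(
    init: PopulationState, params: ModelParameters, t_end: float, cap: int
) -> tuple[dict, float]:
    """Final-state law from the truncated master equation.

    Builds the generator over all states with S + D <= cap and
    exponentiates it segment by segment (finite state projection).
    Probability flowing out of the truncation leaks; the leaked mass is
    returned separately so callers can treat it as an overflow bin.
    """
    states = [(S, D) for tot in range(cap + 1) for S in range(tot + 1) for D in [tot - S]]
    index = {s: i for i, s in enumerate(states)}
    n = len(states)

    def build_Q(k_ds: float):
        Q = lil_matrix((n, n))
        for (S, D), i in index.items():
            moves = (
                (params.alpha_S * S, (S + 1, D)),
                (params.delta_S * S, (S - 1, D)),
                (params.k_SD * S, (S - 1, D + 1)),
                (params.alpha_D * D, (S, D + 1)),
                (params.delta_D * D, (S, D - 1)),
                (k_ds * D, (S + 1, D - 1)),
            )
            out_rate = 0.0
            for rate, target in moves:
                if rate <= 0.0:
                    continue
                out_rate += rate  # births leaving the cap leak probability
                if target in index:
                    Q[index[target], i] += rate
            Q[i, i] -= out_rate
        return Q.tocsc()

    p = np.zeros(n)
    p[index[(int(init.S), int(init.D))]] = 1.0
    for a, b, k in _segment_spans(params, init.t, t_end):
        p = expm_multiply(build_Q(k) * (b - a), p)
    dist = {s: p[i] for s, i in index.items() if p[i] > 0.0}
    return dist, max(0.0, 1.0 - float(p.sum()))
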