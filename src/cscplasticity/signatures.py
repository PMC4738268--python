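"""Fold-change gene signatures and Fisher-exact overlap statistics.

A signature is the set of probes whose normalised signal in a condition
is at least two-fold higher (upregulated) or two-fold lower
(downregulated) than in the designated reference condition, boundary
inclusive in both directions.  Two signatures drawn from the same probe
universe are compared through a 2x2 confusion matrix (overlap, the two
exclusive sets, and the probes in neither) and the two-sided Fisher
exact test, using the standard point-probability convention: the p-value
sums hypergeometric probabilities, at fixed margins, of every table no
more probable than the observed one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ExpressionTable",
    "ProbeSignature",
    "ConfusionMatrix2x2",
    "derive_signature",
    "build_confusion",
    "fisher_exact_two_sided",
    "overlap_report",
]

UP_FOLD = 2.0  # ratio >= 2 joins the up-signature; <= 1/2 the down-signature


@dataclass
class ExpressionTable:
    """Probe-by-condition table of positive normalised signal intensities."""

    data: pd.DataFrame  # index: probe IDs; columns: condition names
    reference: str

    def __post_init__(self):
        if self.reference not in self.data.columns:
            raise ValueError(f"reference condition {self.reference!r} not in table")
        if self.data.index.has_duplicates:
            raise ValueError("probe identifiers must be unique")
        if not np.all(self.data.to_numpy() > 0):
            raise ValueError("signal intensities must be strictly positive")

    @property
    def conditions(self) -> list[str]:
        return [c for c in self.data.columns if c != self.reference]

    @property
    def universe_size(self) -> int:
        return len(self.data)

    @classmethod
    def from_csv(cls, path, reference: str, sep: str = "\t") -> "ExpressionTable":
        df = pd.read_csv(path, sep=sep, index_col=0)
        return cls(df, reference)

    def to_csv(self, path, sep: str = "\t") -> None:
        self.data.to_csv(path, sep=sep, index_label="probe")


@dataclass(frozen=True)
class ProbeSignature:
    direction: str  # "up" or "down"
    probes: frozenset
    condition: str
    universe_size: int

    def __post_init__(self):
        if self.direction not in ("up", "down"):
            raise ValueError("direction must be 'up' or 'down'")
        if len(self.probes) > self.universe_size:
            raise ValueError("signature cannot exceed the probe universe")

    def __len__(self) -> int:
        return len(self.probes)


def derive_signature(
    table: ExpressionTable, condition: str, direction: str
) -> ProbeSignature:
    """Two-fold thresholded probe signature of ``condition`` vs reference.

    Up: sample/reference ratio >= 2 (boundary included); down: ratio
    <= 1/2 (boundary included, mirroring the inclusive up threshold).
    """
    if condition == table.reference:
        raise ValueError("condition must differ from the reference")
    if condition not in table.data.columns:
        raise ValueError(f"unknown condition {condition!r}")
    ref = table.data[table.reference]
    if not np.all(ref.to_numpy() > 0):
        raise ValueError("reference intensities must be strictly positive")
    ratio = table.data[condition] / ref
    if direction == "up":
        mask = ratio >= UP_FOLD
    elif direction == "down":
        mask = ratio <= 1.0 / UP_FOLD
    else:
        raise ValueError("direction must be 'up' or 'down'")
    return ProbeSignature(
        direction=direction,
        probes=frozenset(table.data.index[mask]),
        condition=condition,
        universe_size=table.universe_size,
    )


@dataclass(frozen=True)
class ConfusionMatrix2x2:
    """Overlap table of two probe sets within a shared universe.

    a = |A ∩ B|, b = |A \\ B|, c = |B \\ A|, d = |universe \\ (A ∪ B)|.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        for v in (self.a, self.b, self.c, self.d):
            if v < 0 or int(v) != v:
                raise ValueError("confusion-matrix cells must be non-negative integers")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)


def build_confusion(
    sigA: ProbeSignature | Iterable,
    sigB: ProbeSignature | Iterable,
    universe_size: int,
) -> ConfusionMatrix2x2:
    """Confusion matrix of two signatures over an explicit probe universe."""
    A = set(sigA.probes if isinstance(sigA, ProbeSignature) else sigA)
    B = set(sigB.probes if isinstance(sigB, ProbeSignature) else sigB)
    if len(A) > universe_size or len(B) > universe_size:
        raise ValueError("signature larger than the probe universe")
    a = len(A & B)
    b = len(A - B)
    c = len(B - A)
    d = universe_size - a - b - c
    if d < 0:
        raise ValueError("universe smaller than the union of the signatures")
    return ConfusionMatrix2x2(a, b, c, d)


def fisher_exact_two_sided(m: ConfusionMatrix2x2) -> tuple[float, float]:
    """Two-sided Fisher exact p-value and sample odds ratio.

    Degenerate tables (a zero margin, where only one table is attainable)
    return p = 1.  The odds ratio a*d/(b*c) is ``inf`` when b*c == 0 and
    a*d > 0, and NaN for the doubly degenerate all-zero-product case.
    """
    table = m.as_array()
    _, p = stats.fisher_exact(table, alternative="two-sided")
    num = m.a * m.d
    den = m.b * m.c
    if den == 0:
        odds = math.inf if num > 0 else math.nan
    else:
        odds = num / den
    return min(float(p), 1.0), odds


def overlap_report(
    pairs: Sequence[tuple[ProbeSignature, ProbeSignature]],
    universe_size: int,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One row per signature pair: overlap, odds ratio, p, significance.

    No multiplicity adjustment is applied; each pair is tested at
    ``alpha`` on its own.
    """
    rows = []
    for sigA, sigB in pairs:
        m = build_confusion(sigA, sigB, universe_size)
        p, odds = fisher_exact_two_sided(m)
        rows.append(
            {
                "pair": f"{sigA.condition}:{sigA.direction} vs {sigB.condition}:{sigB.direction}",
                "size_A": len(sigA),
                "size_B": len(sigB),
                "overlap": m.a,
                "odds_ratio": odds,
                "p_value": p,
                "significant": p < alpha,
            }
        )
    return pd.DataFrame(rows)
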