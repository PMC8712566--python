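"""Choquet integral, its t-norm generalizations, OWA and simple baselines.

For scores ``h(x_1..n)`` (per-classifier probabilities of one class for one
sample) sorted non-increasingly, with ``h_(n+1) = 0`` and a Sugeno chain
``G_i = g(U_i)`` aligned to the same ordering, the classic Choquet integral is

    ``C = Σ_i (h_(i) − h_(i+1)) · G_i``,

a weighted mean when the measure is additive.  The generalized (pre-
aggregation) operators replace the product with a t-norm ``M`` in various
ways; e.g. ``C_M = Σ M(h_(i) − h_(i+1), G_i)`` recovers ``C`` exactly when
``M`` is the product.  The difference-based variants ``C_D1..C_D3``
additionally reference ``h_(i−1)``; the leading boundary value ``h_(0)`` is 1
by default (scores are probabilities and the sequence is non-increasing), and
arguments that stray outside ``[0, 1]`` — possible for the D-variants — are
clipped before ``M`` is applied, the minimal extension keeping the t-norm's
domain.  Pre-aggregation weakens classical aggregation axioms: only the
classic integral is guaranteed idempotent and bounded by ``[min h, max h]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from eegfuse.sugeno import FuzzyDensities, SugenoMeasure
from eegfuse.tnorms import TNormSpec

__all__ = [
    "ScoreVector",
    "AggregationResult",
    "choquet",
    "generalized",
    "aggregate",
    "owa",
    "owa_weights",
    "simple_aggregate",
    "GENERALIZED_OPERATORS",
    "SIMPLE_OPERATORS",
    "ALL_OPERATORS",
]

GENERALIZED_OPERATORS = (
    "CM",
    "CFM",
    "CCM",
    "CMC",
    "CMMin",
    "CMMin2",
    "CMinM",
    "CD1",
    "CD2",
    "CD3",
)
SIMPLE_OPERATORS = ("min", "max", "median", "mean", "vote")
ALL_OPERATORS = ("choquet",) + GENERALIZED_OPERATORS + ("owa",) + SIMPLE_OPERATORS


@dataclass(frozen=True)
class ScoreVector:
    """Classifier scores for one sample/class with their descending ordering.

    ``sorted_h`` is ``h`` reordered non-increasingly; ties are broken by the
    original classifier index (stable sort), so the permutation is unique.
    """

    h: tuple[float, ...]
    permutation: tuple[int, ...] = field(init=False)
    sorted_h: tuple[float, ...] = field(init=False)

    def __post_init__(self) -> None:
        h = tuple(float(v) for v in self.h)
        if len(h) == 0:
            raise ValueError("empty score vector")
        if any(not (0.0 <= v <= 1.0) for v in h):
            raise ValueError(f"scores must lie in [0, 1]; got {h}")
        perm = tuple(int(i) for i in np.argsort(-np.asarray(h), kind="stable"))
        object.__setattr__(self, "h", h)
        object.__setattr__(self, "permutation", perm)
        object.__setattr__(self, "sorted_h", tuple(h[i] for i in perm))

    def __len__(self) -> int:
        return len(self.h)


@dataclass(frozen=True)
class AggregationResult:
    value: float
    operator: str
    tnorm: Optional[TNormSpec] = None


def _check_aligned(h: ScoreVector, m: SugenoMeasure) -> None:
    if len(h) != len(m):
        raise ValueError(
            f"score vector of length {len(h)} does not match "
            f"measure chain of length {len(m)}"
        )


def choquet(h: ScoreVector, m: SugenoMeasure) -> AggregationResult:
    """Classic Choquet integral Σ (h_(i) − h_(i+1)) g(U_i)."""
    _check_aligned(h, m)
    hs = np.asarray(h.sorted_h)
    G = np.asarray(m.cumulative)
    diffs = hs - np.append(hs[1:], 0.0)
    return AggregationResult(float(np.dot(diffs, G)), "choquet")


def _clip01(v: float) -> float:
    return 0.0 if v < 0.0 else (1.0 if v > 1.0 else v)


def generalized(
    h: ScoreVector,
    m: SugenoMeasure,
    t: TNormSpec,
    operator: str,
    h0: float = 1.0,
    d3_ratio_of_sum: bool = True,
) -> AggregationResult:
    """Evaluate one of the ten t-norm generalizations of the Choquet integral.

    Parameters
    ----------
    operator
        One of ``CM, CFM, CCM, CMC, CMMin, CMMin2, CMinM, CD1, CD2, CD3``.
    h0
        Boundary score ``h_(0)`` used by the D-variants' first term; pass
        ``h.sorted_h[0]`` for the alternative ``h_(0) = h_(1)`` convention.
    d3_ratio_of_sum
        ``CD3`` integrand: ``(h_(i−1) + h_(i+1)) / h_(i)`` when true (the
        default), ``h_(i−1) + h_(i+1)/h_(i)`` when false.  Terms with
        ``h_(i) = 0`` contribute 0 (all later sorted scores are 0 too).
    """
    _check_aligned(h, m)
    if operator not in GENERALIZED_OPERATORS:
        raise ValueError(f"unknown generalized operator {operator!r}")
    n = len(h)
    hs = list(h.sorted_h) + [0.0]  # h_(1..n) with h_(n+1) = 0
    G = m.cumulative
    M = t

    total = 0.0
    for i in range(n):  # i is 0-based; h_(i+1) == hs[i]
        hi, hnext = hs[i], hs[i + 1]
        hprev = float(h0) if i == 0 else hs[i - 1]
        Gi = G[i]
        if operator == "CM" or operator == "CFM":
            term = M(_clip01(hi - hnext), Gi)
        elif operator == "CCM":
            term = M(hi, Gi) - M(hnext, Gi)
        elif operator == "CMC":
            term = M(hi, Gi) - M(hnext, Gi) + M(_clip01(hi - hnext), Gi)
        elif operator == "CMMin":
            term = M(_clip01(min(hi, Gi) - min(hnext, Gi)), Gi)
        elif operator == "CMMin2":
            term = M(min(hi, Gi), min(hnext, Gi))
        elif operator == "CMinM":
            term = min(M(hi, Gi), M(hnext, Gi))
        elif operator == "CD1":
            term = M(_clip01(hprev - hnext), Gi)
        elif operator == "CD2":
            term = M(_clip01(hprev + hnext - hi), Gi)
        else:  # CD3
            if hi == 0.0:
                continue
            arg = (hprev + hnext) / hi if d3_ratio_of_sum else hprev + hnext / hi
            term = M(_clip01(arg), Gi)
        total += term
    if operator == "CFM":
        total = min(total, 1.0)
    return AggregationResult(float(total), operator, t)


def owa_weights(n: int, normalized: bool = True) -> np.ndarray:
    """Linearly decaying OWA weights ω_j = 1 − (j−1)/n, optionally normalized."""
    if n < 1:
        raise ValueError("n must be positive")
    w = 1.0 - np.arange(n) / n
    return w / w.sum() if normalized else w


def owa(x: Sequence[float], weights: Optional[np.ndarray] = None, normalized: bool = True) -> float:
    """Ordered weighted average: Σ ω_j y_j with y_j the j-th largest input."""
    arr = np.sort(np.asarray(x, dtype=float))[::-1]
    w = owa_weights(len(arr), normalized) if weights is None else np.asarray(weights)
    if len(w) != len(arr):
        raise ValueError("weights and inputs differ in length")
    return float(np.dot(w, arr))


def simple_aggregate(x: Sequence[float], kind: str, threshold: float = 0.5) -> float:
    """Elementary fusion baselines.

    ``vote`` thresholds scores at ``threshold`` and returns 1.0 on a strict
    majority of positives, 0.0 on a strict minority, 0.5 on an exact tie.
    """
    arr = np.asarray(x, dtype=float)
    if kind == "min":
        return float(arr.min())
    if kind == "max":
        return float(arr.max())
    if kind == "median":
        return float(np.median(arr))
    if kind == "mean":
        return float(arr.mean())
    if kind in ("vote", "majority_vote"):
        positives = int((arr >= threshold).sum())
        negatives = len(arr) - positives
        return 1.0 if positives > negatives else (0.0 if positives < negatives else 0.5)
    raise ValueError(f"unknown simple aggregator {kind!r}")


def aggregate(
    h: ScoreVector,
    m: Optional[SugenoMeasure],
    operator: str,
    tnorm: Optional[TNormSpec] = None,
    **kwargs,
) -> AggregationResult:
    """Dispatch on operator name; measure-free operators ignore ``m``."""
    if operator == "choquet":
        return choquet(h, m)
    if operator in GENERALIZED_OPERATORS:
        if tnorm is None:
            raise ValueError(f"operator {operator} requires a t-norm")
        return generalized(h, m, tnorm, operator, **kwargs)
    if operator == "owa":
        return AggregationResult(owa(h.h, **kwargs), "owa")
    if operator in SIMPLE_OPERATORS or operator == "majority_vote":
        return AggregationResult(simple_aggregate(h.h, operator, **kwargs), operator)
    raise ValueError(f"unknown operator {operator!r}")


def fuse_class_scores(
    scores: Sequence[float],
    densities: FuzzyDensities,
    lam: float,
    operator: str,
    tnorm: Optional[TNormSpec] = None,
    **kwargs,
) -> float:
    """Sort one class's scores, align the measure chain, and aggregate.

    ``scores[i]`` is classifier ``i``'s probability for the class; the Sugeno
    chain is rebuilt for the induced ordering (λ itself depends only on the
    densities).  Measure-free operators skip the chain entirely.
    """
    sv = ScoreVector(tuple(scores))
    if operator == "choquet" or operator in GENERALIZED_OPERATORS:
        from eegfuse.sugeno import cumulative_chain

        m = cumulative_chain(densities.reordered(sv.permutation), lam)
    else:
        m = None
    return aggregate(sv, m, operator, tnorm, **kwargs).value
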