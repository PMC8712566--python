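"""Sugeno λ-fuzzy measures over a finite classifier ensemble.

A fuzzy measure (capacity) on the classifier set ``X = {x_1, …, x_n}`` is a
monotone set function ``g`` with ``g(∅) = 0`` and ``g(X) = 1``.  The Sugeno
λ-measure is the one-parameter family satisfying, on disjoint ``U, W``,

    ``g(U ∪ W) = g(U) + g(W) + λ g(U) g(W)``,   λ > −1,

so the whole measure is pinned down by the singleton densities
``g_i = g({x_i})`` — here the cross-validated accuracy of classifier ``i`` —
and the normalization ``g(X) = 1``, which fixes λ as the unique root of

    ``1 + λ = ∏_i (1 + λ g_i)``

with λ > −1, λ ≠ 0 (λ = 0 exactly when the densities already sum to 1, in
which case the measure is additive).  The Choquet sum then needs the chain
``g(U_i)`` for the nested sets ``U_i = {x_(1), …, x_(i)}`` induced by the
score ordering, built by the recursion
``g(U_{i+1}) = g(U_i) + g_{i+1} + λ g_{i+1} g(U_i)``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "FuzzyDensities",
    "SugenoMeasure",
    "solve_lambda",
    "cumulative_chain",
    "clip_densities",
    "read_densities",
    "write_densities",
]

DENSITY_FLOOR = 1e-6
_SUM_TOL = 1e-12
_RESIDUAL_TOL = 1e-10
_TERMINAL_TOL = 1e-9


@dataclass(frozen=True)
class FuzzyDensities:
    """Per-classifier importances ``g_i ∈ (0, 1]``, with optional names."""

    g: tuple[float, ...]
    names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        g = tuple(float(v) for v in self.g)
        if len(g) < 1:
            raise ValueError("at least one density is required")
        if any(not (0.0 < v <= 1.0) for v in g):
            raise ValueError(f"densities must lie in (0, 1]; got {g}")
        if self.names is not None and len(self.names) != len(g):
            raise ValueError("names and densities differ in length")
        object.__setattr__(self, "g", g)

    def __len__(self) -> int:
        return len(self.g)

    def asarray(self) -> np.ndarray:
        return np.asarray(self.g, dtype=float)

    def reordered(self, order) -> "FuzzyDensities":
        names = None if self.names is None else tuple(self.names[i] for i in order)
        return FuzzyDensities(tuple(self.g[i] for i in order), names)


@dataclass(frozen=True)
class SugenoMeasure:
    """Solved λ together with the cumulative chain ``g(U_1..n)``.

    The chain refers to one particular ordering of the classifiers (the
    non-increasing score order of the sample being aggregated).
    """

    lam: float
    cumulative: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.lam <= -1.0:
            raise ValueError(f"lambda must exceed -1; got {self.lam}")
        cum = tuple(float(v) for v in self.cumulative)
        if any(b < a - 1e-12 for a, b in zip(cum, cum[1:])):
            raise ValueError("cumulative chain must be non-decreasing")
        if abs(cum[-1] - 1.0) > _TERMINAL_TOL:
            raise ValueError(f"g(X) = {cum[-1]} differs from 1 beyond tolerance")
        object.__setattr__(self, "cumulative", cum)

    def __len__(self) -> int:
        return len(self.cumulative)


def clip_densities(values, floor: float = DENSITY_FLOOR) -> FuzzyDensities:
    """Coerce raw accuracies into valid densities.

    Values of 0 (a classifier that never got a fold right) would make the
    cumulative chain degenerate, so they are floored at ``floor`` with a
    warning; values of exactly 1 are pulled just below 1 so that λ stays
    solvable for ensembles of several perfect classifiers.
    """
    arr = np.asarray(values, dtype=float)
    if np.any((arr < 0.0) | (arr > 1.0)):
        raise ValueError(f"accuracies must lie in [0, 1]; got {arr}")
    if np.any(arr <= 0.0):
        warnings.warn(
            f"densities of 0 floored at {floor}", RuntimeWarning, stacklevel=2
        )
    arr = np.clip(arr, floor, 1.0 - floor)
    return FuzzyDensities(tuple(arr))


def _chain_gap(lam: float, g: np.ndarray) -> float:
    """q(λ) = (∏(1 + λ g_i) − 1)/λ − 1.

    The cumulative chain telescopes to g(X) = (∏(1 + λ g_i) − 1)/λ, so q is
    exactly the terminal error of the measure.  Dividing by λ also removes
    the trivial root of Eq. ∏(1 + λ g_i) = 1 + λ at λ = 0, which otherwise
    makes residual-based convergence checks insensitive when Σg_i ≈ 1 and
    the true root sits close to zero.
    """
    return float(np.expm1(np.log1p(lam * g).sum()) / lam - 1.0)


def solve_lambda(densities: FuzzyDensities) -> float:
    """Solve the Sugeno normalization for λ.

    Returns 0 when the densities are additive (Σg_i = 1 within 1e-12, or a
    single classifier).  Otherwise brackets the unique nonzero root — in
    (−1, 0) when Σg_i > 1, in (0, ∞) when Σg_i < 1 — and refines it with
    Brent's method.  The sign law follows from convexity of ∏(1+λg_i) in λ.
    """
    g = densities.asarray()
    n = len(g)
    if n == 1:
        if abs(g[0] - 1.0) > 1e-6:
            warnings.warn(
                f"single classifier with density {g[0]:.6g} != 1; "
                "measure normalized trivially",
                RuntimeWarning,
                stacklevel=2,
            )
        return 0.0
    if np.any(g >= 1.0):
        raise ValueError(
            "densities must be strictly below 1 for n >= 2 "
            "(no finite lambda can normalize the measure)"
        )
    total = float(g.sum())
    if abs(total - 1.0) <= _SUM_TOL:
        return 0.0

    if total > 1.0:
        # root in (-1, 0): q(-1+) = 1 - prod(1 - g_i) - ... < 0, q(0-) > 0
        lo, hi = -1.0 + 1e-12, -1e-14
    else:
        # root in (0, inf): q(0+) = sum(g) - 1 < 0, q grows without bound
        lo = 1e-14
        hi = 1.0
        while _chain_gap(hi, g) <= 0.0:
            hi *= 2.0
            if hi > 1e12:  # pragma: no cover - defensive
                raise ArithmeticError(
                    f"failed to bracket lambda for densities {g}; "
                    f"q({hi}) = {_chain_gap(hi, g)}"
                )
    lam = float(brentq(_chain_gap, lo, hi, args=(g,), xtol=1e-15, rtol=8.9e-16))
    residual = abs(_chain_gap(lam, g))
    if residual > _RESIDUAL_TOL:  # pragma: no cover - defensive
        raise ArithmeticError(
            f"lambda root did not converge: terminal gap {residual:.3e} for g = {g}"
        )
    return lam


def cumulative_chain(densities_ordered: FuzzyDensities, lam: float) -> SugenoMeasure:
    """Build ``g(U_1..n)`` for densities given in the score-sorted order."""
    if lam <= -1.0:
        raise ValueError(f"lambda must exceed -1; got {lam}")
    g = densities_ordered.asarray()
    cum = np.empty(len(g))
    cum[0] = g[0]
    for i in range(1, len(g)):
        cum[i] = cum[i - 1] + g[i] + lam * g[i] * cum[i - 1]
    if len(g) == 1:
        cum[0] = 1.0  # singleton ensemble: U_1 = X regardless of its density
    elif abs(cum[-1] - 1.0) <= 1e-10:
        cum[-1] = 1.0  # shave root-finder rounding only; real gaps still raise
    return SugenoMeasure(lam, tuple(cum))


def measure_for(densities: FuzzyDensities) -> SugenoMeasure:
    """Convenience: solve λ and build the chain in the given order."""
    return cumulative_chain(densities, solve_lambda(densities))


def write_densities(path, densities: FuzzyDensities) -> None:
    """Serialize densities to JSON ({name: density}) or CSV by extension."""
    path = Path(path)
    names = densities.names or tuple(f"clf{i}" for i in range(len(densities)))
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(dict(zip(names, densities.g)), indent=2) + "\n")
    else:
        lines = ["classifier,density"]
        lines += [f"{n},{v!r}" for n, v in zip(names, densities.g)]
        path.write_text("\n".join(lines) + "\n")


def read_densities(path) -> FuzzyDensities:
    path = Path(path)
    if path.suffix.lower() == ".json":
        data = json.loads(path.read_text())
        return FuzzyDensities(tuple(float(v) for v in data.values()), tuple(data))
    names, values = [], []
    for line in path.read_text().strip().splitlines()[1:]:
        name, value = line.split(",")
        names.append(name)
        values.append(float(value))
    return FuzzyDensities(tuple(values), tuple(names))
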