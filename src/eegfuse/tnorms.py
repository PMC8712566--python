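"""Parametric triangular-norm families used as Choquet-integral integrands.

A t-norm is a commutative, associative, monotone binary operation on
``[0, 1]`` with neutral element 1.  In the generalized (pre-aggregation)
Choquet integrals of :mod:`eegfuse.aggregators` the product inside the
classic Choquet sum is replaced by an arbitrary t-norm ``M(·,·)``; the choice
of family and of its shape parameter ``α`` is part of the fusion grid search.

Two parametric families are first-class citizens here because they win the
fusion experiments this package reproduces: the family registered under
numeric id 8,

    ``M(x, y) = max(α²xy − (1−x)(1−y), 0) / (α² − (α−1)²(1−x)(1−y))``,  α > 0,

and the Yager family, registered under numeric id 12,

    ``M(x, y) = max(1 − ((1−x)^α + (1−y)^α)^{1/α}, 0)``,  α > 0,

which reduces to the Łukasiewicz t-norm at α = 1.  Classical named families
(product, minimum, Łukasiewicz, Hamacher, Frank, Dombi, Schweizer–Sklar,
Aczél–Alsina) are also registered; further numeric ids can be attached to any
named family with :func:`register_family_id` when reproducing catalogues that
index t-norms by number.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional

__all__ = [
    "AlphaRange",
    "TNormFamily",
    "TNormSpec",
    "evaluate",
    "alpha_grid",
    "list_families",
    "resolve_family",
    "register_family_id",
]

_CLIP_TOL = 1e-12


@dataclass(frozen=True)
class AlphaRange:
    """Admissible interval for a family's shape parameter.

    ``lo``/``hi`` may be ±inf; ``lo_open``/``hi_open`` mark strict endpoints.
    """

    lo: float
    hi: float
    lo_open: bool = True
    hi_open: bool = True

    def contains(self, alpha: float) -> bool:
        if not math.isfinite(alpha):
            return False
        if alpha < self.lo or (self.lo_open and alpha == self.lo):
            return False
        if alpha > self.hi or (self.hi_open and alpha == self.hi):
            return False
        return True

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        left = "(" if self.lo_open else "["
        right = ")" if self.hi_open else "]"
        return f"{left}{self.lo}, {self.hi}{right}"


@dataclass(frozen=True)
class TNormFamily:
    name: str
    func: Callable[[float, float, Optional[float]], float]
    alpha_range: Optional[AlphaRange]
    ids: tuple[int, ...] = ()
    aliases: tuple[str, ...] = ()
    description: str = ""

    @property
    def parametric(self) -> bool:
        return self.alpha_range is not None


def _t_product(x: float, y: float, alpha: Optional[float]) -> float:
    return x * y


def _t_minimum(x: float, y: float, alpha: Optional[float]) -> float:
    return x if x < y else y


def _t_lukasiewicz(x: float, y: float, alpha: Optional[float]) -> float:
    return max(x + y - 1.0, 0.0)


def _t_family8(x: float, y: float, alpha: float) -> float:
    # Rational family, id 8.  The max(·,0) in the numerator decides the
    # outcome before the quotient is formed: when the numerator clips to 0
    # the value is 0 regardless of the denominator's sign.
    num = alpha * alpha * (x * y) - (1.0 - x) * (1.0 - y)
    if num <= 0.0:
        return 0.0
    den = alpha * alpha - (alpha - 1.0) ** 2 * ((1.0 - x) * (1.0 - y))
    if den <= 0.0:
        return 0.0
    return num / den


def _t_yager(x: float, y: float, alpha: float) -> float:
    s = ((1.0 - x) ** alpha + (1.0 - y) ** alpha) ** (1.0 / alpha)
    return max(1.0 - s, 0.0)


def _t_hamacher(x: float, y: float, alpha: float) -> float:
    den = alpha + (1.0 - alpha) * (x + y - x * y)
    if den == 0.0:  # only at alpha == 0, x == y == 0
        return 0.0
    return (x * y) / den


def _t_frank(x: float, y: float, alpha: float) -> float:
    if alpha == 1.0:  # continuous limit of the family
        return x * y
    num = (alpha**x - 1.0) * (alpha**y - 1.0)
    return math.log1p(num / (alpha - 1.0)) / math.log(alpha)


def _t_dombi(x: float, y: float, alpha: float) -> float:
    if x == 0.0 or y == 0.0:
        return 0.0
    s = ((1.0 / x - 1.0) ** alpha + (1.0 / y - 1.0) ** alpha) ** (1.0 / alpha)
    return 1.0 / (1.0 + s)


def _t_schweizer_sklar(x: float, y: float, alpha: float) -> float:
    if alpha == 0.0:  # continuous limit
        return x * y
    if alpha > 0.0:
        return max(x**alpha + y**alpha - 1.0, 0.0) ** (1.0 / alpha)
    if x == 0.0 or y == 0.0:
        return 0.0
    return (x**alpha + y**alpha - 1.0) ** (1.0 / alpha)


def _t_aczel_alsina(x: float, y: float, alpha: float) -> float:
    if x == 0.0 or y == 0.0:
        return 0.0
    s = ((-math.log(x)) ** alpha + (-math.log(y)) ** alpha) ** (1.0 / alpha)
    return math.exp(-s)


_POSITIVE = AlphaRange(0.0, math.inf, lo_open=True)
_NONNEGATIVE = AlphaRange(0.0, math.inf, lo_open=False)
_REALS = AlphaRange(-math.inf, math.inf)

_FAMILIES: dict[str, TNormFamily] = {}
_ID_MAP: dict[int, str] = {}
_ALIAS_MAP: dict[str, str] = {}


def _register(family: TNormFamily) -> None:
    _FAMILIES[family.name] = family
    for i in family.ids:
        _ID_MAP[i] = family.name
    for a in family.aliases:
        _ALIAS_MAP[a.lower()] = family.name


_register(TNormFamily("product", _t_product, None, description="xy"))
_register(TNormFamily("minimum", _t_minimum, None, aliases=("min",), description="min(x,y)"))
_register(
    TNormFamily(
        "lukasiewicz",
        _t_lukasiewicz,
        None,
        aliases=("luka",),
        description="max(x+y-1, 0)",
    )
)
_register(
    TNormFamily(
        "family8",
        _t_family8,
        _POSITIVE,
        ids=(8,),
        description="max(a^2 xy - (1-x)(1-y), 0) / (a^2 - (a-1)^2 (1-x)(1-y)), a > 0",
    )
)
_register(
    TNormFamily(
        "yager",
        _t_yager,
        _POSITIVE,
        ids=(12,),
        aliases=("family12",),
        description="max(1 - ((1-x)^a + (1-y)^a)^(1/a), 0), a > 0; a=1 is Lukasiewicz",
    )
)
_register(
    TNormFamily(
        "hamacher",
        _t_hamacher,
        _NONNEGATIVE,
        description="xy / (a + (1-a)(x+y-xy)), a >= 0",
    )
)
_register(
    TNormFamily(
        "frank",
        _t_frank,
        _POSITIVE,
        description="log_a(1 + (a^x-1)(a^y-1)/(a-1)), a > 0; a=1 is product",
    )
)
_register(
    TNormFamily(
        "dombi",
        _t_dombi,
        _POSITIVE,
        description="1 / (1 + ((1/x-1)^a + (1/y-1)^a)^(1/a)), a > 0",
    )
)
_register(
    TNormFamily(
        "schweizer-sklar",
        _t_schweizer_sklar,
        _REALS,
        aliases=("schweizer_sklar", "ss"),
        description="(max(x^a + y^a - 1, 0))^(1/a); a=0 is product",
    )
)
_register(
    TNormFamily(
        "aczel-alsina",
        _t_aczel_alsina,
        _POSITIVE,
        aliases=("aczel_alsina", "aa"),
        description="exp(-((-ln x)^a + (-ln y)^a)^(1/a)), a > 0",
    )
)


def register_family_id(number: int, name: str) -> None:
    """Attach a numeric id to a registered family (user-supplied numbering)."""
    family = resolve_family(name)
    if number in _ID_MAP and _ID_MAP[number] != family.name:
        raise ValueError(f"id {number} already maps to {_ID_MAP[number]!r}")
    _ID_MAP[number] = family.name


def resolve_family(family: "int | str | TNormFamily") -> TNormFamily:
    """Look a family up by numeric id, name or alias."""
    if isinstance(family, TNormFamily):
        return family
    if isinstance(family, int) and not isinstance(family, bool):
        try:
            return _FAMILIES[_ID_MAP[family]]
        except KeyError:
            raise KeyError(f"no t-norm family registered under id {family}") from None
    key = str(family).strip().lower()
    if key in _FAMILIES:
        return _FAMILIES[key]
    if key in _ALIAS_MAP:
        return _FAMILIES[_ALIAS_MAP[key]]
    if key.isdigit():
        return resolve_family(int(key))
    raise KeyError(f"unknown t-norm family {family!r}")


@dataclass(frozen=True)
class TNormSpec:
    """A concrete, evaluable t-norm: family plus (for parametric families) α.

    Raises ``ValueError`` at construction if α is missing, superfluous, or
    outside the family's admissible range.
    """

    family: "int | str"
    alpha: Optional[float] = None
    _resolved: TNormFamily = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        fam = resolve_family(self.family)
        if fam.parametric:
            if self.alpha is None:
                raise ValueError(f"family {fam.name!r} requires a parameter alpha")
            if not fam.alpha_range.contains(float(self.alpha)):
                raise ValueError(
                    f"alpha={self.alpha} outside admissible range "
                    f"{fam.alpha_range} of family {fam.name!r}"
                )
        elif self.alpha is not None:
            raise ValueError(f"family {fam.name!r} takes no parameter")
        object.__setattr__(self, "_resolved", fam)

    @property
    def name(self) -> str:
        return self._resolved.name

    def label(self) -> str:
        if self.alpha is None:
            return self.name
        return f"{self.name}({self.alpha:g})"

    def __call__(self, x: float, y: float) -> float:
        return evaluate(self, x, y)


def evaluate(spec: TNormSpec, x: float, y: float) -> float:
    """Evaluate ``M(x, y)`` for the given t-norm.

    Both arguments must lie in ``[0, 1]``.  The raw formula of a family may
    stray outside ``[0, 1]`` by rounding only; results are clipped within a
    ``1e-12`` tolerance and any larger excursion raises.
    """
    x = float(x)
    y = float(y)
    if not (0.0 <= x <= 1.0) or not (0.0 <= y <= 1.0):
        raise ValueError(f"t-norm arguments must lie in [0, 1]; got ({x}, {y})")
    alpha = None if spec.alpha is None else float(spec.alpha)
    value = spec._resolved.func(x, y, alpha)
    if value < 0.0:
        if value < -_CLIP_TOL:
            raise FloatingPointError(f"{spec.label()}({x}, {y}) = {value} below 0")
        return 0.0
    if value > 1.0:
        if value > 1.0 + _CLIP_TOL:
            raise FloatingPointError(f"{spec.label()}({x}, {y}) = {value} above 1")
        return 1.0
    return value


def alpha_grid(
    family: "int | str | TNormFamily",
    lo: float = -10.0,
    hi: float = 10.0,
    step: float = 0.1,
) -> tuple[Optional[float], ...]:
    """Arithmetic α grid ``lo, lo+step, …, hi`` intersected with the family's range.

    For parameter-free families returns ``(None,)`` so that a grid search
    visits the family exactly once.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    if lo > hi:
        raise ValueError("lo must not exceed hi")
    fam = resolve_family(family)
    if not fam.parametric:
        return (None,)
    n = int(round((hi - lo) / step)) + 1
    values = []
    for k in range(n):
        a = round(lo + k * step, 10)
        if a <= hi + 1e-12 and fam.alpha_range.contains(a):
            values.append(a)
    return tuple(values)


def list_families() -> dict[str, TNormFamily]:
    """Catalogue of registered families keyed by canonical name."""
    return dict(_FAMILIES)
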