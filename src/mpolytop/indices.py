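"""Degree-based and neighborhood degree-sum topological indices.

Each index is registered once with two independent computation routes:

* an *edge-weight rule* f(a, b) summed over the classes of an edge
  partition (count * f(a, b) per class), and
* an *operator recipe* — a sum of operator chains applied to the
  generating polynomial and evaluated at c = d = 1.

The two routes are algebraically equivalent; the package computes both and
tests their exact agreement, which guards the operator implementations and
the registry entries against each other.

Ten base indices are defined (first/second/modified-second Zagreb,
augmented Zagreb, general Randic, harmonic, inverse sum indeg, symmetric
division deg, forgotten, redefined third Zagreb).  Their neighborhood
analogues use the same arithmetic on neighborhood degree-sum partitions and
are addressed with an ``n`` prefix (``nM1``, ``nAZI``, ...).

Two conventions follow the operator formulations rather than occasionally
garbled formula typesetting: the general Randic weight is the *product*
(a*b)^alpha, and the symmetric division deg weight is (a^2 + b^2)/(a*b).
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Callable, Optional, Sequence, Union

from .graphs import Basis, EdgePartition, MolecularGraph, edge_partition
from .polynomial import (
    BivariatePolynomial,
    UndefinedOperatorError,
    mpoly_from_partition,
    op_D_power,
    op_Dc,
    op_Dd,
    op_Ic,
    op_Id,
    op_J,
    op_Q,
)

__all__ = [
    "IndexDefinition",
    "UndefinedIndexError",
    "INDEX_REGISTRY",
    "BASE_INDEX_NAMES",
    "ALL_INDEX_NAMES",
    "DEFAULT_ALPHAS",
    "index_from_partition",
    "index_from_polynomial",
    "all_indices",
    "IndexReportRow",
]

Exact = Union[Fraction, object]

DEFAULT_ALPHAS: tuple[Fraction, ...] = (
    Fraction(1),
    Fraction(-1),
    Fraction(1, 2),
    Fraction(-1, 2),
)


class UndefinedIndexError(ArithmeticError):
    """The index is genuinely undefined on this input (e.g. AZI on K2)."""


# A recipe is a sum of weighted operator chains; each chain is applied
# left-to-right to the polynomial, the branch results are scaled, summed
# and evaluated at c = d = 1.  Steps: "Dc", "Dd", "Ic", "Id", "J",
# ("Q", k), ("Dpow", var, alpha) where alpha may be the runtime parameter
# marker "alpha".
Step = Union[str, tuple]
Chain = tuple[Step, ...]
Branch = tuple[int, Chain]


@dataclass(frozen=True)
class IndexDefinition:
    name: str
    edge_weight: Callable[[int, int, Optional[Fraction]], Exact]
    recipe: tuple[Branch, ...]
    needs_alpha: bool = False
    description: str = ""


def _w_M1(a, b, alpha=None):
    return Fraction(a + b)


def _w_M2(a, b, alpha=None):
    return Fraction(a * b)


def _w_mM2(a, b, alpha=None):
    if a * b == 0:
        raise UndefinedIndexError("modified second Zagreb undefined on degree 0")
    return Fraction(1, a * b)


def _w_AZI(a, b, alpha=None):
    if a + b == 2:
        raise UndefinedIndexError(
            "augmented Zagreb undefined on a class with a + b = 2"
        )
    return Fraction((a * b) ** 3, (a + b - 2) ** 3)


def _w_GR(a, b, alpha=None):
    if alpha is None:
        raise TypeError("general Randic index requires alpha")
    alpha = Fraction(alpha)
    prod = a * b
    if alpha.denominator == 1:
        k = int(alpha)
        if prod == 0 and k < 0:
            raise UndefinedIndexError("general Randic undefined: zero degree")
        return Fraction(prod) ** k
    import sympy

    if prod == 0 and alpha < 0:
        raise UndefinedIndexError("general Randic undefined: zero degree")
    return sympy.Integer(prod) ** sympy.Rational(str(alpha))


def _w_H(a, b, alpha=None):
    return Fraction(2, a + b)


def _w_ISI(a, b, alpha=None):
    if a + b == 0:
        raise UndefinedIndexError("inverse sum indeg undefined on isolated pair")
    return Fraction(a * b, a + b)


def _w_SDD(a, b, alpha=None):
    if a * b == 0:
        raise UndefinedIndexError("symmetric division deg undefined on degree 0")
    return Fraction(a * a + b * b, a * b)


def _w_F(a, b, alpha=None):
    return Fraction(a * a + b * b)


def _w_ReZG3(a, b, alpha=None):
    return Fraction(a * b * (a + b))


_BASE_DEFINITIONS: tuple[IndexDefinition, ...] = (
    IndexDefinition(
        "M1", _w_M1, ((1, ("Dc",)), (1, ("Dd",))),
        description="first Zagreb index, sum of endpoint-degree sums",
    ),
    IndexDefinition(
        "M2", _w_M2, ((1, ("Dc", "Dd")),),
        description="second Zagreb index, sum of endpoint-degree products",
    ),
    IndexDefinition(
        "mM2", _w_mM2, ((1, ("Ic", "Id")),),
        description="modified second Zagreb index, sum of 1/(a*b)",
    ),
    IndexDefinition(
        "AZI",
        _w_AZI,
        ((1, ("Dc", "Dc", "Dc", "Dd", "Dd", "Dd", "J", ("Q", -2), "Ic", "Ic", "Ic")),),
        description="augmented Zagreb index, sum of (a*b/(a+b-2))^3",
    ),
    IndexDefinition(
        "GR",
        _w_GR,
        ((1, (("Dpow", "c", "alpha"), ("Dpow", "d", "alpha"))),),
        needs_alpha=True,
        description="general Randic index, sum of (a*b)^alpha",
    ),
    IndexDefinition(
        "H", _w_H, ((2, ("J", "Ic")),),
        description="harmonic index, sum of 2/(a+b)",
    ),
    IndexDefinition(
        "ISI", _w_ISI, ((1, ("Dc", "Dd", "J", "Ic")),),
        description="inverse sum indeg index, sum of a*b/(a+b)",
    ),
    IndexDefinition(
        "SDD", _w_SDD, ((1, ("Id", "Dc")), (1, ("Ic", "Dd"))),
        description="symmetric division deg index, sum of (a^2+b^2)/(a*b)",
    ),
    IndexDefinition(
        "F", _w_F, ((1, ("Dc", "Dc")), (1, ("Dd", "Dd"))),
        description="forgotten index, sum of a^2 + b^2",
    ),
    IndexDefinition(
        "ReZG3", _w_ReZG3, ((1, ("Dc", "Dd", "Dc")), (1, ("Dc", "Dd", "Dd"))),
        description="redefined third Zagreb index, sum of a*b*(a+b)",
    ),
)

BASE_INDEX_NAMES: tuple[str, ...] = tuple(d.name for d in _BASE_DEFINITIONS)

# Registry covers the ten base names and their neighborhood analogues; the
# arithmetic is identical, only the partition basis differs.
INDEX_REGISTRY: dict[str, IndexDefinition] = {}
for _d in _BASE_DEFINITIONS:
    INDEX_REGISTRY[_d.name] = _d
    INDEX_REGISTRY["n" + _d.name] = IndexDefinition(
        "n" + _d.name,
        _d.edge_weight,
        _d.recipe,
        _d.needs_alpha,
        "neighborhood " + _d.description,
    )

ALL_INDEX_NAMES: tuple[str, ...] = tuple(INDEX_REGISTRY)


def expected_basis(name: str) -> Basis:
    """Partition basis an index name is conventionally computed on."""
    return "neighborhood" if name.startswith("n") else "degree"


def _lookup(name: str) -> IndexDefinition:
    try:
        return INDEX_REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown index {name!r}; known: {', '.join(ALL_INDEX_NAMES)}"
        ) from None


def index_from_partition(
    name: str, partition: EdgePartition, alpha: Optional[Fraction] = None
) -> Exact:
    """Direct summation route: sum of count * f(a, b) over partition classes."""
    defn = _lookup(name)
    if defn.needs_alpha and alpha is None:
        raise TypeError(f"index {name} requires an alpha parameter")
    total: Exact = Fraction(0)
    for (a, b), count in sorted(partition.classes.items()):
        total = total + count * defn.edge_weight(a, b, alpha)
    return total


def _apply_step(p: BivariatePolynomial, step: Step, alpha) -> BivariatePolynomial:
    if step == "Dc":
        return op_Dc(p)
    if step == "Dd":
        return op_Dd(p)
    if step == "Ic":
        return op_Ic(p)
    if step == "Id":
        return op_Id(p)
    if step == "J":
        return op_J(p)
    if isinstance(step, tuple) and step[0] == "Q":
        return op_Q(p, step[1])
    if isinstance(step, tuple) and step[0] == "Dpow":
        _, var, a = step
        exponent = alpha if a == "alpha" else a
        return op_D_power(p, exponent, var=var)
    raise ValueError(f"unknown recipe step {step!r}")


def index_from_polynomial(
    name: str, poly: BivariatePolynomial, alpha: Optional[Fraction] = None
) -> Exact:
    """Operator route: apply the registered recipe and evaluate at c = d = 1.

    Undefined-operator conditions (an Ic hitting a zero exponent, which is
    the polynomial-side face of the AZI divergence on a + b = 2) surface as
    :class:`UndefinedIndexError`.
    """
    defn = _lookup(name)
    if defn.needs_alpha and alpha is None:
        raise TypeError(f"index {name} requires an alpha parameter")
    acc = BivariatePolynomial.zero()
    try:
        for weight, chain in defn.recipe:
            branch = poly
            for step in chain:
                branch = _apply_step(branch, step, alpha)
            acc = acc + branch.scale(weight)
    except UndefinedOperatorError as exc:
        raise UndefinedIndexError(f"{name} undefined on this polynomial: {exc}") from exc
    return acc.evaluate(1, 1)


@dataclass(frozen=True)
class IndexReportRow:
    name: str
    alpha: Optional[Fraction]
    partition_value: Optional[Exact]
    polynomial_value: Optional[Exact]
    defined: bool
    agree: Optional[bool]
    message: str = ""


def _exactly_equal(x: Exact, y: Exact) -> bool:
    if isinstance(x, Fraction) and isinstance(y, Fraction):
        return x == y
    import sympy

    return sympy.simplify(sympy.sympify(x) - sympy.sympify(y)) == 0


def all_indices(
    g: MolecularGraph,
    alpha_values: Sequence[Fraction] = DEFAULT_ALPHAS,
) -> list[IndexReportRow]:
    """Compute all twenty indices by both routes with per-cell agreement.

    General Randic rows are emitted once per alpha value.  Indices that are
    undefined on the graph (AZI on a graph with a (1,1)-degree edge, for
    instance) are reported as explicit undefined rows, never silently
    dropped.
    """
    partitions = {
        basis: edge_partition(g, basis) for basis in ("degree", "neighborhood")
    }
    polys = {basis: mpoly_from_partition(p) for basis, p in partitions.items()}
    rows: list[IndexReportRow] = []
    for name, defn in INDEX_REGISTRY.items():
        basis = expected_basis(name)
        alphas: tuple[Optional[Fraction], ...]
        alphas = tuple(alpha_values) if defn.needs_alpha else (None,)
        for alpha in alphas:
            try:
                pv = index_from_partition(name, partitions[basis], alpha)
                qv = index_from_polynomial(name, polys[basis], alpha)
            except UndefinedIndexError as exc:
                rows.append(
                    IndexReportRow(name, alpha, None, None, False, None, str(exc))
                )
                continue
            rows.append(
                IndexReportRow(name, alpha, pv, qv, True, _exactly_equal(pv, qv))
            )
    return rows
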