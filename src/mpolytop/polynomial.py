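"""Sparse bivariate polynomials and the operator calculus over them.

The degree-based generating polynomial of a graph is
``M(L) = sum over classes (a,b) of |N_(a,b)| c^a d^b`` and its neighborhood
analogue replaces endpoint degrees by neighborhood degree sums.  Topological
indices are extracted from these polynomials by composing a small set of
operators and evaluating at c = d = 1:

    Dc = c * d/dc     (multiplies each term by its c-exponent)
    Dd = d * d/dd
    Ic = integral_0^c P(t, d)/t dt   (divides each term by its c-exponent)
    Id = the d-analogue
    J  : P(c, d) -> P(c, c)          (exponent merge)
    Q_alpha : multiply by c^alpha    (exponent shift; alpha may be negative)

Coefficients are exact end-to-end: :class:`fractions.Fraction` for every
rational chain, promoted to exact sympy numbers only by the generalized
degree-power operator at non-integer exponents (general Randic at
alpha = 1/2 genuinely leaves the rationals).
"""

from __future__ import annotations

import json
from fractions import Fraction
from typing import TYPE_CHECKING, Mapping, Union

if TYPE_CHECKING:  # pragma: no cover
    from .graphs import EdgePartition

__all__ = [
    "BivariatePolynomial",
    "UndefinedOperatorError",
    "mpoly_from_partition",
    "op_Dc",
    "op_Dd",
    "op_Ic",
    "op_Id",
    "op_J",
    "op_Q",
    "op_D_power",
]

Coefficient = Union[Fraction, object]  # Fraction, or exact sympy number


class UndefinedOperatorError(ArithmeticError):
    """An operator was applied outside its domain (e.g. Ic on a c^0 term)."""


def _as_exact(x) -> Coefficient:
    if isinstance(x, Fraction):
        return x
    if isinstance(x, int):
        return Fraction(x)
    if isinstance(x, float):
        raise TypeError("coefficients must be exact; got a float")
    return x  # assume exact sympy scalar


class BivariatePolynomial:
    """Sparse polynomial in c and d with exact coefficients.

    Terms map exponent pairs (a, b) to nonzero coefficients; integer
    exponents may be negative (the exponent-shift operator can produce
    them).  Arithmetic never touches floating point.
    """

    __slots__ = ("terms",)

    def __init__(self, terms: Mapping[tuple[int, int], Coefficient] = ()) -> None:
        cleaned: dict[tuple[int, int], Coefficient] = {}
        items = terms.items() if hasattr(terms, "items") else terms
        for (a, b), coef in items:
            coef = _as_exact(coef)
            if coef != 0:
                cleaned[(int(a), int(b))] = coef
        self.terms = cleaned

    @classmethod
    def zero(cls) -> "BivariatePolynomial":
        return cls()

    @classmethod
    def monomial(cls, coef, a: int, b: int) -> "BivariatePolynomial":
        return cls({(a, b): coef})

    def __add__(self, other: "BivariatePolynomial") -> "BivariatePolynomial":
        out = dict(self.terms)
        for key, coef in other.terms.items():
            out[key] = out.get(key, Fraction(0)) + coef
        return BivariatePolynomial(out)

    def __sub__(self, other: "BivariatePolynomial") -> "BivariatePolynomial":
        return self + other.scale(-1)

    def scale(self, k) -> "BivariatePolynomial":
        k = _as_exact(k)
        return BivariatePolynomial({key: k * coef for key, coef in self.terms.items()})

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BivariatePolynomial):
            return NotImplemented
        return self.terms == other.terms

    def __hash__(self) -> int:
        return hash(frozenset(self.terms.items()))

    def evaluate(self, c0, d0) -> Coefficient:
        """Exact evaluation; zero base with a negative exponent is an error."""
        c0, d0 = _as_exact(c0), _as_exact(d0)
        total: Coefficient = Fraction(0)
        for (a, b), coef in sorted(self.terms.items()):
            if (c0 == 0 and a < 0) or (d0 == 0 and b < 0):
                raise ZeroDivisionError(
                    f"term c^{a} d^{b}: zero base with negative exponent"
                )
            total = total + coef * c0**a * d0**b
        return total

    def coefficient_sum(self) -> Coefficient:
        return self.evaluate(1, 1)

    def to_text(self) -> str:
        """Canonical rendering: terms sorted lexicographically by (a, b)."""
        if not self.terms:
            return "0"
        parts = [
            f"{coef}*c^{a}*d^{b}" for (a, b), coef in sorted(self.terms.items())
        ]
        return " + ".join(parts)

    def to_json(self) -> str:
        """Structured rendering with coefficients as exact rational strings."""
        return json.dumps(
            {
                "terms": [
                    {"a": a, "b": b, "coef": str(coef)}
                    for (a, b), coef in sorted(self.terms.items())
                ]
            }
        )

    def __repr__(self) -> str:
        return f"BivariatePolynomial({self.to_text()})"


def mpoly_from_partition(partition: "EdgePartition") -> BivariatePolynomial:
    """Build the generating polynomial: each class (a,b) with count k
    contributes the term k c^a d^b.  The coefficient sum equals |E|."""
    return BivariatePolynomial(
        {(a, b): Fraction(count) for (a, b), count in partition.classes.items()}
    )


def op_Dc(p: BivariatePolynomial) -> BivariatePolynomial:
    """Dc = c * dP/dc: multiply each term's coefficient by its c-exponent."""
    return BivariatePolynomial(
        {(a, b): coef * a for (a, b), coef in p.terms.items()}
    )


def op_Dd(p: BivariatePolynomial) -> BivariatePolynomial:
    """Dd = d * dP/dd: multiply each term's coefficient by its d-exponent."""
    return BivariatePolynomial(
        {(a, b): coef * b for (a, b), coef in p.terms.items()}
    )


def op_Ic(p: BivariatePolynomial) -> BivariatePolynomial:
    """Ic: divide each term's coefficient by its c-exponent.

    Undefined on any term with c-exponent 0 — this is exactly why the
    augmented Zagreb index diverges on a (1,1)-degree edge.
    """
    out: dict[tuple[int, int], Coefficient] = {}
    for (a, b), coef in p.terms.items():
        if a == 0:
            raise UndefinedOperatorError("Ic applied to a term with c-exponent 0")
        out[(a, b)] = coef / a
    return BivariatePolynomial(out)


def op_Id(p: BivariatePolynomial) -> BivariatePolynomial:
    """Id: divide each term's coefficient by its d-exponent (b > 0 required)."""
    out: dict[tuple[int, int], Coefficient] = {}
    for (a, b), coef in p.terms.items():
        if b == 0:
            raise UndefinedOperatorError("Id applied to a term with d-exponent 0")
        out[(a, b)] = coef / b
    return BivariatePolynomial(out)


def op_J(p: BivariatePolynomial) -> BivariatePolynomial:
    """J: substitute d -> c, merging colliding exponents by addition."""
    out: dict[tuple[int, int], Coefficient] = {}
    for (a, b), coef in p.terms.items():
        key = (a + b, 0)
        out[key] = out.get(key, Fraction(0)) + coef
    return BivariatePolynomial(out)


def op_Q(p: BivariatePolynomial, alpha: int) -> BivariatePolynomial:
    """Q_alpha: multiply by c^alpha, shifting every c-exponent by alpha."""
    return BivariatePolynomial(
        {(a + alpha, b): coef for (a, b), coef in p.terms.items()}
    )


def op_D_power(p: BivariatePolynomial, alpha, var: str = "c") -> BivariatePolynomial:
    """Generalized degree-power operator Dc^alpha (or Dd^alpha).

    Multiplies each term's coefficient by (exponent)^alpha.  For integer
    alpha this stays in the rationals; for fractional alpha the coefficient
    is promoted to an exact sympy radical.  Negative alpha on a zero
    exponent is undefined.
    """
    import sympy

    out: dict[tuple[int, int], Coefficient] = {}
    alpha_is_int = isinstance(alpha, int) or (
        isinstance(alpha, Fraction) and alpha.denominator == 1
    )
    for (a, b), coef in p.terms.items():
        e = a if var == "c" else b
        if e == 0 and ((not alpha_is_int) or int(alpha) < 0):
            raise UndefinedOperatorError(
                f"D{var}^{alpha} on a term with {var}-exponent 0"
            )
        if alpha_is_int:
            factor: Coefficient = Fraction(e) ** int(alpha)
        else:
            factor = sympy.Integer(e) ** sympy.Rational(str(alpha))
        out[(a, b)] = coef * factor
    return BivariatePolynomial(out)
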