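# Methods

## Graph model

A molecular graph is simple and undirected: atoms are vertices, bonds are
edges, bond order and element identity are discarded because every index
implemented here depends on adjacency alone. Hydrogens are **kept** by
default when reading MOL/SDF files — the cyclodextrin-conjugate family has
degree-1 vertices, so terminal atoms are part of the model — and
suppression is an explicit flag. Disconnected graphs and isolated vertices
are permitted everywhere except where an index's weight rule divides by
zero, in which case the index raises an explicit undefined-index error
rather than skipping terms.

Two vertex statistics drive everything: the degree ρ_r and the open
neighborhood degree sum N(r) = Σ_{s∼r} ρ_s. Edges are grouped by the
unordered pair of endpoint statistics (canonically min ≤ max); class
counts always sum to |E|.

## Polynomials and operators

The generating polynomial Σ |N_(a,b)| c^a d^b is held as a sparse map from
exponent pairs to coefficients. Coefficients are `fractions.Fraction`
end-to-end; no floating point enters any index value. The operator set is
exactly the one the index recipes need: Dc = c ∂/∂c and Dd (multiply a
term by its exponent), Ic and Id (divide by the exponent; an exponent of
zero is a domain error, which is the polynomial-side face of the augmented
Zagreb index diverging on an edge with a + b = 2), J (substitute d → c,
merging exponents additively), and Q_α (shift the c-exponent by α; the
definition is read as multiplication by c^α, forced by the Q₋₂ appearing
in the augmented-Zagreb recipe). A generalized degree-power operator
Dc^α/Dd^α backs the general Randić index; for non-integer α (the defaults
include ±1/2) a coefficient like 2^(1/2) is irrational, so those
coefficients are promoted to exact sympy radicals and route-equivalence
comparisons remain exact symbolically. This is the one place the
coefficient domain leaves the rationals, and it never reaches serialized
output (decimal rendering is a formatting concern only; reports print
exact rational strings with float companions).

Two typeset conventions follow the operator formulations rather than the
occasionally garbled formula column: the general Randić weight is the
product (ρ_r ρ_s)^α (its operator form Dc^α Dd^α and the family expansion
with terms 2^α, 8^α, 4^α, 16^α — endpoint-degree products — force this
reading), and the symmetric division deg weight is (a² + b²)/(ab) (forced
by the operator form Dc Id + Ic Dd and the per-class weights in the
worked proofs).

## Index registry

Each of the ten base indices (M1, M2, mM2, AZI, GR_α, H, ISI, SDD, F,
ReZG3) is registered once with both a weight rule and an operator recipe;
the neighborhood analogues (nM1, …) reuse the same arithmetic on
neighborhood-basis partitions. Recipes are data — small chains over
{Dc, Dd, Ic, Id, J, Q_α, Dpow} summed with integer weights and evaluated
at (1, 1) — so the registry is extensible without new control flow. The
standing property test compares, on seeded random graphs, the partition
route, the operator route, and a brute-force loop over raw edges that
shares no code with either; agreement is exact rational (or exact
symbolic, for fractional α) equality.

## The cyclodextrin-conjugate family

The family is represented by its partition model, not a concrete graph:
every closed-form quantity depends only on the class counts, and no
atom-level connection table for the conjugate is published. The degree
basis has four classes ((1,2): 3n+15, (2,4): 7n+35, (1,4): 7n+35,
(4,4): 5n+25) plus per-degree vertex counts (10n+50 of degree 1, 5n+25 of
degree 2, 6n+30 of degree 4); the neighborhood basis has ten classes. The
structural invariant intercept = 5 × slope holds for every class — the
base is five repeat units — and is inherited by every index's linear form.

Closed forms are recovered by evaluating the index at n ∈ {0, …, 3},
differencing exactly, and demanding zero residual at n ∈ {4, 5}; two
points determine a line, and the extra points guard against registry bugs
and non-linear combinations (which raise rather than fit).

`realize_graph` produces an actual simple graph matching the degree-basis
model: a cyclic chain of n + 5 identical 21-vertex monomer gadgets (six
degree-4 hubs, five degree-2 bridges, ten pendants; 22 edges per repeat
unit counting one hub-to-hub inter-monomer link). The construction is
deterministic and validated against the model after building; the search
problem the interface allows for reduces, for this model, to this verified
gadget. The realization's *neighborhood* partition is reported but not
required to match the published neighborhood classes — and it does not,
which is consistent with the published neighborhood coefficients being
partly irreconcilable with the published class list (below). Whether any
simple cyclic (n+5)-mer realizes both published partitions simultaneously
is open; this package does not claim one.

## Verification of the published coefficients

`verify_printed_theorems` compares each published closed-form coefficient
against exact recomputation from the published partitions. Comparison
policy: coefficients printed as integers or fractions must match exactly;
coefficients printed as decimals must agree within one unit in the last
printed place, because the published decimals are truncated rather than
rounded in at least two places (the neighborhood augmented-Zagreb slope is
exactly 1917.04768…, printed 1917.047; the neighborhood
modified-second-Zagreb intercept is exactly 3.19657…, printed 3.1965).

Fourteen coefficient pairs verify. Six are flagged as mismatches, each
internally consistent with the 5×-slope structure but inconsistent with
direct summation over the published class lists:

| index | printed | computed exactly |
|---|---|---|
| M2 intercept | 830 | 850 (= 5 × 170; the worked proof's "80n+380" term should be 80n+400) |
| mM2 slope | 61/16 | 71/16 (5 × 71/16 = 355/16 matches the printed intercept) |
| H intercept | 483/12 | 503/12 (printed slope 503/60 × 5 = 503/12) |
| nH slope | 3.3666 | 3.20531… |
| nISI slope | 88.145 | 77.88886… |
| nmM2 slope | 0.37637 | 0.63931… |

The report never overwrites computed values; the exact recomputation is
authoritative in every downstream table. Whether the neighborhood trio
reflects a variant partition is not decidable from the published text, so
no correction is guessed.

## QSPR layer

Simple ordinary least squares of one property on one descriptor, the model
form of the published regression tables. Statistics follow the conventions
of the statistics package behind those tables: R is the absolute Pearson
correlation (the slope's sign is visible in the model equation; all
published R values are positive, consistent with |r|), RMSE is the
residual standard error √(SSE/(n−2)) (a flag switches to the population
form √(SSE/n)), and adjusted R² = 1 − (1−R²)(n−1)/(n−2). Fits require at
least three complete pairs and a non-constant descriptor; insufficient
data yields an explicit skip record. The drug property values behind the
published tables are external (a chemical database, not printed), so the
shipped pipeline exercises the layer on synthetic tables; replicating the
published rows requires a user-supplied CSV.

## Synthetic data

Generators are pure functions of their arguments with one
`numpy.random.default_rng(seed)` stream per call. Random graphs draw each
unordered vertex pair independently with probability p (defaults in tests:
12–30 vertices, p ≈ 0.2–0.35, a regime that exercises all twenty indices
including undefined-AZI cases and disconnected graphs); they are
combinatorial fixtures, not chemically realistic molecules — no valence
constraints, no connectivity guarantee — so passing tests demonstrate
arithmetic correctness of the index machinery, not chemical plausibility.
Property tables put the descriptor on the grid 1..n and add Gaussian noise
to an exact line; the default shape (n = 8 compounds, intercept 93.33,
slope 3.098) mirrors a published boiling-point model purely as a plausible
parameterization. The brute-force index oracle loops over raw edges with
no partition or polynomial machinery and is the reference in every
equivalence test.

## Problem sizes and numerical choices

The equivalence property tests use 100 seeded random graphs at 12 vertices
— large enough that both partition bases are rich (dozens of distinct
neighborhood classes across the sweep) while keeping the full
three-route × 20-index × 4-α sweep a few seconds of exact arithmetic.
Family computations are exact rational throughout; decimal output rounds
half-even at the printed precision. Ties, degenerate inputs, and domain
errors (AZI on a (1,1) edge, Ic on a zero exponent, constant QSPR
descriptors, n < 0) raise typed exceptions rather than returning
sentinels.

## Known limitations

- No distance-based indices (Wiener, Hosoya) and no closed-neighborhood
  variants; the closed neighborhood sum N[s] is definable but unused by
  every implemented formula.
- No SMILES parsing, aromaticity perception, or 3-D structure handling;
  MOL/SDF reading is V2000-only and adjacency-only.
- The QSPR layer is deliberately simple regression only — no multiple
  regression, cross-validation, or multicollinearity diagnostics.
- `realize_graph` certifies degree-partition fidelity only; it makes no
  claim to reproduce actual cyclodextrin chemistry (glucose ring topology,
  glycosidic linkages).
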