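"""Seeded generators and the brute-force index oracle.

Everything downstream is testable offline against these: Erdos-Renyi-style
random simple graphs, the canonical small graphs whose index values are
known in closed form, and noisy linear property tables with the statistical
structure the QSPR layer assumes (property = b0 + b1 * descriptor + Gaussian
noise).  Every generator is a pure function of its arguments: one
``numpy.random.default_rng(seed)`` stream per call, no global state.

``brute_force_index`` recomputes any index by looping over raw edges with
no partition grouping and no polynomial machinery — the independent oracle
the equivalence property tests compare both production routes against.
"""

from __future__ import annotations

from fractions import Fraction
from itertools import combinations
from typing import Optional

import numpy as np
import pandas as pd

from .graphs import MolecularGraph, degree_map, nbhd_degree_sum_map
from .indices import INDEX_REGISTRY
from .qspr import PropertyTable

__all__ = [
    "random_graph",
    "canonical_graph",
    "noisy_linear_table",
    "brute_force_index",
]


def random_graph(v: int, edge_prob: float, seed: int) -> MolecularGraph:
    """Simple graph on v vertices; each unordered pair is an edge
    independently with probability edge_prob.  Isolated vertices are kept."""
    if v < 1:
        raise ValueError(f"need at least one vertex, got {v}")
    if not 0.0 <= edge_prob <= 1.0:
        raise ValueError(f"edge_prob must be in [0, 1], got {edge_prob}")
    rng = np.random.default_rng(seed)
    labels = [f"v{i}" for i in range(v)]
    edges = [
        (labels[i], labels[j])
        for i, j in combinations(range(v), 2)
        if rng.random() < edge_prob
    ]
    return MolecularGraph(labels, edges)


def canonical_graph(name: str) -> MolecularGraph:
    """Named small graphs: ``path_k``, ``cycle_k``, ``star_k`` (k leaves),
    ``k2``.  Vertices are labeled v0, v1, ... in construction order."""
    kind, _, num = name.partition("_")
    if name == "k2":
        kind, num = "path", "2"
    if kind not in {"path", "cycle", "star"} or not num.isdigit():
        raise ValueError(f"unknown canonical graph {name!r}")
    k = int(num)
    if not 1 <= k <= 1000:
        raise ValueError(f"size out of range for {name!r}")
    labels = [f"v{i}" for i in range(k + 1 if kind == "star" else k)]
    if kind == "path":
        edges = [(labels[i], labels[i + 1]) for i in range(k - 1)]
    elif kind == "cycle":
        if k < 3:
            raise ValueError("cycles need at least 3 vertices")
        edges = [(labels[i], labels[(i + 1) % k]) for i in range(k)]
    else:  # star with k leaves: center v0
        edges = [(labels[0], labels[i]) for i in range(1, k + 1)]
    return MolecularGraph(labels, edges)


def noisy_linear_table(
    n: int,
    beta0: float,
    beta1: float,
    sigma: float,
    seed: int,
    property_name: str = "Y",
    descriptor_name: str = "X",
) -> PropertyTable:
    """Property table with y = beta0 + beta1 * x + N(0, sigma^2).

    The descriptor x runs over the even grid 1, 2, ..., n; noise draws come
    from the seeded stream, so identical arguments give identical tables.
    """
    if n < 3:
        raise ValueError(f"need n >= 3, got {n}")
    if sigma < 0:
        raise ValueError(f"sigma must be nonnegative, got {sigma}")
    rng = np.random.default_rng(seed)
    x = np.arange(1, n + 1, dtype=float)
    y = beta0 + beta1 * x + (rng.normal(0.0, sigma, size=n) if sigma > 0 else 0.0)
    df = pd.DataFrame(
        {descriptor_name: x, property_name: y},
        index=pd.Index([f"cpd{i}" for i in range(1, n + 1)], name="compound"),
    )
    return PropertyTable(
        data=df, properties=(property_name,), descriptors=(descriptor_name,)
    )


def brute_force_index(
    g: MolecularGraph, name: str, alpha: Optional[Fraction] = None
):
    """Independent oracle: sum f over raw edges, no partitions, no polynomials."""
    defn = INDEX_REGISTRY[name]
    stat = nbhd_degree_sum_map(g) if name.startswith("n") else degree_map(g)
    total = Fraction(0)
    for r, s in g.iter_edges():
        a, b = sorted((stat[r], stat[s]))
        total = total + defn.edge_weight(a, b, alpha)
    return total
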