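"""Molecular graphs, degree bookkeeping and edge partitions.

A molecular graph here is a simple undirected graph: atoms are vertices,
bonds are edges, and bond order is discarded because every index computed
downstream depends only on adjacency.  Two vertex statistics drive the whole
pipeline: the degree of a vertex and its open neighborhood degree sum
(the sum of the degrees of its neighbors).  Grouping edges by the unordered
pair of endpoint statistics yields the edge partition from which the
generating polynomials are built.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import IO, Iterable, Iterator, Literal, Mapping

import networkx as nx

__all__ = [
    "MolecularGraph",
    "EdgePartition",
    "MalformedInputError",
    "UnsupportedFormatError",
    "read_edge_list",
    "read_mol",
    "read_sdf",
    "degree_map",
    "nbhd_degree_sum_map",
    "edge_partition",
]

Basis = Literal["degree", "neighborhood"]


class MalformedInputError(ValueError):
    """Raised when an input stream violates the documented format."""


class UnsupportedFormatError(ValueError):
    """Raised for recognized-but-unsupported formats (e.g. MOL V3000)."""


class MolecularGraph:
    """Simple undirected graph with opaque string vertex labels.

    Backed by a :class:`networkx.Graph`; construction rejects self-loops and
    silently collapses duplicate edges (the graph is simple by contract).
    """

    def __init__(
        self,
        vertices: Iterable[str] = (),
        edges: Iterable[tuple[str, str]] = (),
    ) -> None:
        g = nx.Graph()
        g.add_nodes_from(str(v) for v in vertices)
        for r, s in edges:
            r, s = str(r), str(s)
            if r == s:
                raise MalformedInputError(f"self-loop on vertex {r!r}")
            g.add_edge(r, s)
        self._g = g

    @classmethod
    def from_networkx(cls, g: nx.Graph) -> "MolecularGraph":
        if any(r == s for r, s in g.edges):
            raise MalformedInputError("graph contains a self-loop")
        out = cls()
        out._g = nx.Graph()
        out._g.add_nodes_from(str(v) for v in g.nodes)
        out._g.add_edges_from((str(r), str(s)) for r, s in g.edges)
        return out

    def to_networkx(self) -> nx.Graph:
        return self._g.copy()

    @property
    def vertices(self) -> frozenset[str]:
        return frozenset(self._g.nodes)

    @property
    def edges(self) -> frozenset[frozenset[str]]:
        return frozenset(frozenset(e) for e in self._g.edges)

    def iter_edges(self) -> Iterator[tuple[str, str]]:
        return iter(sorted(tuple(sorted(e)) for e in self._g.edges))

    @property
    def n_vertices(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def degree(self, v: str) -> int:
        return self._g.degree[v]

    def neighbors(self, v: str) -> Iterator[str]:
        return self._g.neighbors(v)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MolecularGraph):
            return NotImplemented
        return self.vertices == other.vertices and self.edges == other.edges

    def __hash__(self) -> int:
        return hash((self.vertices, self.edges))

    def __repr__(self) -> str:
        return f"MolecularGraph(|V|={self.n_vertices}, |E|={self.n_edges})"


@dataclass(frozen=True)
class EdgePartition:
    """Edge counts grouped by unordered endpoint-statistic pairs.

    ``classes[(a, b)]`` with ``a <= b`` is the number of edges whose endpoint
    degrees (or neighborhood degree sums, per ``basis``) are ``a`` and ``b``.
    Empty classes are never stored.
    """

    classes: Mapping[tuple[int, int], int]
    basis: Basis = "degree"

    def __post_init__(self) -> None:
        cleaned: dict[tuple[int, int], int] = {}
        for (a, b), count in self.classes.items():
            if a > b:
                raise ValueError(f"class key {(a, b)} not canonically ordered")
            if count < 0:
                raise ValueError(f"negative count for class {(a, b)}")
            if count > 0:
                cleaned[(int(a), int(b))] = int(count)
        object.__setattr__(self, "classes", cleaned)

    @property
    def total_edges(self) -> int:
        return sum(self.classes.values())

    def items(self) -> Iterator[tuple[tuple[int, int], int]]:
        return iter(sorted(self.classes.items()))


def read_edge_list(stream: IO[str] | str) -> MolecularGraph:
    """Parse a whitespace-delimited edge list into a molecular graph.

    Each non-blank, non-comment line holds exactly two labels; ``#`` starts a
    comment; repeated lines for the same unordered pair collapse to one edge.
    """
    if isinstance(stream, str):
        lines = stream.splitlines()
    else:
        lines = stream.read().splitlines()
    edges: list[tuple[str, str]] = []
    vertices: list[str] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        tokens = line.split()
        if len(tokens) != 2:
            raise MalformedInputError(
                f"line {lineno}: expected two labels, got {len(tokens)}"
            )
        r, s = tokens
        if r == s:
            raise MalformedInputError(f"line {lineno}: self-loop on {r!r}")
        vertices += [r, s]
        edges.append((r, s))
    return MolecularGraph(vertices, edges)


def _mol_from_block(block: str, suppress_hydrogens: bool) -> MolecularGraph:
    from rdkit import Chem

    lines = block.splitlines()
    if len(lines) < 4:
        raise UnsupportedFormatError("truncated MOL block (no counts line)")
    counts = lines[3]
    if "V3000" in counts:
        raise UnsupportedFormatError("MOL V3000 blocks are not supported")
    mol = Chem.MolFromMolBlock(block, sanitize=False, removeHs=False)
    if mol is None:
        raise UnsupportedFormatError("unreadable MOL V2000 block")
    vertices: list[str] = []
    keep: dict[int, str] = {}
    for atom in mol.GetAtoms():
        label = f"{atom.GetIdx() + 1}{atom.GetSymbol()}"
        if suppress_hydrogens and atom.GetSymbol() == "H":
            continue
        keep[atom.GetIdx()] = label
        vertices.append(label)
    edges = [
        (keep[b.GetBeginAtomIdx()], keep[b.GetEndAtomIdx()])
        for b in mol.GetBonds()
        if b.GetBeginAtomIdx() in keep and b.GetEndAtomIdx() in keep
    ]
    return MolecularGraph(vertices, edges)


def read_mol(stream: IO[str] | str, suppress_hydrogens: bool = False) -> MolecularGraph:
    """Read a single MDL MOL (V2000) block; bond orders are ignored.

    Atom vertices are labeled ``<1-based index><element symbol>``.  With
    ``suppress_hydrogens`` set, H atoms and their incident bonds are dropped.
    """
    text = stream if isinstance(stream, str) else stream.read()
    first = text.split("$$$$", 1)[0]
    return _mol_from_block(first, suppress_hydrogens)


def read_sdf(
    stream: IO[str] | str, suppress_hydrogens: bool = False
) -> list[MolecularGraph]:
    """Read a multi-record SDF (V2000) into a list of molecular graphs."""
    text = stream if isinstance(stream, str) else stream.read()
    graphs = []
    for block in text.split("$$$$"):
        if block.strip():
            graphs.append(_mol_from_block(block.lstrip("\n"), suppress_hydrogens))
    return graphs


def degree_map(g: MolecularGraph) -> dict[str, int]:
    """Degree of every vertex; isolated vertices map to 0."""
    nxg = g.to_networkx()
    return {v: d for v, d in nxg.degree}


def nbhd_degree_sum_map(g: MolecularGraph) -> dict[str, int]:
    """Open neighborhood degree sum N(r) = sum of deg(s) over neighbors s."""
    nxg = g.to_networkx()
    deg = dict(nxg.degree)
    return {v: sum(deg[u] for u in nxg.neighbors(v)) for v in nxg.nodes}


def edge_partition(g: MolecularGraph, basis: Basis = "degree") -> EdgePartition:
    """Group edges by the unordered pair of endpoint statistics.

    For ``basis="degree"`` an edge rs lands in class
    ``(min(deg r, deg s), max(deg r, deg s))``; for ``basis="neighborhood"``
    the neighborhood degree sums N(r), N(s) are used instead.  Counts always
    sum to the number of edges.
    """
    if basis == "degree":
        stat = degree_map(g)
    elif basis == "neighborhood":
        stat = nbhd_degree_sum_map(g)
    else:
        raise ValueError(f"unknown basis {basis!r}")
    classes: dict[tuple[int, int], int] = {}
    for r, s in g.iter_edges():
        key = (min(stat[r], stat[s]), max(stat[r], stat[s]))
        classes[key] = classes.get(key, 0) + 1
    return EdgePartition(classes=classes, basis=basis)
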