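"""Causal graph and linear structural-equation parameters.

The augmented causal DAG holds one vertex per latent gene expression level
plus one vertex for the phenotype Y.  Each vertex ``i`` follows the linear
structural equation ``Z_i = sum_j W[j, i] * Z_j + E_i`` over its parents
``j``, with mutually independent Gaussian error terms ``E_i``.  Vertices are
integer indices internally; string labels appear only at I/O boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "CausalGraph",
    "SemParameters",
    "topological_order",
    "relatives",
    "total_effects",
    "write_edge_list",
    "read_edge_list",
]


class CycleError(ValueError):
    """Raised when a directed cycle is found where a DAG is required."""


@dataclass(frozen=True)
class CausalGraph:
    """A directed graph over ``n_vertices`` integer-indexed vertices.

    Parameters
    ----------
    n_vertices:
        Number of vertices.
    edges:
        Ordered ``(parent, child)`` pairs.
    vertex_labels:
        Optional identifiers, one per vertex (defaults to ``V0..V{n-1}``).
    """

    n_vertices: int
    edges: frozenset[tuple[int, int]]
    vertex_labels: tuple[str, ...] = field(default=())

    def __post_init__(self):
        if self.n_vertices < 0:
            raise ValueError("n_vertices must be nonnegative")
        edges = frozenset((int(a), int(b)) for a, b in self.edges)
        object.__setattr__(self, "edges", edges)
        for a, b in edges:
            if not (0 <= a < self.n_vertices and 0 <= b < self.n_vertices):
                raise ValueError(f"edge ({a}, {b}) out of range [0, {self.n_vertices})")
            if a == b:
                raise CycleError(f"self-loop at vertex {a}")
        if not self.vertex_labels:
            object.__setattr__(
                self, "vertex_labels", tuple(f"V{i}" for i in range(self.n_vertices))
            )
        elif len(self.vertex_labels) != self.n_vertices:
            raise ValueError("vertex_labels length must equal n_vertices")

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(range(self.n_vertices))
        g.add_edges_from(self.edges)
        return g

    def parents(self, i: int) -> set[int]:
        self._check_index(i)
        return {a for a, b in self.edges if b == i}

    def children(self, i: int) -> set[int]:
        self._check_index(i)
        return {b for a, b in self.edges if a == i}

    def _check_index(self, i: int) -> None:
        if not (0 <= i < self.n_vertices):
            raise IndexError(f"vertex {i} out of range [0, {self.n_vertices})")


def topological_order(graph: CausalGraph) -> list[int]:
    """Topological order with ties broken by ascending vertex index.

    Raises :class:`CycleError` naming one directed cycle if the graph is not
    acyclic.
    """
    g = graph.to_networkx()
    try:
        return list(nx.lexicographical_topological_sort(g))
    except nx.NetworkXUnfeasible:
        cycle = nx.find_cycle(g)
        path = " -> ".join(str(a) for a, _ in cycle) + f" -> {cycle[0][0]}"
        raise CycleError(f"graph contains a directed cycle: {path}") from None


def relatives(
    graph: CausalGraph,
    i: int,
    mode: Literal["parents", "ancestors", "descendants"],
) -> set[int]:
    """Parents, ancestors or descendants of vertex ``i``.

    Ancestor and descendant sets include ``i`` itself, following the
    convention that a directed path of length zero relates a vertex to
    itself.  Consumers that need strict relatives remove ``i`` explicitly.
    """
    graph._check_index(i)
    g = graph.to_networkx()
    if mode == "parents":
        return set(g.predecessors(i))
    if mode == "ancestors":
        return nx.ancestors(g, i) | {i}
    if mode == "descendants":
        return nx.descendants(g, i) | {i}
    raise ValueError(f"unknown mode {mode!r}")


@dataclass
class SemParameters:
    """Weights and error scales of a linear Gaussian SEM over a DAG.

    ``weights[j, i]`` is the coefficient of parent ``j`` in the equation of
    child ``i`` and is nonzero exactly on the edge set.  ``target_index``
    marks the phenotype vertex Y (at least one parent, no children).
    ``knockdown_offset`` is the additive shift subtracted inside a perturbed
    gene's structural equation, modelling CRISPRi repression.
    """

    graph: CausalGraph
    weights: np.ndarray
    error_scale: np.ndarray
    target_index: int | None = None
    knockdown_offset: float = 2.0

    def __post_init__(self):
        n = self.graph.n_vertices
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (n, n):
            raise ValueError("weights must be (n_vertices, n_vertices)")
        support = {(int(a), int(b)) for a, b in zip(*np.nonzero(self.weights))}
        if support - set(self.graph.edges):
            raise ValueError("weight support must be a subset of the edge set")
        self.error_scale = np.broadcast_to(
            np.asarray(self.error_scale, dtype=float), (n,)
        ).copy()
        if np.any(self.error_scale <= 0):
            raise ValueError("error_scale must be positive")
        if self.target_index is not None:
            self.validate_target()

    def validate_target(self) -> None:
        t = self.target_index
        if not self.graph.parents(t):
            raise ValueError(f"target vertex {t} has no parents")
        if self.graph.children(t):
            raise ValueError(f"target vertex {t} has children")

    @property
    def n_vertices(self) -> int:
        return self.graph.n_vertices

    def gene_indices(self) -> np.ndarray:
        """All vertex indices except the target (the measured genes)."""
        if self.target_index is None:
            return np.arange(self.n_vertices)
        return np.array(
            [i for i in range(self.n_vertices) if i != self.target_index]
        )


def _reduced_form(sem: SemParameters) -> np.ndarray:
    """Map error terms to vertex values: ``values = errors @ M`` with
    ``M = (I - W)^{-1}``.  Solved along the topological order; exact for any
    DAG."""
    n = sem.n_vertices
    ident = np.eye(n)
    # (I - W)^T is permutation-similar to a lower-triangular matrix, so the
    # system is never singular for a DAG.
    return np.linalg.solve((ident - sem.weights).T, ident).T


def total_effects(sem: SemParameters) -> np.ndarray:
    """Reduced-form total effect ``tau_i`` of each gene's error term on Y.

    Writing Y as a linear combination of all error terms, ``tau_i`` is the
    coefficient of ``E_i``; it is exactly zero iff no directed path leads
    from gene ``i`` to Y.  Returns a length-p vector over genes only.
    """
    if sem.target_index is None:
        raise ValueError("target_index must be set")
    m = _reduced_form(sem)
    tau_full = m[:, sem.target_index]
    # Zero out float dust for path-free genes via reachability.
    anc = relatives(sem.graph, sem.target_index, "ancestors")
    mask = np.array([i in anc for i in range(sem.n_vertices)])
    tau_full = np.where(mask, tau_full, 0.0)
    return tau_full[sem.gene_indices()]


def write_edge_list(sem: SemParameters, path: str | Path) -> None:
    """Serialize a SEM as TSV: header comments, then one edge per line."""
    labels = sem.graph.vertex_labels
    lines = ["# rcsp sem edge list"]
    scales = ",".join(f"{s:.17g}" for s in sem.error_scale)
    lines.append(f"# n_vertices={sem.graph.n_vertices}\terror_scale={scales}")
    target = "" if sem.target_index is None else labels[sem.target_index]
    lines.append(f"# target={target}\tknockdown_offset={sem.knockdown_offset:.17g}")
    lines.append("# labels=" + ",".join(labels))
    lines.append("parent\tchild\tweight")
    for a, b in sorted(sem.graph.edges):
        lines.append(f"{labels[a]}\t{labels[b]}\t{sem.weights[a, b]:.17g}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_edge_list(path: str | Path) -> SemParameters:
    """Inverse of :func:`write_edge_list`."""
    text = Path(path).read_text().splitlines()
    meta: dict[str, str] = {}
    rows: list[tuple[str, str, float]] = []
    for line in text:
        if line.startswith("#"):
            for part in line[1:].strip().split("\t"):
                if "=" in part:
                    k, v = part.split("=", 1)
                    meta[k] = v
            continue
        if not line or line.startswith("parent\t"):
            continue
        a, b, w = line.split("\t")
        rows.append((a, b, float(w)))
    n = int(meta["n_vertices"])
    label_set = meta["labels"].split(",")
    if len(label_set) != n:
        raise ValueError("label list length does not match n_vertices")
    target_label = meta.get("target", "")
    index = {lab: i for i, lab in enumerate(label_set)}
    weights = np.zeros((n, n))
    edges = set()
    for a, b, w in rows:
        weights[index[a], index[b]] = w
        edges.add((index[a], index[b]))
    graph = CausalGraph(n, frozenset(edges), tuple(label_set))
    scales = np.array([float(s) for s in meta["error_scale"].split(",")])
    target = index[target_label] if target_label else None
    return SemParameters(
        graph,
        weights,
        scales,
        target_index=target,
        knockdown_offset=float(meta.get("knockdown_offset", 2.0)),
    )
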