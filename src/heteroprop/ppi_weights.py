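"""The weighted protein-protein layer.

Two similarity signals are blended into one edge weight.  The topology
signal ``fs(u, v)`` looks at direct (S1) and level-2 (S2) neighbourhoods:

    fs(u, v) = 1        if v in S1 & S2
             = alpha    if v in S1 - S2
             = 1-alpha  if v in S2 - S1
             = 0        otherwise

with ``0 < alpha < 1`` weighting exclusive direct neighbours.  The module
signal uses protein-complex co-membership,

    ms(u, v) = |C_u & C_v|**2 / (|C_u| * |C_v|),

zero when either membership set is empty.  The edge weight is the convex
blend ``mpp(u, v) = beta * fs(u, v) + (1 - beta) * ms(u, v)``.  Support is
NOT restricted to observed interactions: any pair with fs > 0 (including
pure level-2 pairs) or ms > 0 (complex co-members without an interaction)
receives a weight.  The diagonal is zero throughout -- self-interactions
are removed from the data and downstream maxima over protein lists rely
on ``mpp(u, u) = 0``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .io import ComplexCatalog, PPIGraph

__all__ = [
    "TopologyParams",
    "WeightedPPIMatrix",
    "neighbor_sets",
    "topology_similarity",
    "module_similarity",
    "build_weighted_ppi",
]

logger = logging.getLogger(__name__)

#: Per-ontology defaults for the blend weight beta.
ONTOLOGY_BETA = {"BP": 0.8, "MF": 0.7, "CC": 0.9}
#: Default weight of exclusive direct neighbours.
DEFAULT_ALPHA = 0.8


@dataclass(frozen=True)
class TopologyParams:
    """alpha: exclusive-direct-neighbour weight in (0, 1); beta: blend in [0, 1]."""

    alpha: float = DEFAULT_ALPHA
    beta: float = 0.8

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError(f"beta must be in [0, 1], got {self.beta}")


@dataclass
class WeightedPPIMatrix:
    """Symmetric nonnegative protein-by-protein weights with a zero diagonal."""

    proteins: tuple[str, ...]
    matrix: sp.csr_matrix
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.proteins = tuple(self.proteins)
        self._index = {p: i for i, p in enumerate(self.proteins)}
        n = len(self.proteins)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape does not match protein index")

    @property
    def n_proteins(self) -> int:
        return len(self.proteins)

    def index(self, protein: str) -> int:
        try:
            return self._index[protein]
        except KeyError:
            raise KeyError(f"protein {protein!r} not in the weighted network") from None

    def weight(self, u: str, v: str) -> float:
        return float(self.matrix[self.index(u), self.index(v)])

    def row(self, u: str) -> np.ndarray:
        return np.asarray(self.matrix[self.index(u)].todense()).ravel()

    def to_edge_list(self, path) -> None:
        """Dump nonzero weights as a 3-column TSV (u, v, weight), u < v."""
        coo = sp.triu(self.matrix, k=1).tocoo()
        order = np.lexsort((coo.col, coo.row))
        with open(path, "w", encoding="utf-8") as fh:
            for k in order:
                fh.write(
                    f"{self.proteins[coo.row[k]]}\t{self.proteins[coo.col[k]]}"
                    f"\t{coo.data[k]:.10g}\n"
                )


def neighbor_sets(graph: PPIGraph, u: str) -> tuple[frozenset[str], frozenset[str]]:
    """Direct neighbours S1 and level-2 neighbours S2 of ``u``.

    S2 holds every v != u reachable by a path u-w-v; u belongs to neither
    set.  On an undirected graph both relations are symmetric.
    """
    s1 = graph.neighbors(u)
    s2: set[str] = set()
    for w in s1:
        s2 |= graph.neighbors(w)
    s2.discard(u)
    return s1, frozenset(s2)


def topology_similarity(
    graph: PPIGraph, u: str, v: str, params: TopologyParams | None = None
) -> float:
    """fs(u, v) from the four-way neighbourhood classification."""
    if u == v:
        raise ValueError("topology similarity is undefined for u == v")
    params = params or TopologyParams()
    s1, s2 = neighbor_sets(graph, u)
    if v not in graph:
        raise KeyError(f"protein {v!r} not in the network")
    if v in s1 and v in s2:
        return 1.0
    if v in s1:
        return params.alpha
    if v in s2:
        return 1.0 - params.alpha
    return 0.0


def module_similarity(catalog: ComplexCatalog, u: str, v: str) -> float:
    """ms(u, v) = |C_u & C_v|^2 / (|C_u| |C_v|); 0 when either set is empty."""
    if u == v:
        raise ValueError("module similarity is undefined for u == v")
    cu = catalog.memberships(u)
    cv = catalog.memberships(v)
    if not cu or not cv:
        return 0.0
    shared = len(cu & cv)
    return shared * shared / (len(cu) * len(cv))


def _adjacency(graph: PPIGraph) -> sp.csr_matrix:
    n = graph.n_proteins
    rows, cols = [], []
    for a, b in graph.edges:
        i, j = graph.index(a), graph.index(b)
        rows += [i, j]
        cols += [j, i]
    data = np.ones(len(rows))
    return sp.csr_matrix((data, (rows, cols)), shape=(n, n))


def build_weighted_ppi(
    graph: PPIGraph, catalog: ComplexCatalog, params: TopologyParams | None = None
) -> WeightedPPIMatrix:
    """All-pairs blend of topology and module similarity, stored sparsely.

    Complex members absent from the graph are ignored with a warning;
    level-2 paths may pass through any intermediate node.
    """
    params = params or TopologyParams()
    n = graph.n_proteins
    a = _adjacency(graph)

    # S2 support: nodes joined by a length-2 path (diagonal removed)
    a2 = (a @ a).astype(bool).astype(float)
    a2.setdiag(0)
    a2.eliminate_zeros()
    s1 = a.astype(bool).astype(float)
    # alpha on S1-only, 1-alpha on S2-only, 1 on the intersection
    fs = params.alpha * s1 + (1.0 - params.alpha) * a2

    outside = catalog.proteins - set(graph.proteins)
    if outside:
        logger.warning(
            "ignoring %d complex member(s) absent from the PPI graph", len(outside)
        )
        catalog = catalog.restricted_to(graph.proteins)

    rows, cols, counts = [], [], {}
    for ci, (_, members) in enumerate(catalog.complexes):
        for p in members:
            i = graph.index(p)
            rows.append(i)
            cols.append(ci)
            counts[i] = counts.get(i, 0) + 1
    if rows:
        m = sp.csr_matrix(
            (np.ones(len(rows)), (rows, cols)), shape=(n, catalog.n_complexes)
        )
        overlap = (m @ m.T).tocoo()
        csize = np.asarray(m.sum(axis=1)).ravel()
        data = overlap.data**2 / (csize[overlap.row] * csize[overlap.col])
        ms = sp.csr_matrix((data, (overlap.row, overlap.col)), shape=(n, n))
        ms.setdiag(0)
        ms.eliminate_zeros()
    else:
        ms = sp.csr_matrix((n, n))

    mpp = (params.beta * fs + (1.0 - params.beta) * ms).tocsr()
    mpp.setdiag(0)
    mpp.eliminate_zeros()
    return WeightedPPIMatrix(graph.proteins, mpp)
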