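"""The domain side of the heterogeneous network.

Proteins connect to the Pfam-style domains they contain through a binary
incidence matrix ``mpd``.  Domains are then compared through the weighted
PPI layer: the affinity of a protein ``u`` to a domain's protein list
``PL(dn)`` is

    S_PD(u, PL(dn)) = max over pn in PL(dn) of mpp(u, pn),

and the similarity of two domains averages the internal cohesion of their
protein lists,

    mdd(i, j) = [ sum_{p in PL(i)} S_PD(p, PL(i))
                + sum_{p in PL(j)} S_PD(p, PL(j)) ]
                / (|PL(i)| + |PL(j)|).

Note the formula carries no cross-list term: a pair's similarity depends
only on each domain's own cohesion (this literal property is pinned by a
regression test).  The diagonal is evaluated by the same formula but
zeroed in the stored matrix so that self-transitions cannot trap
probability mass during propagation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .io import DomainAssociationTable
from .ppi_weights import WeightedPPIMatrix

__all__ = [
    "DomainAssociationMatrix",
    "DomainSimilarityMatrix",
    "build_domain_matrix",
    "protein_set_affinity",
    "domain_similarity",
    "build_domain_similarity",
]

logger = logging.getLogger(__name__)


@dataclass
class DomainAssociationMatrix:
    """Binary protein-by-domain incidence with per-domain protein lists."""

    proteins: tuple[str, ...]
    domains: tuple[str, ...]
    incidence: sp.csr_matrix
    _pindex: dict[str, int] = field(init=False, repr=False)
    _dindex: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.proteins = tuple(self.proteins)
        self.domains = tuple(self.domains)
        self._pindex = {p: i for i, p in enumerate(self.proteins)}
        self._dindex = {d: j for j, d in enumerate(self.domains)}
        if self.incidence.shape != (len(self.proteins), len(self.domains)):
            raise ValueError("incidence shape does not match indices")
        data = self.incidence.data
        if data.size and not np.all(np.isin(data, (0.0, 1.0))):
            raise ValueError("incidence must be binary")
        col_deg = np.asarray(self.incidence.sum(axis=0)).ravel()
        if np.any(col_deg == 0):
            raise ValueError("every indexed domain must have >=1 associated protein")

    @property
    def n_proteins(self) -> int:
        return len(self.proteins)

    @property
    def n_domains(self) -> int:
        return len(self.domains)

    def domain_index(self, domain: str) -> int:
        try:
            return self._dindex[domain]
        except KeyError:
            raise KeyError(f"domain {domain!r} not indexed") from None

    def protein_list(self, domain: str) -> tuple[str, ...]:
        """PL(dn): proteins containing ``domain``, in protein-index order."""
        col = self.incidence.getcol(self.domain_index(domain)).tocoo()
        return tuple(self.proteins[i] for i in sorted(col.row))


def build_domain_matrix(
    table: DomainAssociationTable, proteins: tuple[str, ...]
) -> DomainAssociationMatrix:
    """Index the association table against a protein universe.

    Records whose protein is absent from ``proteins`` are dropped with a
    warning (association data is restricted to network proteins); domains
    left with no retained protein disappear.  Domain order is first
    appearance among the retained records.
    """
    pindex = {p: i for i, p in enumerate(proteins)}
    kept: list[tuple[str, str]] = []
    dropped = 0
    for protein, domain in table.records:
        if protein in pindex:
            kept.append((protein, domain))
        else:
            dropped += 1
    if dropped:
        logger.warning(
            "dropped %d domain association(s) whose protein is outside the network",
            dropped,
        )
    domains: dict[str, None] = {}
    for _, d in kept:
        domains.setdefault(d)
    dindex = {d: j for j, d in enumerate(domains)}
    rows = [pindex[p] for p, _ in kept]
    cols = [dindex[d] for _, d in kept]
    inc = sp.csr_matrix(
        (np.ones(len(kept)), (rows, cols)), shape=(len(proteins), len(dindex))
    )
    return DomainAssociationMatrix(tuple(proteins), tuple(domains), inc)


@dataclass
class DomainSimilarityMatrix:
    """Symmetric nonnegative domain-by-domain similarities (zero diagonal)."""

    domains: tuple[str, ...]
    values: np.ndarray
    _dindex: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.domains = tuple(self.domains)
        self.values = np.asarray(self.values, dtype=float)
        self._dindex = {d: j for j, d in enumerate(self.domains)}
        n = len(self.domains)
        if self.values.shape != (n, n):
            raise ValueError("values shape does not match domain index")

    @property
    def n_domains(self) -> int:
        return len(self.domains)

    def similarity(self, a: str, b: str) -> float:
        return float(self.values[self._dindex[a], self._dindex[b]])

    def to_edge_list(self, path) -> None:
        """Dump nonzero off-diagonal similarities as a 3-column TSV."""
        with open(path, "w", encoding="utf-8") as fh:
            n = self.n_domains
            for i in range(n):
                for j in range(i + 1, n):
                    v = self.values[i, j]
                    if v > 0:
                        fh.write(f"{self.domains[i]}\t{self.domains[j]}\t{v:.10g}\n")


def protein_set_affinity(mpp: WeightedPPIMatrix, u: str, pl) -> float:
    """S_PD(u, PL): max weighted-PPI weight from ``u`` into the list.

    A protein belonging to its own domain's list contributes its zero
    self-weight to the max rather than being excluded.
    """
    pl = tuple(pl)
    if not pl:
        raise ValueError("a domain with an empty protein list cannot exist")
    row = mpp.row(u)
    return float(max(row[mpp.index(p)] for p in pl))


def _cohesion(mpp: WeightedPPIMatrix, mpd: DomainAssociationMatrix) -> np.ndarray:
    """Per-domain sum over PL of each member's max weight into PL."""
    dense = mpp.matrix
    out = np.zeros(mpd.n_domains)
    csc = mpd.incidence.tocsc()
    for j in range(mpd.n_domains):
        members = csc.indices[csc.indptr[j] : csc.indptr[j + 1]]
        sub = dense[members][:, members].toarray()
        out[j] = sub.max(axis=1).sum() if members.size else 0.0
    return out


def domain_similarity(
    mpp: WeightedPPIMatrix, mpd: DomainAssociationMatrix, dn_i: str, dn_j: str
) -> float:
    """mdd(dn_i, dn_j): cohesion-averaged similarity of two domains."""
    total = 0.0
    sizes = 0
    for dn in (dn_i, dn_j):
        pl = mpd.protein_list(dn)
        total += sum(protein_set_affinity(mpp, p, pl) for p in pl)
        sizes += len(pl)
    return total / sizes


def build_domain_similarity(
    mpp: WeightedPPIMatrix, mpd: DomainAssociationMatrix, zero_diagonal: bool = True
) -> DomainSimilarityMatrix:
    """Evaluate every domain pair; zero the diagonal for propagation use."""
    if mpd.proteins != mpp.proteins:
        raise ValueError("protein indices of mpp and mpd disagree")
    a = _cohesion(mpp, mpd)
    sizes = np.asarray(mpd.incidence.sum(axis=0)).ravel()
    values = (a[:, None] + a[None, :]) / (sizes[:, None] + sizes[None, :])
    if zero_diagonal:
        np.fill_diagonal(values, 0.0)
    return DomainSimilarityMatrix(mpd.domains, values)
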