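"""Restart propagation on the heterogeneous protein-domain network.

The two node categories are stacked (proteins first, then domains) into
one block adjacency matrix

    HBM = [[MPP, MPD], [MPD^T, MDD]],

which is turned into a transition matrix by per-row normalisation with a
move probability ``lambda`` reserved for crossing between layers: a
protein with at least one domain spends lambda of its outgoing mass on
its domains and 1-lambda on its weighted protein neighbours (and
symmetrically for domains).  Nodes with no cross-layer link keep all
their mass within their own layer; nodes with no outgoing weight at all
get an all-zero row.

Scores then follow the random-walk-with-restart iteration

    pr_{t+1} = (1 - gamma) * HBM_T * pr_t + gamma * pr_0,

stopped when the L1 change drops below ``epsilon``.  The transition
matrix is applied in its literal row-stochastic orientation (new score of
node i sums T(i, j) * pr(j)); since MPP and MDD are symmetric this
matches standard RWR up to per-row normalisation.  A ``column``
orientation (apply T transposed) is exposed for comparison.  For
``gamma > 0`` the update is a contraction with L1 factor at most
(1 - gamma), so the fixed point is unique and also available from a
direct linear solve (:func:`solve_stationary`), which serves as an
independent cross-check of the iteration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .domains import DomainAssociationMatrix, DomainSimilarityMatrix
from .ppi_weights import WeightedPPIMatrix

__all__ = [
    "HeterogeneousNetwork",
    "TransitionMatrix",
    "ScoreVector",
    "assemble_hbm",
    "build_transition",
    "initial_scores",
    "propagate",
    "solve_stationary",
]

DEFAULT_MOVE_PROB = 0.2
DEFAULT_RESTART = 0.5
DEFAULT_TOL = 1e-6
DEFAULT_MAX_ITER = 1000


@dataclass
class HeterogeneousNetwork:
    """The three blocks plus the combined node order (proteins then domains)."""

    mpp: WeightedPPIMatrix
    mpd: DomainAssociationMatrix
    mdd: DomainSimilarityMatrix

    @property
    def n_proteins(self) -> int:
        return self.mpp.n_proteins

    @property
    def n_domains(self) -> int:
        return self.mdd.n_domains

    @property
    def nodes(self) -> tuple[str, ...]:
        return self.mpp.proteins + self.mdd.domains

    def combined(self) -> sp.csr_matrix:
        """The full (n_p + n_d) block adjacency matrix."""
        return sp.bmat(
            [
                [self.mpp.matrix, self.mpd.incidence],
                [self.mpd.incidence.T, sp.csr_matrix(self.mdd.values)],
            ],
            format="csr",
        )


def assemble_hbm(
    mpp: WeightedPPIMatrix,
    mpd: DomainAssociationMatrix,
    mdd: DomainSimilarityMatrix,
) -> HeterogeneousNetwork:
    """Check index consistency and stack the blocks."""
    if mpd.proteins != mpp.proteins:
        raise ValueError("protein indices of MPP and MPD disagree")
    if mpd.domains != mdd.domains:
        raise ValueError("domain indices of MPD and MDD disagree")
    return HeterogeneousNetwork(mpp, mpd, mdd)


@dataclass
class TransitionMatrix:
    """Row-normalised block transition matrix over proteins then domains."""

    matrix: sp.csr_matrix
    n_proteins: int
    n_domains: int
    move_prob: float

    @property
    def n_nodes(self) -> int:
        return self.n_proteins + self.n_domains

    def row_sums(self) -> np.ndarray:
        return np.asarray(self.matrix.sum(axis=1)).ravel()


def _row_normalized(m: sp.spmatrix) -> sp.csr_matrix:
    m = sp.csr_matrix(m, copy=True).astype(float)
    sums = np.asarray(m.sum(axis=1)).ravel()
    scale = np.divide(1.0, sums, out=np.zeros_like(sums), where=sums > 0)
    return sp.diags(scale) @ m


def build_transition(
    hbm: HeterogeneousNetwork, move_prob: float = DEFAULT_MOVE_PROB
) -> TransitionMatrix:
    """Per-row normalisation of the blocks with the lambda layer split.

    Protein rows: mpp(i, .)/sum, scaled by (1 - lambda) iff protein i has
    at least one domain; the domain part is lambda * mpd(i, .)/sum.
    Domain rows mirror this through mdd and the incidence columns.  A row
    with no outgoing weight anywhere stays all-zero.
    """
    if not 0.0 <= move_prob <= 1.0:
        raise ValueError(f"move probability must be in [0, 1], got {move_prob}")
    if hbm.mpp.matrix.nnz and hbm.mpp.matrix.data.min() < 0:
        raise ValueError("negative weights in MPP")
    if np.any(hbm.mdd.values < 0):
        raise ValueError("negative weights in MDD")

    lam = move_prob
    inc = hbm.mpd.incidence
    p_deg = np.asarray(inc.sum(axis=1)).ravel()  # domains per protein
    d_deg = np.asarray(inc.sum(axis=0)).ravel()  # proteins per domain

    pp = _row_normalized(hbm.mpp.matrix)
    pp = sp.diags(np.where(p_deg > 0, 1.0 - lam, 1.0)) @ pp
    pd = lam * _row_normalized(inc)

    dd = _row_normalized(hbm.mdd.values)
    dd = sp.diags(np.where(d_deg > 0, 1.0 - lam, 1.0)) @ dd
    dp = lam * _row_normalized(inc.T)

    t = sp.bmat([[pp, pd], [dp, dd]], format="csr")
    return TransitionMatrix(t, hbm.n_proteins, hbm.n_domains, lam)


@dataclass
class ScoreVector:
    """Propagated scores over the proteins-then-domains node order."""

    values: np.ndarray
    restart: np.ndarray
    gamma: float
    n_proteins: int
    iterations: int = 0
    converged: bool = True

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.restart = np.asarray(self.restart, dtype=float)
        if self.values.shape != self.restart.shape:
            raise ValueError("score and restart vectors differ in length")
        if np.any(self.restart < 0):
            raise ValueError("restart vector must be nonnegative")

    @property
    def protein_scores(self) -> np.ndarray:
        return self.values[: self.n_proteins]

    @property
    def domain_scores(self) -> np.ndarray:
        return self.values[self.n_proteins :]


def initial_scores(
    mpp: WeightedPPIMatrix, mpd: DomainAssociationMatrix, u: str
) -> np.ndarray:
    """Restart vector pr0 = [h(P); h(D)] for a target protein ``u``.

    h(p_i) = mpp(u, p_i) (zero for u itself); h(d_j) is the max of h over
    the domain's protein list.
    """
    if mpd.proteins != mpp.proteins:
        raise ValueError("protein indices of mpp and mpd disagree")
    h_p = mpp.row(u)
    h_d = np.zeros(mpd.n_domains)
    csc = mpd.incidence.tocsc()
    for j in range(mpd.n_domains):
        members = csc.indices[csc.indptr[j] : csc.indptr[j + 1]]
        if members.size:
            h_d[j] = h_p[members].max()
    return np.concatenate([h_p, h_d])


def propagate(
    t: TransitionMatrix,
    pr0: np.ndarray,
    gamma: float = DEFAULT_RESTART,
    epsilon: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    orientation: str = "row",
) -> ScoreVector:
    """Iterate the restart update from pr = pr0 until the L1 change < epsilon.

    Returns the final vector plus the iteration count and a converged
    flag; hitting ``max_iter`` is reported, not raised.
    """
    if not 0.0 <= gamma <= 1.0:
        raise ValueError(f"gamma must be in [0, 1], got {gamma}")
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    if orientation not in ("row", "column"):
        raise ValueError(f"unknown orientation {orientation!r}")
    pr0 = np.asarray(pr0, dtype=float)
    if np.any(pr0 < 0):
        raise ValueError("restart vector must be nonnegative")
    op = t.matrix if orientation == "row" else t.matrix.T.tocsr()

    pr = pr0.copy()
    iterations = 0
    converged = False
    while iterations < max_iter:
        new = (1.0 - gamma) * (op @ pr) + gamma * pr0
        iterations += 1
        if not np.all(np.isfinite(new)):
            raise FloatingPointError("non-finite values during propagation")
        diff = float(np.abs(new - pr).sum())
        pr = new
        if diff < epsilon:
            converged = True
            break
    return ScoreVector(pr, pr0, gamma, t.n_proteins, iterations, converged)


def solve_stationary(
    t: TransitionMatrix,
    pr0: np.ndarray,
    gamma: float = DEFAULT_RESTART,
    orientation: str = "row",
) -> ScoreVector:
    """Exact fixed point via the linear system (I - (1-gamma) T) pr = gamma pr0.

    Exists for gamma > 0 because the update is then a contraction for a
    row-substochastic T; used as an independent oracle for the iteration.
    """
    if not 0.0 < gamma <= 1.0:
        raise ValueError("gamma must be in (0, 1] for a unique fixed point")
    pr0 = np.asarray(pr0, dtype=float)
    if math.isclose(gamma, 1.0):
        return ScoreVector(pr0.copy(), pr0, gamma, t.n_proteins, 0, True)
    op = t.matrix if orientation == "row" else t.matrix.T.tocsr()
    n = t.n_nodes
    a = sp.identity(n, format="csc") - (1.0 - gamma) * op
    pr = spla.spsolve(a.tocsc(), gamma * pr0)
    return ScoreVector(np.asarray(pr).ravel(), pr0, gamma, t.n_proteins, 0, True)
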