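"""A scikit-learn style estimator wrapping the whole pipeline.

:class:`FunctionPropagator` is a transductive multi-label predictor: fit
takes the network evidence (PPI graph, complex catalog, domain table)
plus GO annotations, builds the weighted PPI layer, the domain layers
and the transition matrix, and predict runs restart propagation from
each requested target and selects its top-L terms.  Parameters follow
sklearn conventions (stored untouched in ``__init__``, fitted state in
trailing-underscore attributes), so ``get_params`` / ``set_params`` /
``clone`` work and the estimator slots into sklearn model selection.
"""

from __future__ import annotations

from typing import Iterable

from sklearn.base import BaseEstimator

from . import annotate, propagation
from .domains import build_domain_matrix, build_domain_similarity
from .io import (
    AnnotationCatalog,
    ComplexCatalog,
    DomainAssociationTable,
    PPIGraph,
)
from .ppi_weights import (
    DEFAULT_ALPHA,
    ONTOLOGY_BETA,
    TopologyParams,
    build_weighted_ppi,
)

__all__ = ["FunctionPropagator"]


class FunctionPropagator(BaseEstimator):
    """Predict GO terms by restart propagation on a protein-domain network.

    Parameters
    ----------
    alpha : float, default 0.8
        Weight of exclusive direct neighbours in the topology similarity,
        in (0, 1).
    beta : float or None, default None
        Blend between topology and module similarity in the weighted PPI
        layer, in [0, 1].  ``None`` resolves to the per-ontology default
        (BP 0.8, MF 0.7, CC 0.9) when annotations are supplied at fit.
    move_prob : float, default 0.2
        Lambda, the transition mass reserved for crossing between the
        protein and domain layers.
    restart : float, default 0.5
        Gamma, the restart weight of the propagation iteration.
    epsilon : float, default 1e-6
        L1 convergence tolerance of the iteration.
    max_iter : int, default 1000
        Iteration cap; non-convergence is flagged, not raised.
    min_score : float, default 0.0
        Partners must exceed this propagated score to vote for terms.
    orientation : {"row", "column"}, default "row"
        Which orientation of the transition matrix drives the update.

    Attributes
    ----------
    proteins_, domains_ : node indices (proteins first, then domains).
    mpp_, mpd_, mdd_ : the three network blocks.
    network_ : the assembled heterogeneous network.
    transition_ : the lambda-reserved transition matrix.
    annotations_ : the annotation catalog seen at fit (may be None).
    beta_ : the resolved blend weight actually used.
    """

    def __init__(
        self,
        alpha: float = DEFAULT_ALPHA,
        beta: float | None = None,
        move_prob: float = propagation.DEFAULT_MOVE_PROB,
        restart: float = propagation.DEFAULT_RESTART,
        epsilon: float = propagation.DEFAULT_TOL,
        max_iter: int = propagation.DEFAULT_MAX_ITER,
        min_score: float = 0.0,
        orientation: str = "row",
    ) -> None:
        self.alpha = alpha
        self.beta = beta
        self.move_prob = move_prob
        self.restart = restart
        self.epsilon = epsilon
        self.max_iter = max_iter
        self.min_score = min_score
        self.orientation = orientation

    # ------------------------------------------------------------------
    def fit(self, X, y: AnnotationCatalog | None = None) -> "FunctionPropagator":
        """Build all network layers.

        ``X`` is the evidence triple ``(PPIGraph, ComplexCatalog,
        DomainAssociationTable)``; ``y`` the annotation catalog used for
        term voting (it does not shape the network and may be swapped at
        predict time, which is how cross-validation hides test labels).
        """
        graph, complexes, domain_table = self._unpack(X)
        if y is not None and not isinstance(y, AnnotationCatalog):
            raise TypeError("y must be an AnnotationCatalog or None")
        beta = self.beta
        if beta is None:
            beta = ONTOLOGY_BETA[y.ontology] if y is not None else ONTOLOGY_BETA["BP"]
        params = TopologyParams(alpha=self.alpha, beta=beta)

        self.graph_ = graph
        self.complexes_ = complexes
        self.domain_table_ = domain_table
        self.beta_ = beta
        self.mpp_ = build_weighted_ppi(graph, complexes, params)
        self.mpd_ = build_domain_matrix(domain_table, graph.proteins)
        self.mdd_ = build_domain_similarity(self.mpp_, self.mpd_)
        self.network_ = propagation.assemble_hbm(self.mpp_, self.mpd_, self.mdd_)
        self.transition_ = propagation.build_transition(self.network_, self.move_prob)
        self.annotations_ = y
        self.proteins_ = graph.proteins
        self.domains_ = self.mpd_.domains
        return self

    @staticmethod
    def _unpack(X) -> tuple[PPIGraph, ComplexCatalog, DomainAssociationTable]:
        try:
            graph, complexes, domain_table, *rest = X
        except (TypeError, ValueError):
            raise TypeError(
                "X must be (PPIGraph, ComplexCatalog, DomainAssociationTable)"
            ) from None
        if not isinstance(graph, PPIGraph):
            raise TypeError("first element of X must be a PPIGraph")
        if not isinstance(complexes, ComplexCatalog):
            raise TypeError("second element of X must be a ComplexCatalog")
        if not isinstance(domain_table, DomainAssociationTable):
            raise TypeError("third element of X must be a DomainAssociationTable")
        return graph, complexes, domain_table

    def _check_fitted(self) -> None:
        if not hasattr(self, "transition_"):
            raise RuntimeError("this FunctionPropagator instance is not fitted yet")

    # ------------------------------------------------------------------
    def propagate_scores(self, target: str) -> propagation.ScoreVector:
        """Run the restart propagation seeded at ``target``."""
        self._check_fitted()
        pr0 = propagation.initial_scores(self.mpp_, self.mpd_, target)
        return propagation.propagate(
            self.transition_,
            pr0,
            gamma=self.restart,
            epsilon=self.epsilon,
            max_iter=self.max_iter,
            orientation=self.orientation,
        )

    def partner_scores(self, target: str) -> dict[str, float]:
        """Propagated protein scores as a protein -> score mapping."""
        sv = self.propagate_scores(target)
        return dict(zip(self.proteins_, sv.protein_scores))

    def predict_one(
        self, target: str, annotations: AnnotationCatalog | None = None
    ) -> annotate.Prediction:
        """Top-L prediction for one protein (optionally overriding labels)."""
        self._check_fitted()
        catalog = annotations if annotations is not None else self.annotations_
        if catalog is None:
            raise ValueError("no annotation catalog: pass y at fit or annotations here")
        sv = self.propagate_scores(target)
        scores = dict(zip(self.proteins_, sv.protein_scores))
        return annotate.predict_functions(
            target,
            scores,
            catalog,
            min_score=self.min_score,
            iterations=sv.iterations,
            converged=sv.converged,
        )

    def rank_terms(
        self, target: str, annotations: AnnotationCatalog | None = None
    ) -> annotate.RankedFunctionList:
        """Full ranked candidate-term list for one protein."""
        return self.predict_one(target, annotations).ranked

    def predict(
        self,
        X: str | Iterable[str],
        annotations: AnnotationCatalog | None = None,
    ):
        """Predict for one target ID or a sequence of target IDs."""
        if isinstance(X, str):
            return self.predict_one(X, annotations)
        return [self.predict_one(target, annotations) for target in X]
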