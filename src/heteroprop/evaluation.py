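"""Cross-validated evaluation of term predictions.

Two protocols hide annotations and score their recovery: leave-one-out
(one protein's labels hidden per round) and k-fold (a random tenth of
the annotated proteins hidden simultaneously).  Precision is the
fraction of predicted terms that are true, recall the fraction of true
terms predicted, and the reported F-measure is the harmonic mean of the
DATASET-AVERAGED precision and recall (not the mean of per-protein Fs)
-- the convention consistent with the printed source tables.  Proteins
with empty truth are excluded from the averages; proteins with empty
predictions contribute precision 0 and recall 0.

Ranking quality is summarised by a top-K ladder ROC: for each cutoff K
the top K ranked terms are the positives (the ranked candidate list is
padded with the remaining term universe in term-ID order when shorter),
TPR and FPR are averaged over proteins, and AUROC integrates the curve
by the trapezoidal rule with (0,0) and (1,1) anchors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotate import RankedFunctionList
from .estimator import FunctionPropagator
from .io import AnnotationCatalog

__all__ = [
    "EvaluationReport",
    "ROCCurve",
    "precision_recall",
    "f_measure",
    "leave_one_out",
    "k_fold",
    "roc_curve",
    "beta_sweep",
]


def precision_recall(predicted: Iterable[str], truth: Iterable[str]) -> tuple[float, float]:
    """(precision, recall) of a predicted term set against a nonempty truth."""
    predicted = set(predicted)
    truth = set(truth)
    if not truth:
        raise ValueError("truth set is empty; such proteins are excluded upstream")
    hits = len(predicted & truth)
    precision = hits / len(predicted) if predicted else 0.0
    recall = hits / len(truth)
    return precision, recall


def f_measure(precision: float, recall: float) -> float:
    """Harmonic mean 2PR/(P+R); zero when both vanish."""
    if not (0.0 <= precision <= 1.0 and 0.0 <= recall <= 1.0):
        raise ValueError("precision and recall must be in [0, 1]")
    if precision + recall == 0.0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


@dataclass
class EvaluationReport:
    """Dataset-averaged P/R and their harmonic-mean F, plus per-protein detail."""

    ontology: str
    protocol: str
    precision: float
    recall: float
    f_measure: float
    per_protein: pd.DataFrame
    params: dict = field(default_factory=dict)
    folds: int | None = None
    repeats: int | None = None
    seed: int | None = None
    fold_assignments: dict[str, int] | None = None
    rankings: dict[str, RankedFunctionList] | None = None

    @property
    def n_proteins(self) -> int:
        return len(self.per_protein)

    def to_dict(self) -> dict:
        out = {
            "ontology": self.ontology,
            "protocol": self.protocol,
            "precision": self.precision,
            "recall": self.recall,
            "f_measure": self.f_measure,
            "n_proteins": self.n_proteins,
            "params": self.params,
        }
        for key in ("folds", "repeats", "seed"):
            if getattr(self, key) is not None:
                out[key] = getattr(self, key)
        return out


def _finalize(
    rows: list[tuple[str, float, float]],
    ontology: str,
    protocol: str,
    params: dict,
    **extra,
) -> EvaluationReport:
    frame = pd.DataFrame(rows, columns=["protein", "precision", "recall"])
    p = float(frame["precision"].mean()) if len(frame) else 0.0
    r = float(frame["recall"].mean()) if len(frame) else 0.0
    return EvaluationReport(
        ontology=ontology,
        protocol=protocol,
        precision=p,
        recall=r,
        f_measure=f_measure(p, r),
        per_protein=frame,
        params=params,
        **extra,
    )


def _eval_targets(model: FunctionPropagator, catalog: AnnotationCatalog) -> list[str]:
    """Annotated proteins present in the network, in network order."""
    return [p for p in model.proteins_ if catalog.terms(p)]


def leave_one_out(
    model: FunctionPropagator,
    annotations: AnnotationCatalog | None = None,
    collect_rankings: bool = False,
) -> EvaluationReport:
    """Hide each annotated protein's labels in turn and score its prediction."""
    model._check_fitted()
    catalog = annotations if annotations is not None else model.annotations_
    if catalog is None:
        raise ValueError("no annotation catalog available")
    rows: list[tuple[str, float, float]] = []
    rankings: dict[str, RankedFunctionList] = {}
    for target in _eval_targets(model, catalog):
        training = catalog.drop([target])
        pred = model.predict_one(target, annotations=training)
        p, r = precision_recall(pred.term_set, catalog.terms(target))
        rows.append((target, p, r))
        if collect_rankings:
            rankings[target] = pred.ranked
    return _finalize(
        rows,
        catalog.ontology,
        "loocv",
        model.get_params(),
        rankings=rankings if collect_rankings else None,
    )


def k_fold(
    model: FunctionPropagator,
    folds: int = 10,
    repeats: int = 1,
    seed: int = 0,
    annotations: AnnotationCatalog | None = None,
) -> EvaluationReport:
    """Random fold partition; each fold's labels hidden simultaneously."""
    model._check_fitted()
    if folds < 2:
        raise ValueError("folds must be >= 2")
    catalog = annotations if annotations is not None else model.annotations_
    if catalog is None:
        raise ValueError("no annotation catalog available")
    targets = _eval_targets(model, catalog)
    if folds > len(targets):
        raise ValueError(f"folds={folds} exceeds {len(targets)} annotated proteins")
    rng = np.random.default_rng(seed)
    rows: list[tuple[str, float, float]] = []
    assignments: dict[str, int] = {}
    for _ in range(repeats):
        order = rng.permutation(len(targets))
        fold_of = {targets[i]: int(k % folds) for k, i in enumerate(order)}
        assignments.update(fold_of)
        for fold in range(folds):
            test = [p for p in targets if fold_of[p] == fold]
            training = catalog.drop(test)
            for target in test:
                pred = model.predict_one(target, annotations=training)
                p, r = precision_recall(pred.term_set, catalog.terms(target))
                rows.append((target, p, r))
    return _finalize(
        rows,
        catalog.ontology,
        "kfold",
        model.get_params(),
        folds=folds,
        repeats=repeats,
        seed=seed,
        fold_assignments=assignments,
    )


@dataclass
class ROCCurve:
    """Averaged top-K ladder: TPR/FPR per cutoff plus the trapezoidal AUROC."""

    ks: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auroc: float
    n_proteins: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"K": self.ks, "fpr": self.fpr, "tpr": self.tpr})


def roc_curve(
    rankings: Mapping[str, RankedFunctionList | Sequence[str]],
    truths: AnnotationCatalog,
    term_universe: Sequence[str] | None = None,
    k_max: int | None = None,
) -> ROCCurve:
    """Top-K ladder ROC averaged over proteins.

    For each protein the ranked candidate terms are padded with the rest
    of the universe in term-ID order; positives at cutoff K are the
    first K terms.  Proteins with empty truth (or truth covering the
    whole universe) are skipped.
    """
    universe = tuple(term_universe) if term_universe is not None else truths.term_universe
    if not universe:
        raise ValueError("term universe is empty")
    k_max = k_max if k_max is not None else len(universe)
    if k_max > len(universe):
        raise ValueError("k_max exceeds the term universe size")
    uset = set(universe)
    tpr_rows, fpr_rows = [], []
    for protein, ranked in rankings.items():
        truth = truths.terms(protein) & uset
        if not truth or len(truth) == len(universe):
            continue
        terms = ranked.terms if isinstance(ranked, RankedFunctionList) else tuple(ranked)
        listed = [t for t in terms if t in uset]
        seen = set(listed)
        padded = listed + sorted(uset - seen)
        is_true = np.fromiter((t in truth for t in padded), dtype=float)
        tp = np.cumsum(is_true)[:k_max]
        ks = np.arange(1, k_max + 1)
        tpr_rows.append(tp / len(truth))
        fpr_rows.append((ks - tp) / (len(universe) - len(truth)))
    if not tpr_rows:
        raise ValueError("no protein with a usable truth set")
    ks = np.arange(1, k_max + 1)
    tpr = np.mean(tpr_rows, axis=0)
    fpr = np.mean(fpr_rows, axis=0)
    xs = np.concatenate([[0.0], fpr, [1.0]])
    ys = np.concatenate([[0.0], tpr, [1.0]])
    auroc = float(np.trapezoid(ys, xs))
    return ROCCurve(ks, tpr, fpr, auroc, len(tpr_rows))


def beta_sweep(
    model: FunctionPropagator,
    betas: Sequence[float],
    protocol: str = "loocv",
    folds: int = 10,
    repeats: int = 1,
    seed: int = 0,
    annotations: AnnotationCatalog | None = None,
) -> pd.DataFrame:
    """Re-fit and re-evaluate the pipeline across blend weights.

    Returns a (beta, precision, recall, f_measure) grid; the weighted PPI
    layer (and everything downstream) is rebuilt for each beta.
    """
    model._check_fitted()
    catalog = annotations if annotations is not None else model.annotations_
    if catalog is None:
        raise ValueError("no annotation catalog available")
    X = (model.graph_, model.complexes_, model.domain_table_)
    rows = []
    for beta in betas:
        variant = FunctionPropagator(**{**model.get_params(), "beta": float(beta)})
        variant.fit(X, catalog)
        if protocol == "loocv":
            report = leave_one_out(variant)
        elif protocol == "kfold":
            report = k_fold(variant, folds=folds, repeats=repeats, seed=seed)
        else:
            raise ValueError(f"unknown protocol {protocol!r}")
        rows.append(
            (float(beta), report.precision, report.recall, report.f_measure)
        )
    return pd.DataFrame(rows, columns=["beta", "precision", "recall", "f_measure"])
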