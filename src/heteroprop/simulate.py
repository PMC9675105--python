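"""Synthetic datasets with planted functional structure.

The generator emulates the statistical assumptions the propagation method
exploits: proteins assemble into complexes that are densely wired
internally (edge probability ``p_intra`` within a complex versus
``p_background`` across), complex members share protein domains
(``domains_per_complex`` each, with a ``domain_leakage`` probability that
an assignment is rerouted to a random protein), and complex members share
GO terms (``terms_per_complex`` each, with a ``term_noise`` probability
that an annotation is replaced by a uniformly random term).  Complexes
partition the protein set by default; leftover proteins receive only
background edges and noise annotations, exercising the empty-membership
path of the module-similarity measure.

Everything is drawn from a single named random stream, so a seed fully
determines the dataset down to file bytes.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .io import (
    AnnotationCatalog,
    ComplexCatalog,
    DomainAssociationTable,
    PPIGraph,
)

__all__ = ["SyntheticConfig", "generate_dataset", "dataset_summary"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the planted-structure generator.

    Defaults are a scaled-down analogue of a yeast-sized input: complexes
    of 3-6 members covering most of the proteome, about two domains and
    three ontology terms planted per complex, sparse background noise.
    """

    n_proteins: int = 120
    n_complexes: int = 24
    complex_size_range: tuple[int, int] = (3, 6)
    p_intra: float = 0.9
    p_background: float = 0.01
    n_domains: int = 48
    domains_per_complex: int = 2
    domain_leakage: float = 0.05
    n_terms: int = 72
    terms_per_complex: int = 3
    term_noise: float = 0.1
    seed: int = 0
    ontology: str = "BP"
    overlapping: bool = False

    def __post_init__(self) -> None:
        for name in ("p_intra", "p_background", "domain_leakage", "term_noise"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in (
            "n_proteins",
            "n_complexes",
            "n_domains",
            "domains_per_complex",
            "n_terms",
            "terms_per_complex",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        lo, hi = self.complex_size_range
        if not 1 <= lo <= hi:
            raise ValueError(f"invalid complex_size_range {self.complex_size_range}")
        if self.domains_per_complex > self.n_domains:
            raise ValueError("domains_per_complex exceeds n_domains")
        if self.terms_per_complex > self.n_terms:
            raise ValueError("terms_per_complex exceeds n_terms")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["complex_size_range"] = list(self.complex_size_range)
        return d


def _planted_features(
    rng: np.random.Generator, pool: int, n_complexes: int, per_complex: int
) -> list[np.ndarray]:
    """Feature indices planted per complex.

    Complexes get disjoint blocks of a shuffled pool when it is large
    enough (uniform baseline popularity); otherwise each complex draws
    its features independently without replacement.
    """
    total = n_complexes * per_complex
    if pool >= total:
        shuffled = rng.permutation(pool)[:total]
        return [shuffled[i * per_complex : (i + 1) * per_complex] for i in range(n_complexes)]
    return [rng.choice(pool, size=per_complex, replace=False) for _ in range(n_complexes)]


def _ids(prefix: str, n: int) -> list[str]:
    width = max(3, len(str(n)))
    return [f"{prefix}{i + 1:0{width}d}" for i in range(n)]


def generate_dataset(
    config: SyntheticConfig,
) -> tuple[PPIGraph, ComplexCatalog, DomainAssociationTable, AnnotationCatalog]:
    """Draw one dataset (graph, complexes, domain table, annotations)."""
    rng = np.random.default_rng(config.seed)
    n = config.n_proteins
    proteins = _ids("P", n)
    domains = _ids("PF", config.n_domains)
    terms = [f"GO:{i + 1:07d}" for i in range(config.n_terms)]

    lo, hi = config.complex_size_range
    sizes = rng.integers(lo, hi + 1, size=config.n_complexes)
    if config.overlapping:
        members = [rng.choice(n, size=s, replace=False) for s in sizes]
    else:
        if int(sizes.sum()) > n:
            raise ValueError(
                f"complex sizes sum to {int(sizes.sum())} > n_proteins={n}; "
                "non-overlapping partition is infeasible"
            )
        order = rng.permutation(n)
        members, start = [], 0
        for s in sizes:
            members.append(order[start : start + int(s)])
            start += int(s)
    complex_ids = _ids("CPX", config.n_complexes)
    catalog = ComplexCatalog(
        tuple(
            (cid, frozenset(proteins[i] for i in idx))
            for cid, idx in zip(complex_ids, members)
        )
    )

    # edges: Bernoulli(p_intra) inside a complex, Bernoulli(p_background) across
    co_member = np.zeros((n, n), dtype=bool)
    for idx in members:
        co_member[np.ix_(idx, idx)] = True
    prob = np.where(co_member, config.p_intra, config.p_background)
    draws = rng.random((n, n))
    upper = np.triu(np.ones((n, n), dtype=bool), k=1)
    edge_mask = upper & (draws < prob)
    edges = tuple(
        (proteins[i], proteins[j]) for i, j in zip(*np.nonzero(edge_mask))
    )
    graph = PPIGraph(tuple(proteins), edges)

    # domains: each complex plants domains on its members; an assignment is
    # rerouted to a uniform random protein with probability domain_leakage.
    # When the pool allows, complexes receive disjoint blocks of a shuffled
    # pool so every planted feature has the same baseline popularity (the
    # permutation-null calibration of the evaluation relies on this).
    planted_domains = _planted_features(
        rng, config.n_domains, config.n_complexes, config.domains_per_complex
    )
    records: list[tuple[str, str]] = []
    for idx, planted in zip(members, planted_domains):
        for d in planted:
            for i in idx:
                target = int(i)
                if config.domain_leakage > 0 and rng.random() < config.domain_leakage:
                    target = int(rng.integers(n))
                records.append((proteins[target], domains[int(d)]))
    table = DomainAssociationTable(tuple(records))

    # annotations: each complex plants terms on its members; an annotation is
    # replaced by a uniform random term with probability term_noise
    annotations: dict[str, set[str]] = {}
    in_complex = np.zeros(n, dtype=bool)
    planted_terms = _planted_features(
        rng, config.n_terms, config.n_complexes, config.terms_per_complex
    )
    for idx, planted in zip(members, planted_terms):
        in_complex[idx] = True
        for t in planted:
            for i in idx:
                term = int(t)
                if config.term_noise > 0 and rng.random() < config.term_noise:
                    term = int(rng.integers(config.n_terms))
                annotations.setdefault(proteins[int(i)], set()).add(terms[term])
    # leftover proteins: noise annotations only
    for i in np.nonzero(~in_complex)[0]:
        if config.term_noise > 0 and rng.random() < config.term_noise:
            annotations.setdefault(proteins[int(i)], set()).add(
                terms[int(rng.integers(config.n_terms))]
            )
    gaf = AnnotationCatalog(
        config.ontology, {p: frozenset(t) for p, t in annotations.items()}
    )
    return graph, catalog, table, gaf


def dataset_summary(dataset) -> dict[str, float]:
    """Counts of proteins/edges/complexes/domains/terms plus annotation density.

    Annotation density is (protein, term) pairs per protein.
    """
    graph, catalog, table, gaf = dataset
    n_proteins = graph.n_proteins
    return {
        "n_proteins": n_proteins,
        "n_edges": graph.n_edges,
        "n_complexes": catalog.n_complexes,
        "n_domains": len(table.domains),
        "n_domain_associations": len(table),
        "n_terms": len(gaf.term_universe),
        "n_annotations": gaf.n_annotations,
        "annotation_density": gaf.n_annotations / n_proteins if n_proteins else 0.0,
    }
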