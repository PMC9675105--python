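import numpy as np
import pytest

from heteroprop.io import AnnotationCatalog, ComplexCatalog, PPIGraph
from heteroprop.simulate import SyntheticConfig, generate_dataset


@pytest.fixture
def path_graph():
    """A - B - C chain."""
    return PPIGraph(("A", "B", "C"), (("A", "B"), ("B", "C")))


@pytest.fixture
def triangle_graph():
    return PPIGraph(("A", "B", "C"), (("A", "B"), ("A", "C"), ("B", "C")))


@pytest.fixture
def neighbourhood_graph():
    """A target u with a partner in every neighbourhood class.

    v2 is both a direct and a level-2 neighbour (u-v2, u-w, w-v2);
    v1 is a direct neighbour only; v5 a level-2 neighbour only
    (via w); v6 sits at distance 3 and is in neither set.
    """
    proteins = ("u", "v1", "v2", "w", "v5", "a", "b", "v6")
    edges = (
        ("u", "v1"),
        ("u", "v2"),
        ("u", "w"),
        ("w", "v2"),
        ("w", "v5"),
        ("u", "a"),
        ("a", "b"),
        ("b", "v6"),
    )
    return PPIGraph(proteins, edges)


@pytest.fixture
def small_complexes():
    return ComplexCatalog((("c1", frozenset({"A", "B"})), ("c2", frozenset({"B", "C"}))))


def random_graph(rng: np.random.Generator, n: int, p: float) -> PPIGraph:
    proteins = tuple(f"N{i}" for i in range(n))
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                edges.append((proteins[i], proteins[j]))
    return PPIGraph(proteins, tuple(edges))


def planted_config(**overrides) -> SyntheticConfig:
    """A compact planted-structure configuration without leftover proteins."""
    base = dict(
        n_proteins=20,
        n_complexes=5,
        complex_size_range=(4, 4),
        p_intra=0.9,
        p_background=0.05,
        n_domains=12,
        domains_per_complex=2,
        domain_leakage=0.1,
        n_terms=18,
        terms_per_complex=3,
        term_noise=0.2,
        seed=0,
    )
    base.update(overrides)
    return SyntheticConfig(**base)


@pytest.fixture
def planted_dataset():
    return generate_dataset(planted_config(seed=5))


@pytest.fixture
def zero_noise_dataset():
    """Ten 4-cliques with perfectly coherent domains and terms."""
    cfg = SyntheticConfig(
        n_proteins=40,
        n_complexes=10,
        complex_size_range=(4, 4),
        p_intra=1.0,
        p_background=0.0,
        n_domains=16,
        domains_per_complex=2,
        domain_leakage=0.0,
        n_terms=30,
        terms_per_complex=3,
        term_noise=0.0,
        seed=11,
    )
    return generate_dataset(cfg)


def annotations_from(pairs, ontology="BP") -> AnnotationCatalog:
    out: dict[str, set] = {}
    for protein, term in pairs:
        out.setdefault(protein, set()).add(term)
    return AnnotationCatalog(ontology, {p: frozenset(t) for p, t in out.items()})
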