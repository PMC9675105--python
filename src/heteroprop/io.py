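"""Plain-text formats for network-based protein function prediction.

Four inputs drive the pipeline: an undirected protein-protein interaction
(PPI) edge list, a protein-complex catalog (CYC2008-style: one complex per
line), a protein-domain association table (Pfam-style two-column TSV) and
GO annotations in GAF 2.x filtered to one ontology aspect (BP/MF/CC).
Readers normalise the data on the way in -- self-interactions and repeated
interactions are removed, NOT-qualified GAF rows are dropped, duplicate
associations collapse -- and every ordering is deterministic so the matrix
indices built downstream are reproducible from file bytes alone.

Identifiers are opaque case-sensitive strings; no accession mapping is
attempted.  Comment lines start with ``!`` (GAF) or ``#`` (TSV).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "ParseError",
    "PPIGraph",
    "ComplexCatalog",
    "AnnotationCatalog",
    "DomainAssociationTable",
    "read_ppi_edgelist",
    "read_complex_catalog",
    "read_gaf",
    "read_domain_associations",
    "read_prediction_table",
    "write_ppi_edgelist",
    "write_complex_catalog",
    "write_gaf",
    "write_domain_associations",
    "write_prediction_table",
]

#: GAF aspect code for each ontology.
ASPECT_BY_ONTOLOGY = {"BP": "P", "MF": "F", "CC": "C"}
ONTOLOGY_BY_ASPECT = {v: k for k, v in ASPECT_BY_ONTOLOGY.items()}


class ParseError(ValueError):
    """A malformed line in an input file (message names the line number)."""


def _canonical(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


@dataclass
class PPIGraph:
    """An undirected PPI network.

    ``proteins`` is the full node list in first-appearance order (it may
    include isolated proteins); ``edges`` holds canonically ordered,
    de-duplicated pairs with no self-loops.
    """

    proteins: tuple[str, ...]
    edges: tuple[tuple[str, str], ...]
    _index: dict[str, int] = field(init=False, repr=False)
    _adj: dict[str, set[str]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.proteins = tuple(self.proteins)
        self._index = {p: i for i, p in enumerate(self.proteins)}
        if len(self._index) != len(self.proteins):
            raise ValueError("duplicate protein IDs in protein list")
        edges = []
        seen: set[tuple[str, str]] = set()
        adj: dict[str, set[str]] = {p: set() for p in self.proteins}
        for a, b in self.edges:
            if a == b:
                raise ValueError(f"self-interaction {a!r} is not allowed")
            if a not in self._index or b not in self._index:
                raise ValueError(f"edge ({a!r}, {b!r}) references unknown protein")
            key = _canonical(a, b)
            if key in seen:
                raise ValueError(f"duplicate edge ({a!r}, {b!r})")
            seen.add(key)
            edges.append(key)
            adj[a].add(b)
            adj[b].add(a)
        self.edges = tuple(edges)
        self._adj = adj

    @property
    def n_proteins(self) -> int:
        return len(self.proteins)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def __contains__(self, protein: str) -> bool:
        return protein in self._index

    def index(self, protein: str) -> int:
        try:
            return self._index[protein]
        except KeyError:
            raise KeyError(f"protein {protein!r} not in the network") from None

    def neighbors(self, protein: str) -> frozenset[str]:
        if protein not in self._index:
            raise KeyError(f"protein {protein!r} not in the network")
        return frozenset(self._adj[protein])

    def has_edge(self, a: str, b: str) -> bool:
        return b in self._adj.get(a, ())

    def to_networkx(self):
        """Export as a :class:`networkx.Graph` (isolated nodes preserved)."""
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.proteins)
        g.add_edges_from(self.edges)
        return g


@dataclass
class ComplexCatalog:
    """A protein-complex catalog with its inverted membership index.

    ``memberships(u)`` returns the set of complex IDs containing protein
    ``u`` (the C_u of the module-similarity measure); proteins absent from
    every complex get the empty set.
    """

    complexes: tuple[tuple[str, frozenset[str]], ...]
    _membership: dict[str, frozenset[str]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.complexes = tuple(
            (str(cid), frozenset(members)) for cid, members in self.complexes
        )
        names = [cid for cid, _ in self.complexes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate complex IDs")
        member_index: dict[str, set[str]] = {}
        for cid, members in self.complexes:
            if not members:
                raise ValueError(f"complex {cid!r} has no members")
            for p in members:
                member_index.setdefault(p, set()).add(cid)
        self._membership = {p: frozenset(c) for p, c in member_index.items()}

    @property
    def n_complexes(self) -> int:
        return len(self.complexes)

    @property
    def proteins(self) -> frozenset[str]:
        return frozenset(self._membership)

    def memberships(self, protein: str) -> frozenset[str]:
        """C_u: complexes containing ``protein`` (empty set if none)."""
        return self._membership.get(protein, frozenset())

    def restricted_to(self, proteins: Iterable[str]) -> "ComplexCatalog":
        """Drop members outside ``proteins``; drop emptied complexes."""
        keep = set(proteins)
        kept = []
        for cid, members in self.complexes:
            inside = members & keep
            if inside:
                kept.append((cid, inside))
        return ComplexCatalog(tuple(kept))


@dataclass
class AnnotationCatalog:
    """Per-ontology GO annotations: protein -> set of flat term IDs.

    Terms are treated as flat labels (no ontology-hierarchy propagation).
    ``term_universe`` is the sorted union of every annotation set.
    """

    ontology: str
    annotations: dict[str, frozenset[str]]
    term_universe: tuple[str, ...] = field(init=False)

    def __post_init__(self) -> None:
        if self.ontology not in ASPECT_BY_ONTOLOGY:
            raise ValueError(f"unknown ontology {self.ontology!r}; expected BP, MF or CC")
        cleaned: dict[str, frozenset[str]] = {}
        for protein, terms in self.annotations.items():
            terms = frozenset(terms)
            if not terms:
                raise ValueError(f"protein {protein!r} annotated with zero terms")
            cleaned[protein] = terms
        self.annotations = cleaned
        universe: set[str] = set()
        for terms in cleaned.values():
            universe |= terms
        self.term_universe = tuple(sorted(universe))

    @property
    def n_proteins(self) -> int:
        return len(self.annotations)

    @property
    def n_annotations(self) -> int:
        return sum(len(t) for t in self.annotations.values())

    def terms(self, protein: str) -> frozenset[str]:
        return self.annotations.get(protein, frozenset())

    def drop(self, proteins: Iterable[str]) -> "AnnotationCatalog":
        """Hide the annotations of ``proteins`` (for cross-validation)."""
        hide = set(proteins)
        kept = {p: t for p, t in self.annotations.items() if p not in hide}
        return AnnotationCatalog(self.ontology, kept)

    def permuted(self, seed: int) -> "AnnotationCatalog":
        """Shuffle annotation sets among annotated proteins (null model)."""
        import numpy as np

        proteins = sorted(self.annotations)
        sets = [self.annotations[p] for p in proteins]
        rng = np.random.default_rng(seed)
        order = rng.permutation(len(proteins))
        return AnnotationCatalog(
            self.ontology, {proteins[i]: sets[order[i]] for i in range(len(proteins))}
        )


@dataclass
class DomainAssociationTable:
    """Binary protein-domain associations: mpd(u, dn) = 1 iff (u, dn) present."""

    records: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        deduped = []
        for protein, domain in self.records:
            pair = (str(protein), str(domain))
            if pair not in seen:
                seen.add(pair)
                deduped.append(pair)
        self.records = tuple(deduped)
        self._pairs = seen

    def __len__(self) -> int:
        return len(self.records)

    def has(self, protein: str, domain: str) -> bool:
        return (protein, domain) in self._pairs

    @property
    def proteins(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for p, _ in self.records:
            seen.setdefault(p)
        return tuple(seen)

    @property
    def domains(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for _, d in self.records:
            seen.setdefault(d)
        return tuple(seen)


# ---------------------------------------------------------------------------
# readers


def _data_lines(path, comment: str):
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith(comment):
                continue
            yield lineno, line


def read_ppi_edgelist(path) -> PPIGraph:
    """Read a 2+-column TSV of undirected interactions.

    Self-pairs are dropped (their endpoints still enter the protein list),
    duplicate pairs in either orientation collapse, and protein order is
    first appearance.  An empty file is an error.
    """
    proteins: dict[str, None] = {}
    edges: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    for lineno, line in _data_lines(path, "#"):
        fields = line.split("\t")
        if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
            raise ParseError(f"{path}: line {lineno}: expected >=2 tab-separated fields")
        a, b = fields[0].strip(), fields[1].strip()
        proteins.setdefault(a)
        proteins.setdefault(b)
        if a == b:
            continue
        key = _canonical(a, b)
        if key not in seen:
            seen.add(key)
            edges.append(key)
    if not proteins:
        raise ValueError(f"{path}: no interactions found (empty edge list)")
    return PPIGraph(tuple(proteins), tuple(edges))


def read_complex_catalog(path) -> ComplexCatalog:
    """Read one complex per line: complex ID, then tab-separated members."""
    complexes: list[tuple[str, frozenset[str]]] = []
    for lineno, line in _data_lines(path, "#"):
        fields = [f.strip() for f in line.split("\t") if f.strip()]
        if len(fields) < 2:
            raise ParseError(f"{path}: line {lineno}: complex with zero members")
        complexes.append((fields[0], frozenset(fields[1:])))
    return ComplexCatalog(tuple(complexes))


def read_gaf(path, ontology: str) -> AnnotationCatalog:
    """Read a GAF 2.x file, keeping rows of one ontology aspect.

    Rows whose qualifier contains ``NOT`` are excluded (standard GAF
    semantics); duplicate (protein, term) rows collapse.
    """
    if ontology not in ASPECT_BY_ONTOLOGY:
        raise ValueError(f"unknown ontology {ontology!r}; expected BP, MF or CC")
    want = ASPECT_BY_ONTOLOGY[ontology]
    annotations: dict[str, set[str]] = {}
    for lineno, line in _data_lines(path, "!"):
        fields = line.split("\t")
        if len(fields) < 9:
            raise ParseError(f"{path}: line {lineno}: expected >=9 GAF columns")
        protein = fields[1].strip()
        qualifier = fields[3].strip()
        term = fields[4].strip()
        aspect = fields[8].strip()
        if aspect not in ONTOLOGY_BY_ASPECT:
            raise ParseError(f"{path}: line {lineno}: unknown aspect code {aspect!r}")
        if aspect != want:
            continue
        if "NOT" in qualifier.split("|"):
            continue
        if not protein or not term:
            raise ParseError(f"{path}: line {lineno}: empty protein or term ID")
        annotations.setdefault(protein, set()).add(term)
    return AnnotationCatalog(ontology, {p: frozenset(t) for p, t in annotations.items()})


def read_domain_associations(path) -> DomainAssociationTable:
    """Read a 2-column TSV of (protein ID, domain accession) pairs."""
    records: list[tuple[str, str]] = []
    for lineno, line in _data_lines(path, "#"):
        fields = line.split("\t")
        if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
            raise ParseError(f"{path}: line {lineno}: expected protein and domain columns")
        records.append((fields[0].strip(), fields[1].strip()))
    return DomainAssociationTable(tuple(records))


def read_prediction_table(path) -> dict[str, list[tuple[str, float]]]:
    """Read a prediction TSV back into protein -> ranked (term, score) lists."""
    out: dict[str, list[tuple[str, float]]] = {}
    header_skipped = False
    for lineno, line in _data_lines(path, "#"):
        fields = line.split("\t")
        if not header_skipped:
            header_skipped = True
            if fields[0] == "protein":
                continue
        if len(fields) < 4:
            raise ParseError(f"{path}: line {lineno}: expected 4 columns")
        protein, _rank, term, score = fields[0], fields[1], fields[2], fields[3]
        out.setdefault(protein, []).append((term, float(score)))
    return out


# ---------------------------------------------------------------------------
# writers


def write_ppi_edgelist(graph: PPIGraph, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        # the edge-list format cannot carry isolated proteins; callers that
        # need them keep the generator's protein list (simulate sidecar).
        for a, b in graph.edges:
            fh.write(f"{a}\t{b}\n")


def write_complex_catalog(catalog: ComplexCatalog, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for cid, members in catalog.complexes:
            fh.write(cid + "\t" + "\t".join(sorted(members)) + "\n")


def write_gaf(catalog: AnnotationCatalog, path) -> None:
    aspect = ASPECT_BY_ONTOLOGY[catalog.ontology]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("!gaf-version: 2.2\n")
        for protein in sorted(catalog.annotations):
            for term in sorted(catalog.annotations[protein]):
                row = [
                    "SYN",  # DB
                    protein,  # DB object ID
                    protein,  # symbol
                    "involved_in",  # qualifier
                    term,  # GO ID
                    "SYN:0000000",  # reference
                    "IEA",  # evidence
                    "",  # with/from
                    aspect,  # aspect
                    "",
                    "",
                    "protein",
                    "taxon:4932",
                    "20220825",
                    "SYN",
                    "",
                    "",
                ]
                fh.write("\t".join(row) + "\n")


def write_domain_associations(table: DomainAssociationTable, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for protein, domain in table.records:
            fh.write(f"{protein}\t{domain}\n")


def write_prediction_table(
    predictions: Mapping[str, Sequence[tuple[str, float]]], path
) -> None:
    """Write a 4-column TSV: protein, rank, term, score.

    Rows per protein are ordered by score descending, then term ID
    ascending, so output bytes are a pure function of the input.
    """
    for protein, entries in predictions.items():
        for term, score in entries:
            if not math.isfinite(score) or score < 0:
                raise ValueError(
                    f"score for ({protein!r}, {term!r}) must be finite and nonnegative"
                )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("protein\trank\tterm\tscore\n")
        for protein, entries in predictions.items():
            ordered = sorted(entries, key=lambda e: (-e[1], e[0]))
            for rank, (term, score) in enumerate(ordered, start=1):
                fh.write(f"{protein}\t{rank}\t{term}\t{score:.10g}\n")
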