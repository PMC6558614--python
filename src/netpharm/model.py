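"""Domain types shared by every pipeline stage.

Gene symbols are case-normalized to upper case wherever they enter the
system (parsers, generators, constructors that accept raw strings); mixed
case symbols from different source databases otherwise cause silent
intersection failures downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import networkx as nx
import numpy as np


class FormatError(ValueError):
    """A file does not conform to the expected tabular/GMT/graph dialect."""


class ValidationError(ValueError):
    """A value violates a domain invariant (range, uniqueness, reference)."""


# Node roles used across all networks.
ROLE_COMPOUND = "compound"
ROLE_TARGET = "target"
ROLE_HERB = "herb"
ROLE_PATHWAY = "pathway"

NETWORK_KINDS = ("bipartite", "unipartite", "heterogeneous")
GENESET_CATEGORIES = ("BP", "MF", "CC", "pathway")


@dataclass
class Compound:
    """A chemical entity of the preparation.

    Parameters
    ----------
    compound_id
        Opaque unique key (e.g. a PubChem CID or a local accession).
    name
        Human-readable compound name.
    smiles
        Canonical structure string, or ``None`` when the source database
        carried no structure.  Curated collections never contain ``None``.
    herb
        Herb of origin (e.g. ``"kushen"``, ``"baituling"``).
    descriptors
        Molecular descriptor vector, filled in by
        :func:`netpharm.chem.compute_descriptors`.
    cluster
        K-means cluster label, filled in by clustering.
    """

    compound_id: str
    name: str
    smiles: Optional[str] = None
    herb: Optional[str] = None
    descriptors: Optional[np.ndarray] = None
    cluster: Optional[int] = None


@dataclass(frozen=True)
class TargetGene:
    """A protein target, identified by its gene symbol.

    ``roles`` is a subset of {"putative", "disease", "common"}; "common"
    (appearing in both the compound-putative-target network and the disease
    PPI network) implies both of the others.
    """

    symbol: str
    roles: frozenset = frozenset()

    def __post_init__(self):
        if not self.symbol:
            raise ValidationError("target gene symbol must be non-empty")
        if "common" in self.roles and not {"putative", "disease"} <= set(self.roles):
            raise ValidationError(
                f"{self.symbol}: role 'common' implies 'putative' and 'disease'"
            )


@dataclass(frozen=True)
class CompoundTargetEdge:
    """One compound→predicted-target association."""

    compound_id: str
    symbol: str
    provenance: Optional[str] = None


@dataclass(frozen=True)
class PPIEdge:
    """An undirected protein-protein interaction with a combined
    confidence score in [0, 1] (STRING convention)."""

    a: str
    b: str
    score: float

    def __post_init__(self):
        if self.a == self.b:
            raise ValidationError(f"PPI self-loop on {self.a!r}")
        if not (0.0 <= self.score <= 1.0):
            raise ValidationError(
                f"PPI score {self.score} for ({self.a}, {self.b}) outside [0, 1]"
            )

    @property
    def key(self) -> tuple:
        """Order-independent pair key used for deduplication."""
        return (self.a, self.b) if self.a <= self.b else (self.b, self.a)


@dataclass(frozen=True)
class GeneSet:
    """An annotation term (GO category or pathway) with its member genes."""

    term_id: str
    term_name: str
    category: str
    genes: frozenset

    def __post_init__(self):
        if self.category not in GENESET_CATEGORIES:
            raise ValidationError(
                f"{self.term_id}: category {self.category!r} not one of "
                f"{GENESET_CATEGORIES}"
            )
        if not self.genes:
            raise ValidationError(f"{self.term_id}: gene set is empty")


@dataclass
class Network:
    """An undirected typed graph with node-role attributes.

    ``kind`` is one of ``bipartite`` (compound-target), ``unipartite``
    (protein-protein) or ``heterogeneous`` (herb-compound-target-pathway).
    The underlying container is a :class:`networkx.Graph`; every node
    carries a ``role`` attribute.
    """

    name: str
    kind: str
    graph: nx.Graph = field(default_factory=nx.Graph)

    def __post_init__(self):
        if self.kind not in NETWORK_KINDS:
            raise ValidationError(f"unknown network kind {self.kind!r}")

    # -- construction -------------------------------------------------

    def add_node(self, node: str, role: str) -> None:
        self.graph.add_node(node, role=role)

    def add_edge(self, u: str, v: str) -> None:
        if u == v:
            raise ValidationError(f"self-loop on {u!r}")
        if u not in self.graph or v not in self.graph:
            raise ValidationError(f"edge ({u}, {v}) references an unknown node")
        self.graph.add_edge(u, v)

    # -- queries ------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def role(self, node: str) -> str:
        return self.graph.nodes[node]["role"]

    def nodes_by_role(self, role: str) -> list:
        return sorted(n for n, d in self.graph.nodes(data=True) if d["role"] == role)

    def edge_set(self) -> set:
        return {tuple(sorted(e)) for e in self.graph.edges()}

    def validate(self) -> None:
        """Check the structural invariants; raise ValidationError on breach."""
        for n, d in self.graph.nodes(data=True):
            if "role" not in d:
                raise ValidationError(f"node {n!r} has no role attribute")
        for u, v in self.graph.edges():
            if u == v:
                raise ValidationError(f"self-loop on {u!r}")
            if self.kind == "bipartite":
                roles = {self.role(u), self.role(v)}
                if roles != {ROLE_COMPOUND, ROLE_TARGET}:
                    raise ValidationError(
                        f"bipartite edge ({u}, {v}) joins roles {sorted(roles)}"
                    )


def normalize_symbol(symbol: str) -> str:
    return symbol.strip().upper()


def dedupe_ct_edges(edges: Iterable[CompoundTargetEdge]) -> list:
    """Collapse duplicate (compound, target) pairs, keeping first provenance."""
    seen = {}
    for e in edges:
        key = (e.compound_id, e.symbol)
        if key not in seen:
            seen[key] = e
    return list(seen.values())


def dedupe_ppi_edges(edges: Iterable[PPIEdge]) -> list:
    """Collapse unordered-pair duplicates keeping the maximum score.

    Maximum is the conservative merge for a downstream "confidence above
    threshold" filter: an interaction reported at high confidence by any
    row stays above the cutoff.
    """
    best: Mapping[tuple, PPIEdge] = {}
    for e in edges:
        prev = best.get(e.key)
        if prev is None or e.score > prev.score:
            best[e.key] = e
    return list(best.values())
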