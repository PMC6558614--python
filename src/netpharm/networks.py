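"""Construction of the four analysis networks.

1. compound-putative-target (bipartite),
2. disease PPI (seeds + first neighbors, induced high-confidence edges),
3. their intersection — the compound-disease-target network,
4. the heterogeneous herb-compound-target-pathway summary network.

Isolated nodes are dropped from every constructed network: all reported
node counts refer to endpoint-bearing nodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx

from netpharm.model import (
    Compound,
    CompoundTargetEdge,
    Network,
    PPIEdge,
    ValidationError,
    dedupe_ct_edges,
    dedupe_ppi_edges,
    ROLE_COMPOUND,
    ROLE_HERB,
    ROLE_PATHWAY,
    ROLE_TARGET,
)


@dataclass
class IntersectionResult:
    """Outcome of intersecting the compound network with the disease network.

    ``common_targets`` are the putative targets that also appear in the
    disease PPI network; compounds left without any common target are
    recorded in ``dropped_compounds``, non-common targets in
    ``dropped_targets``.
    """

    network: Network
    common_targets: set = field(default_factory=set)
    dropped_compounds: set = field(default_factory=set)
    dropped_targets: set = field(default_factory=set)


def build_bipartite(
    compounds: Iterable[Compound],
    ct_edges: Iterable[CompoundTargetEdge],
    name: str = "compound-putative-target",
) -> Network:
    """Link compounds to their predicted targets.

    Compounds without any edge are omitted (the node count equals
    edge-bearing compounds plus distinct targets).

    Raises
    ------
    ValidationError
        If an edge references a compound absent from ``compounds``.
    """
    known = {c.compound_id for c in compounds}
    edges = dedupe_ct_edges(ct_edges)
    net = Network(name, "bipartite")
    for e in edges:
        if e.compound_id not in known:
            raise ValidationError(f"edge references unknown compound {e.compound_id!r}")
        net.add_node(e.compound_id, ROLE_COMPOUND)
        net.add_node(e.symbol, ROLE_TARGET)
        net.add_edge(e.compound_id, e.symbol)
    return net


def filter_ppi(edges: Iterable[PPIEdge], min_score: float = 0.7, strict: bool = True) -> list:
    """Keep interactions above the confidence cutoff.

    ``strict=True`` (default) keeps score > min_score — the literal
    reading of a "confidence higher than 0.7" extraction; ``strict=False``
    keeps score >= min_score.
    """
    if not (0.0 <= min_score <= 1.0):
        raise ValidationError(f"min_score {min_score} outside [0, 1]")
    if strict:
        return [e for e in edges if e.score > min_score]
    return [e for e in edges if e.score >= min_score]


def expand_disease_network(
    seeds: Iterable[str],
    ppi: Iterable[PPIEdge],
    name: str = "disease-ppi",
) -> Network:
    """One-shell expansion: seeds plus their first neighbors, with all
    filtered PPI edges among that node set (induced subgraph).

    Seeds with no interaction in the filtered PPI are dropped, so a seed
    set disjoint from the PPI yields an empty network.
    """
    seeds = {s.strip().upper() for s in seeds}
    if not seeds:
        raise ValidationError("empty disease seed list")
    edges = dedupe_ppi_edges(ppi)
    g = nx.Graph()
    for e in edges:
        g.add_edge(e.a, e.b)
    present = seeds & set(g.nodes)
    shell = set(present)
    for s in present:
        shell.update(g.neighbors(s))
    sub = g.subgraph(shell)
    net = Network(name, "unipartite")
    for u, v in sub.edges():
        net.add_node(u, ROLE_TARGET)
        net.add_node(v, ROLE_TARGET)
        net.add_edge(u, v)
    return net


def intersect(compound_net: Network, disease_net: Network) -> IntersectionResult:
    """Keep the targets common to both networks and the compound edges
    incident to them; compounds reduced to degree 0 are dropped.

    The operation is idempotent: intersecting the result with the same
    disease network again changes nothing.
    """
    if compound_net.kind != "bipartite":
        raise ValidationError("compound network must be bipartite")
    putative = set(compound_net.nodes_by_role(ROLE_TARGET))
    disease_genes = set(disease_net.graph.nodes)
    common = putative & disease_genes

    net = Network("compound-disease-target", "bipartite")
    for u, v in compound_net.graph.edges():
        c, t = (u, v) if compound_net.role(u) == ROLE_COMPOUND else (v, u)
        if t in common:
            net.add_node(c, ROLE_COMPOUND)
            net.add_node(t, ROLE_TARGET)
            net.add_edge(c, t)
    kept_compounds = set(net.nodes_by_role(ROLE_COMPOUND))
    return IntersectionResult(
        network=net,
        common_targets=common,
        dropped_compounds=set(compound_net.nodes_by_role(ROLE_COMPOUND)) - kept_compounds,
        dropped_targets=putative - common,
    )


def assemble_hctp(
    herb_map: Mapping[str, str],
    intersection: IntersectionResult,
    enrichment,
    name: str = "herb-compound-target-pathway",
) -> Network:
    """Assemble the heterogeneous summary network.

    Herb–compound edges come from ``herb_map`` (compound id → herb);
    compound–target edges are those of the intersected network; each
    significant pathway term is linked to its member genes among the
    retained targets.

    Parameters
    ----------
    herb_map
        Herb of origin for every retained compound.
    intersection
        Result of :func:`intersect`.
    enrichment
        Significant :class:`~netpharm.enrichment.EnrichmentRow` objects;
        only rows with category ``pathway`` contribute pathway nodes.
    """
    inner = intersection.network
    compounds = inner.nodes_by_role(ROLE_COMPOUND)
    targets = set(inner.nodes_by_role(ROLE_TARGET))

    net = Network(name, "heterogeneous")
    for c in compounds:
        herb = herb_map.get(c)
        if not herb:
            raise ValidationError(f"compound {c!r} has no herb of origin")
        net.add_node(herb, ROLE_HERB)
        net.add_node(c, ROLE_COMPOUND)
        net.add_edge(herb, c)
    for u, v in inner.graph.edges():
        net.add_node(u, inner.role(u))
        net.add_node(v, inner.role(v))
        net.add_edge(u, v)
    for row in enrichment:
        if row.category != "pathway":
            continue
        hit = row.genes & targets
        if not hit:
            continue
        net.add_node(row.term_id, ROLE_PATHWAY)
        for t in sorted(hit):
            net.add_edge(t, row.term_id)
    return net
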