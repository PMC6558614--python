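import random

import pytest

from netpharm.enrichment import EnrichmentRow
from netpharm.model import Compound, CompoundTargetEdge, Network, PPIEdge, ValidationError
from netpharm.networks import (
    assemble_hctp,
    build_bipartite,
    expand_disease_network,
    filter_ppi,
    intersect,
    IntersectionResult,
)


def _compounds(*ids):
    return [Compound(compound_id=i, name=i, smiles="C", herb="kushen") for i in ids]


def _ct(pairs):
    return [CompoundTargetEdge(c, t) for c, t in pairs]


class TestBuildBipartite:
    def test_case_study_counts(self, bipartite_net):
        assert bipartite_net.n_nodes == 196
        assert bipartite_net.n_edges == 326
        assert len(bipartite_net.nodes_by_role("compound")) == 16
        assert len(bipartite_net.nodes_by_role("target")) == 180

    def test_two_compounds_sharing_a_target(self):
        net = build_bipartite(_compounds("c1", "c2"), _ct([("c1", "T1"), ("c2", "T1")]))
        assert (net.n_nodes, net.n_edges) == (3, 2)

    def test_empty_edge_list_gives_empty_network(self):
        net = build_bipartite(_compounds("c1"), [])
        assert (net.n_nodes, net.n_edges) == (0, 0)

    def test_unknown_compound_rejected(self):
        with pytest.raises(ValidationError, match="ghost"):
            build_bipartite(_compounds("c1"), _ct([("ghost", "T1")]))

    def test_duplicate_edges_collapse(self):
        net = build_bipartite(
            _compounds("c1"), _ct([("c1", "T1"), ("c1", "T1"), ("c1", "T2")])
        )
        assert net.n_edges == 2


class TestFilterPpi:
    def test_strict_threshold_excludes_boundary(self):
        edges = [PPIEdge("A", "B", 0.6), PPIEdge("A", "C", 0.7), PPIEdge("B", "C", 0.71)]
        kept = filter_ppi(edges, 0.7, strict=True)
        assert [(e.a, e.b) for e in kept] == [("B", "C")]

    def test_inclusive_variant_keeps_boundary(self):
        edges = [PPIEdge("A", "B", 0.6), PPIEdge("A", "C", 0.7)]
        assert len(filter_ppi(edges, 0.7, strict=False)) == 1
        assert len(filter_ppi(edges, 0.7, strict=True)) == 0

    def test_zero_cutoff_inclusive_keeps_everything(self):
        edges = [PPIEdge("A", "B", 0.0), PPIEdge("A", "C", 0.5)]
        assert len(filter_ppi(edges, 0.0, strict=False)) == 2

    def test_empty_input_empty_output(self):
        assert filter_ppi([], 0.7) == []

    def test_filter_is_idempotent(self):
        edges = [PPIEdge("A", "B", 0.65), PPIEdge("A", "C", 0.9), PPIEdge("B", "D", 0.75)]
        once = filter_ppi(edges, 0.7)
        assert filter_ppi(once, 0.7) == once

    def test_out_of_range_cutoff_rejected(self):
        with pytest.raises(ValidationError):
            filter_ppi([], 1.5)


class TestExpandDiseaseNetwork:
    def test_case_study_counts(self, disease_net):
        assert (disease_net.n_nodes, disease_net.n_edges) == (188, 2019)

    def test_star_around_seed(self):
        ppi = [PPIEdge("S", f"N{i}", 0.9) for i in range(4)]
        net = expand_disease_network(["S"], ppi)
        assert (net.n_nodes, net.n_edges) == (5, 4)

    def test_seeds_absent_from_ppi_are_dropped(self):
        ppi = [PPIEdge("X", "Y", 0.9)]
        net = expand_disease_network(["S1", "S2"], ppi)
        assert net.n_nodes == 0

    def test_induced_edges_between_neighbors_included(self):
        ppi = [PPIEdge("S", "A", 0.9), PPIEdge("S", "B", 0.9), PPIEdge("A", "B", 0.9),
               PPIEdge("B", "C", 0.9)]
        net = expand_disease_network(["S"], ppi)
        # C is two hops away: excluded; A-B edge is induced
        assert set(net.graph.nodes) == {"S", "A", "B"}
        assert net.n_edges == 3

    def test_empty_seed_list_rejected(self):
        with pytest.raises(ValidationError):
            expand_disease_network([], [PPIEdge("A", "B", 0.9)])


def _toy_disease(genes):
    net = Network("d", "unipartite")
    genes = list(genes)
    for g in genes:
        net.add_node(g, "target")
    for a, b in zip(genes, genes[1:]):
        net.add_edge(a, b)
    return net


class TestIntersect:
    def test_case_study_counts(self, intersection):
        net = intersection.network
        assert net.n_nodes == 39
        assert net.n_edges == 41
        assert len(net.nodes_by_role("compound")) == 12
        assert len(net.nodes_by_role("target")) == 27
        assert len(intersection.common_targets) == 27

    def test_compound_with_no_common_target_is_dropped(self):
        bip = build_bipartite(
            _compounds("c1", "c2"), _ct([("c1", "T1"), ("c2", "T2")])
        )
        result = intersect(bip, _toy_disease(["T1", "X"]))
        assert result.common_targets == {"T1"}
        assert result.dropped_compounds == {"c2"}
        assert result.dropped_targets == {"T2"}
        assert result.network.n_nodes == 2

    def test_disjoint_universes_empty_network(self):
        bip = build_bipartite(_compounds("c1"), _ct([("c1", "T1")]))
        result = intersect(bip, _toy_disease(["X", "Y"]))
        assert result.network.n_nodes == 0
        assert result.dropped_compounds == {"c1"}

    def test_intersection_is_idempotent(self, intersection, disease_net):
        again = intersect(intersection.network, disease_net)
        assert again.network.edge_set() == intersection.network.edge_set()
        assert again.dropped_compounds == set()

    def test_edges_are_subset_of_compound_network(self, intersection, bipartite_net):
        assert intersection.network.edge_set() <= bipartite_net.edge_set()

    @pytest.mark.parametrize("seed", range(100))
    def test_random_pairs_idempotence_and_conservation(self, seed):
        rng = random.Random(seed)
        compounds = _compounds(*[f"c{i}" for i in range(rng.randint(2, 6))])
        targets = [f"T{i}" for i in range(rng.randint(2, 10))]
        pairs = set()
        for c in compounds:
            for t in rng.sample(targets, rng.randint(1, len(targets))):
                pairs.add((c.compound_id, t))
        bip = build_bipartite(compounds, _ct(sorted(pairs)))
        disease = _toy_disease(rng.sample(targets, rng.randint(2, len(targets))))
        result = intersect(bip, disease)
        # conservation: intersected edges are a subset, roles preserved
        assert result.network.edge_set() <= bip.edge_set()
        for node in result.network.graph.nodes:
            assert result.network.role(node) == bip.role(node)
        # no retained compound has degree 0
        deg = dict(result.network.graph.degree())
        assert all(deg[c] > 0 for c in result.network.nodes_by_role("compound"))
        # idempotence
        again = intersect(result.network, disease)
        assert again.network.edge_set() == result.network.edge_set()


def _row(term_id, genes, category="pathway"):
    k = len(genes)
    return EnrichmentRow(
        term_id=term_id, term_name=term_id, category=category,
        k=k, n=10, K=k + 5, N=100, p_value=1e-4, fdr=1e-3,
        genes=frozenset(genes),
    )


class TestAssembleHctp:
    def test_single_chain(self):
        bip = build_bipartite(_compounds("c1"), _ct([("c1", "T1")]))
        inter = intersect(bip, _toy_disease(["T1", "X"]))
        net = assemble_hctp({"c1": "kushen"}, inter, [_row("P1", ["T1"])])
        assert net.n_nodes == 4
        assert net.edge_set() == {("c1", "kushen"), ("T1", "c1"), ("P1", "T1")}

    def test_empty_enrichment_no_pathway_nodes(self, intersection):
        herbs = {c: "kushen" for c in intersection.network.nodes_by_role("compound")}
        net = assemble_hctp(herbs, intersection, [])
        assert net.nodes_by_role("pathway") == []

    def test_case_study_two_herbs_22_pathways(self, bundle, intersection):
        from netpharm.enrichment import enrich

        herbs = {c.compound_id: c.herb for c in bundle.compounds if c.herb}
        rows = enrich(
            intersection.network.nodes_by_role("target"), bundle.gene_sets, fdr_max=0.01
        )
        net = assemble_hctp(herbs, intersection, rows)
        assert len(net.nodes_by_role("herb")) == 2
        assert len(net.nodes_by_role("pathway")) == 22
        assert len(net.nodes_by_role("compound")) == 12
        assert len(net.nodes_by_role("target")) == 27

    def test_missing_herb_rejected(self):
        bip = build_bipartite(_compounds("c1"), _ct([("c1", "T1")]))
        inter = intersect(bip, _toy_disease(["T1", "X"]))
        with pytest.raises(ValidationError, match="c1"):
            assemble_hctp({}, inter, [])

    def test_go_rows_do_not_create_pathway_nodes(self):
        bip = build_bipartite(_compounds("c1"), _ct([("c1", "T1")]))
        inter = intersect(bip, _toy_disease(["T1", "X"]))
        net = assemble_hctp({"c1": "kushen"}, inter, [_row("G1", ["T1"], category="BP")])
        assert net.nodes_by_role("pathway") == []
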