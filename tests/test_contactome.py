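"""Contact-network filtering, hub/connector taxonomy (with a brute-force
remove-and-test oracle), and hypergeometric enrichment."""

import math

import networkx as nx
import numpy as np
import pytest

from aggnuc import contactome as ctm
from aggnuc.simulate import SimScenario, simulate_contactome


def node(pid, hits=(20, 20, 20), length=500, tags=()):
    return ctm.ProteinNode(pid, length, tuple(hits), frozenset(tags))


def connector_oracle(g: nx.Graph, hub_min_degree: int = 5) -> set[str]:
    """Brute force: remove each low-degree node in turn and test whether two
    previously co-component central hubs end up in different components."""
    hubs = {n for n, d in g.degree() if d >= hub_min_degree}
    out = set()
    for v in g.nodes:
        if g.degree(v) >= hub_min_degree:
            continue
        comp = nx.node_connected_component(g, v)
        local = [h for h in hubs if h in comp and h != v]
        if len(local) < 2:
            continue
        g2 = g.copy()
        g2.remove_node(v)
        for i in range(len(local)):
            for j in range(i + 1, len(local)):
                if not nx.has_path(g2, local[i], local[j]):
                    out.add(v)
    return out


class TestFilterProteins:
    def test_rule_application(self):
        kept = ctm.filter_proteins(
            [node("keep", (12, 11, 0)), node("drop", (12, 0, 0))]
        )
        assert [n.protein_id for n in kept] == ["keep"]

    def test_idempotent(self):
        nodes = [node("a", (12, 11, 0)), node("b", (5, 5, 5)), node("c", (30, 0, 30))]
        once = ctm.filter_proteins(nodes)
        assert ctm.filter_proteins(once) == once

    def test_edges_to_dropped_nodes_discarded(self):
        nodes = [node("a"), node("b", (3, 3, 3))]
        g = ctm.build_graph(
            ctm.filter_proteins(nodes), [ctm.ContactEdge("a", "b", 5)]
        )
        assert g.number_of_edges() == 0 and list(g.nodes) == ["a"]


class TestNormalizedDegree:
    def test_per_residue_arithmetic(self):
        assert ctm.normalized_degree(500, 250) == 2.0
        assert ctm.normalized_degree(0, 250) == 0.0

    def test_size_compensation_ordering(self):
        # titin-scale protein ranks below a small protein with fewer contacts
        titin = ctm.normalized_degree(100, 34_000)
        small = ctm.normalized_degree(10, 300)
        assert titin == pytest.approx(100 / 34_000)
        assert small > titin

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            ctm.normalized_degree(5, 0)


def star(center, n_leaves, prefix):
    nodes = [node(center)] + [node(f"{prefix}{i}") for i in range(n_leaves)]
    edges = [ctm.ContactEdge(center, f"{prefix}{i}") for i in range(n_leaves)]
    return nodes, edges


class TestClassifyHubs:
    def test_star_center_is_central_hub(self):
        nodes, edges = star("hub", 5, "leaf")
        labels = ctm.classify_hubs(ctm.build_graph(nodes, edges))
        roles = {l.protein_id: l.role for l in labels}
        assert roles["hub"] == "central_hub"
        assert all(r == "other" for pid, r in roles.items() if pid != "hub")

    def test_bridge_node_is_hub_connector(self):
        n1, e1 = star("hubA", 5, "a")
        n2, e2 = star("hubB", 5, "b")
        nodes = n1 + n2 + [node("bridge")]
        edges = e1 + e2 + [ctm.ContactEdge("hubA", "bridge"),
                           ctm.ContactEdge("bridge", "hubB")]
        labels = ctm.classify_hubs(ctm.build_graph(nodes, edges))
        roles = {l.protein_id: l.role for l in labels}
        assert roles["bridge"] == "hub_connector"

    def test_parallel_bridges_are_not_connectors(self):
        n1, e1 = star("hubA", 5, "a")
        n2, e2 = star("hubB", 5, "b")
        nodes = n1 + n2 + [node("br1"), node("br2")]
        edges = e1 + e2
        for br in ("br1", "br2"):
            edges += [ctm.ContactEdge("hubA", br), ctm.ContactEdge(br, "hubB")]
        labels = ctm.classify_hubs(ctm.build_graph(nodes, edges))
        roles = {l.protein_id: l.role for l in labels}
        assert roles["br1"] == "other" and roles["br2"] == "other"

    def test_matches_remove_and_test_oracle_on_random_graphs(self):
        """Connector labels equal the brute-force oracle on sparse random
        graphs up to 200 nodes."""
        rng = np.random.default_rng(53)
        for trial in range(12):
            n = int(rng.integers(20, 201))
            g = nx.gnm_random_graph(n, int(n * 1.3), seed=int(rng.integers(2**31)))
            g = nx.relabel_nodes(g, {i: f"P{i:03d}" for i in g.nodes})
            for v in g.nodes:
                g.nodes[v]["node"] = node(v)
            labels = ctm.classify_hubs(g)
            got = {l.protein_id for l in labels if l.role == "hub_connector"}
            assert got == connector_oracle(g)

    def test_role_counts_conserved(self):
        nodes, edges, _ = simulate_contactome(
            SimScenario(hub_spec=(6, 2, 30), seed=1)
        )
        kept = ctm.filter_proteins(nodes)
        labels = ctm.classify_hubs(ctm.build_graph(kept, edges))
        _, n_hub, n_conn = ctm.count_roles(labels)
        n_other = sum(l.role == "other" for l in labels)
        assert n_hub + n_conn + n_other == len(kept)

    def test_cluster_ids_deterministic_by_sorted_protein_id(self):
        nodes = [node("b1"), node("b2"), node("a1"), node("a2")]
        edges = [ctm.ContactEdge("b1", "b2"), ctm.ContactEdge("a1", "a2")]
        labels = ctm.classify_hubs(ctm.build_graph(nodes, edges))
        by_id = {l.protein_id: l.cluster_id for l in labels}
        assert by_id["a1"] == by_id["a2"] == 1
        assert by_id["b1"] == by_id["b2"] == 2


class TestCountRoles:
    def test_empty_graph(self):
        assert ctm.count_roles([]) == (0, 0, 0)

    def test_single_edge_is_one_cluster_no_hubs(self):
        labels = ctm.classify_hubs(
            ctm.build_graph([node("a"), node("b")], [ctm.ContactEdge("a", "b")])
        )
        assert ctm.count_roles(labels) == (1, 0, 0)

    def test_planted_census_recovered_exactly(self):
        """The 11-cluster / 24-hub / 4-connector scenario is recovered
        exactly from the generated tables."""
        scn = SimScenario(hub_spec=(24, 4, 120), n_clusters=11, seed=3)
        nodes, edges, truth = simulate_contactome(scn)
        kept = ctm.filter_proteins(nodes)
        labels = ctm.classify_hubs(ctm.build_graph(kept, edges))
        assert ctm.count_roles(labels) == (11, 24, 4)
        by_role = {}
        for l in labels:
            by_role.setdefault(l.role, set()).add(l.protein_id)
        assert by_role["central_hub"] == set(
            truth[truth.role == "central_hub"].protein_id
        )
        assert by_role["hub_connector"] == set(
            truth[truth.role == "hub_connector"].protein_id
        )

    def test_recovery_exact_across_seeds(self):
        """Hub and connector labels recovered exactly on many seeded
        scenarios (the construction guarantees them)."""
        for seed in range(25):
            scn = SimScenario(hub_spec=(8, 3, 40), n_clusters=4, seed=seed)
            nodes, edges, truth = simulate_contactome(scn)
            kept = ctm.filter_proteins(nodes)
            labels = ctm.classify_hubs(ctm.build_graph(kept, edges))
            n_clusters, n_hub, n_conn = ctm.count_roles(labels)
            assert (n_clusters, n_hub, n_conn) == (4, 8, 3)

    def test_planted_dropouts_absent_after_filtering(self):
        scn = SimScenario(hub_spec=(4, 1, 20), n_dropout_proteins=5, seed=7)
        nodes, edges, truth = simulate_contactome(scn)
        kept_ids = {n.protein_id for n in ctm.filter_proteins(nodes)}
        assert kept_ids == set(truth[truth.kept].protein_id)


class TestAnnotationEnrichment:
    def test_fully_tagged_background_gives_p_one(self):
        bg = [node(f"p{i}", tags=("RNA-binding",)) for i in range(10)]
        count, p = ctm.annotation_enrichment(
            {"p0", "p1", "p2"}, "RNA-binding", bg
        )
        assert count == 3 and p == pytest.approx(1.0)

    def test_perfect_selection_closed_form(self):
        # 5 tagged among 100; selecting exactly those 5: p = 1/C(100,5)
        bg = [node(f"p{i}", tags=("RNA-binding",) if i < 5 else ())
              for i in range(100)]
        count, p = ctm.annotation_enrichment(
            {f"p{i}" for i in range(5)}, "RNA-binding", bg
        )
        assert count == 5
        assert p == pytest.approx(1 / math.comb(100, 5))

    def test_matches_enumeration_oracle_small_universe(self):
        rng = np.random.default_rng(61)
        for _ in range(20):
            m = int(rng.integers(8, 51))
            k = int(rng.integers(1, m + 1))
            n_draw = int(rng.integers(1, m + 1))
            bg = [node(f"p{i}", tags=("T",) if i < k else ()) for i in range(m)]
            sel = {f"p{i}" for i in rng.choice(m, size=n_draw, replace=False)}
            count, p = ctm.annotation_enrichment(sel, "T", bg)
            # enumeration: sum over x >= count of C(k,x) C(m-k, n-x) / C(m,n)
            expect = sum(
                math.comb(k, x) * math.comb(m - k, n_draw - x)
                for x in range(count, min(k, n_draw) + 1)
            ) / math.comb(m, n_draw)
            assert p == pytest.approx(expect, rel=1e-9)

    def test_empty_background_rejected(self):
        with pytest.raises(ValueError):
            ctm.annotation_enrichment(set(), "T", [])
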