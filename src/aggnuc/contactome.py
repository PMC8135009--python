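"""Crosslink contact network construction and hub taxonomy.

Proteins identified in crosslinking mass-spectrometry replicates form the
nodes; crosslinked peptide pairs form the edges.  Nodes are retained only
when enough replicates independently support them (>= 10 spectral hits in
>= 2 of 3 replicates by default).  On the filtered graph:

* a *central hub* has degree > 4;
* a *hub connector* has degree <= 4 and its removal separates at least two
  central hubs that were connected through it;
* *clusters* are connected components, indexed deterministically by their
  smallest protein id.

Because long proteins accumulate contacts simply by size, a per-residue
normalized degree (degree / protein length in amino acids) is carried
alongside raw degree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Optional, Sequence

import networkx as nx
from scipy import stats


@dataclass
class ProteinNode:
    """A protein with per-replicate spectral support.

    ``length_aa`` is the length in amino acids of the most abundant isoform.
    """

    protein_id: str
    length_aa: int
    hits_per_replicate: tuple[int, ...]
    annotations: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.length_aa < 1:
            raise ValueError(f"{self.protein_id}: length_aa must be >= 1")
        if len(self.hits_per_replicate) < 1:
            raise ValueError(f"{self.protein_id}: need at least 1 replicate")


@dataclass
class ContactEdge:
    protein_a: str
    protein_b: str
    crosslink_count: int = 1
    replicate_support: int = 1

    def __post_init__(self) -> None:
        if self.protein_a == self.protein_b:
            raise ValueError("self-contacts are not edges")
        if self.crosslink_count < 1:
            raise ValueError("crosslink_count must be >= 1")


@dataclass
class HubLabel:
    protein_id: str
    degree: int
    normalized_degree: float
    role: str  # central_hub / hub_connector / other
    cluster_id: int


def filter_proteins(
    nodes: Sequence[ProteinNode], min_hits: int = 10, min_replicates: int = 2
) -> list[ProteinNode]:
    """Keep proteins with >= min_hits spectral hits in >= min_replicates
    replicates.  Idempotent; edges touching dropped nodes are discarded
    when the graph is built."""
    if min_hits < 1 or min_replicates < 1:
        raise ValueError("min_hits and min_replicates must be >= 1")
    return [
        n
        for n in nodes
        if sum(h >= min_hits for h in n.hits_per_replicate) >= min_replicates
    ]


def build_graph(
    nodes: Iterable[ProteinNode], edges: Iterable[ContactEdge]
) -> nx.Graph:
    """Contact graph over the given (already filtered) nodes; edges touching
    absent nodes are dropped."""
    g = nx.Graph()
    for n in nodes:
        g.add_node(n.protein_id, node=n)
    for e in edges:
        if e.protein_a in g and e.protein_b in g:
            g.add_edge(
                e.protein_a,
                e.protein_b,
                crosslink_count=e.crosslink_count,
                replicate_support=e.replicate_support,
            )
    return g


def normalized_degree(degree: int, length_aa: int) -> float:
    """Degree per residue: compensates for protein-size variation, so a
    300-aa protein with 10 contacts ranks above a titin-scale 34,000-aa
    protein with 100."""
    if length_aa < 1:
        raise ValueError("length_aa must be >= 1")
    return degree / length_aa


def _is_connector(g: nx.Graph, node: str, hubs: set[str]) -> bool:
    """True when removing ``node`` places two central hubs of its component
    into different components."""
    comp = nx.node_connected_component(g, node)
    local_hubs = [h for h in hubs if h in comp and h != node]
    if len(local_hubs) < 2:
        return False
    g2 = g.subgraph(comp - {node})
    seen_comp: dict[str, int] = {}
    for idx, cc in enumerate(nx.connected_components(g2)):
        for h in local_hubs:
            if h in cc:
                seen_comp[h] = idx
    ids = {seen_comp.get(h) for h in local_hubs}
    return len(ids) > 1


def classify_hubs(g: nx.Graph, hub_min_degree: int = 5) -> list[HubLabel]:
    """Label every node of a filtered contact graph.

    central_hub: degree >= hub_min_degree (i.e. > 4 edges by default);
    hub_connector: low-degree node whose removal disconnects >= 2 central
    hubs; other: everything else.  cluster_id indexes connected components
    ordered by their smallest protein id (1-based).
    """
    if g.number_of_nodes() == 0:
        return []
    degrees = dict(g.degree())
    hubs = {n for n, d in degrees.items() if d >= hub_min_degree}
    components = sorted(nx.connected_components(g), key=lambda c: min(c))
    cluster_of: dict[str, int] = {}
    for idx, comp in enumerate(components, start=1):
        for n in comp:
            cluster_of[n] = idx
    labels = []
    for n in sorted(g.nodes):
        d = degrees[n]
        if n in hubs:
            role = "central_hub"
        elif _is_connector(g, n, hubs):
            role = "hub_connector"
        else:
            role = "other"
        node_obj: Optional[ProteinNode] = g.nodes[n].get("node")
        nd = normalized_degree(d, node_obj.length_aa) if node_obj else float("nan")
        labels.append(HubLabel(n, d, nd, role, cluster_of[n]))
    return labels


def count_roles(labels: Sequence[HubLabel]) -> tuple[int, int, int]:
    """(n_clusters, n_central_hubs, n_connectors)."""
    if not labels:
        return (0, 0, 0)
    n_clusters = len({l.cluster_id for l in labels})
    n_hubs = sum(l.role == "central_hub" for l in labels)
    n_conn = sum(l.role == "hub_connector" for l in labels)
    return n_clusters, n_hubs, n_conn


def annotation_enrichment(
    selected: set[str],
    annotation_tag: str,
    background: Sequence[ProteinNode],
) -> tuple[int, float]:
    """Upper-tail hypergeometric enrichment of a tag in a selected node set.

    Returns (tagged count in selection, P(X >= count) when drawing
    |selected| nodes from the background universe containing its tagged
    members).
    """
    if not background:
        raise ValueError("background universe is empty")
    universe = {n.protein_id for n in background}
    if not selected <= universe:
        raise ValueError("selected nodes must be a subset of the background")
    tagged = {n.protein_id for n in background if annotation_tag in n.annotations}
    count = len(selected & tagged)
    m, k, n_draw = len(universe), len(tagged), len(selected)
    p = float(stats.hypergeom.sf(count - 1, m, k, n_draw))
    return count, p
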