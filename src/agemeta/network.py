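"""Gene-set similarity network using the overlap coefficient.

Terms are nodes; an edge joins two terms whose gene sets have
oc = |A ∩ B| / min(|A|, |B|) strictly above a threshold (0.4 by default).
Connected components with fewer than a minimum number of nodes (5 by
default) are discarded entirely, leaving only substantial clusters of
related processes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx

from .exceptions import DataError
from .io import GeneSetCatalogue

DEFAULT_OC_THRESHOLD = 0.4
DEFAULT_MIN_CLUSTER = 5


@dataclass
class TermNetwork:
    """Filtered term-similarity graph with its retained components."""

    graph: nx.Graph
    components: list[frozenset[str]]
    oc_threshold: float
    min_cluster: int
    node_attributes: dict[str, dict] = field(default_factory=dict)

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str, float]]:
        return sorted(
            (min(a, b), max(a, b), d["oc"]) for a, b, d in self.graph.edges(data=True)
        )

    def component_of(self, term_id: str) -> int | None:
        for i, comp in enumerate(self.components):
            if term_id in comp:
                return i
        return None


def overlap_coefficient(set_a: Iterable[str], set_b: Iterable[str]) -> float:
    """|A ∩ B| / min(|A|, |B|) for two non-empty gene sets."""
    a, b = set(set_a), set(set_b)
    if not a or not b:
        raise DataError("overlap coefficient undefined for empty sets")
    return len(a & b) / min(len(a), len(b))


def build_network(
    catalogue: GeneSetCatalogue,
    oc_threshold: float = DEFAULT_OC_THRESHOLD,
    min_cluster: int = DEFAULT_MIN_CLUSTER,
    node_attributes: Mapping[str, Mapping] | None = None,
) -> TermNetwork:
    """All-pairs overlap-coefficient network with edge and component filters.

    Edges require oc strictly greater than ``oc_threshold``; components with
    fewer than ``min_cluster`` nodes are removed entirely (including their
    nodes). The result is independent of term input order.
    """
    if len(catalogue) < 1:
        raise DataError("catalogue must contain at least one term")
    graph = nx.Graph()
    terms = sorted(catalogue, key=lambda t: t.term_id)
    for t in terms:
        graph.add_node(t.term_id)
    for i, ta in enumerate(terms):
        for tb in terms[i + 1:]:
            oc = overlap_coefficient(ta.genes, tb.genes)
            if oc > oc_threshold:
                graph.add_edge(ta.term_id, tb.term_id, oc=oc)
    keep: set[str] = set()
    components: list[frozenset[str]] = []
    for comp in nx.connected_components(graph):
        if len(comp) >= min_cluster:
            keep |= comp
            components.append(frozenset(comp))
    graph.remove_nodes_from(set(graph.nodes) - keep)
    components.sort(key=lambda c: (-len(c), min(c)))
    attrs = {}
    if node_attributes:
        attrs = {n: dict(node_attributes[n]) for n in graph.nodes if n in node_attributes}
        nx.set_node_attributes(graph, attrs)
    return TermNetwork(
        graph=graph,
        components=components,
        oc_threshold=oc_threshold,
        min_cluster=min_cluster,
        node_attributes=attrs,
    )
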