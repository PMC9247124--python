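"""Seed-and-connector assembly of per-disease biological networks.

Refined disease genes become network seeds; where direct seed–seed
interactions are sparse (as they typically are for short curated lists),
non-seed *connector* genes are recruited greedily from a supplied weighted
gene–gene interaction network — a local, deterministic surrogate for a
web-based gene-function-prediction service, accepting its exported edge
lists unchanged.  Assembled networks carry curated gene→process
annotations and can be merged across diseases to expose shared processes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx

__all__ = [
    "EDGE_KINDS",
    "InteractionNetwork",
    "DiseaseNetwork",
    "MergedNetwork",
    "find_direct_links",
    "find_connectors",
    "annotate_processes",
    "build_disease_network",
    "merge_networks",
]

EDGE_KINDS = ("physical", "coexpression", "pathway", "predicted", "other")

UNANNOTATED = "unannotated"


class InteractionNetwork:
    """Undirected weighted gene–gene interaction network.

    At most one edge per unordered pair per interaction kind; per-pair kind
    weights are kept separately and summed for ranking.  Self-loops are
    rejected; weights must lie in (0, 1].
    """

    def __init__(self) -> None:
        self.graph = nx.Graph()

    def add_edge(self, a: str, b: str, weight: float, kind: str = "other") -> None:
        if a == b:
            raise ValueError(f"self-loop rejected: {a!r}")
        if not 0.0 < weight <= 1.0:
            raise ValueError(f"edge weight must be in (0, 1], got {weight}")
        if kind not in EDGE_KINDS:
            raise ValueError(f"unknown interaction kind {kind!r}")
        if self.graph.has_edge(a, b):
            kinds = self.graph[a][b]["kinds"]
        else:
            kinds = {}
            self.graph.add_edge(a, b, kinds=kinds)
        kinds[kind] = weight
        self.graph[a][b]["weight"] = sum(kinds.values())

    def add_node(self, node: str) -> None:
        self.graph.add_node(node)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    def edges(self) -> list[tuple[str, str, float]]:
        return [
            (*sorted((a, b)), data["weight"]) for a, b, data in self.graph.edges(data=True)
        ]

    def neighbors(self, node: str) -> set[str]:
        if node not in self.graph:
            return set()
        return set(self.graph.neighbors(node))

    def weight(self, a: str, b: str) -> float:
        return self.graph[a][b]["weight"]

    def __contains__(self, node: str) -> bool:
        return node in self.graph

    def __len__(self) -> int:
        return self.graph.number_of_nodes()


@dataclass
class DiseaseNetwork:
    """Assembled network for one disease.

    ``seed_genes`` maps each refined gene to its direction label;
    ``edges`` maps sorted node pairs to summed interaction weight.  The
    ``partial`` flag records that the seeds could not all be interlinked.
    """

    disease_id: str
    seed_genes: dict[str, str]
    connector_genes: set[str]
    edges: dict[tuple[str, str], float]
    process_annotations: dict[str, frozenset[str]] = field(default_factory=dict)
    partial: bool = False

    @property
    def nodes(self) -> set[str]:
        return set(self.seed_genes) | set(self.connector_genes)

    def validate(self) -> None:
        """Machine-check the structural invariants."""
        overlap = set(self.seed_genes) & self.connector_genes
        if overlap:
            raise ValueError(f"seed/connector overlap: {sorted(overlap)}")
        nodes = self.nodes
        adjacency: dict[str, set[str]] = {}
        for (a, b) in self.edges:
            if a not in nodes or b not in nodes:
                raise ValueError(f"edge ({a}, {b}) has endpoint outside the network")
            adjacency.setdefault(a, set()).add(b)
            adjacency.setdefault(b, set()).add(a)
        for c in self.connector_genes:
            if len(adjacency.get(c, set())) < 2:
                raise ValueError(
                    f"connector {c!r} has fewer than 2 neighbors in the network"
                )

    def processes(self) -> set[str]:
        out: set[str] = set()
        for labels in self.process_annotations.values():
            out |= labels
        return out - {UNANNOTATED}


@dataclass
class MergedNetwork:
    """Union of per-disease networks with disease-membership tags."""

    members: list[DiseaseNetwork]
    node_diseases: dict[str, set[str]]
    edges: dict[tuple[str, str], float]
    shared_processes: dict[str, set[str]]

    @property
    def nodes(self) -> set[str]:
        return set(self.node_diseases)

    def processes_shared_by_all(self) -> set[str]:
        disease_ids = {m.disease_id for m in self.members}
        return {
            p for p, ds in self.shared_processes.items() if ds == disease_ids
        }

    def processes_shared_by(self, diseases: Iterable[str]) -> set[str]:
        wanted = set(diseases)
        return {p for p, ds in self.shared_processes.items() if wanted <= ds}


def find_direct_links(
    seeds: Iterable[str], net: InteractionNetwork
) -> set[tuple[str, str]]:
    """All network edges with both endpoints in the seed set."""
    seed_set = set(seeds)
    return {
        (a, b) for a, b, _w in net.edges() if a in seed_set and b in seed_set
    }


def find_connectors(
    seeds: Iterable[str],
    net: InteractionNetwork,
    max_connectors: int = 10,
) -> list[str]:
    """Greedy recruitment of connector genes interlinking the seeds.

    Repeatedly adds the non-seed node with the most neighbors among
    seeds ∪ selected connectors (ties: higher summed edge weight, then
    lexicographic name), requiring at least two such neighbors spanning at
    least two of the current seed-containing components, until the seeds
    form a single component, no eligible candidate remains, or
    ``max_connectors`` is reached.  Deterministic for a given network.
    """
    if max_connectors < 0:
        raise ValueError("max_connectors must be >= 0")
    seed_set = set(seeds)
    selected: list[str] = []

    def seed_components() -> list[set[str]]:
        sub = net.graph.subgraph((seed_set | set(selected)) & net.nodes)
        comps = [set(c) for c in nx.connected_components(sub)] if len(sub) else []
        # seeds absent from the supplied network are isolated components
        comps.extend({s} for s in seed_set - net.nodes)
        return [c for c in comps if c & seed_set or c & set(selected)]

    def component_of() -> dict[str, int]:
        return {node: i for i, comp in enumerate(seed_components()) for node in comp}

    while len(selected) < max_connectors:
        comp_index = component_of()
        n_comps = len(set(comp_index.values()))
        if n_comps <= 1:
            break
        active = (seed_set | set(selected)) & net.nodes
        best: tuple[int, float, str] | None = None
        best_node: str | None = None
        for v in sorted(net.nodes - seed_set - set(selected)):
            nbrs = net.neighbors(v) & active
            if len(nbrs) < 2:
                continue
            touched = {comp_index[u] for u in nbrs if u in comp_index}
            if len(touched) < 2:
                continue  # cannot merge anything
            wsum = sum(net.weight(v, u) for u in nbrs)
            key = (len(nbrs), wsum, v)
            if best is None or (key[0], key[1]) > (best[0], best[1]):
                best, best_node = key, v
        if best_node is None:
            break
        selected.append(best_node)
    return selected


def annotate_processes(
    genes: Iterable[str], annotation: Mapping[str, Iterable[str]]
) -> dict[str, frozenset[str]]:
    """Restrict a curated gene→process annotation to the given genes.

    Genes without an entry map to the sentinel label ``unannotated``.
    """
    out: dict[str, frozenset[str]] = {}
    for g in genes:
        labels = annotation.get(g)
        out[g] = frozenset(labels) if labels else frozenset({UNANNOTATED})
    return out


def build_disease_network(
    selection,
    net: InteractionNetwork,
    annotation: Mapping[str, Iterable[str]] | None = None,
    max_connectors: int = 10,
) -> DiseaseNetwork:
    """Assemble seeds + direct links + connector-incident edges.

    ``selection`` is a GeneSelection (or any object with ``refined_genes``
    as (gene, direction, score) triples).  Raises on an empty refined list.
    Seeds disconnected from the supplied network remain as isolated nodes
    and the network is flagged partial.
    """
    refined = list(selection.refined_genes)
    if not refined:
        raise ValueError(f"empty refined gene list for {selection.disease_id!r}")
    seed_genes = {gene: direction for gene, direction, _score in refined}
    seeds = set(seed_genes)
    direct = find_direct_links(seeds, net)
    connectors = find_connectors(seeds, net, max_connectors=max_connectors)
    members = seeds | set(connectors)
    edges: dict[tuple[str, str], float] = {
        (a, b): net.weight(a, b) for (a, b) in direct
    }
    for c in connectors:
        for u in net.neighbors(c) & members:
            a, b = sorted((c, u))
            edges[(a, b)] = net.weight(a, b)
    # partial if the seeds still span more than one component
    sub = nx.Graph()
    sub.add_nodes_from(members)
    sub.add_edges_from(edges)
    n_seed_comps = len({frozenset(comp) for comp in nx.connected_components(sub) if comp & seeds})
    network = DiseaseNetwork(
        disease_id=selection.disease_id,
        seed_genes=seed_genes,
        connector_genes=set(connectors),
        edges=edges,
        process_annotations=annotate_processes(members, annotation or {}),
        partial=n_seed_comps > 1,
    )
    network.validate()
    return network


def merge_networks(nets: Sequence[DiseaseNetwork]) -> MergedNetwork:
    """Union per-disease networks into one joint network.

    Nodes and edges are unioned (no edges invented); each node carries the
    set of diseases whose network contains it.  ``shared_processes`` maps
    each annotated process to the diseases exhibiting it, so a process
    mapped to every member disease is a common event across the diseases.
    """
    if len(nets) < 2:
        raise ValueError("need at least two networks to merge")
    node_diseases: dict[str, set[str]] = {}
    edges: dict[tuple[str, str], float] = {}
    shared: dict[str, set[str]] = {}
    for n in nets:
        for node in n.nodes:
            node_diseases.setdefault(node, set()).add(n.disease_id)
        edges.update(n.edges)
        for p in n.processes():
            shared.setdefault(p, set()).add(n.disease_id)
    return MergedNetwork(
        members=list(nets),
        node_diseases=node_diseases,
        edges=edges,
        shared_processes=shared,
    )
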