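"""Sequence similarity networks.

All-vs-all comparison of a protein set, 100 %-identity collapsing into
weighted representative nodes, e-value-thresholded edges (D-protein
networks at 1e-54, all-protein networks at 1e-30), optional removal of
small connected components, and component extraction (isofunctional
groups).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx

from . import align

D_NETWORK_EVALUE = 1e-54
ALL_NETWORK_EVALUE = 1e-30
DEFAULT_MIN_COMPONENT = 5

_MAX_NEGLOG10 = 324.0  # clamp for e-values at machine precision


@dataclass
class SSNNode:
    node_id: str  # representative protein id (lexicographically smallest)
    multiplicity: int
    member_ids: list[str]
    attributes: dict = field(default_factory=dict)


@dataclass
class SSNGraph:
    threshold: float
    nodes: dict[str, SSNNode]
    graph: nx.Graph

    @property
    def edges(self) -> list[tuple[str, str, float]]:
        return sorted(
            (min(u, v), max(u, v), data["evalue"]) for u, v, data in self.graph.edges(data=True)
        )


def collapse_identical(proteins: Mapping[str, str]) -> dict[str, SSNNode]:
    """Group exact-duplicate sequences; the representative is the
    lexicographically smallest member id, multiplicity the group size."""
    by_seq: dict[str, list[str]] = {}
    for pid in sorted(proteins):
        by_seq.setdefault(proteins[pid], []).append(pid)
    nodes = {}
    for seq, members in by_seq.items():
        rep = min(members)
        nodes[rep] = SSNNode(node_id=rep, multiplicity=len(members), member_ids=sorted(members))
    return nodes


def build_network(
    proteins: Mapping[str, str],
    threshold: float,
    min_component_size: int | None = None,
    *,
    strict: bool = False,
    count_multiplicity: bool = False,
    node_attributes: Mapping[str, dict] | None = None,
    params: align.ScoringParams = align.DEFAULT_PARAMS,
) -> SSNGraph:
    """Identity-collapsed network with edges where the pairwise e-value
    passes the threshold (``<=`` by default, ``<`` with ``strict=True``).

    Components smaller than ``min_component_size`` are dropped; size counts
    distinct representative nodes unless ``count_multiplicity`` is set.
    Edge weight is -log10(e-value), clamped at machine precision.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    nodes = collapse_identical(proteins)
    reps = {rep: proteins[rep] for rep in nodes}
    graph = nx.Graph()
    log_threshold = math.log10(threshold)
    for rep, node in nodes.items():
        attrs = dict(node_attributes.get(rep, {})) if node_attributes else {}
        graph.add_node(rep, multiplicity=node.multiplicity, **attrs)
        node.attributes = attrs
    if len(reps) > 1:
        hits = align.all_vs_all(reps, params)
        for hit in hits:
            ok = hit.log10_evalue < log_threshold if strict else hit.log10_evalue <= log_threshold
            if ok:
                graph.add_edge(
                    hit.query_id,
                    hit.subject_id,
                    evalue=hit.evalue,
                    neglog10e=min(-hit.log10_evalue, _MAX_NEGLOG10),
                )
    if min_component_size is not None:
        for component in list(nx.connected_components(graph)):
            size = (
                sum(nodes[r].multiplicity for r in component)
                if count_multiplicity
                else len(component)
            )
            if size < min_component_size:
                graph.remove_nodes_from(component)
                for rep in component:
                    del nodes[rep]
    return SSNGraph(threshold=threshold, nodes=nodes, graph=graph)


def components(ssn: SSNGraph) -> list[list[str]]:
    """Connected components (isofunctional groups), deterministically
    ordered by their smallest member."""
    comps = [sorted(c) for c in nx.connected_components(ssn.graph)]
    comps.sort(key=lambda c: c[0])
    return comps


def write_edges_tsv(ssn: SSNGraph, path) -> None:
    with open(path, "w") as fh:
        fh.write("node_a\tnode_b\tevalue\tneglog10e\n")
        for u, v, data in sorted(ssn.graph.edges(data=True)):
            fh.write(f"{u}\t{v}\t{data['evalue']:.3g}\t{data['neglog10e']:.2f}\n")


def write_nodes_tsv(ssn: SSNGraph, path) -> None:
    with open(path, "w") as fh:
        fh.write("node_id\tmultiplicity\trole\tfamily\n")
        for rep in sorted(ssn.nodes):
            node = ssn.nodes[rep]
            role = node.attributes.get("role", ".")
            family = node.attributes.get("family", ".")
            fh.write(f"{rep}\t{node.multiplicity}\t{role}\t{family}\n")


def write_graphml(ssn: SSNGraph, path) -> None:
    nx.write_graphml(ssn.graph, str(path))
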