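"""Five-layer drug--herb--compound--target--pathway network assembly.

The network is strictly layered: edges only connect adjacent layers in
the order drug > herb > compound > target > pathway.  Node ids are
layer-prefixed (``compound:curcumin``) so a compound and a gene may
share a display name.  Compounds with no core-gene target are omitted
by default, as are herbs left without any retained compound.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx

from .ingest import CompoundRecord, GeneSet, TargetMapping

LAYERS = ("drug", "herb", "compound", "target", "pathway")
_LAYER_INDEX = {layer: i for i, layer in enumerate(LAYERS)}


@dataclass(frozen=True)
class LayerNode:
    node_id: str
    layer: str
    display_name: str

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise ValueError(f"unknown layer {self.layer!r}")
        if not self.node_id.startswith(self.layer + ":"):
            raise ValueError(f"node_id {self.node_id!r} must be prefixed '{self.layer}:'")


def make_id(layer: str, name: str) -> str:
    return f"{layer}:{name}"


@dataclass
class MultipartiteNetwork:
    """Layered node list plus adjacent-layer edges (stored upper->lower)."""

    nodes: list[LayerNode] = field(default_factory=list)
    edges: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        by_id = {n.node_id: n for n in self.nodes}
        if len(by_id) != len(self.nodes):
            raise ValueError("duplicate node ids")
        if len(set(self.edges)) != len(self.edges):
            raise ValueError("duplicate edges")
        for a, b in self.edges:
            if a not in by_id or b not in by_id:
                raise ValueError(f"edge ({a}, {b}) references unknown node")
            la, lb = _LAYER_INDEX[by_id[a].layer], _LAYER_INDEX[by_id[b].layer]
            if lb - la != 1:
                raise ValueError(f"edge ({a}, {b}) does not connect adjacent layers")

    def node_index(self) -> dict[str, LayerNode]:
        return {n.node_id: n for n in self.nodes}


def assemble(
    drug_name: str,
    records: list[CompoundRecord],
    mapping: TargetMapping,
    core: GeneSet,
    pathway_map: dict[str, set[str]],
    keep_all_compounds: bool = False,
) -> MultipartiteNetwork:
    """Integrate curated compounds, core genes and pathway annotations.

    Compound--target edges are restricted to core genes; compounds (and
    subsequently herbs) with no core-gene link are dropped unless
    ``keep_all_compounds``.  ``pathway_map`` maps gene symbol -> set of
    pathway names; an empty map yields a four-layer network.
    """
    if len(core) == 0:
        raise ValueError("core gene set is empty")
    nodes: list[LayerNode] = [LayerNode(make_id("drug", drug_name), "drug", drug_name)]
    edges: list[tuple[str, str]] = []

    compound_targets = {
        rec.compound_name: mapping.entries.get(rec.compound_name, set()) & core.genes
        for rec in records
    }
    kept = [
        rec
        for rec in records
        if keep_all_compounds or compound_targets[rec.compound_name]
    ]
    herbs = sorted({rec.herb for rec in kept})
    seen_compounds: set[str] = set()

    for herb in herbs:
        nodes.append(LayerNode(make_id("herb", herb), "herb", herb))
        edges.append((make_id("drug", drug_name), make_id("herb", herb)))
    for rec in kept:
        cid = make_id("compound", rec.compound_name)
        if rec.compound_name not in seen_compounds:
            seen_compounds.add(rec.compound_name)
            nodes.append(LayerNode(cid, "compound", rec.compound_name))
        edge = (make_id("herb", rec.herb), cid)
        if edge not in edges:
            edges.append(edge)
    for gene in sorted(core.genes):
        nodes.append(LayerNode(make_id("target", gene), "target", gene))
    for name in sorted(seen_compounds):
        for gene in sorted(compound_targets[name]):
            edges.append((make_id("compound", name), make_id("target", gene)))
    pathways = sorted({p for gene in core.genes for p in pathway_map.get(gene, set())})
    for pathway in pathways:
        nodes.append(LayerNode(make_id("pathway", pathway), "pathway", pathway))
    for gene in sorted(core.genes):
        for pathway in sorted(pathway_map.get(gene, set())):
            edges.append((make_id("target", gene), make_id("pathway", pathway)))
    return MultipartiteNetwork(nodes=nodes, edges=edges)


def layer_degree(network: MultipartiteNetwork, node_id: str) -> int:
    """Edges incident to ``node_id`` toward the next (lower) layer."""
    index = network.node_index()
    if node_id not in index:
        raise KeyError(f"unknown node {node_id!r}")
    return sum(1 for a, _ in network.edges if a == node_id)


def to_networkx(network: MultipartiteNetwork) -> nx.Graph:
    graph = nx.Graph()
    for node in network.nodes:
        graph.add_node(node.node_id, layer=node.layer, display_name=node.display_name)
    graph.add_edges_from(network.edges)
    return graph


def from_networkx(graph: nx.Graph) -> MultipartiteNetwork:
    nodes = [
        LayerNode(node_id, data["layer"], data.get("display_name", node_id))
        for node_id, data in sorted(graph.nodes(data=True))
    ]
    index = {n.node_id: _LAYER_INDEX[n.layer] for n in nodes}
    edges = []
    for a, b in graph.edges:
        if index[a] > index[b]:
            a, b = b, a
        edges.append((a, b))
    edges.sort()
    return MultipartiteNetwork(nodes=nodes, edges=edges)


def export(network: MultipartiteNetwork, path: str | Path, fmt: str) -> None:
    """Write the network as ``sif``, ``graphml`` or a node/edge ``tsv`` pair.

    SIF relations name the layer pair (``drug_herb`` etc.); the TSV
    format writes ``<stem>_nodes.tsv`` and ``<stem>_edges.tsv``.  All
    formats round-trip node ids, layers and edges losslessly (SIF keeps
    ids and edges; layers are recoverable from the id prefixes).
    """
    path = Path(path)
    index = network.node_index()
    if fmt == "sif":
        with open(path, "w", encoding="utf-8") as fh:
            for a, b in network.edges:
                relation = f"{index[a].layer}_{index[b].layer}"
                fh.write(f"{a}\t{relation}\t{b}\n")
    elif fmt == "graphml":
        nx.write_graphml(to_networkx(network), path)
    elif fmt == "tsv":
        stem = path.parent / path.stem
        with open(f"{stem}_nodes.tsv", "w", encoding="utf-8") as fh:
            fh.write("node_id\tlayer\tdisplay_name\n")
            for node in network.nodes:
                fh.write(f"{node.node_id}\t{node.layer}\t{node.display_name}\n")
        with open(f"{stem}_edges.tsv", "w", encoding="utf-8") as fh:
            fh.write("source\ttarget\n")
            for a, b in network.edges:
                fh.write(f"{a}\t{b}\n")
    else:
        raise ValueError(f"unknown export format {fmt!r}")


def read_graphml(path: str | Path) -> MultipartiteNetwork:
    return from_networkx(nx.read_graphml(path))


def read_tsv_pair(nodes_path: str | Path, edges_path: str | Path) -> MultipartiteNetwork:
    nodes: list[LayerNode] = []
    with open(nodes_path, encoding="utf-8") as fh:
        next(fh)
        for line in fh:
            node_id, layer, display = line.rstrip("\n").split("\t")
            nodes.append(LayerNode(node_id, layer, display))
    edges: list[tuple[str, str]] = []
    with open(edges_path, encoding="utf-8") as fh:
        next(fh)
        for line in fh:
            a, b = line.rstrip("\n").split("\t")
            edges.append((a, b))
    return MultipartiteNetwork(nodes=nodes, edges=edges)
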