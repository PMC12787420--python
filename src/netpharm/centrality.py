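"""Weighted PPI graph construction and the three screening centralities.

Edges carry a confidence ("combined") score in [0, 1], STRING-export
style; the score acts purely as an inclusion filter.  All shortest-path
quantities are computed on unweighted hop counts, which is what makes
degree values integers and closeness values small exact rationals on
hub-dominated networks.

Conventions
-----------
degree      : raw neighbour count (integer, unnormalised).
betweenness : Brandes accumulation normalised by (n-1)(n-2)/2; node pairs
              in different components contribute zero.
closeness   : component-restricted, (n_c - 1) / sum of intra-component
              distances; isolated nodes score 0.  No Wasserman-Faust
              rescaling across components.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

SCORE_ATTR = "combined_score"


@dataclass(frozen=True)
class WeightedEdge:
    """An undirected gene--gene interaction with a confidence score."""

    gene_a: str
    gene_b: str
    combined_score: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.combined_score <= 1.0:
            raise ValueError(f"combined_score out of [0,1]: {self.combined_score}")


@dataclass(frozen=True)
class CentralityRecord:
    node: str
    dc: int
    bc: float
    cc: float


def read_edge_list(path: str | Path) -> list[WeightedEdge]:
    """Read a (gene_a, gene_b, combined_score) TSV.

    Scores given on the STRING 0-1000 integer scale are auto-detected
    (any value > 1) and divided by 1000.
    """
    rows: list[tuple[str, str, float]] = []
    with open(path, encoding="utf-8") as fh:
        lines = [
            (i, ln.rstrip("\n"))
            for i, ln in enumerate(fh, start=1)
            if ln.strip() and not ln.lstrip().startswith("#")
        ]
    if not lines:
        return []
    header = [c.strip().lower() for c in lines[0][1].split("\t")]
    for col in ("gene_a", "gene_b", "combined_score"):
        if col not in header:
            raise ValueError(f"{path}: missing required column '{col}'")
    ia, ib, isc = (header.index(c) for c in ("gene_a", "gene_b", "combined_score"))
    for lineno, line in lines[1:]:
        fields = line.split("\t")
        if len(fields) <= max(ia, ib, isc):
            raise ValueError(f"{path}:{lineno}: malformed edge row {line!r}")
        try:
            score = float(fields[isc])
        except ValueError:
            raise ValueError(f"{path}:{lineno}: non-numeric score {fields[isc]!r}") from None
        rows.append((fields[ia].strip(), fields[ib].strip(), score))
    if any(score > 1.0 for _, _, score in rows):  # 0-1000 integer export
        rows = [(a, b, score / 1000.0) for a, b, score in rows]
    return [WeightedEdge(a, b, s) for a, b, s in rows]


def write_edge_list(graph: nx.Graph, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_a\tgene_b\tcombined_score\n")
        for a, b in sorted(tuple(sorted(e)) for e in graph.edges):
            score = graph.edges[a, b].get(SCORE_ATTR, 1.0)
            fh.write(f"{a}\t{b}\t{score:.3f}\n")


def build_graph(
    edges: Iterable[WeightedEdge],
    min_score: float = 0.7,
    isolated_nodes: Iterable[str] = (),
) -> nx.Graph:
    """Build a simple undirected graph from scored edges.

    Self-loops are dropped, duplicate pairs collapse keeping the maximum
    score, and only edges with score >= ``min_score`` are retained.
    ``isolated_nodes`` adds nodes that survive even without a kept edge.
    """
    if not 0.0 <= min_score <= 1.0:
        raise ValueError(f"min_score out of [0,1]: {min_score}")
    best: dict[tuple[str, str], float] = {}
    for edge in edges:
        if edge.gene_a == edge.gene_b:
            continue
        key = tuple(sorted((edge.gene_a, edge.gene_b)))
        if edge.combined_score > best.get(key, -1.0):
            best[key] = edge.combined_score
    graph = nx.Graph()
    graph.add_nodes_from(isolated_nodes)
    for (a, b), score in best.items():
        if score >= min_score:
            graph.add_edge(a, b, **{SCORE_ATTR: score})
    return graph


def degree_centrality(graph: nx.Graph) -> dict[str, int]:
    """Raw neighbour counts (the integer degree column of hub tables)."""
    return {node: int(deg) for node, deg in graph.degree()}


def betweenness_centrality(graph: nx.Graph) -> dict[str, float]:
    """Normalised betweenness; all zeros for graphs with fewer than 3 nodes."""
    return nx.betweenness_centrality(graph, normalized=True)


def closeness_centrality(graph: nx.Graph) -> dict[str, float]:
    """Component-restricted closeness (n_c - 1) / sum of distances."""
    return nx.closeness_centrality(graph, wf_improved=False)


def centrality_table(graph: nx.Graph) -> list[CentralityRecord]:
    """One record per node, ordered by descending degree then symbol."""
    dc = degree_centrality(graph)
    bc = betweenness_centrality(graph)
    cc = closeness_centrality(graph)
    records = [
        CentralityRecord(node=node, dc=dc[node], bc=bc[node], cc=cc[node])
        for node in graph.nodes
    ]
    records.sort(key=lambda r: (-r.dc, r.node))
    return records


def write_centrality_table(records: list[CentralityRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("node\tdegree\tbetweenness\tcloseness\n")
        for rec in records:
            fh.write(f"{rec.node}\t{rec.dc}\t{rec.bc:.9f}\t{rec.cc:.9f}\n")


def edge_scores(graph: nx.Graph, nodes: Iterable[str] | None = None) -> list[float]:
    """Confidence scores of all edges (optionally of an induced subgraph)."""
    g = graph if nodes is None else graph.subgraph(set(nodes))
    return [data.get(SCORE_ATTR, 1.0) for _, _, data in g.edges(data=True)]


def summarize_pairwise_scores(scores: list[float]) -> float:
    """Arithmetic mean of pairwise interaction confidence scores."""
    if not scores:
        raise ValueError("cannot summarise an empty score list")
    if any(not 0.0 <= s <= 1.0 for s in scores):
        raise ValueError("scores must lie in [0,1]")
    return float(sum(scores) / len(scores))
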