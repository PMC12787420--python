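"""Seeded synthetic inputs for every pipeline stage.

Live compound, target, disease-gene, interaction and annotation
databases are replaced here by generators that reproduce the
*statistical structure* the analysis relies on:

* PPI networks with a densely interconnected planted core (a clique
  whose members also attach to a fixed fraction of the periphery)
  embedded in a sparse random background — the topology under which
  iterative mean-threshold screening has a well-defined ground truth;
* a 40-node hub network with one universal node (degree 39) and labelled
  hub nodes of degree 36 and 35, whose closeness values are forced to
  the exact rationals 39/39, 39/42 and 39/43 by the universal node;
* multi-herb compound--target tables with controlled disease-gene
  overlap enrichment;
* GMT annotation libraries with planted over-represented terms.

All generators are pure functions of their spec (including the seed):
identical inputs give byte-identical written files.  Gene symbols are
synthetic tokens ``G000001…`` except in the 40-node hub fixture, whose
six labelled nodes carry their literal symbols.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import networkx as nx
import numpy as np

from .centrality import SCORE_ATTR
from .ingest import CompoundRecord, GeneSet, TargetMapping
from .enrichment import AnnotationLibrary

#: the six labelled hub genes of the 40-node fixture, with target degrees
TABLE_HUB_DEGREES = {
    "IL6": 39,
    "AKT1": 36,
    "STAT3": 36,
    "IL1B": 36,
    "TNF": 35,
    "EGFR": 35,
}


def _gene_token(i: int) -> str:
    return f"G{i:06d}"


@dataclass(frozen=True)
class SyntheticNetworkSpec:
    """Parameters of a planted-core PPI network.

    ``core_size`` nodes form a clique and each additionally attaches to
    ``ceil(core_attach_frac * (n_total - core_size))`` periphery nodes;
    background edges are drawn independently with ``bg_edge_prob`` over
    all remaining pairs.
    """

    n_total: int = 300
    core_size: int = 6
    core_attach_frac: float = 0.4
    bg_edge_prob: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.core_size < 2:
            raise ValueError("core_size must be >= 2")
        if self.core_size >= self.n_total:
            raise ValueError("core_size must be < n_total")
        if not 0.0 <= self.core_attach_frac <= 1.0:
            raise ValueError("core_attach_frac must be in [0,1]")
        if not 0.0 <= self.bg_edge_prob <= 1.0:
            raise ValueError("bg_edge_prob must be in [0,1]")
        if self.core_attach_frac == 0.0 and self.bg_edge_prob == 0.0:
            raise ValueError("graph cannot be connected: all attachment probabilities are zero")


@dataclass(frozen=True)
class SyntheticStudySpec:
    """Parameters of a synthetic multi-herb compound--target study.

    ``overlap_enrichment`` is the sampling-weight multiplier applied to
    disease genes when drawing compound targets; 1.0 gives independent
    (hypergeometric-rate) overlap, values > 1 over-represent disease
    genes among predicted targets.  Defaults emulate a nine-herb
    formulation at reduced gene-universe scale.
    """

    n_herbs: int = 9
    compounds_per_herb: tuple[int, ...] | int = (6, 20, 5, 17, 34, 83, 17, 5, 5)
    gene_universe_size: int = 20000
    targets_per_compound: tuple[int, int] = (5, 25)
    disease_set_size: int = 8886
    overlap_enrichment: float = 1.2
    seed: int = 0

    def __post_init__(self) -> None:
        counts = self.herb_compound_counts()
        if len(counts) != self.n_herbs:
            raise ValueError("compounds_per_herb length must equal n_herbs")
        if any(c < 1 for c in counts):
            raise ValueError("each herb needs at least one compound")
        if self.disease_set_size > self.gene_universe_size:
            raise ValueError("disease_set_size must be <= gene_universe_size")
        lo, hi = self.targets_per_compound
        if not (1 <= lo <= hi <= self.gene_universe_size):
            raise ValueError("targets_per_compound range invalid")
        if self.overlap_enrichment <= 0:
            raise ValueError("overlap_enrichment must be positive")

    def herb_compound_counts(self) -> tuple[int, ...]:
        if isinstance(self.compounds_per_herb, int):
            return (self.compounds_per_herb,) * self.n_herbs
        return tuple(self.compounds_per_herb)


def gen_planted_core_network(spec: SyntheticNetworkSpec) -> tuple[nx.Graph, set[str]]:
    """A sparse background graph with a planted dense core.

    Returns the graph and the ground-truth core labels.  The induced
    subgraph on the core is always a complete clique (C(core_size, 2)
    edges).  Disconnected periphery components are repaired by wiring
    one of their nodes to a uniformly chosen core node, which keeps
    closeness well-defined without materially altering core structure.
    """
    rng = np.random.default_rng(spec.seed)
    nodes = [_gene_token(i + 1) for i in range(spec.n_total)]
    core = nodes[: spec.core_size]
    periphery = nodes[spec.core_size :]

    graph = nx.Graph()
    graph.add_nodes_from(nodes)
    for i, u in enumerate(core):
        for v in core[i + 1 :]:
            graph.add_edge(u, v)

    # every core member attaches to the same sampled periphery set: hub
    # cores in PPI data share interaction partners, and the shared
    # neighbourhood keeps the core symmetric in every induced subgraph
    n_attach = math.ceil(spec.core_attach_frac * len(periphery))
    if n_attach:
        chosen = rng.choice(len(periphery), size=n_attach, replace=False)
        for u in core:
            for j in chosen:
                graph.add_edge(u, periphery[j])

    if spec.bg_edge_prob > 0:
        iu, iv = np.triu_indices(spec.n_total, k=1)
        mask = rng.random(iu.size) < spec.bg_edge_prob
        for a, b in zip(iu[mask], iv[mask]):
            graph.add_edge(nodes[a], nodes[b])

    # connectivity repair: wire stray components into the core
    for component in list(nx.connected_components(graph)):
        if component.isdisjoint(core):
            straggler = sorted(component)[0]
            graph.add_edge(straggler, core[rng.integers(len(core))])

    core_set = set(core)
    for a, b in sorted(tuple(sorted(e)) for e in graph.edges):
        in_core = a in core_set and b in core_set
        graph.edges[a, b][SCORE_ATTR] = 0.95 if in_core else round(float(rng.uniform(0.4, 0.95)), 3)
    return graph, core_set


def gen_table2_network(seed: int = 0) -> nx.Graph:
    """A connected 40-node hub network with fixed labelled degrees.

    ``IL6`` is universal (adjacent to all 39 others); ``AKT1``,
    ``STAT3`` and ``IL1B`` have degree exactly 36; ``TNF`` and ``EGFR``
    degree exactly 35; the 34 unlabelled nodes have arbitrary degrees.
    Construction: the three degree-36 nodes form a triangle and each
    connects to IL6 plus 33 of the 34 unlabelled nodes (the skipped node
    is seed-dependent); the degree-35 nodes connect to IL6 plus all 34
    unlabelled nodes; random unlabelled--unlabelled padding edges vary
    the background.  The universal node pins every inter-node distance
    at <= 2, so closeness of the labelled nodes is exactly
    39/39, 39/42 and 39/43 for every seed.
    """
    rng = np.random.default_rng(seed)
    filler = [f"G{i:02d}" for i in range(1, 35)]
    labelled36 = ["AKT1", "STAT3", "IL1B"]
    labelled35 = ["TNF", "EGFR"]
    graph = nx.Graph()
    graph.add_nodes_from(["IL6", *labelled36, *labelled35, *filler])

    for node in list(graph.nodes):
        if node != "IL6":
            graph.add_edge("IL6", node)
    # triangle among the degree-36 hubs: 1 (IL6) + 2 (triangle) + 33 = 36
    graph.add_edge("AKT1", "STAT3")
    graph.add_edge("AKT1", "IL1B")
    graph.add_edge("STAT3", "IL1B")
    for node in labelled36:
        skip = int(rng.integers(len(filler)))
        for j, other in enumerate(filler):
            if j != skip:
                graph.add_edge(node, other)
    for node in labelled35:  # 1 (IL6) + 34 = 35
        for other in filler:
            graph.add_edge(node, other)
    # arbitrary-degree padding among unlabelled nodes
    for i in range(len(filler)):
        for j in range(i + 1, len(filler)):
            if rng.random() < 0.1:
                graph.add_edge(filler[i], filler[j])
    nx.set_edge_attributes(graph, 0.9, SCORE_ATTR)
    return graph


def gen_compound_target_data(
    spec: SyntheticStudySpec,
) -> tuple[list[CompoundRecord], TargetMapping, GeneSet]:
    """Synthetic herb--compound table, target map and disease gene set.

    Every compound receives at least one target (the curation step that
    drops target-less compounds is therefore a no-op on freshly
    generated data — tests exercise it by deleting entries).  Disease
    genes are drawn uniformly; compound targets are drawn without
    replacement with disease genes weighted by ``overlap_enrichment``,
    so at weight 1 the target/disease overlap matches the hypergeometric
    expectation.
    """
    rng = np.random.default_rng(spec.seed)
    universe = [_gene_token(i + 1) for i in range(spec.gene_universe_size)]
    disease_idx = rng.choice(spec.gene_universe_size, size=spec.disease_set_size, replace=False)
    disease = {universe[i] for i in disease_idx}

    weights = np.ones(spec.gene_universe_size)
    weights[disease_idx] = spec.overlap_enrichment
    probs = weights / weights.sum()

    records: list[CompoundRecord] = []
    mapping: dict[str, set[str]] = {}
    lo, hi = spec.targets_per_compound
    cid = 100000
    idx = 0
    for h, count in enumerate(spec.herb_compound_counts(), start=1):
        herb = f"HERB{h:02d}"
        for _ in range(count):
            idx += 1
            cid += 1
            name = f"CMP{idx:04d}"
            records.append(CompoundRecord(compound_name=name, pubchem_cid=cid, herb=herb))
            n_targets = int(rng.integers(lo, hi + 1))
            chosen = rng.choice(spec.gene_universe_size, size=n_targets, replace=False, p=probs)
            mapping[name] = {universe[i] for i in chosen}
    return records, TargetMapping(entries=mapping), GeneSet(label="disease", genes=disease)


def gen_annotation_library(
    universe: Sequence[str],
    n_terms: int,
    term_size_range: tuple[int, int],
    planted_query: Sequence[str] = (),
    n_planted: int = 0,
    enrichment_factor: float = 1.0,
    seed: int = 0,
    name: str = "SYN_LIB",
) -> AnnotationLibrary:
    """A GMT-style library with optionally planted enriched terms.

    The first ``n_planted`` terms (ids ``PLANTED_…``) over-sample
    members of ``planted_query`` with weight ``enrichment_factor``;
    remaining terms (ids ``T…``) sample the universe uniformly.  At
    ``enrichment_factor == 1`` all terms are exchangeable null draws.
    """
    if n_planted > n_terms:
        raise ValueError("n_planted must be <= n_terms")
    lo, hi = term_size_range
    if not (1 <= lo <= hi <= len(universe)):
        raise ValueError("term_size_range outside the universe")
    if enrichment_factor <= 0:
        raise ValueError("enrichment_factor must be positive")
    rng = np.random.default_rng(seed)
    universe = list(universe)
    query_mask = np.isin(np.asarray(universe), np.asarray(list(planted_query)))

    terms: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    for t in range(n_terms):
        size = int(rng.integers(lo, hi + 1))
        planted = t < n_planted
        if planted and enrichment_factor != 1.0:
            weights = np.where(query_mask, enrichment_factor, 1.0)
            probs = weights / weights.sum()
            chosen = rng.choice(len(universe), size=size, replace=False, p=probs)
        else:
            chosen = rng.choice(len(universe), size=size, replace=False)
        term_id = f"PLANTED_{t + 1:03d}" if planted else f"T{t + 1:04d}"
        terms[term_id] = {universe[i] for i in chosen}
        descriptions[term_id] = "planted" if planted else "background"
    return AnnotationLibrary(name=name, terms=terms, universe=set(universe), descriptions=descriptions)
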