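"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the library routines they check:
closeness/betweenness use a hand-rolled BFS and exhaustive shortest-path
enumeration, and the hypergeometric tail enumerates every possible draw.
"""

from __future__ import annotations

import itertools
from collections import deque
from math import comb

import networkx as nx
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from netpharm.ingest import CompoundRecord, GeneSet, TargetMapping


# ---------------------------------------------------------------- oracles

def bfs_distances(adj: dict, source) -> dict:
    """Plain BFS hop distances from ``source`` over an adjacency dict."""
    dist = {source: 0}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


def adjacency(graph: nx.Graph) -> dict:
    return {u: sorted(graph.neighbors(u)) for u in graph.nodes}


def oracle_closeness(graph: nx.Graph) -> dict:
    """(n_c - 1) / sum of intra-component distances, 0 for isolates."""
    adj = adjacency(graph)
    out = {}
    for v in graph.nodes:
        dist = bfs_distances(adj, v)
        total = sum(dist.values())
        out[v] = (len(dist) - 1) / total if total > 0 else 0.0
    return out


def _all_shortest_paths(adj: dict, s, t, dist_s: dict):
    """Enumerate every shortest s->t path by DFS along decreasing distance."""
    if t not in dist_s:
        return
    target_len = dist_s[t]

    def extend(path):
        head = path[-1]
        if head == t:
            yield path
            return
        for nxt in adj[head]:
            if nxt in dist_s and dist_s[nxt] == dist_s[head] + 1 and dist_s[nxt] <= target_len:
                yield from extend(path + [nxt])

    yield from extend([s])


def oracle_betweenness(graph: nx.Graph) -> dict:
    """Normalised betweenness by explicit shortest-path enumeration."""
    nodes = list(graph.nodes)
    n = len(nodes)
    adj = adjacency(graph)
    bc = {v: 0.0 for v in nodes}
    for s, t in itertools.combinations(nodes, 2):
        dist_s = bfs_distances(adj, s)
        paths = list(_all_shortest_paths(adj, s, t, dist_s))
        if not paths:
            continue
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            bc[v] += through / len(paths)
    if n > 2:
        scale = 2.0 / ((n - 1) * (n - 2))
        bc = {v: val * scale for v, val in bc.items()}
    return bc


def oracle_hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """P[|draw ∩ term| >= k] by exhaustive enumeration of all C(N, n) draws."""
    universe = list(range(N))
    term = set(universe[:K])
    hits = sum(
        1 for draw in itertools.combinations(universe, n) if len(term & set(draw)) >= k
    )
    return hits / comb(N, n)


# --------------------------------------------------------------- fixtures

CORE_GENES = ("AKT1", "STAT3", "IL6", "TNF", "EGFR", "IL1B")

# compound -> core-gene targets; every compound hits TNF/IL6/AKT1, extras
# bring each to its published layer-degree count
COMPOUND_CORE_TARGETS = {
    "curcumin": {"TNF", "IL6", "AKT1", "STAT3", "EGFR"},
    "glycyrrhetic acid": {"TNF", "IL6", "AKT1", "EGFR", "IL1B"},
    "Tanshinone IIA": {"TNF", "IL6", "AKT1", "STAT3"},
    "tenuifolin": {"TNF", "IL6", "AKT1", "IL1B"},
    "albiflorin": {"TNF", "IL6", "AKT1", "EGFR"},
    "paeoniflorin": {"TNF", "IL6", "AKT1", "IL1B"},
    "salvianolic acid B": {"TNF", "IL6", "AKT1"},
    "liquiritigenin": {"TNF", "IL6", "AKT1"},
}

PATHWAYS = (
    "Toll-like receptor signaling",
    "C-type lectin receptor signaling",
    "HIF-1 signaling",
    "TNF signaling",
    "FoxO signaling",
    "JAK-STAT signaling",
    "MAPK signaling",
    "Adipocytokine signaling",
)

# gene -> pathway membership sized to the published pathway-degree counts
GENE_PATHWAYS = {
    "AKT1": set(PATHWAYS),
    "IL6": set(PATHWAYS[:6]),
    "TNF": set(PATHWAYS[:5]),
    "EGFR": set(PATHWAYS[:4]),
    "IL1B": set(PATHWAYS[:4]),
    "STAT3": set(PATHWAYS[:3]),
}

COMPOUND_HERBS = {
    "curcumin": "Curcumae Longa",
    "glycyrrhetic acid": "Glycyrrhiza uralensis",
    "Tanshinone IIA": "Salvia miltiorrhiza",
    "tenuifolin": "Polygala tenuifolia",
    "albiflorin": "Paeonia lactiflora",
    "paeoniflorin": "Paeonia lactiflora",
    "salvianolic acid B": "Salvia miltiorrhiza",
    "liquiritigenin": "Paeonia lactiflora",
}


@pytest.fixture
def dhctp_inputs():
    """Synthetic stand-in for the published five-layer network inputs."""
    records = [
        CompoundRecord(compound_name=name, pubchem_cid=1000 + i, herb=COMPOUND_HERBS[name])
        for i, name in enumerate(sorted(COMPOUND_CORE_TARGETS))
    ]
    mapping = TargetMapping(entries={k: set(v) for k, v in COMPOUND_CORE_TARGETS.items()})
    core = GeneSet(label="core", genes=set(CORE_GENES))
    return records, mapping, core, {k: set(v) for k, v in GENE_PATHWAYS.items()}


@pytest.fixture
def small_random_graphs():
    """100 seeded random graphs with n <= 8 for oracle comparisons."""
    graphs = []
    for seed in range(100):
        n = 3 + seed % 6
        p = 0.2 + 0.1 * (seed % 7)
        graphs.append(nx.gnp_random_graph(n, p, seed=seed))
    return graphs
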