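"""Iterative mean-threshold hub screening on a PPI network.

Each round computes degree (DC), betweenness (BC) and closeness (CC) on
the *current* graph, sets each metric's threshold to its arithmetic mean
over the current node set, and retains exactly the nodes that strictly
exceed all three thresholds.  The next round operates on the induced
subgraph of the retained nodes, with all three centralities recomputed
there.  Because no node can strictly exceed the mean of a constant
vector, the node set shrinks strictly every round until either the
stopping policy fires or a round retains nothing (at which point the
round's input set — typically a mutually interconnected core — is the
final hub set).

The mean-degree threshold of round one is always 2E/N by the handshake
lemma, which makes the first-round DC cutoff auditable from the input
graph's node and edge counts alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Union

import networkx as nx

from .centrality import (
    betweenness_centrality,
    closeness_centrality,
    degree_centrality,
)


@dataclass(frozen=True)
class FixedRounds:
    """Stop after exactly ``k`` rounds (earlier if a round retains nothing)."""

    k: int

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("fixed_rounds requires k >= 1")


@dataclass(frozen=True)
class TargetSize:
    """Stop once the retained set has at most ``m`` nodes."""

    m: int

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("target_size requires m >= 1")


@dataclass(frozen=True)
class Convergence:
    """Iterate until a round retains nothing (or everything)."""


StopPolicy = Union[FixedRounds, TargetSize, Convergence]


def parse_policy(text: str) -> StopPolicy:
    """Parse ``convergence``, ``rounds:<k>`` or ``size:<m>``."""
    if text == "convergence":
        return Convergence()
    kind, _, arg = text.partition(":")
    if kind == "rounds" and arg.isdigit():
        return FixedRounds(int(arg))
    if kind == "size" and arg.isdigit():
        return TargetSize(int(arg))
    raise ValueError(f"unknown stop policy {text!r}")


@dataclass
class ScreeningRound:
    """Audit record of one filtering round.

    Thresholds are the arithmetic means of each centrality over the
    round's input nodes; ``retained`` holds the nodes strictly exceeding
    all three.
    """

    round_index: int
    dc_threshold: float
    bc_threshold: float
    cc_threshold: float
    n_nodes_in: int
    n_edges_in: int
    n_nodes_out: int
    n_edges_out: int
    retained: frozenset[str]


@dataclass
class ScreeningResult:
    rounds: list[ScreeningRound] = field(default_factory=list)
    core: frozenset[str] = frozenset()
    core_subgraph: nx.Graph = field(default_factory=nx.Graph)


def mean_degree_threshold(n_nodes: int, n_edges: int) -> float:
    """First-round DC threshold from counts alone: 2E/N (handshake lemma)."""
    if n_nodes <= 0:
        raise ValueError("graph must be non-empty")
    return 2.0 * n_edges / n_nodes


def format_dc(value: float) -> str:
    """Display rounding used for degree thresholds (5 decimals)."""
    return f"{value:.5f}"


def format_bc_cc(value: float) -> str:
    """Display rounding used for betweenness/closeness thresholds (6 decimals)."""
    return f"{value:.6f}"


def screening_round(graph: nx.Graph, round_index: int = 1) -> ScreeningRound:
    """One mean-threshold round on ``graph``.

    Raises
    ------
    ValueError
        If the graph has no nodes.
    """
    n = graph.number_of_nodes()
    if n == 0:
        raise ValueError("screening_round requires a non-empty graph")
    dc = degree_centrality(graph)
    bc = betweenness_centrality(graph)
    cc = closeness_centrality(graph)
    dc_t = sum(dc.values()) / n
    bc_t = sum(bc.values()) / n
    cc_t = sum(cc.values()) / n
    retained = frozenset(
        v for v in graph.nodes if dc[v] > dc_t and bc[v] > bc_t and cc[v] > cc_t
    )
    sub = graph.subgraph(retained)
    return ScreeningRound(
        round_index=round_index,
        dc_threshold=dc_t,
        bc_threshold=bc_t,
        cc_threshold=cc_t,
        n_nodes_in=n,
        n_edges_in=graph.number_of_edges(),
        n_nodes_out=sub.number_of_nodes(),
        n_edges_out=sub.number_of_edges(),
        retained=retained,
    )


def iterative_screen(
    graph: nx.Graph,
    stop_policy: StopPolicy | str = Convergence(),
    max_rounds: int = 100,
) -> ScreeningResult:
    """Apply mean-threshold rounds to successive induced subgraphs.

    Stopping: a round retaining nothing ends the loop with that round's
    input set as the core (the round is still recorded in the audit
    trail); a round retaining every input node ends it with that set
    (cannot occur under strict thresholds, kept as a guard); otherwise
    the policy decides — ``FixedRounds(k)`` stops after k rounds,
    ``TargetSize(m)`` once at most m nodes remain, ``Convergence`` only
    on the empty-retention rule.
    """
    if isinstance(stop_policy, str):
        stop_policy = parse_policy(stop_policy)
    if graph.number_of_nodes() == 0:
        raise ValueError("iterative_screen requires a non-empty graph")

    current = graph
    rounds: list[ScreeningRound] = []
    core: frozenset[str] = frozenset(current.nodes)
    for index in range(1, max_rounds + 1):
        rnd = screening_round(current, round_index=index)
        rounds.append(rnd)
        if not rnd.retained:
            core = frozenset(current.nodes)
            break
        core = rnd.retained
        if rnd.retained == frozenset(current.nodes):
            break
        current = graph.subgraph(rnd.retained)
        if isinstance(stop_policy, FixedRounds) and index >= stop_policy.k:
            break
        if isinstance(stop_policy, TargetSize) and len(core) <= stop_policy.m:
            break
    core_subgraph = nx.Graph(graph.subgraph(core))
    return ScreeningResult(rounds=rounds, core=core, core_subgraph=core_subgraph)


def thresholds_report(result: ScreeningResult) -> str:
    """Per-round thresholds and counts, with the display rounding used
    for reporting (degree to 5 decimals, betweenness/closeness to 6)."""
    header = (
        "round\tnodes_in\tedges_in\tDC>\tBC>\tCC>\tnodes_out\tedges_out"
    )
    lines = [header]
    for rnd in result.rounds:
        lines.append(
            "\t".join(
                [
                    str(rnd.round_index),
                    str(rnd.n_nodes_in),
                    str(rnd.n_edges_in),
                    format_dc(rnd.dc_threshold),
                    format_bc_cc(rnd.bc_threshold),
                    format_bc_cc(rnd.cc_threshold),
                    str(rnd.n_nodes_out),
                    str(rnd.n_edges_out),
                ]
            )
        )
    return "\n".join(lines)


def result_to_dict(result: ScreeningResult) -> dict:
    """JSON-serialisable audit trail (full precision thresholds)."""
    return {
        "core": sorted(result.core),
        "core_edges": sorted(sorted(e) for e in result.core_subgraph.edges),
        "rounds": [
            {
                "round_index": r.round_index,
                "dc_threshold": r.dc_threshold,
                "bc_threshold": r.bc_threshold,
                "cc_threshold": r.cc_threshold,
                "n_nodes_in": r.n_nodes_in,
                "n_edges_in": r.n_edges_in,
                "n_nodes_out": r.n_nodes_out,
                "n_edges_out": r.n_edges_out,
                "retained": sorted(r.retained),
            }
            for r in result.rounds
        ],
    }
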