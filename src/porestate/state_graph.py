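"""Ion-binding state transition graph.

The per-frame state sequence is collapsed into runs of identical states;
nodes carry occupancy statistics (frame counts → probabilities) and edges
the observed transitions between *distinct* adjacent states (no
self-edges: dwell time lives in the node counts).  Node probability is
defined over frames; edge probability over the total number of distinct
transitions (a global, not per-source, normalization).  The graph is
exported as GML for visualization in standard network tools.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx

from .site_model import state_ion_count

__all__ = [
    "NodeStats",
    "EdgeStats",
    "StateGraph",
    "collapse_runs",
    "build_graph",
    "most_stable_state",
    "write_gml",
    "write_edge_list",
]

log = logging.getLogger(__name__)


@dataclass
class NodeStats:
    count: int
    probability: float
    n_ions: int
    char: str | None = None


@dataclass
class EdgeStats:
    count: int
    probability: float
    multi_jump: bool = False


@dataclass
class StateGraph:
    nodes: dict[str, NodeStats]
    edges: dict[tuple[str, str], EdgeStats]
    total_frames: int
    total_transitions: int
    collapsed: list[str] = field(default_factory=list)
    run_lengths: list[int] = field(default_factory=list)


def collapse_runs(states: Sequence[str]) -> tuple[list[str], list[int]]:
    """Collapse consecutive duplicates; returns (distinct sequence, run lengths)."""
    if len(states) == 0:
        raise ValueError("empty state sequence")
    seq: list[str] = []
    runs: list[int] = []
    for s in states:
        if seq and s == seq[-1]:
            runs[-1] += 1
        else:
            seq.append(s)
            runs.append(1)
    return seq, runs


def _sites_changed(a: str, b: str) -> int:
    """Minimum number of ion moves between two states.

    A single hop swaps one site for another (max one-sided set difference
    1); entries/exits change one side only.  >1 means the snapshot
    interval skipped an intermediate state.
    """
    from .site_model import parse_state_label

    occ_a = parse_state_label(a).occupied
    occ_b = parse_state_label(b).occupied
    return max(len(occ_a - occ_b), len(occ_b - occ_a))


def build_graph(states: Sequence[str]) -> StateGraph:
    """Count states and transitions of a per-frame state label sequence."""
    seq, runs = collapse_runs(states)
    total_frames = len(states)
    counts: dict[str, int] = {}
    for s, n in zip(seq, runs):
        counts[s] = counts.get(s, 0) + n
    edge_counts: dict[tuple[str, str], int] = {}
    for a, b in zip(seq, seq[1:]):
        edge_counts[(a, b)] = edge_counts.get((a, b), 0) + 1
    total_transitions = len(seq) - 1
    nodes = {
        s: NodeStats(count=c, probability=c / total_frames, n_ions=state_ion_count(s))
        for s, c in counts.items()
    }
    edges: dict[tuple[str, str], EdgeStats] = {}
    n_multi = 0
    for (a, b), c in edge_counts.items():
        multi = _sites_changed(a, b) > 1
        n_multi += multi
        edges[(a, b)] = EdgeStats(
            count=c, probability=c / total_transitions, multi_jump=multi
        )
    if n_multi:
        log.warning(
            "%d edges change more than one site per transition (snapshot "
            "interval may skip intermediate states)",
            n_multi,
        )
    return StateGraph(
        nodes=nodes,
        edges=edges,
        total_frames=total_frames,
        total_transitions=total_transitions,
        collapsed=seq,
        run_lengths=runs,
    )


def most_stable_state(graph: StateGraph) -> str:
    """State with the highest occupancy probability (ties → lexicographic)."""
    if not graph.nodes:
        raise ValueError("empty graph")
    best_p = max(ns.probability for ns in graph.nodes.values())
    tied = sorted(s for s, ns in graph.nodes.items() if ns.probability == best_p)
    if len(tied) > 1:
        log.warning(
            "most-stable state tie among %s; choosing %r lexicographically",
            tied,
            tied[0],
        )
    return tied[0]


def _node_order(graph: StateGraph) -> list[str]:
    return sorted(graph.nodes, key=lambda s: (-graph.nodes[s].probability, s))


def to_networkx(graph: StateGraph) -> nx.DiGraph:
    """Deterministically ordered DiGraph (nodes by descending probability)."""
    g = nx.DiGraph()
    for s in _node_order(graph):
        ns = graph.nodes[s]
        g.add_node(
            s,
            count=ns.count,
            probability=ns.probability,
            n_ions=ns.n_ions,
            char=ns.char if ns.char is not None else "",
        )
    for a, b in sorted(graph.edges):
        es = graph.edges[(a, b)]
        g.add_edge(
            a,
            b,
            count=es.count,
            probability=es.probability,
            multi_jump=int(es.multi_jump),
        )
    return g


def write_gml(graph: StateGraph, path: str | Path) -> None:
    """Write the graph as GML (Cytoscape-compatible), byte-stable per graph."""
    nx.write_gml(to_networkx(graph), str(path))


def write_edge_list(graph: StateGraph, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("source\ttarget\tcount\tprobability\tmulti_jump\n")
        for a, b in sorted(graph.edges):
            es = graph.edges[(a, b)]
            fh.write(f"{a}\t{b}\t{es.count}\t{es.probability:.8g}\t{int(es.multi_jump)}\n")
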