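"""Character encoding, alignment and clustering of conduction events.

Each ion-binding state is assigned one printable character so that a
cyclic path becomes a short string.  The character classes follow the ion
count *relative to the anchor state* (the most stable state, always
``*``): states with the anchor's count get upper-case letters, one more
ion lower-case letters, two more the symbols ``#``, ``%``, ``&``, ...;
any other count falls into a digit/punctuation pool.  Within a class,
characters are handed out in descending node-probability order, so the
encoding is deterministic for a given graph.

Event similarity uses global (Needleman–Wunsch-style) alignment under the
three-point substitution rule — 1.0 for the identical state, 0.5 for a
different state with the same ion count, 0.0 otherwise — with a linear gap
score (default 0: gaps are neither rewarded nor penalized, which with
non-negative match scores makes the optimum a maximum-weight monotone
matching).  Raw scores are normalized by the longer sequence length so
similarities lie in [0, 1] and length mismatch is penalized; agglomerative
clustering then runs on distance = 1 − similarity (UPGMA by default).
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage, to_tree
from scipy.spatial.distance import squareform

from .site_model import state_ion_count
from .state_graph import StateGraph, most_stable_state

__all__ = [
    "CharacterMap",
    "assign_characters",
    "cycle_to_sequence",
    "ScoreMatrix",
    "make_score_matrix",
    "AlignmentResult",
    "align",
    "brute_force_align_score",
    "event_similarity",
    "ClusterResult",
    "cluster_events",
]

ANCHOR_CHAR = "*"
_PLUS2_CHARS = "#%&@$+=!?^~"
_POOL_CHARS = string.digits + "".join(
    c for c in string.punctuation if c not in set("*:#%&@$+=!?^~-()[]{},\t ")
)


@dataclass
class CharacterMap:
    """Bijection between state labels and single characters."""

    to_char: dict[str, str]
    anchor: str

    def __post_init__(self) -> None:
        self.to_state = {c: s for s, c in self.to_char.items()}
        if len(self.to_state) != len(self.to_char):
            raise ValueError("character map is not injective")

    def encode(self, states: Sequence[str]) -> str:
        try:
            return "".join(self.to_char[s] for s in states)
        except KeyError as exc:
            raise KeyError(f"state {exc.args[0]!r} has no character assigned") from exc

    def decode(self, sequence: str) -> list[str]:
        try:
            return [self.to_state[c] for c in sequence]
        except KeyError as exc:
            raise KeyError(f"character {exc.args[0]!r} maps to no state") from exc


def assign_characters(
    graph: StateGraph,
    anchor: str | None = None,
    restrict_to: set[str] | None = None,
) -> CharacterMap:
    """Assign one character per state of a graph (see module docstring).

    ``restrict_to`` limits the encoding to a subset of states (e.g. only
    those appearing in conduction events) when the full graph would
    exhaust the printable alphabet.
    """
    if anchor is None:
        anchor = most_stable_state(graph)
    if anchor not in graph.nodes:
        raise ValueError(f"anchor {anchor!r} is not a node of the graph")
    anchor_count = graph.nodes[anchor].n_ions
    pool_states = graph.nodes if restrict_to is None else (
        {s for s in restrict_to if s in graph.nodes} | {anchor}
    )
    order = sorted(pool_states, key=lambda s: (-graph.nodes[s].probability, s))
    classes: dict[int, list[str]] = {
        0: list(string.ascii_uppercase),
        1: list(string.ascii_lowercase),
        2: list(_PLUS2_CHARS),
    }
    pool = list(_POOL_CHARS)
    used: set[str] = {ANCHOR_CHAR}
    to_char: dict[str, str] = {anchor: ANCHOR_CHAR}
    for s in order:
        if s == anchor:
            continue
        delta = graph.nodes[s].n_ions - anchor_count
        supply = classes.get(delta, pool)
        while supply and supply[0] in used:  # may have been taken as fallback
            supply.pop(0)
        if not supply:  # class alphabet spent: spill into the shared pool
            supply = pool
            while supply and supply[0] in used:
                supply.pop(0)
        if not supply:  # last resort: any unused printable ASCII
            supply = [
                c
                for c in string.printable
                if c not in used and c.isprintable() and c not in " \t*:,-"
            ]
        if not supply:
            raise ValueError(
                "character alphabet exhausted; consider a coarser site model"
            )
        ch = supply.pop(0)
        used.add(ch)
        to_char[s] = ch
    return CharacterMap(to_char=to_char, anchor=anchor)


def cycle_to_sequence(states: Sequence[str], cmap: CharacterMap, compact: bool = False) -> str:
    """Encode a path's states as a character string.

    Stored form is explicit (anchored cycles begin and end with ``*``);
    ``compact=True`` drops a leading ``*`` for the short display form.
    """
    seq = cmap.encode(states)
    if compact and seq.startswith(ANCHOR_CHAR) and len(seq) > 1:
        return seq[1:]
    return seq


# ---------------------------------------------------------------------------
# score matrix
# ---------------------------------------------------------------------------


@dataclass
class ScoreMatrix:
    """Symmetric three-point similarity over symbols (states or characters)."""

    symbols: list[str]
    matrix: np.ndarray
    index: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        self.index = {s: i for i, s in enumerate(self.symbols)}
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.symbols), len(self.symbols)):
            raise ValueError("score matrix shape mismatch")
        self.matrix = m

    def score(self, a: str, b: str) -> float:
        try:
            return float(self.matrix[self.index[a], self.index[b]])
        except KeyError as exc:
            raise KeyError(f"symbol {exc.args[0]!r} not in score matrix") from exc

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("symbol\t" + "\t".join(self.symbols) + "\n")
            for s, row in zip(self.symbols, self.matrix):
                fh.write(s + "\t" + "\t".join(f"{v:.1f}" for v in row) + "\n")


def _three_point(counts: Sequence[int], same: np.ndarray) -> np.ndarray:
    c = np.asarray(counts)
    m = np.where(c[:, None] == c[None, :], 0.5, 0.0)
    m[same] = 1.0
    return m


def make_score_matrix(states: Sequence[str]) -> ScoreMatrix:
    """Score matrix over state labels: 1.0 identical, 0.5 same ion count, else 0."""
    labels = list(dict.fromkeys(states))
    counts = [state_ion_count(s) for s in labels]
    same = np.eye(len(labels), dtype=bool)
    return ScoreMatrix(symbols=labels, matrix=_three_point(counts, same))


def score_matrix_for_characters(cmap: CharacterMap) -> ScoreMatrix:
    """Same rule keyed by the characters of a :class:`CharacterMap`."""
    chars = sorted(cmap.to_state)
    counts = [state_ion_count(cmap.to_state[c]) for c in chars]
    same = np.eye(len(chars), dtype=bool)
    return ScoreMatrix(symbols=chars, matrix=_three_point(counts, same))


# ---------------------------------------------------------------------------
# global alignment
# ---------------------------------------------------------------------------


@dataclass
class AlignmentResult:
    score: float
    aligned_a: str
    aligned_b: str


def align(
    seq_a: Sequence[str] | str,
    seq_b: Sequence[str] | str,
    scores: ScoreMatrix,
    gap_score: float = 0.0,
) -> AlignmentResult:
    """Global alignment maximizing total score under linear gap scoring.

    Recurrence: ``S[i][j] = max(S[i-1][j-1] + score(a_i, b_j),
    S[i-1][j] + gap, S[i][j-1] + gap)`` with gap-filled borders.
    Traceback ties are broken diagonal > up > left.
    """
    a = list(seq_a)
    b = list(seq_b)
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    n, m = len(a), len(b)
    ia = np.array([scores.index[x] if x in scores.index else _raise_sym(x) for x in a])
    ib = np.array([scores.index[x] if x in scores.index else _raise_sym(x) for x in b])
    sub = scores.matrix[np.ix_(ia, ib)]
    S = np.empty((n + 1, m + 1))
    S[0, :] = gap_score * np.arange(m + 1)
    S[:, 0] = gap_score * np.arange(n + 1)
    for i in range(1, n + 1):
        diag = S[i - 1, :-1] + sub[i - 1]
        row = S[i]
        prev = S[i - 1]
        # left-dependency forces a scan within the row
        acc = S[i, 0]
        for j in range(1, m + 1):
            acc = max(diag[j - 1], prev[j] + gap_score, acc + gap_score)
            row[j] = acc
    # traceback
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and j > 0 and np.isclose(S[i, j], S[i - 1, j - 1] + sub[i - 1, j - 1]):
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            i -= 1
            j -= 1
        elif i > 0 and np.isclose(S[i, j], S[i - 1, j] + gap_score):
            out_a.append(a[i - 1])
            out_b.append("-")
            i -= 1
        else:
            out_a.append("-")
            out_b.append(b[j - 1])
            j -= 1
    return AlignmentResult(
        score=float(S[n, m]),
        aligned_a="".join(reversed(out_a)) if isinstance(seq_a, str) else list(reversed(out_a)),
        aligned_b="".join(reversed(out_b)) if isinstance(seq_b, str) else list(reversed(out_b)),
    )


def _raise_sym(x: str):
    raise KeyError(f"symbol {x!r} not in score matrix")


def brute_force_align_score(
    seq_a: Sequence[str] | str,
    seq_b: Sequence[str] | str,
    scores: ScoreMatrix,
    gap_score: float = 0.0,
) -> float:
    """Exhaustive enumeration over all monotone global alignments.

    Independent oracle for :func:`align`; exponential, use only for short
    sequences.
    """
    a, b = list(seq_a), list(seq_b)

    def rec(i: int, j: int) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        best = -np.inf
        if i < len(a) and j < len(b):
            best = max(best, scores.score(a[i], b[j]) + rec(i + 1, j + 1))
        if i < len(a):
            best = max(best, gap_score + rec(i + 1, j))
        if j < len(b):
            best = max(best, gap_score + rec(i, j + 1))
        return best

    return rec(0, 0)


# ---------------------------------------------------------------------------
# event similarity and clustering
# ---------------------------------------------------------------------------


def event_similarity(
    events: Sequence[Sequence[str] | str],
    scores: ScoreMatrix,
    gap_score: float = 0.0,
    normalize: bool = True,
) -> np.ndarray:
    """Pairwise alignment-similarity matrix over events.

    With ``normalize`` the raw score is divided by the longer sequence's
    length, giving entries in [0, 1] with an exact diagonal of 1.
    """
    if len(events) < 2:
        raise ValueError("need at least 2 events")
    n = len(events)
    sim = np.zeros((n, n))
    for i in range(n):
        sim[i, i] = 1.0 if normalize else float(len(events[i]))
        for j in range(i + 1, n):
            raw = align(events[i], events[j], scores, gap_score).score
            if normalize:
                raw /= max(len(events[i]), len(events[j]))
            sim[i, j] = sim[j, i] = raw
    return sim


@dataclass
class ClusterResult:
    """Agglomerative clustering of events on distance = 1 − similarity."""

    linkage_matrix: np.ndarray  # scipy linkage encoding
    labels: list[str]
    method: str

    def flat_clusters(self, cut: float) -> np.ndarray:
        return fcluster(self.linkage_matrix, t=cut, criterion="distance")

    def midpoint_cut(self) -> np.ndarray:
        """Flat clusters at the midpoint between the two highest merges.

        This is the natural two-cluster cut: it falls inside the gap that
        separates the final merge from everything below it (for a single
        merge the cut is at half its height).
        """
        heights = self.linkage_matrix[:, 2]
        top = float(heights[-1])
        below = float(heights[-2]) if len(heights) > 1 else 0.0
        return self.flat_clusters(0.5 * (top + below))

    def to_newick(self) -> str:
        tree = to_tree(self.linkage_matrix)

        def rec(node, parent_h: float) -> str:
            length = max(parent_h - node.dist, 0.0)
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6g}"
            left = rec(node.left, node.dist)
            right = rec(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return rec(tree, tree.dist) + ";"

    def write_merge_table(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("step\tleft\tright\theight\tsize\n")
            for k, (a, b, h, sz) in enumerate(self.linkage_matrix):
                fh.write(f"{k}\t{int(a)}\t{int(b)}\t{h:.8g}\t{int(sz)}\n")


def cluster_events(
    similarity: np.ndarray,
    labels: Sequence[str] | None = None,
    method: str = "average",
) -> ClusterResult:
    """UPGMA (or other scipy linkage) on an event similarity matrix."""
    sim = np.asarray(similarity, dtype=float)
    if sim.ndim != 2 or sim.shape[0] != sim.shape[1]:
        raise ValueError("similarity matrix must be square")
    if not np.allclose(sim, sim.T, atol=1e-12):
        raise ValueError("similarity matrix must be symmetric")
    dist = 1.0 - sim
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    Z = linkage(condensed, method=method)
    if labels is None:
        labels = [f"event{i}" for i in range(sim.shape[0])]
    return ClusterResult(linkage_matrix=Z, labels=list(labels), method=method)
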