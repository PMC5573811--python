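"""Independent oracles used by the test suite.

Each oracle recomputes an expected value by a route that shares no code with
the implementation it checks: exhaustive enumeration, closed forms, regular
expressions, or least-squares fits.
"""

from __future__ import annotations

import itertools
import re
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.optimize import nnls

AA20 = "ACDEFGHIKLMNPQRSTVWY"


# ---------------------------------------------------------------------------
# Global alignment by exhaustive enumeration (affine gaps)
# ---------------------------------------------------------------------------


def brute_force_align_score(a, b, score_fn, gap_open, gap_extend):
    """Maximum global alignment score by enumerating every monotone path.

    Gap run of length L costs gap_open + L * gap_extend (first gap position
    charged open + extend, as in the implementation's convention).
    """
    best = [-np.inf]

    def rec(i, j, score, last):  # last in {None, 'd', 'u', 'l'}
        if i == len(a) and j == len(b):
            best[0] = max(best[0], score)
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, score + score_fn(a[i], b[j]), "d")
        if i < len(a):
            cost = gap_extend if last == "u" else gap_open + gap_extend
            rec(i + 1, j, score - cost, "u")
        if j < len(b):
            cost = gap_extend if last == "l" else gap_open + gap_extend
            rec(i, j + 1, score - cost, "l")

    rec(0, 0, 0.0, None)
    return best[0]


# ---------------------------------------------------------------------------
# Motif notation -> regular expression (independent mini-parser)
# ---------------------------------------------------------------------------


def notation_to_regex(spec: str) -> re.Pattern:
    """Second, regex-based reading of the motif notation for cross-checking."""
    out = []
    i = 0
    while i < len(spec):
        c = spec[i]
        if c == "(":
            close = spec.index(")", i)
            out.append("[" + spec[i + 1 : close].replace("/", "") + "]")
            i = close + 1
        elif c == "X":
            j = i + 1
            while j < len(spec) and spec[j].isdigit():
                j += 1
            n = int(spec[i + 1 : j]) if j > i + 1 else 1
            out.append(f"[{AA20}]{{{n}}}")
            i = j
        else:
            out.append(c)
            i += 1
    return re.compile("(?=(" + "".join(out) + "))")


def regex_hits(pattern_spec: str, peptide: str) -> list[int]:
    """1-based overlapping match starts."""
    return [m.start() + 1 for m in notation_to_regex(pattern_spec).finditer(peptide)]


def expand_language(spec: str) -> set[str]:
    """Full expansion of a (small) pattern into its string language."""
    sets = []
    i = 0
    while i < len(spec):
        c = spec[i]
        if c == "(":
            close = spec.index(")", i)
            sets.append(tuple(spec[i + 1 : close].split("/")))
            i = close + 1
        elif c == "X":
            j = i + 1
            while j < len(spec) and spec[j].isdigit():
                j += 1
            n = int(spec[i + 1 : j]) if j > i + 1 else 1
            sets.extend([tuple(AA20)] * n)
            i = j
        else:
            sets.append((c,))
            i += 1
    return {"".join(t) for t in itertools.product(*sets)}


# ---------------------------------------------------------------------------
# Unrooted tree topologies and least-squares branch fits
# ---------------------------------------------------------------------------


@lru_cache(maxsize=None)
def unrooted_topologies(n: int) -> tuple:
    """All unrooted binary leaf-labeled topologies on leaves 0..n-1.

    Each topology is a frozenset of edges (node pairs); internal nodes are
    numbered from n upward. 1, 3, 15, 105 topologies for n = 3..6.
    """
    assert n >= 3
    base = frozenset({(0, n), (1, n), (2, n)})
    trees = [(base, n + 1)]
    for leaf in range(3, n):
        new_trees = []
        for edges, next_node in trees:
            for edge in sorted(edges):
                rest = set(edges) - {edge}
                u, v = edge
                w = next_node
                rest |= {(u, w), (v, w), (leaf, w)}
                new_trees.append((frozenset(rest), next_node + 1))
        trees = new_trees
    return tuple(t[0] for t in trees)


def _paths(edges: frozenset, n: int) -> dict[tuple[int, int], list]:
    adj: dict[int, list[tuple[int, int]]] = {}
    edge_list = sorted(edges)
    for idx, (u, v) in enumerate(edge_list):
        adj.setdefault(u, []).append((v, idx))
        adj.setdefault(v, []).append((u, idx))
    paths = {}
    for a in range(n):
        stack = [(a, None, [])]
        seen = {a}
        while stack:
            node, _, used = stack.pop()
            if node < n and node != a:
                if a < node:
                    paths[(a, node)] = used
                continue
            for nxt, eidx in adj[node]:
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append((nxt, node, used + [eidx]))
    return paths


def ls_topology_sse(edges: frozenset, dm: np.ndarray) -> float:
    """Least-squares (non-negative branch lengths) fit error of a topology."""
    n = dm.shape[0]
    n_edges = len(edges)
    paths = _paths(edges, n)
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    A = np.zeros((len(pairs), n_edges))
    y = np.zeros(len(pairs))
    for row, (i, j) in enumerate(pairs):
        for eidx in paths[(i, j)]:
            A[row, eidx] = 1.0
        y[row] = dm[i, j]
    x, _ = nnls(A, y)
    return float(((A @ x - y) ** 2).sum())


def topology_bipartitions(edges: frozenset, n: int) -> set[frozenset]:
    """Non-trivial splits (leaf-id frozensets, canonical smaller side)."""
    adj: dict[int, set[int]] = {}
    for u, v in edges:
        adj.setdefault(u, set()).add(v)
        adj.setdefault(v, set()).add(u)
    leafset = frozenset(range(n))
    out = set()
    for u, v in edges:
        # leaves on v's side when edge removed
        seen = {u, v}
        stack = [v]
        side = set()
        while stack:
            node = stack.pop()
            if node < n:
                side.add(node)
            for nxt in adj[node]:
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append(nxt)
        clade = frozenset(side)
        if 2 <= len(clade) <= n - 2:
            other = leafset - clade
            if len(clade) < len(other) or (len(clade) == len(other) and sorted(clade) < sorted(other)):
                out.add(clade)
            else:
                out.add(other)
    return out


def random_additive_tree(
    n: int, rng: np.random.Generator, min_branch: float = 0.05, max_branch: float = 1.0
):
    """Random binary unrooted tree with positive branch lengths.

    Returns (distance DataFrame over string labels t0..t{n-1}, set of
    canonical bipartitions over those labels).
    """
    topos = None
    # build by random leaf attachment rather than enumerating
    edges: dict[tuple[int, int], float] = {}
    nxt = n

    def add_edge(u, v, w):
        edges[(u, v)] = w

    add_edge(0, n, float(rng.uniform(min_branch, max_branch)))
    add_edge(1, n, float(rng.uniform(min_branch, max_branch)))
    add_edge(2, n, float(rng.uniform(min_branch, max_branch)))
    nxt = n + 1
    for leaf in range(3, n):
        keys = sorted(edges)
        u, v = keys[int(rng.integers(0, len(keys)))]
        w = edges.pop((u, v))
        mid = nxt
        nxt += 1
        split = float(rng.uniform(0.2, 0.8))
        add_edge(u, mid, w * split)
        add_edge(v, mid, w * (1 - split))
        add_edge(leaf, mid, float(rng.uniform(min_branch, max_branch)))

    adj: dict[int, list] = {}
    for (u, v), w in edges.items():
        adj.setdefault(u, []).append((v, w))
        adj.setdefault(v, []).append((u, w))
    dm = np.zeros((n, n))
    for a in range(n):
        dist = {a: 0.0}
        stack = [a]
        while stack:
            node = stack.pop()
            for nxt_node, w in adj[node]:
                if nxt_node not in dist:
                    dist[nxt_node] = dist[node] + w
                    stack.append(nxt_node)
        for b in range(n):
            dm[a, b] = dist[b]
    dm = (dm + dm.T) / 2.0  # exact float symmetry
    np.fill_diagonal(dm, 0.0)
    labels = [f"t{i}" for i in range(n)]
    df = pd.DataFrame(dm, index=labels, columns=labels)
    splits_idx = topology_bipartitions(frozenset(edges), n)
    splits = {frozenset(labels[i] for i in s) for s in splits_idx}
    return df, splits


# ---------------------------------------------------------------------------
# Misc small oracles
# ---------------------------------------------------------------------------


def codon_walk_phases(exon_lengths_nt: list[int]) -> list[int]:
    """Intron phases by literally walking codon positions nucleotide by nucleotide."""
    phases = []
    pos_in_codon = 0
    for exon_len in exon_lengths_nt[:-1]:
        for _ in range(exon_len):
            pos_in_codon = (pos_in_codon + 1) % 3
        phases.append(pos_in_codon)
    return phases


def shannon_column_bits(freqs: dict[str, float], n: int) -> float:
    """2 - (H + 3/(2 ln2 n)), floored at 0 — closed-form column information."""
    h = -sum(p * np.log2(p) for p in freqs.values() if p > 0)
    en = 3.0 / (2.0 * np.log(2) * n)
    return max(0.0, 2.0 - (h + en))
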