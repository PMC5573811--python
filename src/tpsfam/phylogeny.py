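"""Distance-based phylogeny: p-distances, neighbor joining, bootstrap, subfamily calls.

The tree method is classical neighbor joining (Saitou-Nei): repeatedly join
the pair minimizing Q_ij = (n-2) d_ij - r_i - r_j. NJ is consistent on
additive matrices (it recovers the generating tree exactly), which the test
suite exploits as an oracle. Negative branch-length estimates are clamped to
zero with the deficit transferred to the sister branch (standard practice;
total path lengths preserved). Ties in the Q matrix break deterministically
toward the lowest (row, column) index pair.

Distances default to p-distance (mismatches / compared columns) under
pairwise deletion of gap columns; a Poisson correction -ln(1-p) is available
behind a flag. Bootstrap supports resample alignment columns with
replacement and report the percentage of replicate NJ trees containing each
internal bipartition of the reference tree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from skbio import TreeNode

from .genome_io import ProteinRecord
from .homology import GAP, global_align

# ---------------------------------------------------------------------------
# Multiple alignment container
# ---------------------------------------------------------------------------


@dataclass
class MultipleAlignment:
    """Equal-length aligned rows over the amino-acid alphabet plus '-'."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in count")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate ids in alignment")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError(f"rows of unequal length: {sorted(lengths)}")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def as_matrix(self) -> np.ndarray:
        """uint8 matrix; gaps encode as 0."""
        arr = np.frombuffer("".join(self.rows).encode(), dtype=np.uint8)
        arr = arr.reshape(self.n_rows, self.n_columns).copy()
        arr[arr == ord(GAP)] = 0
        return arr

    def resample_columns(self, rng: np.random.Generator) -> "MultipleAlignment":
        cols = rng.integers(0, self.n_columns, size=self.n_columns)
        rows = ["".join(r[c] for c in cols) for r in self.rows]
        return MultipleAlignment(list(self.ids), rows)

    def write_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name, row in zip(self.ids, self.rows):
                fh.write(f">{name}\n{row}\n")

    @classmethod
    def read_fasta(cls, path: str | Path) -> "MultipleAlignment":
        ids, rows = [], []
        name, chunks = None, []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if line.startswith(">"):
                    if name is not None:
                        ids.append(name)
                        rows.append("".join(chunks))
                    name, chunks = line[1:].split()[0], []
                elif line:
                    chunks.append(line)
        if name is not None:
            ids.append(name)
            rows.append("".join(chunks))
        return cls(ids, rows)


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------


def p_distance_matrix(msa: MultipleAlignment, poisson: bool = False) -> pd.DataFrame:
    """Pairwise p-distances with pairwise deletion of gap columns.

    d(i,j) = mismatches / compared columns over columns where both rows are
    ungapped. With ``poisson=True`` the Poisson multiple-hit correction
    -ln(1 - p) is applied. A pair with zero comparable columns is an error.
    """
    if msa.n_rows < 2:
        raise ValueError("need at least 2 rows")
    arr = msa.as_matrix()
    mask = arr != 0
    n = msa.n_rows
    d = np.zeros((n, n))
    for i in range(n):
        both = mask[i] & mask
        comp = both.sum(axis=1)
        if np.any(comp[np.arange(n) != i] == 0):
            j = int(np.where((comp == 0) & (np.arange(n) != i))[0][0])
            raise ValueError(f"no comparable columns between {msa.ids[i]} and {msa.ids[j]}")
        diff = ((arr[i] != arr) & both).sum(axis=1)
        d[i] = diff / comp
    d = (d + d.T) / 2.0  # exact symmetry against float noise
    np.fill_diagonal(d, 0.0)
    if poisson:
        if np.any(d >= 1.0):
            raise ValueError("p-distance >= 1, Poisson correction undefined")
        d = -np.log1p(-d)
        np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=msa.ids, columns=msa.ids)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------


@dataclass
class DistanceTree:
    """Unrooted NJ tree; internal structure is a scikit-bio TreeNode.

    The root is a degree-3 placeholder (unrooted convention). Bootstrap
    supports, when computed, live in ``supports`` keyed by canonical
    bipartition and are written as internal node labels in Newick output.
    """

    root: TreeNode
    ids: list[str]
    supports: dict[frozenset, float] = field(default_factory=dict)

    def bipartitions(self) -> set[frozenset]:
        """Canonical non-trivial bipartitions (smaller side, deterministic)."""
        return tree_bipartitions(self.root, self.ids)

    def to_newick(self, path: str | Path | None = None) -> str:
        tree = self.root.copy()
        if self.supports:
            leafset = frozenset(self.ids)
            for node in tree.non_tips(include_self=False):
                clade = frozenset(t.name for t in node.tips())
                key = canonical_bipartition(clade, leafset)
                if key in self.supports:
                    node.name = f"{self.supports[key]:.0f}"
        for node in tree.traverse():
            if node.length is not None:
                node.length = round(node.length, 6)
        newick = str(tree)
        if path is not None:
            Path(path).write_text(newick)
        return newick


def canonical_bipartition(clade: frozenset, leafset: frozenset) -> frozenset:
    """Pick the canonical side of an edge-induced split (smaller; ties by sort)."""
    other = leafset - clade
    if len(clade) != len(other):
        return clade if len(clade) < len(other) else other
    return min(clade, other, key=lambda s: sorted(s))


def tree_bipartitions(root: TreeNode, ids: Sequence[str]) -> set[frozenset]:
    leafset = frozenset(ids)
    out: set[frozenset] = set()
    for node in root.non_tips(include_self=False):
        clade = frozenset(t.name for t in node.tips())
        if 2 <= len(clade) <= len(leafset) - 2:
            out.add(canonical_bipartition(clade, leafset))
    return out


def nj_tree(d: pd.DataFrame | np.ndarray, ids: Sequence[str] | None = None) -> DistanceTree:
    """Neighbor-joining tree from a symmetric zero-diagonal distance matrix."""
    if isinstance(d, pd.DataFrame):
        ids = list(d.index)
        mat = d.to_numpy(dtype=float)
    else:
        mat = np.asarray(d, dtype=float)
        if ids is None:
            ids = [f"t{i}" for i in range(mat.shape[0])]
        ids = list(ids)
    n = mat.shape[0]
    if mat.shape != (n, n) or n < 3:
        raise ValueError("need a square matrix with n >= 3")
    if not np.allclose(mat, mat.T, atol=1e-8):
        raise ValueError("distance matrix is not symmetric")
    if not np.allclose(np.diag(mat), 0.0, atol=1e-8):
        raise ValueError("distance matrix diagonal must be zero")

    nodes: list[TreeNode] = [TreeNode(name=name) for name in ids]
    D = mat.copy()
    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        # row-major argmin = lowest (i, j) on ties
        flat = int(np.argmin(Q))
        i, j = divmod(flat, m)
        if i > j:
            i, j = j, i
        vi = 0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        vj = D[i, j] - vi
        # clamp-and-transfer for negative estimates
        if vi < 0:
            vj += -vi
            vi = 0.0
        if vj < 0:
            vi += -vj
            vj = 0.0
        parent = TreeNode(children=[nodes[i], nodes[j]])
        nodes[i].length = float(vi)
        nodes[j].length = float(vj)
        new_d = 0.5 * (D[i] + D[j] - D[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        D = np.vstack([D[keep][:, keep], new_d[keep][None, :]])
        D = np.hstack([D, np.append(new_d[keep], 0.0)[:, None]])
        nodes = [nodes[k] for k in keep] + [parent]

    # final trio around the central (degree-3) node
    (a, b, c) = nodes
    dab, dac, dbc = D[0, 1], D[0, 2], D[1, 2]
    va = 0.5 * (dab + dac - dbc)
    vb = 0.5 * (dab + dbc - dac)
    vc = 0.5 * (dac + dbc - dab)
    a.length, b.length, c.length = (max(0.0, float(v)) for v in (va, vb, vc))
    root = TreeNode(children=[a, b, c])
    return DistanceTree(root=root, ids=ids)


def tree_length(tree: DistanceTree) -> float:
    return float(
        sum(n.length or 0.0 for n in tree.root.traverse(include_self=False))
    )


def tree_to_distances(tree: DistanceTree) -> pd.DataFrame:
    """Leaf-to-leaf path-length matrix (for round-trip checks)."""
    tips = list(tree.root.tips())
    names = [t.name for t in tips]
    n = len(tips)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = tips[i].distance(tips[j])
    return pd.DataFrame(mat, index=names, columns=names).loc[
        sorted(names), sorted(names)
    ]


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------


def bootstrap_supports(
    msa: MultipleAlignment,
    n_reps: int = 1000,
    seed: int = 0,
    poisson: bool = False,
) -> DistanceTree:
    """Column-resampling bootstrap on the NJ tree of ``msa``.

    Returns the reference tree with ``supports`` filled: for each internal
    bipartition, the percentage of replicate trees containing it. Fully
    reproducible under a fixed seed.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    ref = nj_tree(p_distance_matrix(msa, poisson=poisson))
    splits = ref.bipartitions()
    counts = {s: 0 for s in splits}
    rng = np.random.default_rng(seed)
    for _ in range(n_reps):
        rep = msa.resample_columns(rng)
        try:
            rep_tree = nj_tree(p_distance_matrix(rep, poisson=poisson))
        except ValueError:  # degenerate resample (e.g. all-gap overlap)
            continue
        rep_splits = rep_tree.bipartitions()
        for s in splits:
            if s in rep_splits:
                counts[s] += 1
    ref.supports = {s: 100.0 * c / n_reps for s, c in counts.items()}
    return ref


# ---------------------------------------------------------------------------
# Reference-anchored subfamily assignment
# ---------------------------------------------------------------------------


def assign_subfamily(
    tree: DistanceTree, reference_labels: Mapping[str, str]
) -> dict[str, str]:
    """Assign each non-reference leaf the subfamily of its smallest pure clade.

    For every edge-induced bipartition side containing the query and at least
    one reference, the side qualifies if all its references share one
    subfamily; the query gets that subfamily from the smallest qualifying
    side. Queries with no qualifying side are "ambiguous".
    """
    refs = {r for r in reference_labels if r in set(tree.ids)}
    if not refs:
        raise ValueError("no reference leaves present in tree")
    leafset = frozenset(tree.ids)
    sides: list[frozenset] = []
    for node in tree.root.non_tips(include_self=False):
        clade = frozenset(t.name for t in node.tips())
        sides.append(clade)
        sides.append(leafset - clade)
    queries = [l for l in tree.ids if l not in reference_labels]
    out: dict[str, str] = {}
    for q in queries:
        best: tuple[int, list, str] | None = None
        for side in sides:
            if q not in side:
                continue
            side_refs = {reference_labels[r] for r in side & refs}
            if len(side_refs) != 1:
                continue
            key = (len(side), sorted(side))
            if best is None or key < (best[0], best[1]):
                best = (len(side), sorted(side), next(iter(side_refs)))
        out[q] = best[2] if best else "ambiguous"
    return out


# ---------------------------------------------------------------------------
# Progressive multiple alignment
# ---------------------------------------------------------------------------


def _kmer_distance(seqs: Sequence[str], k: int = 3) -> np.ndarray:
    sets = [set(s[i : i + k] for i in range(max(1, len(s) - k + 1))) for s in seqs]
    n = len(seqs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            union = len(sets[i] | sets[j])
            shared = len(sets[i] & sets[j])
            d[i, j] = d[j, i] = 1.0 - (shared / union if union else 0.0)
    return d


def _consensus(rows: Sequence[str]) -> str:
    """Per-column majority residue (ties alphabetical; gap only if unanimous)."""
    out = []
    for col in zip(*rows):
        counts: dict[str, int] = {}
        for c in col:
            if c != GAP:
                counts[c] = counts.get(c, 0) + 1
        if not counts:
            out.append("A")  # all-gap column: neutral placeholder
        else:
            out.append(min(counts, key=lambda c: (-counts[c], c)))
    return "".join(out)


def _project(rows: list[str], gapped: str) -> list[str]:
    """Insert gap columns into profile rows wherever ``gapped`` has gaps."""
    out = []
    for row in rows:
        buf = []
        it = iter(row)
        for c in gapped:
            buf.append(GAP if c == GAP else next(it))
        out.append("".join(buf))
    return out


def progressive_msa(
    seqs: Sequence[ProteinRecord] | Mapping[str, str], k: int = 3
) -> MultipleAlignment:
    """Deterministic progressive alignment.

    Guide tree: average-linkage clustering of k-mer Jaccard distances.
    Merging: the two profiles' column consensuses are globally aligned with
    the package aligner and the resulting gap pattern is projected into every
    row of each profile. Two input sequences reduce exactly to the pairwise
    global alignment.
    """
    if isinstance(seqs, Mapping):
        items = [(name, s) for name, s in seqs.items()]
    else:
        items = [(p.protein_id, p.residues) for p in seqs]
    if len(items) < 2:
        raise ValueError("need at least 2 sequences")
    ids = [name for name, _ in items]
    if len(items) == 2:
        aln = global_align(items[0][1], items[1][1], molecule="protein")
        return MultipleAlignment(ids, [aln.aligned_a, aln.aligned_b])

    d = _kmer_distance([s for _, s in items], k=k)
    link = hierarchy.linkage(squareform(d, checks=False), method="average")
    profiles: dict[int, tuple[list[str], list[str]]] = {
        i: ([name], [s]) for i, (name, s) in enumerate(items)
    }
    next_id = len(items)
    for a_idx, b_idx, _, _ in link:
        ids_a, rows_a = profiles.pop(int(a_idx))
        ids_b, rows_b = profiles.pop(int(b_idx))
        aln = global_align(_consensus(rows_a), _consensus(rows_b), molecule="protein")
        rows_a = _project(rows_a, aln.aligned_a)
        rows_b = _project(rows_b, aln.aligned_b)
        profiles[next_id] = (ids_a + ids_b, rows_a + rows_b)
        next_id += 1
    (final_ids, final_rows) = profiles.popitem()[1]
    order = {name: i for i, name in enumerate(final_ids)}
    rows = [final_rows[order[name]] for name in ids]
    return MultipleAlignment(ids, rows)
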