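"""p-distances, NJ consistency, bootstrap, subfamily assignment, progressive MSA."""

import numpy as np
import pandas as pd
import pytest
from skbio import DistanceMatrix
from skbio.tree import nj as skbio_nj

from tpsfam import phylogeny as ph

from oracles import ls_topology_sse, random_additive_tree, topology_bipartitions, unrooted_topologies

AA = "ACDEFGHIKLMNPQRSTVWY"


def random_msa(rng, n_rows=5, n_cols=20):
    rows = ["".join(AA[i] for i in rng.integers(0, 20, size=n_cols)) for _ in range(n_rows)]
    return ph.MultipleAlignment([f"s{i}" for i in range(n_rows)], rows)


class TestPDistance:
    def test_identical_rows_zero(self):
        msa = ph.MultipleAlignment(["a", "b"], ["MKLV", "MKLV"])
        assert ph.p_distance_matrix(msa).loc["a", "b"] == 0.0

    def test_one_in_ten(self):
        msa = ph.MultipleAlignment(["a", "b"], ["AAAAAAAAAA", "AAAAAAAAAC"])
        assert ph.p_distance_matrix(msa).loc["a", "b"] == pytest.approx(0.1)

    def test_pairwise_deletion(self):
        msa = ph.MultipleAlignment(["a", "b"], ["MK-VD", "MKLV-"])
        # comparable columns: 1,2,4 -> 1 mismatch (V vs V at col4? cols: M=M, K=K, -L, VV, D-)
        assert ph.p_distance_matrix(msa).loc["a", "b"] == pytest.approx(0.0)

    def test_matches_hand_count_on_random_alignments(self, rng):
        for _ in range(20):
            msa = random_msa(rng, 5, 20)
            d = ph.p_distance_matrix(msa)
            for i in range(5):
                for j in range(i + 1, 5):
                    mism = sum(a != b for a, b in zip(msa.rows[i], msa.rows[j]))
                    assert d.iloc[i, j] == pytest.approx(mism / 20)

    def test_no_comparable_columns_error(self):
        msa = ph.MultipleAlignment(["a", "b"], ["M-", "-K"])
        with pytest.raises(ValueError, match="comparable"):
            ph.p_distance_matrix(msa)

    def test_poisson_correction(self):
        msa = ph.MultipleAlignment(["a", "b"], ["AAAAAAAAAA", "AAAAAAAAAC"])
        d = ph.p_distance_matrix(msa, poisson=True)
        assert d.loc["a", "b"] == pytest.approx(-np.log(0.9))


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        d = pd.DataFrame(
            [[0, 2, 4], [2, 0, 4], [4, 4, 0]], index=list("ABC"), columns=list("ABC"), dtype=float
        )
        tree = ph.nj_tree(d)
        lengths = {t.name: t.length for t in tree.root.tips()}
        assert lengths == {"A": 1.0, "B": 1.0, "C": 3.0}

    def test_asymmetric_rejected(self):
        d = np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]], dtype=float)
        with pytest.raises(ValueError, match="symmetric"):
            ph.nj_tree(d)

    def test_additive_recovery_100_random_trees(self, rng):
        """NJ is consistent: exact topology and lengths on additive matrices."""
        for _ in range(100):
            n = int(rng.integers(4, 13))
            dm, true_splits = random_additive_tree(n, rng)
            tree = ph.nj_tree(dm)
            assert tree.bipartitions() == true_splits
            back = ph.tree_to_distances(tree)
            assert np.allclose(back.to_numpy(), dm.loc[back.index, back.columns].to_numpy(), atol=1e-8)

    def test_agrees_with_skbio_nj_topology(self, rng):
        for _ in range(10):
            dm, _ = random_additive_tree(8, rng)
            ours = ph.nj_tree(dm).bipartitions()
            sk_tree = skbio_nj(DistanceMatrix(dm.to_numpy(), ids=list(dm.index)))
            sk_splits = set()
            leafset = frozenset(dm.index)
            for node in sk_tree.non_tips(include_self=False):
                clade = frozenset(t.name for t in node.tips())
                if 2 <= len(clade) <= len(leafset) - 2:
                    sk_splits.add(ph.canonical_bipartition(clade, leafset))
            assert ours == sk_splits

    def test_matches_least_squares_search_n6(self, rng):
        """NJ topology equals the best topology over all 105 on additive input."""
        topos = unrooted_topologies(6)
        assert len(topos) == 105
        for _ in range(5):
            dm, _ = random_additive_tree(6, rng)
            labels = list(dm.index)
            arr = dm.to_numpy()
            sse = [(ls_topology_sse(t, arr), i) for i, t in enumerate(topos)]
            best = topos[min(sse)[1]]
            best_splits = {
                frozenset(labels[i] for i in s) for s in topology_bipartitions(best, 6)
            }
            assert ph.nj_tree(dm).bipartitions() == best_splits

    def test_tree_length_invariant_under_leaf_permutation(self, rng):
        dm, _ = random_additive_tree(7, rng)
        perm = list(rng.permutation(dm.index))
        t1 = ph.nj_tree(dm)
        t2 = ph.nj_tree(dm.loc[perm, perm])
        assert ph.tree_length(t1) == pytest.approx(ph.tree_length(t2))

    def test_branch_lengths_nonnegative_on_noisy_input(self, rng):
        dm, _ = random_additive_tree(8, rng)
        noisy = dm + rng.uniform(0, 0.05, size=dm.shape)
        noisy = (noisy + noisy.T) / 2
        np.fill_diagonal(noisy.values, 0.0)
        tree = ph.nj_tree(noisy)
        assert all((t.length or 0) >= 0 for t in tree.root.traverse(include_self=False))


def two_clade_msa(n_per_clade=4, n_cols=60, seed=5):
    """Strong two-clade signal: clades differ at half the columns."""
    rng = np.random.default_rng(seed)
    base = [AA[i] for i in rng.integers(0, 20, size=n_cols)]
    alt = list(base)
    for i in range(0, n_cols, 2):
        alt[i] = AA[(AA.index(alt[i]) + 1) % 20]
    ids, rows = [], []
    for c, template in (("x", base), ("y", alt)):
        for k in range(n_per_clade):
            row = list(template)
            for _ in range(2):  # light within-clade noise
                p = int(rng.integers(0, n_cols))
                row[p] = AA[int(rng.integers(0, 20))]
            ids.append(f"{c}{k}")
            rows.append("".join(row))
    return ph.MultipleAlignment(ids, rows)


class TestBootstrap:
    def test_supports_in_range_and_reproducible(self, rng):
        msa = random_msa(rng, 6, 30)
        t1 = ph.bootstrap_supports(msa, n_reps=30, seed=42)
        t2 = ph.bootstrap_supports(msa, n_reps=30, seed=42)
        assert t1.supports == t2.supports
        assert all(0 <= v <= 100 for v in t1.supports.values())

    def test_congruent_alignment_full_support(self):
        msa = ph.MultipleAlignment(
            ["a", "b", "c", "d"],
            ["AAAAAAAAAA", "AAAAAAAAAC", "CCCCCCCCCA", "CCCCCCCCCC"],
        )
        tree = ph.bootstrap_supports(msa, n_reps=100, seed=0)
        key = ph.canonical_bipartition(frozenset({"a", "b"}), frozenset("abcd"))
        assert tree.supports[key] == 100.0

    def test_planted_two_clade_split_strongly_supported(self):
        msa = two_clade_msa()
        tree = ph.bootstrap_supports(msa, n_reps=200, seed=1)
        key = ph.canonical_bipartition(
            frozenset({"x0", "x1", "x2", "x3"}), frozenset(msa.ids)
        )
        assert tree.supports[key] > 95

    def test_newick_carries_supports(self):
        msa = two_clade_msa()
        tree = ph.bootstrap_supports(msa, n_reps=50, seed=2)
        assert ")" in tree.to_newick()
        # internal labels present
        assert any(ch.isdigit() for ch in tree.to_newick().split(")")[-2])


class TestAssignSubfamily:
    def _tree(self):
        # ((q1,r_b1),(q2,(r_g1,r_b2)))-ish via distances
        ids = ["q1", "rb1", "q2", "rg1", "rb2", "rg2"]
        coords = {"q1": 0.0, "rb1": 0.1, "rb2": 0.15, "q2": 5.0, "rg1": 5.1, "rg2": 5.2}
        d = pd.DataFrame(
            [[abs(coords[a] - coords[b]) + (0 if a == b else 0.01) for b in ids] for a in ids],
            index=ids, columns=ids,
        )
        np.fill_diagonal(d.values, 0.0)
        return ph.nj_tree(d)

    def test_sister_to_single_reference(self):
        tree = self._tree()
        labels = {"rb1": "tps-b", "rb2": "tps-b", "rg1": "tps-g", "rg2": "tps-g"}
        out = ph.assign_subfamily(tree, labels)
        assert out["q1"] == "tps-b"
        assert out["q2"] == "tps-g"

    def test_mixed_clade_ambiguous(self):
        ids = ["q", "rb", "rg"]
        d = pd.DataFrame(
            [[0, 0.1, 0.1], [0.1, 0, 0.1], [0.1, 0.1, 0]], index=ids, columns=ids, dtype=float
        )
        tree = ph.nj_tree(d)
        out = ph.assign_subfamily(tree, {"rb": "tps-b", "rg": "tps-g"})
        assert out["q"] == "ambiguous"

    def test_no_references_error(self):
        tree = self._tree()
        with pytest.raises(ValueError):
            ph.assign_subfamily(tree, {"zz": "tps-b"})

    def test_planted_subfamilies_recovered(self, small_genome):
        """>= 95% of planted functional genes assigned to their subfamily."""
        from tpsfam.phylogeny import assign_subfamily, nj_tree, p_distance_matrix, progressive_msa

        truth = small_genome.ground_truth
        functional = truth[truth.functional]
        seqs = {r.gene_id: small_genome.genes[r.gene_id].protein for _, r in functional.iterrows()}
        seqs.update(small_genome.references)
        msa = progressive_msa(seqs)
        tree = nj_tree(p_distance_matrix(msa))
        out = assign_subfamily(tree, small_genome.reference_labels)
        correct = sum(
            out[r.gene_id] == r.subfamily for _, r in functional.iterrows()
        )
        assert correct / len(functional) >= 0.95


class TestProgressiveMsa:
    def test_identical_sequences_gap_free(self):
        msa = ph.progressive_msa({"a": "MKLVDE", "b": "MKLVDE", "c": "MKLVDE"})
        assert all("-" not in row for row in msa.rows)

    def test_two_sequences_reduce_to_pairwise(self):
        from tpsfam.homology import global_align

        aln = global_align("MKLVDE", "MKLDE", molecule="protein")
        msa = ph.progressive_msa({"a": "MKLVDE", "b": "MKLDE"})
        assert msa.rows == [aln.aligned_a, aln.aligned_b]

    def test_rows_recover_inputs(self, small_genome):
        truth = small_genome.ground_truth
        ids = list(truth[truth.functional].gene_id[:5])
        seqs = {g: small_genome.genes[g].protein for g in ids}
        msa = ph.progressive_msa(seqs)
        for name, row in zip(msa.ids, msa.rows):
            assert row.replace("-", "") == seqs[name]

    def test_planted_indel_family_column_recovery(self, rng):
        """Low-divergence family with one planted deletion: the true columns
        (flanking blocks) are recovered for >= 90% of positions."""
        base = "".join(AA[i] for i in rng.integers(0, 20, size=80))
        variant = base[:40] + base[45:]  # 5-residue deletion
        seqs = {"a": base, "b": base, "c": variant}
        msa = ph.progressive_msa(seqs)
        row_c = msa.rows[msa.ids.index("c")]
        # c's row should be base with a 5-column gap at the deletion site
        assert row_c.count("-") == 5
        gap_start = row_c.index("-")
        assert 35 <= gap_start <= 45
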