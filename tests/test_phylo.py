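"""Alignment, distances, neighbor joining, bootstrap, monophyly."""

import math

import numpy as np
import pytest

from _oracles import monophyly_by_edge_removal, random_additive_tree
from t4apscan import (
    MultipleAlignment,
    bootstrap_support,
    distance_matrix,
    neighbor_joining,
    progressive_align,
    test_monophyly as check_monophyly,
)
from t4apscan.homology import global_align
from t4apscan.phylo import SaturationError, bipartitions, tree_path_distances
from t4apscan.synthetic_data import AA20, mutate


def rand_seq(rng, n):
    return "".join(np.array(list(AA20))[rng.integers(0, 20, size=n)])


class TestProgressiveAlign:
    def test_identical_sequences_align_without_gaps(self):
        aln = progressive_align(["MKVLADEF" * 5] * 4)
        assert all("-" not in row for row in aln.rows)
        assert aln.n_columns == 40

    def test_two_sequences_equal_optimal_pairwise(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            a, b = rand_seq(rng, 40), rand_seq(rng, 35)
            aln = progressive_align([a, b])
            _, ga, gb = global_align(a, b)
            assert aln.rows == [ga, gb]

    def test_column_count_at_least_longest_input(self):
        rng = np.random.default_rng(4)
        seqs = [rand_seq(rng, int(n)) for n in rng.integers(20, 60, size=5)]
        aln = progressive_align(seqs)
        assert aln.n_columns >= max(len(s) for s in seqs)
        for row, seq in zip(aln.rows, seqs):
            assert row.replace("-", "") == seq

    def test_single_sequence_rejected(self):
        with pytest.raises(ValueError):
            progressive_align(["MKV"])


class TestDistances:
    def test_identical_rows_give_zero(self):
        aln = MultipleAlignment(["a", "b"], ["MKVL", "MKVL"])
        assert distance_matrix(aln, "poisson")[0, 1] == 0.0

    def test_poisson_closed_form(self):
        rows = ["A" * 9 + "V", "A" * 10]  # p = 0.1
        aln = MultipleAlignment(["a", "b"], rows)
        d = distance_matrix(aln, "poisson")[0, 1]
        assert d == pytest.approx(-math.log(0.9), rel=1e-12)

    def test_jc69_closed_form_and_saturation(self):
        aln = MultipleAlignment(["a", "b"], ["AACC", "AACG"], "nucleotide")
        d = distance_matrix(aln, "jc69")[0, 1]
        assert d == pytest.approx(-0.75 * math.log(1 - 4 * 0.25 / 3))
        sat = MultipleAlignment(["a", "b"], ["AAAA", "CCCC"], "nucleotide")
        with pytest.raises(SaturationError, match="a / b"):
            distance_matrix(sat, "jc69")

    def test_symmetric_zero_diagonal(self):
        rng = np.random.default_rng(6)
        rows = [rand_seq(rng, 50) for _ in range(5)]
        D = distance_matrix(MultipleAlignment([f"t{i}" for i in range(5)], rows), "p")
        assert np.allclose(D, D.T) and np.allclose(np.diag(D), 0.0)

    def test_distances_use_only_shared_ungapped_columns(self):
        aln = MultipleAlignment(["a", "b"], ["MK-LA", "MKV-A"])  # 3 shared cols
        assert distance_matrix(aln, "p")[0, 1] == 0.0


class TestNeighborJoining:
    def test_three_taxa_three_point_formulas(self):
        D = np.array([[0.0, 0.3, 0.5], [0.3, 0.0, 0.6], [0.5, 0.6, 0.0]])
        tree = neighbor_joining(D, ["a", "b", "c"])
        la = tree.find("a").length
        lb = tree.find("b").length
        lc = tree.find("c").length
        assert la == pytest.approx(0.5 * (0.3 + 0.5 - 0.6))
        assert lb == pytest.approx(0.5 * (0.3 + 0.6 - 0.5))
        assert lc == pytest.approx(0.5 * (0.5 + 0.6 - 0.3))

    def test_recovers_random_additive_trees_exactly(self):
        rng = np.random.default_rng(8)
        for _ in range(5):
            true_tree, labels, D = random_additive_tree(rng, 8)
            est = neighbor_joining(D, labels)
            assert set(bipartitions(est)) == set(bipartitions(true_tree))
            assert np.allclose(tree_path_distances(est, labels), D, atol=1e-9)

    def test_invariant_under_taxon_permutation(self):
        rng = np.random.default_rng(9)
        _, labels, D = random_additive_tree(rng, 7)
        base = set(bipartitions(neighbor_joining(D, labels)))
        perm = list(rng.permutation(7))
        Dp = D[np.ix_(perm, perm)]
        shuffled = set(
            bipartitions(neighbor_joining(Dp, [labels[i] for i in perm]))
        )
        assert base == shuffled

    def test_agrees_with_skbio_on_additive_matrix(self):
        from skbio import DistanceMatrix
        from skbio.tree import nj

        rng = np.random.default_rng(10)
        _, labels, D = random_additive_tree(rng, 6)
        ours = set(bipartitions(neighbor_joining(D, labels)))
        theirs = set(bipartitions(nj(DistanceMatrix(D, labels))))
        assert ours == theirs

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError):
            neighbor_joining(np.zeros((2, 2)), ["a", "b"])


def block_alignment(n_per_block=3, n_cols=120, d_between=0.6, seed=0):
    """Two blocks of near-identical taxa separated by a clean signal."""
    rng = np.random.default_rng(seed)
    anc = rand_seq(rng, n_cols)
    other = mutate(anc, d_between, rng)
    labels, rows = [], []
    for i in range(n_per_block):
        labels.append(f"A{i}")
        rows.append(anc)
    for i in range(n_per_block):
        labels.append(f"B{i}")
        rows.append(other)
    return MultipleAlignment(labels, rows)


class TestBootstrap:
    def test_clean_split_gets_full_support(self):
        aln = block_alignment()
        tree = bootstrap_support(aln, n_replicates=100, seed=5)
        verdict = check_monophyly(tree, ["A0", "A1", "A2"])
        assert verdict.is_monophyletic
        assert verdict.support_pct == 100.0

    def test_same_seed_reproduces_supports(self):
        aln = block_alignment(seed=1)
        t1 = bootstrap_support(aln, 50, seed=9)
        t2 = bootstrap_support(aln, 50, seed=9)
        assert str(t1) == str(t2)

    def test_supports_match_independent_replicate_loop(self):
        """Support values agree (within sampling error) with a separately
        coded resample-and-count loop at higher replicate count."""
        rng = np.random.default_rng(11)
        anc = rand_seq(rng, 150)
        rows = [mutate(anc, 0.25, rng) for _ in range(6)]
        aln = MultipleAlignment([f"t{i}" for i in range(6)], rows)
        tree = bootstrap_support(aln, n_replicates=1000, seed=3)
        base_bips = bipartitions(tree)

        counts = {bip: 0 for bip in base_bips}
        rng2 = np.random.default_rng(12345)
        n_rep = 1000
        for _ in range(n_rep):
            cols = rng2.integers(0, aln.n_columns, size=aln.n_columns)
            rep_rows = ["".join(r[c] for c in cols) for r in aln.rows]
            rep = MultipleAlignment(aln.labels, rep_rows)
            D = distance_matrix(rep, "poisson", saturation="cap")
            rep_bips = set(bipartitions(neighbor_joining(D, rep.labels)))
            for bip in counts:
                counts[bip] += bip in rep_bips
        for bip, node in base_bips.items():
            ours = float(node.name)
            independent = 100.0 * counts[bip] / n_rep
            assert abs(ours - independent) <= 5.0


class TestMonophyly:
    def test_caterpillar_subsets(self):
        from skbio import TreeNode

        tree = TreeNode.read(["((a:1,b:1):1,(c:1,d:1):1);"])
        assert check_monophyly(tree, ["a", "b"]).is_monophyletic
        assert not check_monophyly(tree, ["a", "c"]).is_monophyletic

    def test_unknown_taxon_rejected(self):
        from skbio import TreeNode

        tree = TreeNode.read(["((a:1,b:1):1,(c:1,d:1):1);"])
        with pytest.raises(ValueError, match="unknown"):
            check_monophyly(tree, ["a", "z"])

    def test_matches_edge_removal_oracle_on_random_trees(self):
        rng = np.random.default_rng(13)
        for _ in range(30):
            tree, labels, _ = random_additive_tree(rng, 10)
            size = int(rng.integers(2, 9))
            subset = set(rng.choice(labels, size=size, replace=False).tolist())
            got = check_monophyly(tree, subset).is_monophyletic
            assert got == monophyly_by_edge_removal(tree, subset)

    def test_pilt_subfamily_structure_recovered(self, ancestors):
        """Cluster-resident pilT copies descend from one subfamily ancestor;
        the tree isolates them with high support."""
        from t4apscan import generate_pilt_subfamilies

        labels, seqs, resident = generate_pilt_subfamilies(17, ancestors)
        aln = progressive_align(seqs, labels)
        tree = bootstrap_support(aln, 100, seed=17)
        verdict = check_monophyly(tree, resident)
        assert verdict.is_monophyletic
        assert verdict.support_pct is not None and verdict.support_pct >= 90.0
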