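import itertools
import math
from collections import deque

import numpy as np
import pandas as pd
import pytest

from pancore.phylo import (
    MSA, DistanceMatrix, Tree, bipartitions, bootstrap_support,
    center_star_align, gene_tree_screen, jc_distance_matrix, nj_tree,
    nodal_distance, path_length_matrix, random_topology,
    random_tree_baseline, read_msa_fasta, write_msa_fasta,
)
from pancore.synthetic import mutate_sequence


# ------------------------------------------------------------ helpers

def _quartet(ab_cd=True) -> Tree:
    if ab_cd:
        return Tree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
    return Tree.from_newick("((A:1,C:1):1,(B:1,D:1):1);")


def _weighted_path(tree: Tree, a: str, b: str) -> float:
    dist = {a: 0.0}
    queue = deque([a])
    while queue:
        node = queue.popleft()
        for nbr, length in tree.adjacency[node].items():
            if nbr not in dist:
                dist[nbr] = dist[node] + length
                queue.append(nbr)
    return dist[b]


def _all_quartet_topologies():
    return [Tree.from_newick(nwk) for nwk in (
        "((A,B),(C,D));", "((A,C),(B,D));", "((A,D),(B,C));")]


def _all_five_leaf_topologies():
    # attach E to each of the 5 edges of each quartet topology: 15 trees
    trees = []
    for base in ("((A,B),(C,D));", "((A,C),(B,D));", "((A,D),(B,C));"):
        t0 = Tree.from_newick(base)
        edges = set()
        for u in t0.adjacency:
            for v in t0.adjacency[u]:
                edges.add((min(u, v), max(u, v)))
        for u, v in sorted(edges):
            t = t0.copy()
            new = "_X"
            del t.adjacency[u][v]
            del t.adjacency[v][u]
            for x, y in ((u, new), (v, new), ("E", new)):
                t.adjacency.setdefault(x, {})[y] = 1.0
                t.adjacency.setdefault(y, {})[x] = 1.0
            trees.append(t)
    return trees


# --------------------------------------------------------- center-star

class TestCenterStar:
    def test_identical_sequences_gap_free(self):
        msa = center_star_align({"a": "ACGTACGT", "b": "ACGTACGT",
                                 "c": "ACGTACGT"})
        assert all("-" not in row for row in msa.rows)

    def test_one_gap_column_for_length_difference(self):
        msa = center_star_align({"x": "ACGT", "y": "ACG"})
        assert msa.length == 4
        gap_columns = sum(1 for i in range(4)
                          if any(r[i] == "-" for r in msa.rows))
        assert gap_columns == 1

    def test_rows_equal_length_and_ungap_recovers_input(self):
        seqs = {"a": "ACGTAC", "b": "ACTAC", "c": "ACGTGTAC"}
        msa = center_star_align(seqs)
        assert len({len(r) for r in msa.rows}) == 1
        for name, row in zip(msa.names, msa.rows):
            assert row.replace("-", "") == seqs[name]

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            center_star_align({"a": "ACGT", "b": ""})

    def test_deterministic(self):
        seqs = {"a": "ACGTACAA", "b": "ACTTACAA", "c": "ACGTACAT"}
        assert center_star_align(seqs).rows == center_star_align(seqs).rows


def test_msa_fasta_round_trip(tmp_path):
    msa = center_star_align({"a": "ACGTAC", "b": "ACTAC"})
    path = write_msa_fasta(msa, tmp_path / "x.fasta")
    back = read_msa_fasta(path)
    assert back.names == msa.names and back.rows == msa.rows


# ----------------------------------------------------------------- JC

class TestJukesCantor:
    def test_identical_rows_zero(self):
        d = jc_distance_matrix(MSA(["a", "b"], ["ACGT", "ACGT"]))
        assert d.matrix[0, 1] == 0.0

    def test_closed_form_p_01(self):
        row_a = "A" * 100
        row_b = "C" * 10 + "A" * 90  # p = 0.1
        d = jc_distance_matrix(MSA(["a", "b"], [row_a, row_b]))
        expected = -0.75 * math.log(1 - 4 * 0.1 / 3)
        assert d.matrix[0, 1] == pytest.approx(expected)
        assert d.matrix[0, 1] == pytest.approx(0.10733, abs=1e-5)

    def test_saturation_capped_with_flag(self):
        row_a = "A" * 10
        row_b = "C" * 8 + "A" * 2  # p = 0.8 >= 0.75
        with pytest.warns(UserWarning, match="cap"):
            d = jc_distance_matrix(MSA(["a", "b"], [row_a, row_b]))
        assert d.matrix[0, 1] == 5.0
        assert ("a", "b") in d.capped_pairs

    def test_pairwise_deletion(self):
        # gapped columns are dropped per pair, not per alignment
        d = jc_distance_matrix(MSA(["a", "b"], ["AC-T", "ACGT"]))
        assert d.matrix[0, 1] == 0.0

    def test_no_comparable_columns_rejected(self):
        with pytest.raises(ValueError, match="comparable"):
            jc_distance_matrix(MSA(["a", "b"], ["A--", "-CC"]))


# ----------------------------------------------------------------- NJ

class TestNeighborJoining:
    def test_additive_quartet_reconstruction(self):
        # tree ((A:1,B:2):1,(C:3,D:4)) -> distances below
        names = ["A", "B", "C", "D"]
        D = np.array([
            [0, 3, 5, 6],
            [3, 0, 6, 7],
            [5, 6, 0, 7],
            [6, 7, 7, 0]], dtype=float)
        tree = nj_tree(DistanceMatrix(names, D))
        assert bipartitions(tree) == {frozenset({"C", "D"})}
        # additivity: weighted path lengths reproduce the input exactly
        for i, a in enumerate(names):
            for j, b in enumerate(names):
                if i < j:
                    assert _weighted_path(tree, a, b) == pytest.approx(D[i, j])

    def test_three_taxa_star(self):
        D = np.array([[0, 2, 3], [2, 0, 4], [3, 4, 0]], dtype=float)
        tree = nj_tree(DistanceMatrix(["a", "b", "c"], D))
        assert tree.leaves == {"a", "b", "c"}
        assert _weighted_path(tree, "a", "b") == pytest.approx(2.0)

    def test_leaf_set_preserved(self):
        rng = np.random.default_rng(0)
        names = [f"t{i}" for i in range(7)]
        x = rng.uniform(0, 5, size=(7, 2))
        D = np.sqrt(((x[:, None] - x[None, :]) ** 2).sum(-1))
        tree = nj_tree(DistanceMatrix(names, D))
        assert tree.leaves == set(names)

    def test_too_few_taxa(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(["a", "b"], np.zeros((2, 2))))

    def test_negative_branches_clamped(self):
        D = np.array([[0, 1, 1, 1], [1, 0, 1, 1],
                      [1, 1, 0, 1], [1, 1, 1, 0]], dtype=float)
        tree = nj_tree(DistanceMatrix(list("ABCD"), D))
        for node in tree.adjacency:
            for length in tree.adjacency[node].values():
                assert length >= 0.0

    @pytest.mark.parametrize("n_taxa", [4, 5, 6])
    def test_recovers_generating_topology_from_additive_matrices(self, n_taxa):
        # oracle: the generating random topology itself
        rng = np.random.default_rng(100 + n_taxa)
        leaves = [f"L{i}" for i in range(n_taxa)]
        for _ in range(30):
            truth = random_topology(leaves, rng)
            for node in truth.adjacency:
                for nbr in truth.adjacency[node]:
                    length = truth.adjacency[node][nbr]
                    if length == 1.0:  # assign random positive lengths once
                        val = float(rng.uniform(0.5, 3.0))
                        truth.adjacency[node][nbr] = val
                        truth.adjacency[nbr][node] = val
            D = np.zeros((n_taxa, n_taxa))
            for i, a in enumerate(leaves):
                for j, b in enumerate(leaves):
                    if i < j:
                        D[i, j] = D[j, i] = _weighted_path(truth, a, b)
            got = nj_tree(DistanceMatrix(leaves, D))
            assert bipartitions(got) == bipartitions(truth)


# -------------------------------------------------------------- nodal

class TestNodalDistance:
    def test_identity_is_zero(self):
        t = _quartet()
        assert nodal_distance(t, t) == 0.0

    def test_nni_quartet_value(self):
        # hand-computed path matrices differ in 4 of 6 pairs by 1
        got = nodal_distance(_quartet(True), _quartet(False))
        assert got == pytest.approx(math.sqrt(4 / 6))

    def test_leaf_mismatch_rejected_with_listing(self):
        t1 = Tree.from_newick("((A,B),C);")
        t2 = Tree.from_newick("((A,B),D);")
        with pytest.raises(ValueError, match="only in first \\['C'\\]"):
            nodal_distance(t1, t2)

    def test_symmetry(self):
        rng = np.random.default_rng(8)
        leaves = [f"x{i}" for i in range(8)]
        t1 = random_topology(leaves, rng)
        t2 = random_topology(leaves, rng)
        assert nodal_distance(t1, t2) == pytest.approx(nodal_distance(t2, t1))

    def test_rooted_newick_contracts_to_unrooted(self):
        # a rooted pectinate tree vs its unrooted equivalent
        t1 = Tree.from_newick("(((A,B),C),D);")
        t2 = Tree.from_newick("((A,B),(C,D));")  # same unrooted topology? no:
        # (((A,B),C),D) unrooted = AB|CD, so distance must be 0
        assert nodal_distance(t1, t2) == 0.0

    def test_zero_iff_identical_all_4_and_5_leaf_topologies(self):
        for trees in (_all_quartet_topologies(), _all_five_leaf_topologies()):
            for i, t1 in enumerate(trees):
                for j, t2 in enumerate(trees):
                    d = nodal_distance(t1, t2)
                    if bipartitions(t1) == bipartitions(t2):
                        assert d == 0.0
                    else:
                        assert d > 0.0

    def test_path_matrix_quartet(self):
        mat = path_length_matrix(_quartet())
        assert mat.loc["A", "B"] == 2
        assert mat.loc["A", "C"] == 3


class TestRandomBaseline:
    def test_seeded_determinism(self):
        focal = _quartet()
        a = random_tree_baseline(["A", "B", "C", "D"], focal, seed=4)
        b = random_tree_baseline(["A", "B", "C", "D"], focal, seed=4)
        assert a == b

    def test_default_n_random_is_10(self):
        import inspect

        sig = inspect.signature(random_tree_baseline)
        assert sig.parameters["n_random"].default == 10

    def test_mean_non_negative(self):
        rng = np.random.default_rng(1)
        leaves = [f"z{i}" for i in range(6)]
        focal = random_topology(leaves, rng)
        mean, sd = random_tree_baseline(leaves, focal, seed=2)
        assert mean >= 0.0 and sd >= 0.0

    def test_too_few_leaves(self):
        with pytest.raises(ValueError):
            random_tree_baseline(["A", "B", "C"], _quartet(), seed=0)


# ----------------------------------------------------------- bootstrap

def _simulate_quartet_msa(length=10_000, deep=0.25, shallow=0.02, seed=0):
    rng = np.random.default_rng(seed)
    root = "".join(rng.choice(list("ACGT"), size=length))
    left = mutate_sequence(root, deep, 1)
    right = mutate_sequence(root, deep, 2)
    return MSA(["A", "B", "C", "D"], [
        mutate_sequence(left, shallow, 3),
        mutate_sequence(left, shallow, 4),
        mutate_sequence(right, shallow, 5),
        mutate_sequence(right, shallow, 6),
    ])


class TestBootstrap:
    def test_replicates_preserve_length_and_supports_bounded(self):
        msa = _simulate_quartet_msa(length=2000)
        tree = bootstrap_support(msa, n_replicates=50, seed=1)
        assert tree.supports
        for value in tree.supports.values():
            assert 0.0 <= value <= 100.0

    def test_same_seed_same_supports(self):
        msa = _simulate_quartet_msa(length=1000)
        t1 = bootstrap_support(msa, n_replicates=30, seed=7)
        t2 = bootstrap_support(msa, n_replicates=30, seed=7)
        assert t1.supports == t2.supports

    def test_clean_quartet_high_support(self):
        msa = _simulate_quartet_msa(length=10_000)
        tree = bootstrap_support(msa, n_replicates=100, seed=3)
        split = frozenset({"C", "D"})
        assert tree.supports[split] >= 95.0


# ---------------------------------------------------- gene-tree screen

def _msa_from_tree(tree: Tree, length, rng, rate=0.08):
    """Evolve a sequence down a topology; long branches, so NJ recovers it."""
    root = next(n for n in sorted(tree.adjacency) if n.startswith("_"))
    seqs = {}
    seq0 = "".join(rng.choice(list("ACGT"), size=length))

    def walk(node, parent, seq):
        if not node.startswith("_"):
            seqs[node] = seq
        for child in sorted(tree.adjacency[node]):
            if child != parent:
                walk(child, node, mutate_sequence(seq, rate,
                                                  int(rng.integers(2**31))))

    walk(root, None, seq0)
    return MSA(sorted(seqs), [seqs[k] for k in sorted(seqs)])


class TestGeneTreeScreen:
    def test_100_genes_five_per_tail(self):
        rng = np.random.default_rng(2024)
        leaves = [f"s{i:02d}" for i in range(12)]
        reference = random_topology(leaves, rng)
        msas = {f"G{i:03d}": _msa_from_tree(random_topology(leaves, rng),
                                            300, rng)
                for i in range(100)}
        report = gene_tree_screen(msas, reference, n_random=5, seed=1)
        assert len(report.table) == 100
        # 5%/95% percentiles of 100 values leave at most 5 strictly outside
        assert 1 <= len(report.lower_tail) <= 5
        assert 1 <= len(report.upper_tail) <= 5

    def test_identical_trees_degenerate_warning(self):
        rng = np.random.default_rng(5)
        leaves = [f"s{i}" for i in range(8)]
        reference = random_topology(leaves, rng)
        msa = _msa_from_tree(reference, 400, rng)
        msas = {f"G{i}": msa for i in range(25)}
        with pytest.warns(UserWarning, match="degenerate"):
            report = gene_tree_screen(msas, reference, n_random=5, seed=0)
        assert (report.table["nodal_distance"] == 0.0).all()

    def test_leaf_mismatch_skipped_and_logged(self):
        rng = np.random.default_rng(6)
        leaves = [f"s{i}" for i in range(8)]
        reference = random_topology(leaves, rng)
        good = {f"G{i}": _msa_from_tree(random_topology(leaves, rng), 300, rng)
                for i in range(20)}
        bad = _msa_from_tree(random_topology(leaves[:6], rng), 300, rng)
        with pytest.warns(UserWarning, match="mismatch"):
            report = gene_tree_screen({**good, "BAD": bad}, reference,
                                      n_random=5, seed=0)
        assert report.skipped == ["BAD"]
        assert len(report.table) == 20

    def test_planted_discordance_in_upper_tail(self):
        rng = np.random.default_rng(7)
        leaves = [f"s{i}" for i in range(10)]
        reference = random_topology(leaves, rng)
        msas = {f"G{i:02d}": _msa_from_tree(reference, 300, rng, rate=0.05)
                for i in range(24)}
        # one family evolves down a very different topology
        msas["DISC"] = _msa_from_tree(random_topology(leaves, rng), 300, rng,
                                      rate=0.05)
        with pytest.warns(UserWarning):
            report = gene_tree_screen(msas, reference, n_random=5, seed=0)
        assert "DISC" in report.upper_tail
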