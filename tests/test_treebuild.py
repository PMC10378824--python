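"""Neighbor joining, bootstrap support and clade/motif concordance."""

import numpy as np
import pytest

from sbscan.treebuild import (
    DistanceMatrix,
    Tree,
    TreeNode,
    bootstrap_support,
    clade_motif_concordance,
    distance_matrix,
    neighbor_joining,
    p_distance,
    read_alignment,
    write_phylip,
)


def _random_additive(n, rng):
    """Random binary tree with positive branch lengths; returns (D, bips)."""
    nodes = [frozenset([i]) for i in range(n)]
    children, lens = {}, {}
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        a, b = nodes[j], nodes[i]
        new = a | b
        children[new] = (a, b)
        lens[(new, a)] = float(rng.uniform(0.5, 3.0))
        lens[(new, b)] = float(rng.uniform(0.5, 3.0))
        nodes = [x for k, x in enumerate(nodes) if k not in (i, j)] + [new]
    root = nodes[0]
    D = np.zeros((n, n))

    def leafdists(node):
        if len(node) == 1:
            return {next(iter(node)): 0.0}
        a, b = children[node]
        da = {k: v + lens[(node, a)] for k, v in leafdists(a).items()}
        db = {k: v + lens[(node, b)] for k, v in leafdists(b).items()}
        for x in da:
            for y in db:
                D[x, y] = D[y, x] = da[x] + db[y]
        return {**da, **db}

    leafdists(root)
    labels = [f"t{i}" for i in range(n)]
    allset = frozenset(labels)
    ref = min(labels)
    bips = set()
    for clade in children:
        names = frozenset(f"t{i}" for i in clade)
        if 2 <= len(names) <= n - 2:
            bips.add(names if ref not in names else allset - names)
    return labels, D, bips


class TestPDistance:
    @pytest.mark.parametrize(
        "a,b,expected",
        [("ACGT", "ACGT", 0.0), ("ACGT", "ACGA", 0.25), ("A-GT", "AAGT", 0.25)],
    )
    def test_known_values(self, a, b, expected):
        assert p_distance(a, b) == expected

    def test_gap_gap_columns_ignored(self):
        assert p_distance("A--T", "A--A", gap_as_difference=True) == 0.5

    def test_gap_base_ignored_when_configured(self):
        assert p_distance("A-GT", "AAGT", gap_as_difference=False) == 0.0

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            p_distance("AC", "ACG")


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        dm = DistanceMatrix(["a", "b", "c"], np.array([[0, 4, 6], [4, 0, 8], [6, 8, 0]], float))
        t = neighbor_joining(dm)
        lengths = {n.name: n.length for n in t.root.children}
        assert lengths == {"a": 1.0, "b": 3.0, "c": 5.0}

    def test_four_taxon_additive_matrix_recovered_exactly(self):
        # tree ((a:2,b:3):1,(c:4,d:5))
        D = np.array(
            [[0, 5, 7, 8], [5, 0, 8, 9], [7, 8, 0, 9], [8, 9, 9, 0]], float
        )
        t = neighbor_joining(DistanceMatrix(list("abcd"), D))
        assert t.bipartitions() == {frozenset({"c", "d"})}
        lengths = {}

        def rec(n):
            for c in n.children:
                if c.is_leaf:
                    lengths[c.name] = c.length
                rec(c)

        rec(t.root)
        assert lengths == {"a": 2.0, "b": 3.0, "c": 4.0, "d": 5.0}

    def test_identical_sequences_give_zero_branch_lengths(self):
        dm = DistanceMatrix(list("abcd"), np.zeros((4, 4)))
        t = neighbor_joining(dm)

        def rec(n):
            for c in n.children:
                assert c.length == 0.0
                rec(c)

        rec(t.root)

    def test_additive_recovery_up_to_twelve_taxa(self):
        rng = np.random.default_rng(42)
        for _ in range(15):
            n = int(rng.integers(4, 13))
            labels, D, want = _random_additive(n, rng)
            t = neighbor_joining(DistanceMatrix(labels, D))
            assert t.bipartitions() == want

    def test_agrees_with_independent_nj_implementation(self):
        skbio = pytest.importorskip("skbio")
        from skbio.tree import nj as sknj

        rng = np.random.default_rng(7)
        for _ in range(5):
            n = int(rng.integers(5, 10))
            labels, D, _ = _random_additive(n, rng)
            mine = neighbor_joining(DistanceMatrix(labels, D))
            sk = sknj(skbio.DistanceMatrix(D, ids=labels))
            allset = frozenset(labels)
            ref = min(labels)
            skbips = set()
            for node in sk.non_tips():
                side = frozenset(t.name for t in node.tips())
                if 2 <= len(side) <= n - 2:
                    skbips.add(side if ref not in side else allset - side)
            assert mine.bipartitions() == skbips

    def test_bipartitions_invariant_under_label_permutation(self):
        rng = np.random.default_rng(3)
        labels, D, _ = _random_additive(8, rng)
        t1 = neighbor_joining(DistanceMatrix(labels, D))
        perm = rng.permutation(8)
        labels2 = [labels[i] for i in perm]
        D2 = D[np.ix_(perm, perm)]
        t2 = neighbor_joining(DistanceMatrix(labels2, D2))
        assert t1.bipartitions() == t2.bipartitions()

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix(["a", "b"], np.zeros((2, 2))))

    def test_invalid_matrices_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], np.array([[0, 1], [2, 0]], float))
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], np.array([[1, 1], [1, 0]], float))


class TestBootstrap:
    def _two_clade_alignment(self):
        a = "A" * 30 + "C" * 30
        b = "A" * 30 + "C" * 29 + "T"
        c = "G" * 30 + "T" * 29 + "C"
        d = "G" * 30 + "T" * 30
        return [("a", a), ("b", b), ("c", c), ("d", d)]

    def test_forced_bipartition_has_full_support(self):
        t = bootstrap_support(self._two_clade_alignment(), replicates=100, seed=0)
        supports = [n.support for n in t.internal_nodes() if n.support is not None]
        assert supports and all(s == 100.0 for s in supports)

    def test_zero_replicates_gives_no_annotations(self):
        t = bootstrap_support(self._two_clade_alignment(), replicates=0, seed=0)
        assert all(n.support is None for n in t.internal_nodes())

    def test_same_seed_reproduces_supports(self):
        rng = np.random.default_rng(11)
        aln = [
            (f"s{i}", "".join(rng.choice(list("ACGT"), size=60))) for i in range(6)
        ]
        t1 = bootstrap_support(aln, replicates=50, seed=4)
        t2 = bootstrap_support(aln, replicates=50, seed=4)
        s1 = sorted(n.support for n in t1.internal_nodes() if n.support is not None)
        s2 = sorted(n.support for n in t2.internal_nodes() if n.support is not None)
        assert s1 == s2

    def test_newick_roundtrips_through_skbio(self, tmp_path):
        skbio = pytest.importorskip("skbio")
        t = bootstrap_support(self._two_clade_alignment(), replicates=10, seed=0)
        p = tmp_path / "t.nwk"
        p.write_text(t.to_newick() + "\n")
        sk = skbio.TreeNode.read(str(p))
        assert {x.name for x in sk.tips()} == {"a", "b", "c", "d"}


class TestConcordance:
    def test_homogeneous_clades_have_purity_one(self):
        aln = [
            ("a", "A" * 30 + "C" * 30),
            ("b", "A" * 30 + "C" * 30),
            ("c", "G" * 30 + "T" * 30),
            ("d", "G" * 30 + "T" * 30),
        ]
        t = neighbor_joining(distance_matrix(aln))
        _, overall = clade_motif_concordance(
            t, {"a": "ITR-1", "b": "ITR-1", "c": "ITR-2", "d": "ITR-2"}
        )
        assert overall == 1.0

    def test_two_leaf_tree_with_two_motifs_has_half_purity(self):
        leaf_a, leaf_b = TreeNode(name="a"), TreeNode(name="b")
        t = Tree(TreeNode(children=[leaf_a, leaf_b]))
        _, overall = clade_motif_concordance(t, {"a": "m1", "b": "m2"})
        assert overall == 0.5

    def test_random_labels_approach_reciprocal_motif_count(self):
        # Monte-Carlo null: purity of a large clade with k uniform labels ~ 1/k
        rng = np.random.default_rng(0)
        k = 4
        n = 40
        aln = [(f"s{i}", "".join(rng.choice(list("ACGT"), size=200))) for i in range(n)]
        t = neighbor_joining(distance_matrix(aln))
        purities = []
        for _ in range(20):
            mapping = {f"s{i}": f"m{rng.integers(0, k)}" for i in range(n)}
            per_clade, _ = clade_motif_concordance(t, mapping)
            purities.extend(p for clade, p in per_clade if len(clade) >= 10)
        assert purities
        mean = float(np.mean(purities))
        assert 1 / k <= mean < 1 / k + 0.2

    def test_missing_motif_label_rejected(self):
        leaf_a, leaf_b = TreeNode(name="a"), TreeNode(name="b")
        t = Tree(TreeNode(children=[leaf_a, leaf_b]))
        with pytest.raises(ValueError, match="no motif label"):
            clade_motif_concordance(t, {"a": "m1"})


class TestIO:
    def test_alignment_reader_validates_lengths(self, tmp_path):
        p = tmp_path / "aln.fasta"
        p.write_text(">a\nACGT\n>b\nACG\n")
        with pytest.raises(ValueError, match="unequal"):
            read_alignment(p)

    def test_phylip_square_output(self, tmp_path):
        dm = DistanceMatrix(["a", "b", "c"], np.array([[0, 1, 2], [1, 0, 3], [2, 3, 0]], float))
        p = tmp_path / "d.phy"
        write_phylip(dm, p)
        lines = p.read_text().splitlines()
        assert lines[0].strip() == "3"
        assert len(lines) == 4
        assert lines[1].startswith("a")
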