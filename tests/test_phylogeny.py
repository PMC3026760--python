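"""p-distances, neighbor joining, bootstrap supports and newick IO."""

import numpy as np
import pytest

from virna.errors import ConfigError, DataError, FormatError, InputError
from virna.phylogeny import (
    DistanceMatrix,
    Msa,
    PhyloTree,
    TreeNode,
    bootstrap_support,
    neighbor_joining,
    p_distance_matrix,
    read_newick,
    write_newick,
)


def random_additive_tree(n_leaves: int, rng: np.random.Generator) -> PhyloTree:
    """Random binary topology with strictly positive branch lengths."""
    nodes = [
        TreeNode(label=f"t{i}", length=float(rng.uniform(0.05, 1.0)))
        for i in range(n_leaves)
    ]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        joined = TreeNode(
            length=float(rng.uniform(0.05, 1.0)), children=[nodes[i], nodes[j]]
        )
        nodes = [x for k, x in enumerate(nodes) if k not in (i, j)] + [joined]
    return PhyloTree(root=TreeNode(children=nodes))


def tree_to_matrix(tree: PhyloTree) -> DistanceMatrix:
    labels = tuple(sorted(tree.taxa))
    pl = tree.path_lengths()
    n = len(labels)
    m = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            m[a, b] = m[b, a] = pl[(labels[a], labels[b])]
    return DistanceMatrix(labels=labels, values=m)


class TestPDistance:
    def test_identical_rows_zero(self):
        msa = Msa(labels=("a", "b", "c"), rows=("ARND", "ARND", "ARNE"))
        d = p_distance_matrix(msa)
        assert d.values[0, 1] == 0.0
        assert d.values[0, 2] == pytest.approx(0.25)

    def test_half_mismatch(self):
        msa = Msa(labels=("a", "b", "c"), rows=("AR", "AK", "AR"))
        assert p_distance_matrix(msa).values[0, 1] == pytest.approx(0.5)

    def test_pairwise_gap_deletion_against_counting_oracle(self, rng):
        alphabet = list("ACDEFGHIKLMNPQRSTVWY-")
        rows = tuple(
            "".join(rng.choice(alphabet, size=100)) for _ in range(6)
        )
        msa = Msa(labels=tuple("abcdef"), rows=rows)
        d = p_distance_matrix(msa)
        for i in range(6):
            for j in range(i + 1, 6):
                comp = [
                    (x, y)
                    for x, y in zip(rows[i], rows[j])
                    if x != "-" and y != "-"
                ]
                expected = sum(1 for x, y in comp if x != y) / len(comp)
                assert d.values[i, j] == pytest.approx(expected)

    def test_no_comparable_columns_is_data_error(self):
        msa = Msa(labels=("a", "b", "c"), rows=("A-", "-A", "AA"))
        with pytest.raises(DataError, match="'a'"):
            p_distance_matrix(msa)


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        d = DistanceMatrix(
            labels=("A", "B", "C"),
            values=np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], float),
        )
        tree = neighbor_joining(d)
        assert write_newick(tree) == "(A:1,B:1,C:3);"

    @pytest.mark.parametrize("trial", range(20))
    def test_recovers_random_additive_trees(self, trial):
        rng = np.random.default_rng(900 + trial)
        true = random_additive_tree(int(rng.integers(4, 13)), rng)
        rec = neighbor_joining(tree_to_matrix(true))
        assert rec.bipartitions() == true.bipartitions()
        true_pl, rec_pl = true.path_lengths(), rec.path_lengths()
        for pair, dist in true_pl.items():
            assert rec_pl[pair] == pytest.approx(dist, abs=1e-9)

    def test_branch_lengths_never_negative(self, rng):
        for _ in range(20):
            n = int(rng.integers(4, 9))
            m = rng.uniform(0.1, 1.0, size=(n, n))
            m = (m + m.T) / 2
            np.fill_diagonal(m, 0)
            tree = neighbor_joining(
                DistanceMatrix(labels=tuple(f"x{i}" for i in range(n)), values=m)
            )

            def check(node):
                if node.length is not None:
                    assert node.length >= 0
                for c in node.children:
                    check(c)

            check(tree.root)

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(DataError):
            DistanceMatrix(
                labels=("a", "b", "c"),
                values=np.array([[0, 1, 2], [9, 0, 2], [2, 2, 0]], float),
            )


class TestBootstrap:
    def _msa(self):
        rng = np.random.default_rng(12)
        alphabet = list("ACDEFGHIKLMNPQRSTVWY")
        base = "".join(rng.choice(alphabet, size=80))
        far = "".join(rng.choice(alphabet, size=80))

        def mutate(s, k):
            s = list(s)
            for p in rng.choice(80, size=k, replace=False):
                s[p] = alphabet[int(rng.integers(20))]
            return "".join(s)

        return Msa(
            labels=("A", "B", "C", "D", "E"),
            rows=(base, base, far, mutate(far, 6), mutate(far, 12)),
        )

    def test_identical_pair_has_full_support(self):
        tree = bootstrap_support(self._msa(), n_reps=100, seed=5)
        supports = {
            frozenset(bp): node.support for bp, node in tree.internal_edges()
        }
        # A,B identical: the bipartition separating them from C,D,E is
        # canonicalized as {C,D,E} (side without the first taxon)
        assert supports[frozenset({"C", "D", "E"})] == 1.0

    def test_same_seed_reproducible_and_topology_seed_free(self):
        msa = self._msa()
        t1 = bootstrap_support(msa, n_reps=50, seed=9)
        t2 = bootstrap_support(msa, n_reps=50, seed=9)
        assert write_newick(t1) == write_newick(t2)
        t3 = bootstrap_support(msa, n_reps=50, seed=10)
        assert t1.bipartitions() == t3.bipartitions()
        for _, node in t1.internal_edges():
            assert 0.0 <= node.support <= 1.0

    def test_supports_match_independent_bipartition_count(self):
        """Recompute supports with dendropy's bipartition machinery."""
        import dendropy

        msa = self._msa()
        n_reps, seed = 40, 3
        tree = bootstrap_support(msa, n_reps=n_reps, seed=seed)

        # independently regenerate the same replicate stream
        rng = np.random.default_rng(seed)
        taxa = dendropy.TaxonNamespace()
        rep_trees = []
        for _ in range(n_reps):
            rep = neighbor_joining(p_distance_matrix(msa.resample_columns(rng)))
            rep_trees.append(
                dendropy.Tree.get(data=write_newick(rep), schema="newick",
                                  taxon_namespace=taxa)
            )
        for t in rep_trees:
            t.encode_bipartitions()

        full = dendropy.Tree.get(
            data=write_newick(neighbor_joining(p_distance_matrix(msa))),
            schema="newick", taxon_namespace=taxa,
        )
        full.encode_bipartitions()
        my_supports = {
            bp: node.support for bp, node in tree.internal_edges()
        }
        for edge in full.preorder_edge_iter():
            if edge.head_node.is_leaf() or edge.head_node is full.seed_node:
                continue
            split = edge.bipartition.split_bitmask
            count = sum(
                1 for t in rep_trees
                if split in {e.bipartition.split_bitmask
                             for e in t.preorder_edge_iter()}
            )
            side = frozenset(
                lf.taxon.label for lf in edge.head_node.leaf_iter()
            )
            all_taxa = frozenset(msa.labels)
            canon = side if min(all_taxa) not in side else all_taxa - side
            assert my_supports[canon] == pytest.approx(count / n_reps)

    def test_zero_replicates_rejected(self):
        with pytest.raises(ConfigError):
            bootstrap_support(self._msa(), n_reps=0, seed=1)


class TestNewick:
    def test_quoting_of_metacharacters(self):
        tree = PhyloTree(
            root=TreeNode(children=[
                TreeNode(label="a b", length=1.0),
                TreeNode(label="c:d", length=2.0),
                TreeNode(label="e", length=3.0),
            ])
        )
        text = write_newick(tree)
        assert "'a b'" in text and "'c:d'" in text

    @pytest.mark.parametrize("trial", range(10))
    def test_roundtrip_preserves_topology_and_lengths(self, trial):
        rng = np.random.default_rng(40 + trial)
        tree = random_additive_tree(int(rng.integers(4, 10)), rng)
        back = read_newick(write_newick(tree))
        assert back.bipartitions() == tree.bipartitions()
        for pair, dist in tree.path_lengths().items():
            assert back.path_lengths()[pair] == pytest.approx(dist, abs=1e-9)

    def test_empty_tree_rejected(self):
        with pytest.raises(FormatError):
            write_newick(PhyloTree(root=TreeNode()))
        with pytest.raises(FormatError):
            read_newick("  ;")

    def test_divergent_sister_pair_recovered_from_alignment(self):
        """Two closely related taxa inside a distant outgroup set come
        out as sisters with high support (the analysis pattern used for
        placing two new viruses among known ones)."""
        rng = np.random.default_rng(77)
        alphabet = list("ACDEFGHIKLMNPQRSTVWY")
        anc = rng.choice(alphabet, size=120)

        def descend(src, k):
            s = src.copy()
            for p in rng.choice(len(s), size=k, replace=False):
                s[p] = alphabet[int(rng.integers(20))]
            return s

        novel = descend(anc, 70)
        rows = {
            "orsay_like": descend(novel, 15),
            "santeuil_like": descend(novel, 20),
            "noda1": descend(anc, 12),
            "noda2": descend(anc, 18),
            "noda3": descend(anc, 25),
            "noda4": descend(anc, 22),
        }
        msa = Msa(
            labels=tuple(rows), rows=tuple("".join(r) for r in rows.values())
        )
        tree = bootstrap_support(msa, n_reps=100, seed=2)
        sisters = frozenset({"orsay_like", "santeuil_like"})
        all_taxa = frozenset(msa.labels)
        canon = (
            sisters if min(all_taxa) not in sisters else all_taxa - sisters
        )
        supports = {bp: n.support for bp, n in tree.internal_edges()}
        assert canon in tree.bipartitions()
        assert supports[canon] >= 0.8
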