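import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from famkit import phylo
from famkit.errors import FamkitError, SaturationError
from famkit.model import GeneRecord
from famkit.phylo import Alignment, DistanceMatrix, SupportedTree, TreeNode


def random_tree(rng, n_taxa, min_bl=0.05, max_bl=0.5):
    """Random unrooted binary topology with uniform branch lengths."""
    nodes = [TreeNode(name=f"t{i}") for i in range(n_taxa)]
    bl = lambda: float(rng.uniform(min_bl, max_bl))
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        merged = TreeNode(children=[(nodes[i], bl()), (nodes[j], bl())])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    root = TreeNode(children=[(n, bl()) for n in nodes])
    taxa = sorted(root.leaves())
    return SupportedTree(root=root, taxa=taxa)


def path_distance_matrix(tree):
    """Additive matrix from leaf-to-leaf path lengths (independent of NJ)."""
    leaf_paths = {}

    def collect(node, path):
        if node.is_leaf:
            leaf_paths[node.name] = path
            return
        for k, (child, length) in enumerate(node.children):
            collect(child, path + [(id(node), k, length)])

    collect(tree.root, [])
    taxa = sorted(leaf_paths)
    n = len(taxa)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        pa, pb = leaf_paths[taxa[i]], leaf_paths[taxa[j]]
        shared = 0
        for ea, eb in zip(pa, pb):
            if ea[:2] == eb[:2]:
                shared += 1
            else:
                break
        total = sum(l for _, _, l in pa[shared:]) + sum(l for _, _, l in pb[shared:])
        d[i, j] = d[j, i] = total
    return DistanceMatrix(taxa=taxa, d=d)


class TestPDistance:
    def test_identical_rows(self):
        aln = Alignment(taxa=["a", "b"], rows=["ACDE", "ACDE"])
        assert phylo.p_distance(aln, "a", "b") == 0.0

    def test_quarter_difference(self):
        aln = Alignment(taxa=["a", "b"], rows=["AAAA", "AAAT"])
        assert phylo.p_distance(aln, "a", "b") == 0.25

    def test_pairwise_deletion_ignores_gapped_columns(self):
        aln = Alignment(taxa=["a", "b"], rows=["AAA-", "AAAT"])
        assert phylo.p_distance(aln, "a", "b") == 0.0

    def test_no_comparable_columns_errors(self):
        aln = Alignment(taxa=["a", "b"], rows=["A--", "-TT"])
        with pytest.raises(FamkitError):
            phylo.p_distance(aln, "a", "b")


class TestPoissonCorrection:
    @pytest.mark.parametrize("p,d", [(0.0, 0.0), (0.5, 0.6931), (0.1, 0.10536)])
    def test_closed_form(self, p, d):
        assert phylo.poisson_correct(p) == pytest.approx(d, abs=1e-4)

    def test_saturation_maps_to_inf(self):
        assert phylo.poisson_correct(1.0) == math.inf

    @settings(max_examples=60, deadline=None)
    @given(st.floats(min_value=0.0, max_value=0.99))
    def test_monotone_and_at_least_identity(self, p):
        d = phylo.poisson_correct(p)
        assert d >= p
        assert phylo.poisson_correct(min(p + 0.005, 0.995)) >= d


def quartet_oracle(dm):
    """Brute-force over the 3 quartet topologies: by the four-point
    condition, the correct pairing {i,j}|{k,l} of an additive matrix
    minimizes d(i,j) + d(k,l)."""
    a, b, c, d = range(4)
    pairings = [((a, b), (c, d)), ((a, c), (b, d)), ((a, d), (b, c))]
    best, best_sum = None, math.inf
    for (i, j), (k, l) in pairings:
        pair_sum = dm.d[i, j] + dm.d[k, l]
        if pair_sum < best_sum:
            best_sum = pair_sum
            best = frozenset({dm.taxa[i], dm.taxa[j]})
    return best


class TestNeighborJoining:
    def test_three_taxa_three_point_formulas(self):
        d = np.array([[0, 3.0, 4.0], [3.0, 0, 5.0], [4.0, 5.0, 0]])
        tree = phylo.nj_tree(DistanceMatrix(taxa=["a", "b", "c"], d=d))
        lengths = {child.name: l for child, l in tree.root.children}
        assert lengths["a"] == pytest.approx(1.0)
        assert lengths["b"] == pytest.approx(2.0)
        assert lengths["c"] == pytest.approx(3.0)

    def test_four_taxon_additive_matrix_vs_brute_force(self, rng):
        for _ in range(20):
            tree = random_tree(rng, 4)
            dm = path_distance_matrix(tree)
            nj = phylo.nj_tree(dm)
            cherry_sides = {frozenset(side) for side in nj.bipartitions()}
            oracle = quartet_oracle(dm)
            full = frozenset(dm.taxa)
            assert oracle in cherry_sides or (full - oracle) in cherry_sides

    def test_ultrametric_five_taxon_recovery(self, rng):
        tree = random_tree(rng, 5)
        dm = path_distance_matrix(tree)
        nj = phylo.nj_tree(dm)
        assert set(nj.bipartitions()) == set(tree.bipartitions())
        # nonnegative branch lengths throughout
        def check(node):
            for child, length in node.children:
                assert length >= 0
                check(child)
        check(nj.root)

    def test_additive_recovery_batch(self, rng):
        for _ in range(30):
            n = int(rng.integers(4, 9))
            tree = random_tree(rng, n)
            dm = path_distance_matrix(tree)
            assert set(phylo.nj_tree(dm).bipartitions()) == set(tree.bipartitions())

    def test_taxon_relabeling_invariance(self, rng):
        tree = random_tree(rng, 6)
        dm = path_distance_matrix(tree)
        splits = set(phylo.nj_tree(dm).bipartitions())
        perm = rng.permutation(len(dm.taxa))
        dm2 = DistanceMatrix(
            taxa=[dm.taxa[i] for i in perm], d=dm.d[np.ix_(perm, perm)]
        )
        assert set(phylo.nj_tree(dm2).bipartitions()) == splits

    def test_infinite_entry_advises_saturation(self):
        d = np.array([[0, 1.0, math.inf], [1.0, 0, 1.0], [math.inf, 1.0, 0]])
        with pytest.raises(SaturationError, match="saturation"):
            phylo.nj_tree(DistanceMatrix(taxa=["a", "b", "c"], d=d))

    def test_fewer_than_three_taxa_rejected(self):
        d = np.array([[0, 1.0], [1.0, 0]])
        with pytest.raises(FamkitError):
            phylo.nj_tree(DistanceMatrix(taxa=["a", "b"], d=d))


def two_cluster_alignment(rng, per_column_noise=0.0):
    """Six taxa in two well-separated triplets; long internal edge."""
    from famkit.simulate import gen_alignment_on_tree

    t = TreeNode
    left = t(children=[(t(children=[(t(name="a1"), 0.02), (t(name="a2"), 0.02)]), 0.02), (t(name="a3"), 0.03)])
    right = t(children=[(t(children=[(t(name="b1"), 0.02), (t(name="b2"), 0.02)]), 0.02), (t(name="b3"), 0.03)])
    root = t(children=[(left, 0.6), (right, 0.6)])
    return gen_alignment_on_tree(root, length=500, seed=int(rng.integers(1 << 30)))


class TestBootstrap:
    def test_strong_internal_edge_support(self, rng):
        aln = two_cluster_alignment(rng)
        tree = phylo.bootstrap_supports(aln, replicates=100, seed=11)
        split = frozenset({"a1", "a2", "a3"})
        supports = {bp: node.support for bp, node in tree.bipartitions().items()}
        full = frozenset(aln.taxa)
        key = split if split in supports else full - split
        assert supports[key] >= 95

    def test_star_like_data_has_weak_supports(self):
        from famkit.simulate import gen_alignment_on_tree

        t = TreeNode
        kids = [t(name=f"s{i}") for i in range(6)]
        # near-star: tiny internal structure, long terminal branches
        inner1 = t(children=[(kids[0], 0.5), (kids[1], 0.5)])
        inner2 = t(children=[(inner1, 1e-4), (kids[2], 0.5)])
        inner3 = t(children=[(kids[3], 0.5), (kids[4], 0.5)])
        root = t(children=[(inner2, 1e-4), (inner3, 1e-4), (kids[5], 0.5)])
        aln = gen_alignment_on_tree(root, length=300, seed=5)
        tree = phylo.bootstrap_supports(aln, replicates=100, seed=6)
        supports = [n.support for n in tree.bipartitions().values()]
        assert min(supports) < 90

    def test_same_seed_reproducible(self, rng):
        aln = two_cluster_alignment(rng)
        t1 = phylo.bootstrap_supports(aln, replicates=50, seed=42)
        t2 = phylo.bootstrap_supports(aln, replicates=50, seed=42)
        s1 = {bp: n.support for bp, n in t1.bipartitions().items()}
        s2 = {bp: n.support for bp, n in t2.bipartitions().items()}
        assert s1 == s2

    def test_newick_contains_supports(self, rng):
        aln = two_cluster_alignment(rng)
        tree = phylo.bootstrap_supports(aln, replicates=20, seed=1)
        newick = tree.newick()
        assert newick.endswith(";") and "(" in newick


class TestSisterPairs:
    def build_tree(self, support):
        t = TreeNode
        cherry = t(children=[(t(name="x"), 0.1), (t(name="y"), 0.1)], support=support)
        root = t(children=[(cherry, 0.2), (t(name="z"), 0.1), (t(name="w"), 0.1)])
        return SupportedTree(root=root, taxa=["x", "y", "z", "w"])

    def test_supported_cherry_reported(self):
        # in the unrooted 4-taxon tree xy|zw both sides of the internal
        # edge are cherries
        assert phylo.sister_pairs(self.build_tree(90)) == [("w", "z"), ("x", "y")]

    def test_threshold_is_strict(self):
        assert phylo.sister_pairs(self.build_tree(65)) == []

    def test_caterpillar_without_cherries(self):
        t = TreeNode
        inner = t(children=[(t(name="a"), 0.1), (t(children=[(t(name="b"), 0.1), (t(name="c"), 0.1)], support=10), 0.1)], support=10)
        root = t(children=[(inner, 0.1), (t(name="d"), 0.1), (t(name="e"), 0.1)])
        tree = SupportedTree(root=root, taxa=["a", "b", "c", "d", "e"])
        assert phylo.sister_pairs(tree, threshold=65) == []


def gene(name, exons):
    return GeneRecord(
        name=name, locus_id="l", protein_id="p", chromosome="Ca1", start=1, end=2,
        strand="+", protein_length=10, pi=7.0, mol_wt=1.0, exon_count=exons, isoform_count=1,
    )


class TestExonGroupContrast:
    def test_identical_groups(self):
        records = [gene(f"a{i}", x) for i, x in enumerate([2, 3, 4])]
        records += [gene(f"b{i}", x) for i, x in enumerate([2, 3, 4])]
        membership = {r.name: ("I" if r.name.startswith("a") else "II") for r in records}
        result = phylo.exon_group_contrast(records, membership)
        assert result.t_statistic == pytest.approx(0.0)
        assert result.p_value == pytest.approx(1.0)

    def test_separated_groups_welch(self):
        records = [gene("a1", 2), gene("a2", 3), gene("a3", 4),
                   gene("b1", 14), gene("b2", 15), gene("b3", 16)]
        membership = {"a1": "I", "a2": "I", "a3": "I", "b1": "II", "b2": "II", "b3": "II"}
        result = phylo.exon_group_contrast(records, membership)
        assert (result.mean_a, result.mean_b) == (3.0, 15.0)
        # closed-form Welch: equal variances 1, t = -12 / sqrt(2/3)
        assert abs(result.t_statistic) == pytest.approx(12 / math.sqrt(2 / 3), rel=1e-6)
        assert result.p_value < 0.01

    def test_singleton_group_withholds_test(self):
        records = [gene("a1", 2), gene("b1", 14), gene("b2", 15)]
        membership = {"a1": "I", "b1": "II", "b2": "II"}
        result = phylo.exon_group_contrast(records, membership)
        assert result.mean_a == 2.0 and result.t_statistic is None
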