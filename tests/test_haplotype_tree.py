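import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from haplocn.haplotype_freq import pairwise_tables
from haplocn.haplotype_tree import (
    AllelicState,
    Branch,
    DecayParams,
    HaplotypeTree,
    TreeNode,
    allowed_transition,
    allowed_transitions,
    branch_aberrant,
    build_binary_tree,
    decay,
    merge_level,
    merge_nodes,
    merge_threshold,
    similarity_score,
    six_state_matrix,
)
from haplocn.signal_io import GenotypeMatrix, SnpMap


class TestAllowedTransitions:
    def test_exactly_28_by_enumeration(self):
        # independent oracle: name the gain/loss states and forbid mixing
        gains = {AllelicState.A_PLUS, AllelicState.B_PLUS}
        losses = {AllelicState.A_MINUS, AllelicState.B_MINUS}
        expected = {
            (x, y)
            for x in AllelicState
            for y in AllelicState
            if not ((x in gains and y in losses) or (x in losses and y in gains))
        }
        assert len(expected) == 28
        assert set(allowed_transitions()) == {(int(x), int(y)) for x, y in expected}

    def test_normal_states_transit_everywhere(self):
        for x in (AllelicState.A, AllelicState.B):
            assert all(allowed_transition(x, y) for y in range(6))


def _leaf_pair(locus, ca):
    """An 'A'-labelled node at `locus` whose two children carry C = (ca, 1-ca)."""
    node = TreeNode(locus, "A", 100.0)
    for lab, c in (("A", ca), ("B", 1 - ca)):
        node.children.append(Branch(TreeNode(locus + 1, lab, 100.0 * c), c, c))
    return node


class TestSimilarityAndThreshold:
    def test_worked_example_score(self):
        u = _leaf_pair(2, 0.976)
        v = _leaf_pair(2, 0.985)  # C = (0.985, 0.015)
        # parallel descendants differ by |0.976-0.985|=0.009 on one branch,
        # |0.024-0.015|=0.009 on the other
        v.children[0].c = 0.976
        v.children[1].c = 0.015
        assert similarity_score(u, v) == pytest.approx(0.009)

    def test_identical_nodes_score_zero(self):
        assert similarity_score(_leaf_pair(1, 0.7), _leaf_pair(1, 0.7)) == 0.0

    def test_opposite_nodes_score_one(self):
        assert similarity_score(_leaf_pair(1, 1.0), _leaf_pair(1, 0.0)) == 1.0

    def test_mismatched_descendants_rejected(self):
        u = _leaf_pair(1, 0.5)
        v = TreeNode(1, "A", 10.0)
        v.children.append(Branch(TreeNode(2, "A", 10.0), 1.0, 1.0))
        with pytest.raises(ValueError, match="descendant"):
            similarity_score(u, v)

    def test_threshold_values(self):
        assert merge_threshold(100, 100) == pytest.approx(np.sqrt(0.02))
        assert merge_threshold(1, 1) == pytest.approx(np.sqrt(2))
        assert merge_threshold(1e12, 1e12) < 1e-5  # ->0: only identical nodes merge

    def test_zero_count_threshold_infinite_with_warning(self):
        with pytest.warns(UserWarning):
            assert merge_threshold(0, 5) == np.inf


def _two_node_tree(mu, cu, mv, cv):
    root = TreeNode(0, "", mu + mv)
    u, v = _leaf_pair(1, cu), _leaf_pair(1, cv)
    u.m, v.m = mu, mv
    tot = mu + mv
    root.children = [Branch(u, mu / tot, mu / tot), Branch(v, mv / tot, mv / tot)]
    leaves = u.children[0].child, u.children[1].child
    tree = HaplotypeTree([[root], [u, v], [leaves[0], leaves[1], v.children[0].child, v.children[1].child]], tot)
    return tree, u, v


class TestMerging:
    def test_weighted_average_of_conditionals(self):
        tree, u, v = _two_node_tree(100, 0.976, 100, 0.976)
        v.children[1].c = 0.015
        v.children[0].c = 0.976
        # renormalize v so the example matches the printed conditionals
        merged = merge_nodes(tree, u, v)
        cm = {br.child.label: br.c for br in merged.children}
        assert cm["B"] == pytest.approx(0.0195)
        assert merged.m == 200

    def test_zero_weight_node_keeps_other_distribution(self):
        tree, u, v = _two_node_tree(0, 0.9, 50, 0.3)
        merged = merge_nodes(tree, u, v)
        assert {br.child.label: br.c for br in merged.children}["A"] == pytest.approx(0.3)

    def test_identical_merge_idempotent_distribution(self):
        tree, u, v = _two_node_tree(40, 0.7, 60, 0.7)
        merged = merge_nodes(tree, u, v)
        assert {br.child.label: br.c for br in merged.children}["A"] == pytest.approx(0.7)
        assert merged.m == 100

    def test_merge_level_greedy_smallest_first(self):
        # three A-context nodes with pairwise scores 0.001, 0.002, 0.003;
        # every pair is below threshold, so all collapse into one node whose
        # C is the count-weighted average — verified by re-simulating the
        # greedy procedure by hand
        root = TreeNode(0, "", 300.0)
        nodes = [_leaf_pair(1, c) for c in (0.500, 0.501, 0.503)]
        for nd in nodes:
            nd.m = 100.0
            root.children.append(Branch(nd, 1 / 3, 1 / 3))
        leaves = [br.child for nd in nodes for br in nd.children]
        tree = HaplotypeTree([[root], nodes, leaves], 300.0)
        merge_level(tree, 1)
        assert tree.level_width(1) == 1
        final = tree.levels[1][0]
        # hand-trace: (0.500,0.501) merge first -> 0.5005 (M=200); then with
        # 0.503 -> (200*0.5005 + 100*0.503)/300
        expected = (200 * 0.5005 + 100 * 0.503) / 300
        assert {br.child.label: br.c for br in final.children}["A"] == pytest.approx(expected)

    def test_far_apart_nodes_not_merged(self):
        tree, u, v = _two_node_tree(10000, 0.9, 10000, 0.1)
        merge_level(tree, 1)
        assert tree.level_width(1) == 2

    def test_single_node_level_unchanged(self):
        tree, u, v = _two_node_tree(100, 0.9, 100, 0.2)
        tree.levels[1] = [u]
        merge_level(tree, 1)
        assert tree.levels[1] == [u]

    def test_merged_joint_equals_count_weighted_mixture(self):
        # invariant on a 3-locus instance: the merged tree's implied
        # two-locus joint equals the count-weighted mixture of the originals
        tree, u, v = _two_node_tree(80, 0.9, 40, 0.88)
        pre = tree.marginal_c(1).copy()
        merge_nodes(tree, u, v)
        np.testing.assert_allclose(tree.marginal_c(1), pre, atol=1e-12)


class TestBuildBinaryTree:
    def _small(self):
        rng = np.random.default_rng(2)
        genos = GenotypeMatrix(rng.integers(1, 4, size=(4, 30)))
        tables = pairwise_tables(genos)
        return genos, tables, build_binary_tree(genos, tables)

    def test_level_structure_and_counts(self):
        genos, tables, tree = self._small()
        assert tree.n_loci == 4
        for j in range(1, 5):
            assert tree.level_width(j) == 2
        level1 = tree.levels[1]
        assert sum(nd.m for nd in level1) == pytest.approx(2 * 30)

    def test_branch_c_and_j_from_tables(self):
        genos, tables, tree = self._small()
        for j in range(1, 4):
            np.testing.assert_allclose(tree.marginal_c(j), tables[j - 1].c, atol=1e-12)
        # J on a branch equals marginal * C (the haplotype-set joint)
        nodeA = next(nd for nd in tree.levels[1] if nd.label == "A")
        fA = tree.level_marginals(1)[0]
        for br in nodeA.children:
            assert br.j == pytest.approx(fA * br.c)

    def test_uniform_two_locus_tree(self):
        genos = GenotypeMatrix(np.array([[2] * 8, [2] * 8]))
        tables = pairwise_tables(genos)
        tree = build_binary_tree(genos, tables)
        assert tree.level_width(1) == 2
        for nd in tree.levels[1]:
            assert len(nd.children) == 2
            for br in nd.children:
                assert br.c == pytest.approx(0.5)


class TestDecayAndBranching:
    def test_decay_values(self):
        assert decay(0.0, 1e5) == 1.0
        assert decay(1e5, 1e5) == pytest.approx(np.exp(-1))
        d = np.array([decay(x, 1e5) for x in (0, 10, 1e4, 1e6)])
        assert (np.diff(d) < 0).all()

    def test_gain_state_redistribution_example(self):
        # from A+ with C[A->A]=1 and rho_var=0.6: stay 0.6, return 0.4, loss 0
        c = np.array([[1.0, 0.0], [0.5, 0.5]])
        d = -1e5 * np.log(0.6)  # distance giving rho_var = 0.6
        t = six_state_matrix(c, d, DecayParams(d_norm=1e300, d_var=1e5))
        ap = int(AllelicState.A_PLUS)
        assert t[ap, ap] == pytest.approx(0.6)
        assert t[ap, int(AllelicState.A)] == pytest.approx(0.4)
        assert t[ap, int(AllelicState.A_MINUS)] == 0.0

    def test_zero_distance_kills_aberrant_mass_from_normal(self):
        c = np.full((2, 2), 0.5)
        t = six_state_matrix(c, 0.0, DecayParams())
        a = int(AllelicState.A)
        for s in (AllelicState.A_MINUS, AllelicState.A_PLUS, AllelicState.B_MINUS, AllelicState.B_PLUS):
            assert t[a, int(s)] == 0.0

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(
        caa=st.floats(0.0, 1.0),
        cba=st.floats(0.0, 1.0),
        d=st.floats(0.0, 1e7),
    )
    def test_rows_sum_to_one_and_forbidden_zero(self, caa, cba, d):
        c = np.array([[caa, 1 - caa], [cba, 1 - cba]])
        t = six_state_matrix(c, d, DecayParams())
        np.testing.assert_allclose(t.sum(axis=1), 1.0, atol=1e-12)
        for x in range(6):
            for y in range(6):
                if not allowed_transition(x, y):
                    assert t[x, y] == 0.0

    def test_branched_tree_rows_sum_after_random_build(self):
        rng = np.random.default_rng(9)
        genos = GenotypeMatrix(rng.integers(1, 4, size=(20, 25)))
        tables = pairwise_tables(genos)
        tree = build_binary_tree(genos, tables)
        snps = SnpMap(
            np.array([f"s{i}" for i in range(20)]),
            np.array(["1"] * 20),
            1 + np.cumsum(rng.integers(500, 5000, size=20)),
        )
        bt = branch_aberrant(tree, snps, DecayParams())
        np.testing.assert_allclose(np.exp(bt.log_trans).sum(axis=2), 1.0, atol=1e-12)
        assert np.exp(bt.log_init).sum() == pytest.approx(1.0)

    def test_branching_preserves_allele_level_chain(self):
        # collapsing the six-state matrix back to alleles recovers C exactly
        rng = np.random.default_rng(4)
        c = rng.dirichlet((2, 2), size=2)
        t = six_state_matrix(c, 12345.0, DecayParams())
        collapsed = np.empty((2, 2))
        for x, row in ((0, 1), (1, 4)):  # from the normal states A, B
            collapsed[x, 0] = t[row, 0:3].sum()
            collapsed[x, 1] = t[row, 3:6].sum()
        np.testing.assert_allclose(collapsed, c, atol=1e-12)
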