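import numpy as np
import pytest

import neurosim as ns
from neurosim.solvers import SingularSystemError, stone_residual
from conftest import random_physical_system


def serial_reduce_oracle(sys_):
    """Plain serial triangularization, written independently in the test."""
    d = sys_.d.copy()
    rhs = sys_.rhs.copy()
    for i in range(sys_.n - 1, 0, -1):
        f = sys_.a[i] / d[i]
        p = sys_.parent[i]
        d[p] -= f * sys_.b_sup[i]
        rhs[p] -= f * rhs[i]
    return d, rhs


def identity_system(rhs):
    n = len(rhs)
    return ns.HinesSystem(d=np.ones(n), a=np.zeros(n), b_sup=np.zeros(n),
                          rhs=np.asarray(rhs, float),
                          parent=np.arange(-1, n - 1))


class TestSerialSolve:
    def test_identity_system(self):
        x = ns.serial_solve(identity_system([3.0, -1.0, 7.0]))
        assert np.allclose(x, [3.0, -1.0, 7.0])

    def test_symmetric_two_segment_chain(self):
        sys_ = ns.HinesSystem(d=np.array([2.0, 2.0]), a=np.array([0.0, -1.0]),
                              b_sup=np.array([0.0, -1.0]), rhs=np.ones(2),
                              parent=np.array([-1, 0]))
        assert np.allclose(ns.serial_solve(sys_), [1.0, 1.0])

    def test_input_system_is_not_modified(self):
        _, sys_ = random_physical_system(32, seed=5)
        before = (sys_.d.copy(), sys_.rhs.copy())
        ns.serial_solve(sys_)
        assert np.array_equal(sys_.d, before[0])
        assert np.array_equal(sys_.rhs, before[1])

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_dense_oracle_on_random_trees(self, seed):
        rng = np.random.default_rng(seed)
        _, sys_ = random_physical_system(int(rng.integers(4, 200)), seed=seed)
        x = ns.serial_solve(sys_)
        x_ref = ns.dense_oracle_solve(sys_)
        assert np.allclose(x, x_ref, rtol=1e-12, atol=1e-15)

    def test_singular_pivot_raises(self):
        sys_ = identity_system([1.0, 1.0])
        sys_.d[:] = 0.0
        with pytest.raises(SingularSystemError):
            ns.serial_solve(sys_)


class TestLevelTriangularization:
    def test_cable_reduction_identical_to_serial(self, cable8, passive_params):
        _, sys_ = random_physical_system(8, seed=1)
        m = ns.make_cable(8)
        reduced, sched = ns.triangularize_levels(sys_, m)
        d_ref, rhs_ref = serial_reduce_oracle(sys_)
        assert sched.rounds == 1
        assert np.allclose(reduced.d, d_ref, rtol=1e-12)
        assert np.allclose(reduced.rhs, rhs_ref, rtol=1e-12)

    def test_fork_two_rounds_matches_serial(self, fork_small):
        rng = np.random.default_rng(7)
        p = ns.BiophysParams()
        v = rng.uniform(-80, 0, fork_small.n_segments)
        sys_ = ns.assemble_system(fork_small, p, ns.GateState.steady(v), v,
                                  np.zeros_like(v), 0.1)
        reduced, sched = ns.triangularize_levels(sys_, fork_small)
        d_ref, rhs_ref = serial_reduce_oracle(sys_)
        assert sched.rounds == 2
        assert np.allclose(reduced.d, d_ref, rtol=1e-12)

    def test_btree_depth6_seven_rounds(self):
        m = ns.make_binary_tree(6)
        p = ns.BiophysParams()
        v = np.full(m.n_segments, -65.0)
        sys_ = ns.assemble_system(m, p, ns.GateState.steady(v), v,
                                  np.zeros_like(v), 0.1)
        _, sched = ns.triangularize_levels(sys_, m)
        assert sched.rounds == 7


class TestBranchBacksub:
    def test_single_compartment(self):
        sys_ = identity_system([5.0])
        m = ns.make_cable(1)
        reduced, _ = ns.triangularize_levels(sys_, m)
        assert np.allclose(ns.backsub_branch(reduced, m), [5.0])

    def test_fork_equals_serial(self, fork_small):
        rng = np.random.default_rng(11)
        p = ns.BiophysParams()
        v = rng.uniform(-80, 0, fork_small.n_segments)
        sys_ = ns.assemble_system(fork_small, p, ns.GateState.steady(v), v,
                                  rng.uniform(-1, 1, v.size), 0.1)
        assert np.allclose(ns.branch_solve(sys_, fork_small),
                           ns.serial_solve(sys_), rtol=1e-12)

    def test_btree_depth8_matches_dense_oracle(self):
        m = ns.make_binary_tree(8)
        rng = np.random.default_rng(3)
        p = ns.BiophysParams()
        v = rng.uniform(-80, 0, m.n_segments)
        sys_ = ns.assemble_system(m, p, ns.GateState.steady(v), v,
                                  rng.uniform(-1, 1, v.size), 0.1)
        x = ns.branch_solve(sys_, m)
        x_ref = ns.dense_oracle_solve(sys_)
        scale = np.abs(x_ref).max()
        assert np.abs(x - x_ref).max() / scale < 1e-10


class TestAncestorTable:
    def test_chain_of_eight_jump_values(self):
        t = ns.build_ancestor_table(ns.make_cable(8))
        assert t.jump[0][7] == 6
        assert t.jump[1][7] == 5
        assert t.jump[2][7] == 3

    def test_chain_of_32_needs_five_rounds(self):
        t = ns.build_ancestor_table(ns.make_cable(32))
        assert t.rounds == 5

    def test_jump_composition_invariant(self, btree5):
        t = ns.build_ancestor_table(btree5)
        for j in range(1, t.rounds):
            assert np.array_equal(t.jump[j], t.jump[j - 1][t.jump[j - 1]])

    @pytest.mark.parametrize("maker", [
        lambda: ns.make_cable(19), lambda: ns.make_fork(6, 9),
        lambda: ns.make_binary_tree(6),
        lambda: ns.make_random_tree(120, np.random.default_rng(9)),
    ])
    def test_every_segment_reaches_root(self, maker):
        """Walking the exhaustive parent chain (oracle) and applying the
        final jump row `rounds` times must both land on the root."""
        m = maker()
        t = ns.build_ancestor_table(m)
        for i in range(m.n_segments):
            # oracle: step the plain parent chain
            node, hops = i, 0
            while m.parent[node] != -1:
                node = m.parent[node]
                hops += 1
            assert hops <= 2 ** t.rounds
        idx = np.arange(m.n_segments)
        if t.rounds:
            for _ in range(t.rounds):
                idx = t.jump[-1][idx]
        assert np.all(idx == 0)


class TestStoneBacksub:
    def test_root_only_system(self):
        m = ns.make_cable(1)
        sys_ = identity_system([4.0])
        t = ns.build_ancestor_table(m)
        assert t.rounds == 0
        assert np.allclose(ns.stone_solve(sys_, m, t), [4.0])

    def test_cable_equals_serial(self):
        m = ns.make_cable(8)
        rng = np.random.default_rng(2)
        p = ns.BiophysParams()
        v = rng.uniform(-80, 0, 8)
        sys_ = ns.assemble_system(m, p, ns.GateState.steady(v), v,
                                  rng.uniform(-1, 1, 8), 0.1)
        x = ns.stone_solve(sys_, m)
        assert np.allclose(x, ns.serial_solve(sys_), rtol=1e-12)

    def test_unequal_fork_matches_serial_on_both_leaf_paths(self):
        """Trunk of 4 with two 4-segment daughters: the distal values on each
        daughter path depend only on that path's segments plus the shared
        trunk, and must equal the serial solution."""
        m = ns.make_fork(4, 4)
        rng = np.random.default_rng(13)
        p = ns.BiophysParams()
        v = rng.uniform(-80, 0, m.n_segments)
        sys_ = ns.assemble_system(m, p, ns.GateState.steady(v), v,
                                  rng.uniform(-1, 1, v.size), 0.1)
        x = ns.stone_solve(sys_, m)
        x_ref = ns.serial_solve(sys_)
        assert np.allclose(x[:8], x_ref[:8], rtol=1e-12)    # trunk + daughter A
        assert np.allclose(x[8:], x_ref[8:], rtol=1e-12)    # daughter B

    def test_multiplier_fully_eliminated(self):
        m, sys_ = random_physical_system(100, seed=17)
        reduced, _ = ns.triangularize_levels(sys_, m)
        t = ns.build_ancestor_table(m)
        x = ns.backsub_stone(reduced, t)
        assert stone_residual(reduced, t) < 1e-12 * np.abs(x).max()

    def test_rounds_are_ceil_log2_m(self):
        for maker, m_expected in [(lambda: ns.make_cable(32), 32),
                                  (lambda: ns.make_binary_tree(7), 8),
                                  (lambda: ns.make_fork(10, 5), 15)]:
            m = maker()
            t = ns.build_ancestor_table(m)
            assert t.m == m_expected
            assert t.rounds == int(np.ceil(np.log2(m_expected)))


class TestCrossEquivalence:
    @pytest.mark.parametrize("seed", range(15))
    def test_all_methods_agree_on_random_physical_systems(self, seed):
        rng = np.random.default_rng(seed + 1000)
        n = int(rng.integers(4, 300))
        m, sys_ = random_physical_system(n, seed=seed + 1000)
        xs = ns.serial_solve(sys_)
        xb = ns.branch_solve(sys_, m)
        xt = ns.stone_solve(sys_, m)
        xd = ns.dense_oracle_solve(sys_)
        scale = np.abs(xd).max()
        for x in (xs, xb, xt):
            assert np.abs(x - xd).max() / scale < 1e-9

    def test_dispatch_names(self):
        m, sys_ = random_physical_system(10, seed=3)
        for method in ns.SOLVERS:
            ns.solve(sys_, m, method)
        with pytest.raises(ValueError, match="unknown method"):
            ns.solve(sys_, m, "gpu")
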