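"""MRF energies, max-sum belief propagation, and exact top-K extraction."""

import numpy as np
import pytest

import mrffit as mf
from mrffit.mrf_topk import (MRFGraph, NoValidModelsError, Weights,
                             edge_energy, enumerate_all, extract_top_k,
                             node_energy, run_max_sum, total_energy)
from mrffit.pair_scoring import InteractionScore


def _pose(cc, ov):
    class P:
        pass

    p = P()
    p.cc, p.ov = cc, ov
    return p


class TestEnergies:
    def test_node_energy_zero(self):
        assert node_energy(_pose(0.0, 0.0), Weights()) == 0.0

    def test_node_energy_default_weights(self):
        # perfect fit: -(0.5 * 1 + 0.9 * 1) = -1.4
        assert node_energy(_pose(1.0, 1.0), Weights()) == pytest.approx(-1.4)

    def test_node_energy_linear_in_weights(self):
        w1 = Weights()
        w2 = Weights(w_cc=1.0, w_ov=1.8, w_ph=2.0, w_cl=1.6)
        p = _pose(0.7, 0.8)
        assert node_energy(p, w2) == pytest.approx(2 * node_energy(p, w1))

    def test_edge_energy_zero(self):
        assert edge_energy(InteractionScore(), Weights()) == 0.0

    def test_edge_energy_default_weights(self):
        # 1.0 * (-2) + 0.8 * 5 = 2.0
        s = InteractionScore(vdw=-2.0, clash_count=5)
        assert edge_energy(s, Weights()) == pytest.approx(2.0)

    def test_edge_energy_monotone_in_clashes(self):
        w = Weights()
        energies = [
            edge_energy(InteractionScore(vdw=-1.0, clash_count=k), w)
            for k in range(5)
        ]
        assert all(b > a for a, b in zip(energies, energies[1:]))

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            Weights(w_cc=-0.1)


def small_graph(node_e, edges):
    return MRFGraph([str(i) for i in range(len(node_e))], node_e, edges)


class TestTotalEnergy:
    def test_single_node(self):
        g = small_graph([[1.5, -2.0]], {})
        assert total_energy((1,), g) == pytest.approx(-2.0)

    def test_two_by_two_hand_summed(self):
        node_e = [np.array([0.1, 0.2]), np.array([-0.3, 0.4])]
        table = np.array([[1.0, -1.0], [2.0, 0.5]])
        g = small_graph(node_e, {(0, 1): table})
        for i in range(2):
            for j in range(2):
                expect = node_e[0][i] + node_e[1][j] + table[i, j]
                assert total_energy((i, j), g) == pytest.approx(expect)

    def test_shift_invariance_of_ranking(self):
        rng = np.random.default_rng(1)
        node_e = [rng.normal(size=3), rng.normal(size=4)]
        table = rng.normal(size=(3, 4))
        g1 = small_graph([node_e[0], node_e[1]], {(0, 1): table.copy()})
        g2 = small_graph([node_e[0] + 5.0, node_e[1]], {(0, 1): table.copy()})
        e1 = [(m.energy, m.assignment) for m in enumerate_all(g1)]
        e2 = [(m.energy, m.assignment) for m in enumerate_all(g2)]
        assert [a for _, a in e1] == [a for _, a in e2]
        for (v1, _), (v2, _) in zip(e1, e2):
            assert v2 == pytest.approx(v1 + 5.0)

    def test_incomplete_assignment_rejected(self):
        g = small_graph([[0.0], [0.0]], {(0, 1): [[0.0]]})
        with pytest.raises(ValueError):
            total_energy((0,), g)


class TestMaxSum:
    def test_single_node_beliefs_unchanged(self):
        g = small_graph([[0.3, -0.7, 1.1]], {})
        b = run_max_sum(g)
        np.testing.assert_array_equal(b.initial[0], b.final[0])

    def test_two_node_map_matches_enumeration(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            node_e = [rng.normal(size=4), rng.normal(size=5)]
            table = rng.normal(size=(4, 5))
            g = small_graph(node_e, {(0, 1): table})
            b = run_max_sum(g)
            i0 = int(np.argmin(b.final[0]))
            j0 = int(np.argmin(table[i0] + node_e[1]))
            best = enumerate_all(g)[0]
            assert (i0, j0) == best.assignment
            assert total_energy((i0, j0), g) == pytest.approx(best.energy)

    def test_constant_edge_adds_constant_to_beliefs(self):
        node_e = [np.array([0.1, 0.9]), np.array([0.5, -0.5])]
        g0 = small_graph([e.copy() for e in node_e], {})
        gc = small_graph([e.copy() for e in node_e],
                         {(0, 1): np.full((2, 2), 3.25)})
        b0 = run_max_sum(g0)
        bc = run_max_sum(gc)
        for n in range(2):
            np.testing.assert_allclose(
                bc.final[n] - b0.final[n],
                3.25 + node_e[1 - n].min(),
            )

    def test_empty_pose_set_raises(self):
        g = small_graph([[], [0.0]], {})
        with pytest.raises(RuntimeError, match="0"):
            run_max_sum(g)


def random_instance(rng):
    n = int(rng.integers(2, 5))
    sizes = rng.integers(3, 9, size=n)
    node_e = [rng.normal(size=int(k)) for k in sizes]
    edges = {}
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < 0.85:
                edges[(i, j)] = rng.normal(size=(int(sizes[i]), int(sizes[j])))
    return small_graph(node_e, edges)


class TestExtractTopK:
    def test_k_exceeding_assignment_count_gives_all_sorted(self):
        rng = np.random.default_rng(3)
        g = small_graph([rng.normal(size=2), rng.normal(size=3)],
                        {(0, 1): rng.normal(size=(2, 3))})
        models = extract_top_k(g, k=100)
        oracle = enumerate_all(g)
        assert len(models) == 6
        for m, o in zip(models, oracle):
            assert m.assignment == o.assignment
            assert m.energy == pytest.approx(o.energy)

    def test_three_by_five_matches_enumeration(self):
        rng = np.random.default_rng(4)
        g = small_graph(
            [rng.normal(size=5) for _ in range(3)],
            {(0, 1): rng.normal(size=(5, 5)),
             (0, 2): rng.normal(size=(5, 5)),
             (1, 2): rng.normal(size=(5, 5))},
        )
        top = extract_top_k(g, k=10)
        oracle = enumerate_all(g)[:10]
        assert [(m.assignment, pytest.approx(m.energy)) for m in top] == \
            [(o.assignment, o.energy) for o in oracle]

    def test_k1_is_argmin(self):
        rng = np.random.default_rng(5)
        g = small_graph([rng.normal(size=6), rng.normal(size=7)],
                        {(0, 1): rng.normal(size=(6, 7))})
        (m,) = extract_top_k(g, k=1)
        assert m.assignment == enumerate_all(g)[0].assignment

    def test_fifty_random_instances_match_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(50):
            g = random_instance(rng)
            top = extract_top_k(g, k=10)
            oracle = enumerate_all(g)[:10]
            assert [m.assignment for m in top] == [o.assignment for o in oracle]
            for m, o in zip(top, oracle):
                assert m.energy == pytest.approx(o.energy, abs=1e-9)

    def test_energy_ties_broken_lexicographically(self):
        g = small_graph([np.zeros(3), np.zeros(2)], {(0, 1): np.zeros((3, 2))})
        models = extract_top_k(g, k=6)
        assert [m.assignment for m in models] == [
            (0, 0), (0, 1), (1, 0), (1, 1), (2, 0), (2, 1)
        ]

    def test_clash_filter_discards_and_continues(self):
        rng = np.random.default_rng(7)
        g = small_graph([rng.normal(size=4), rng.normal(size=4)],
                        {(0, 1): rng.normal(size=(4, 4))})
        oracle = enumerate_all(g)
        banned = {oracle[0].assignment, oracle[2].assignment}
        models = extract_top_k(g, k=3, is_valid=lambda a: a not in banned)
        expect = [o.assignment for o in oracle if o.assignment not in banned][:3]
        assert [m.assignment for m in models] == expect
        assert [m.rank for m in models] == [1, 2, 3]

    def test_no_valid_model_raises(self):
        g = small_graph([[0.0], [0.0]], {(0, 1): [[1.0]]})
        with pytest.raises(NoValidModelsError):
            extract_top_k(g, k=1, is_valid=lambda a: False)

    def test_deterministic(self):
        rng = np.random.default_rng(8)
        g = random_instance(rng)
        a = extract_top_k(g, k=10)
        b = extract_top_k(g, k=10)
        assert [m.assignment for m in a] == [m.assignment for m in b]
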