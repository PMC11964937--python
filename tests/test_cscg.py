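"""Cloned-HMM inference and learning, checked against brute-force oracles."""

from itertools import product

import numpy as np
import pytest

from osmlab import tasks
from osmlab.cscg import CSCG, CSCGError


def brute_force_loglik(model: CSCG, seq) -> float:
    """Sum the joint probability over every hidden path (the independent
    oracle for the forward pass)."""
    blocks = [range(model.clone_map.block(s).start, model.clone_map.block(s).stop)
              for s in seq]
    total = 0.0
    for path in product(*blocks):
        p = model.pi[path[0]]
        for a, b in zip(path, path[1:]):
            p *= model.T[a, b]
        total += p
    return float(np.log(total))


class TestInit:
    def test_state_count_and_row_sums(self):
        m = CSCG(tasks.alphabet("cscg_visual_first"), 100, seed=0)
        assert m.clone_map.n_states == 800
        np.testing.assert_allclose(m.T.sum(axis=1), 1.0, atol=1e-9)
        np.testing.assert_allclose(m.pi.sum(), 1.0, atol=1e-9)

    def test_minimal_model(self):
        assert CSCG([0, 1], 1).clone_map.n_states == 2

    def test_zero_clones_rejected(self):
        with pytest.raises(CSCGError):
            CSCG([0, 1], 0)


class TestForwardBackward:
    def test_deterministic_self_loop_has_loglik_zero(self):
        m = CSCG([0], 1, seed=0)
        m.T = np.array([[1.0]])
        m.pi = np.array([1.0])
        post = m.forward_backward([0, 0, 0, 0, 0])
        assert abs(post.loglik) < 1e-12

    @pytest.mark.parametrize("n_symbols,clones,length,seed", [
        (2, 2, 6, 0), (3, 2, 6, 1), (2, 3, 5, 2), (3, 1, 8, 3),
    ])
    def test_loglik_matches_path_enumeration(self, n_symbols, clones, length, seed):
        rng = np.random.default_rng(seed)
        m = CSCG(list(range(n_symbols)), clones, seed=seed)
        seq = rng.integers(0, n_symbols, size=length)
        post = m.forward_backward(seq)
        assert abs(post.loglik - brute_force_loglik(m, seq)) < 1e-10

    def test_gamma_rows_sum_to_one_and_respect_emissions(self, rng):
        m = CSCG([0, 1, 2], 4, seed=5)
        seq = rng.integers(0, 3, size=20)
        post = m.forward_backward(seq)
        np.testing.assert_allclose(post.gamma.sum(axis=1), 1.0, atol=1e-9)
        for t, s in enumerate(seq):
            outside = np.delete(post.gamma[t], np.r_[m.clone_map.block(s)])
            assert np.all(outside == 0.0)

    def test_symbol_outside_alphabet_errors(self):
        with pytest.raises(CSCGError):
            CSCG([0, 1], 2).forward_backward([0, 5])

    def test_loglik_matches_hmmlearn_reference(self, rng):
        """Cross-check against a general-purpose HMM library: a cloned
        HMM is an ordinary categorical HMM whose emission matrix is the
        0/1 clone-membership indicator."""
        from hmmlearn.hmm import CategoricalHMM
        m = CSCG([0, 1, 2], 3, seed=11)
        seq = rng.integers(0, 3, size=15)
        ref = CategoricalHMM(n_components=9, init_params="")
        ref.startprob_ = m.pi
        ref.transmat_ = m.T
        emission = np.zeros((9, 3))
        for j in range(3):
            emission[m.clone_map.block(j), j] = 1.0
        ref.emissionprob_ = emission
        expected = ref.score(seq.reshape(-1, 1))
        assert abs(m.forward_backward(seq).loglik - expected) < 1e-8


class TestBaumWelch:
    def test_deterministic_cycle_fixed_point(self):
        """EM on a strict A,B,A,B... stream drives T to the swap matrix."""
        m = CSCG([0, 1], 1, seed=2)
        seqs = [np.array([0, 1] * 20)]
        for _ in range(60):
            m._em_iteration(seqs)
        assert abs(m.T[0, 1] - 1.0) < 1e-6
        assert abs(m.T[1, 0] - 1.0) < 1e-6

    def test_loglik_monotone_within_training_step(self):
        sch = tasks.sample_session(40, dialect="cscg_visual_first", seed=4)
        m = CSCG(tasks.alphabet("cscg_visual_first"), 10, seed=4)
        res = m.fit(sch, n_steps=3, n_em_iters=20, batch_trials=10)
        assert np.all(np.diff(res.loglik_curve, axis=1) >= -1e-8)

    def test_checkpoint_count(self):
        sch = tasks.sample_session(20, dialect="cscg_visual_first", seed=4)
        m = CSCG(tasks.alphabet("cscg_visual_first"), 5, seed=4)
        res = m.fit(sch, n_steps=4, n_em_iters=2, batch_trials=5)
        assert len(res.checkpoints) == 4
        assert res.summary().startswith("CSCG fit summary")

    def test_empty_schedule_errors(self):
        with pytest.raises(CSCGError):
            CSCG([0, 1], 2).fit([], n_steps=1)

    def test_emission_structure_preserved_by_updates(self):
        sch = tasks.sample_session(20, dialect="cscg_visual_first", seed=6)
        m = CSCG(tasks.alphabet("cscg_visual_first"), 5, seed=6)
        m.fit(sch, n_steps=2, n_em_iters=5, batch_trials=5)
        near = tasks.make_trial("near", "cscg_visual_first")
        post = m.forward_backward(np.asarray(near.symbols))
        for t, s in enumerate(near.symbols):
            outside = np.delete(post.gamma[t], np.r_[m.clone_map.block(s)])
            assert np.all(outside == 0.0)


class TestViterbi:
    def test_refinement_is_fixed_point_on_deterministic_model(self):
        m = CSCG([0, 1, 2], 1, seed=0)
        m.T = np.array([[0, 1, 0], [0, 0, 1], [1, 0, 0]], dtype=float)
        m.pi = np.array([1.0, 0.0, 0.0])
        T_before = m.T.copy()
        m.viterbi_refine([np.array([0, 1, 2, 0, 1, 2])], n_iters=3)
        np.testing.assert_allclose(m.T, T_before, atol=1e-9)

    def test_tie_break_prefers_lowest_state(self):
        m = CSCG([0], 2, seed=0)
        m.T = np.full((2, 2), 0.5)
        m.pi = np.array([0.5, 0.5])
        path, _ = m.viterbi([0, 0, 0])
        assert list(path) == [0, 0, 0]

    def test_path_probability_nondecreasing_across_refinement(self):
        sch = tasks.sample_session(30, dialect="cscg_visual_first", seed=7)
        m = CSCG(tasks.alphabet("cscg_visual_first"), 10, seed=7)
        m.fit(sch, n_steps=3, n_em_iters=10, batch_trials=10)
        seqs = [np.asarray(t.symbols) for t in sch.trials[:6]]
        scores = []
        for _ in range(4):
            m.viterbi_refine(seqs, n_iters=1)
            scores.append(sum(m.viterbi(s)[1] for s in seqs))
        assert all(b >= a - 1e-8 for a, b in zip(scores, scores[1:]))


class TestGraphAndPV:
    def test_deterministic_cycle_graph(self):
        m = CSCG([0, 1, 2], 1, seed=0)
        m.T = np.array([[0, 1, 0], [0, 0, 1], [1, 0, 0]], dtype=float)
        m.pi = np.array([1.0, 0.0, 0.0])
        g = m.extract_graph([np.array([0, 1, 2, 0, 1, 2, 0])], prob_floor=0.01)
        assert g.number_of_nodes() == 3
        assert g.number_of_edges() == 3
        assert all(g.nodes[n]["symbol"] == n for n in g.nodes)

    def test_prob_floor_zero_keeps_all_positive_edges(self):
        m = CSCG([0, 1], 2, seed=1)
        seqs = [np.array([0, 1, 0, 1])]
        g = m.extract_graph(seqs, prob_floor=0.0)
        used = {n for n in g.nodes}
        expect = sum((m.T[i, j] > 0) for i in used for j in used)
        assert g.number_of_edges() == expect

    def test_untrained_pv_rows_sum_to_one(self):
        m = CSCG(tasks.alphabet("cscg_visual_first"), 10, seed=3)
        near = tasks.make_trial("near", "cscg_visual_first")
        pv = m.state_occupancy_pv(near)
        np.testing.assert_allclose(pv.matrix.sum(axis=1), 1.0, atol=1e-9)
        assert pv.matrix.shape == (26, 80)

    def test_untrained_uniform_model_gives_unit_correlation_at_shared_positions(self):
        """Before learning, clone occupancies are symmetric over clones, so
        near/far PVs agree wherever the two trials show the same symbol."""
        from osmlab import repr_analysis as ra
        m = CSCG(tasks.alphabet("cscg_visual_first"), 8, seed=9)
        S = m.clone_map.n_states
        m.T = np.full((S, S), 1.0 / S)
        m.pi = np.full(S, 1.0 / S)
        near = tasks.make_trial("near", "cscg_visual_first")
        far = tasks.make_trial("far", "cscg_visual_first")
        mat = ra.pv_cross_correlation(m.state_occupancy_pv(near),
                                      m.state_occupancy_pv(far)).matrix
        shared = [i for i, (a, b) in enumerate(zip(near.symbols, far.symbols))
                  if a == b]
        for i in shared:
            assert mat[i, i] > 0.999

    def test_hdf5_round_trip(self, tmp_path):
        m = CSCG([0, 1, 2], 3, seed=4)
        path = tmp_path / "model.h5"
        m.to_hdf5(path)
        m2 = CSCG.from_hdf5(path)
        np.testing.assert_allclose(m.T, m2.T)
        np.testing.assert_allclose(m.pi, m2.pi)
        assert m2.clone_map.symbols == [0, 1, 2]

    def test_graph_and_curve_exports(self, tmp_path):
        import networkx as nx
        from osmlab.cscg import export_graph
        m = CSCG([0, 1, 2], 1, seed=0)
        m.T = np.array([[0, 1, 0], [0, 0, 1], [1, 0, 0]], dtype=float)
        m.pi = np.array([1.0, 0.0, 0.0])
        g = m.extract_graph([np.array([0, 1, 2, 0])], prob_floor=0.01)
        export_graph(g, tmp_path / "g.graphml")
        back = nx.read_graphml(tmp_path / "g.graphml")
        assert back.number_of_nodes() == 3
        export_graph(g, tmp_path / "g.dot")
        dot = (tmp_path / "g.dot").read_text()
        assert dot.startswith("digraph") and "->" in dot
        with pytest.raises(CSCGError):
            export_graph(g, tmp_path / "g.xyz")
        # training-curve CSV
        sch = tasks.sample_session(10, dialect="cscg_visual_first", seed=1)
        res = CSCG(tasks.alphabet("cscg_visual_first"), 3, seed=1).fit(
            sch, n_steps=2, n_em_iters=3, batch_trials=4)
        res.loglik_to_csv(tmp_path / "curve.csv")
        lines = (tmp_path / "curve.csv").read_text().splitlines()
        assert lines[0] == "step,em_iter,loglik"
        assert len(lines) == 1 + 2 * 3
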