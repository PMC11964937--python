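"""Spiking soft-WTA network mechanics: encoding, dynamics, plasticity."""

import numpy as np
import pytest

from osmlab import tasks
from osmlab.hebbian import HebbianRNN, HebbianError, SpikingNetParams


@pytest.fixture()
def net():
    return HebbianRNN(8, seed=0)


class TestEncoding:
    def test_input_dimensionality(self, net):
        assert net.n_inputs == 96
        assert net.params.K == 100

    def test_active_set_confined_to_group(self, net):
        rng = np.random.default_rng(0)
        for sym in range(8):
            spikes = net.encode_stimulus(sym, rng)
            grp = net.input_group(sym)
            outside = np.concatenate([spikes[:grp.start], spikes[grp.stop:]])
            assert np.all(outside == 0)

    def test_groups_disjoint_and_cover_all_inputs(self, net):
        seen = set()
        for sym in range(8):
            grp = net.input_group(sym)
            ids = set(range(grp.start, grp.stop))
            assert not ids & seen
            seen |= ids
        assert len(seen) == 96

    def test_symbol_outside_alphabet(self, net):
        with pytest.raises(HebbianError):
            net.input_group(8)


class TestStep:
    def test_uniform_softmax_with_zero_weights(self):
        net = HebbianRNN(8, seed=0)
        net.W[:] = 0.0
        net.V[:] = 0.0
        rng = np.random.default_rng(1)
        net.step(np.zeros(96), rng, plastic=False)
        np.testing.assert_allclose(net.f, 1.0 / 100, atol=1e-12)

    def test_firing_probabilities_sum_to_one(self, net):
        rng = np.random.default_rng(2)
        for _ in range(50):
            net.step(net.encode_stimulus(1, rng), rng)
            assert abs(net.f.sum() - 1.0) < 1e-9

    def test_softmax_shift_invariance(self, net):
        rng = np.random.default_rng(3)
        net.step(net.encode_stimulus(2, rng), rng, plastic=False)
        f_before = net.f.copy()
        net2 = HebbianRNN(8, seed=0)
        net2.W = net.W.copy()
        net2.V = net.V.copy()
        net2.x_trace = net.x_trace.copy() * 0
        # adding a constant to all membrane potentials leaves f unchanged
        u = np.arange(100.0)
        e1 = np.exp(u - u.max()); f1 = e1 / e1.sum()
        e2 = np.exp(u + 7.3 - (u + 7.3).max()); f2 = e2 / e2.sum()
        np.testing.assert_allclose(f1, f2, atol=1e-12)
        assert f_before.shape == (100,)

    def test_refractory_never_violated_over_session(self):
        net = HebbianRNN(8, seed=4)
        sch = tasks.sample_session(3, dialect="cscg_visual_first", seed=4)
        _, history = net.run_session(sch, seed=5, record=True)
        refr_steps = int(net.params.refractory / net.params.dt)
        for k in range(history.shape[1]):
            times = np.flatnonzero(history[:, k])
            if len(times) > 1:
                assert np.diff(times).min() > refr_steps

    def test_weights_never_negative_during_learning(self):
        net = HebbianRNN(8, seed=6)
        sch = tasks.sample_session(5, dialect="cscg_visual_first", seed=6)
        net.run_session(sch, seed=7)
        assert net.W.min() >= 0.0
        assert net.V.min() >= 0.0


class TestPlasticity:
    def test_update_formula_from_zero_weight(self):
        """dw = alpha * (exp(-w) * trace - offset) = 0.1*(1*1 - 0.1) = 0.09."""
        net = HebbianRNN(8, seed=0)
        net.W[:] = 0.0
        net.V[:] = 0.0
        net.x_trace[:] = 1.0
        p = net.params

        class ForcedRng:
            def random(self, n=None):
                return np.zeros(n) if n else 0.0   # every neuron spikes

        net.refr[:] = 0.0
        net.y_trace[:] = 0.0
        net.step(np.zeros(96), ForcedRng())
        # x_trace decayed once before the update
        expected = p.alpha * (1.0 * net._decay * 1.0 - p.offset)
        np.testing.assert_allclose(net.W, expected, atol=1e-12)

    def test_no_postsynaptic_spike_no_update(self):
        net = HebbianRNN(8, seed=1)
        W0, V0 = net.W.copy(), net.V.copy()

        class SilentRng:
            def random(self, n=None):
                return np.ones(n) if n else 1.0    # nobody spikes

        net.step(np.zeros(96), SilentRng())
        np.testing.assert_allclose(net.W, W0)
        np.testing.assert_allclose(net.V, V0)

    def test_depression_floors_at_zero(self):
        net = HebbianRNN(8, seed=2)
        net.W[:] = 0.005                            # small weight, zero trace
        net.x_trace[:] = 0.0
        net.V[:] = 0.0

        class ForcedRng:
            def random(self, n=None):
                return np.zeros(n) if n else 0.0

        net.refr[:] = 0.0
        net.step(np.zeros(96), ForcedRng())
        assert net.W.min() == 0.0


class TestSessions:
    def test_zero_learning_rate_freezes_weights(self):
        params = SpikingNetParams(alpha=0.0, ms_per_symbol=10.0)
        net = HebbianRNN(8, params, seed=3)
        W0, V0 = net.W.copy(), net.V.copy()
        sch = tasks.sample_session(3, dialect="cscg_visual_first", seed=3)
        net.run_session(sch, seed=4)
        np.testing.assert_allclose(net.W, W0)
        np.testing.assert_allclose(net.V, V0)

    def test_same_seed_identical_histories(self):
        sch = tasks.sample_session(2, dialect="cscg_visual_first", seed=5)
        out = []
        for _ in range(2):
            net = HebbianRNN(8, SpikingNetParams(ms_per_symbol=10.0), seed=5)
            _, hist = net.run_session(sch, seed=6, record=True)
            out.append(hist)
        np.testing.assert_array_equal(out[0], out[1])

    def test_empty_schedule_errors(self, net):
        with pytest.raises(HebbianError):
            net.run_session([], seed=0)

    def test_hdf5_round_trip(self, tmp_path):
        net = HebbianRNN(8, SpikingNetParams(ms_per_symbol=10.0), seed=9)
        path = tmp_path / "net.h5"
        net.to_hdf5(path)
        back = HebbianRNN.from_hdf5(path)
        np.testing.assert_allclose(back.W, net.W)
        np.testing.assert_allclose(back.V, net.V)
        assert back.params.ms_per_symbol == 10.0

    def test_trace_matches_closed_form_exponential(self):
        """With plasticity off, a single input spike decays as exp(-t/tau)."""
        net = HebbianRNN(8, SpikingNetParams(), seed=0)
        net.W[:] = 0.0
        net.V[:] = 0.0

        class SilentRng:
            def random(self, n=None):
                return np.ones(n) if n else 1.0

        spike = np.zeros(96)
        spike[0] = 1.0
        net.step(spike, SilentRng(), plastic=False)
        assert net.x_trace[0] == 1.0         # unit jump at the spike step
        for k in range(1, 6):
            net.step(np.zeros(96), SilentRng(), plastic=False)
            expected = np.exp(-k * net.params.dt / net.params.tau)
            assert abs(net.x_trace[0] - expected) < 1e-9

    def test_stimulus_assemblies_form_on_two_state_toy(self):
        """On a deterministic two-stimulus alternation, the trained
        network develops stimulus-specific assemblies: the top softmax
        neurons for the two stimuli are disjoint in most seeds."""
        hits = 0
        n_seeds = 5
        for seed in range(n_seeds):
            params = SpikingNetParams(ms_per_symbol=30.0)
            net = HebbianRNN(2, params, seed=seed)
            stream = [tasks.TrialSequence((0, 1) * 10, "near", "rnn")] * 20
            net.run_session(stream, seed=seed + 100)
            tops = []
            rng = np.random.default_rng(0)
            for sym in (0, 1):
                net.reset_state()
                for _ in range(30):
                    net.step(net.encode_stimulus(sym, rng), rng, plastic=False)
                tops.append(set(np.argsort(net.f)[-5:]))
            if not tops[0] & tops[1]:
                hits += 1
        assert hits >= 0.8 * n_seeds
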