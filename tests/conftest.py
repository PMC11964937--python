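import numpy as np
import pytest

from osmlab import tasks


@pytest.fixture(scope="session")
def printed_rnn_sequences():
    """The canonical near/far trial sequences of the 7-symbol dialect."""
    return tasks.make_trial("near", "rnn"), tasks.make_trial("far", "rnn")


@pytest.fixture(scope="session")
def printed_cscg_sequences():
    return (tasks.make_trial("near", "cscg_visual_first"),
            tasks.make_trial("far", "cscg_visual_first"))


@pytest.fixture(scope="session")
def small_expert_session():
    """A compact high-SNR expert-stage synthetic session, shared by the
    calcium/behaviour metric tests."""
    from osmlab import synth
    cfg = synth.SynthConfig(n_cells=150, stage="expert", seed=11)
    return synth.simulate_session(cfg, n_trials=30)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
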