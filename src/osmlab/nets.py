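"""Gradient-trained next-symbol predictors: rate RNNs, LSTMs and a small
transformer.

All three families are trained with backpropagation (through time) and
the Adam optimizer to predict the next sensory symbol of the 7-symbol
task stream under cross-entropy loss.  The scientific point is not task
performance -- every family solves the prediction task -- but the
correlational structure of the hidden representations: rate RNNs whose
activation implements a soft winner-take-all (exponential or polynomial
softmax) orthogonalize the near/far representations like hippocampus,
whereas ReLU/sigmoid RNNs, standard LSTMs and transformers solve the task
while keeping the two trial types highly correlated, unless an explicit
correlation penalty is added to the objective.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .repr_analysis import PositionPV
from .tasks import SessionSchedule, TrialSequence, make_trial, sample_session

N_SYMBOLS = 7        # rnn-dialect alphabet size; io dimensionality of all nets

ACTIVATIONS = ("exp_softmax", "poly_softmax", "relu", "sigmoid")
REGULARIZERS = (None, "l1_hidden", "dropout", "correlation_penalty")


class NetConfigError(ValueError):
    pass


def one_hot(symbols: np.ndarray, n: int = N_SYMBOLS) -> np.ndarray:
    symbols = np.asarray(symbols, dtype=int)
    if symbols.min() < 0 or symbols.max() >= n:
        raise NetConfigError(f"symbols must lie in [0, {n})")
    out = np.zeros(symbols.shape + (n,))
    np.put_along_axis(out, symbols[..., None], 1.0, axis=-1)
    return out


def decode_one_hot(vectors: np.ndarray) -> np.ndarray:
    return np.argmax(vectors, axis=-1)


def correlation_penalty(hidden_near: Tensor, hidden_far: Tensor,
                        eps: float = 1e-12) -> Tensor:
    """Mean over positions of squared Pearson r between paired hidden
    vectors; differentiable, and a zero-variance vector contributes 0."""
    hn = hidden_near - hidden_near.mean(axis=-1, keepdims=True)
    hf = hidden_far - hidden_far.mean(axis=-1, keepdims=True)
    cov = (hn * hf).sum(axis=-1)
    var_n = (hn * hn).sum(axis=-1)
    var_f = (hf * hf).sum(axis=-1)
    r2 = (cov * cov) / (var_n * var_f + eps)
    return r2.mean()


def _split_session(session: SessionSchedule | list[TrialSequence], rng
                   ) -> tuple[list[TrialSequence], list[TrialSequence]]:
    """Disjoint half/half train/test split of a session's trials."""
    trials = session.trials if isinstance(session, SessionSchedule) else list(trials := session)
    idx = rng.permutation(len(trials))
    half = len(trials) // 2
    train = [trials[i] for i in idx[:half]]
    test = [trials[i] for i in idx[half:]]
    return train, test


@dataclass
class NetResults:
    """Training outcome shared by all net families."""

    model: "SequenceNet"
    loss_curve: np.ndarray
    train_trials: list[TrialSequence]
    test_trials: list[TrialSequence]
    checkpoint_pvs: list[tuple[PositionPV, PositionPV]] = field(default_factory=list)

    def summary(self) -> str:
        acc = self.model.next_symbol_accuracy(self.test_trials)
        return "\n".join([
            f"{type(self.model).__name__} fit summary",
            "-" * 30,
            f"epochs/iters:   {len(self.loss_curve)}",
            f"final loss:     {self.loss_curve[-1]:.4f}",
            f"test accuracy:  {acc:.3f} (all positions)",
            f"checkpoints:    {len(self.checkpoint_pvs)}",
        ])


class SequenceNet:
    """Base class: parameter registry, PV extraction, accuracy."""

    def __init__(self, seed: int = 0):
        self.seed = seed
        self.rng = np.random.default_rng(seed)
        self.params: list[Tensor] = []
        self.trained = False

    def _param(self, shape, sd) -> Tensor:
        t = Tensor(self.rng.normal(0.0, sd, shape), requires_grad=True)
        self.params.append(t)
        return t

    # subclasses implement: forward(batch_symbols, train=...) -> (logits, hidden)
    def forward(self, symbols: np.ndarray, train: bool = False):
        raise NotImplementedError

    def hidden_pv(self, trial: TrialSequence) -> PositionPV:
        """Hidden-state matrix (positions x units) for one trial.

        For recurrent nets this is the recurrent state after consuming
        each symbol; the transformer overrides this with its pre-logit
        representation.
        """
        if not self.trained:
            import warnings
            warnings.warn("extracting PVs from an untrained network")
        syms = np.asarray(trial.symbols)[None, :]
        _, hidden = self.forward(syms)
        return PositionPV(hidden.data[0], np.arange(len(trial.symbols), dtype=float),
                          trial_type=trial.trial_type, source=type(self).__name__)

    def pv_pair(self) -> tuple[PositionPV, PositionPV]:
        return (self.hidden_pv(make_trial("near", "rnn")),
                self.hidden_pv(make_trial("far", "rnn")))

    def predict_logits(self, trial: TrialSequence) -> np.ndarray:
        """(T-1, n_symbols) logits; row t predicts symbol t+1."""
        syms = np.asarray(trial.symbols)[None, :]
        logits, _ = self.forward(syms)
        return logits.data[0, :-1]

    def next_symbol_accuracy(self, trials, position_filter=None) -> float:
        """Argmax next-symbol accuracy, optionally restricted to target
        positions (indices of the symbol being predicted)."""
        if position_filter is not None and len(position_filter) == 0:
            raise NetConfigError("empty position filter")
        hits, total = 0, 0
        for tr in trials:
            pred = np.argmax(self.predict_logits(tr), axis=-1)
            actual = np.asarray(tr.symbols)[1:]
            for t, (p, a) in enumerate(zip(pred, actual), start=1):
                if position_filter is not None and t not in position_filter:
                    continue
                hits += int(p == a)
                total += 1
        return hits / max(total, 1)

    # ------------------------------------------------------------------ #
    def _checkpoint(self, store, every, epoch):
        if every and (epoch % every == 0):
            was = self.trained
            self.trained = True
            store.append(self.pv_pair())
            self.trained = was


class RateRNN(SequenceNet):
    """Vanilla rate RNN h_t = act(W_in x_t + W_rec h_{t-1} + b).

    ``activation`` selects the hidden nonlinearity; the two softmax
    variants implement divisive normalisation (soft winner-take-all),
    with ``poly_softmax`` using 8th-power normalisation
    a_i = |u_i|^8 / sum_j |u_j|^8.
    """

    def __init__(self, hidden: int = 500, activation: str = "exp_softmax",
                 seed: int = 0, out_sd: float = 0.1):
        super().__init__(seed)
        if activation not in ACTIVATIONS:
            raise NetConfigError(f"unknown activation {activation!r}")
        self.hidden = hidden
        self.activation = activation
        self.Wxh = self._param((N_SYMBOLS, hidden), 0.001)
        self.Whh = self._param((hidden, hidden), 0.001)
        self.bh = self._param((hidden,), 0.0)
        self.Why = self._param((hidden, N_SYMBOLS), out_sd)
        self.by = self._param((N_SYMBOLS,), 0.0)

    def _act(self, pre: Tensor) -> Tensor:
        if self.activation == "exp_softmax":
            return pre.softmax()
        if self.activation == "poly_softmax":
            p = pre.abs() ** 8.0
            return p / (p.sum(axis=-1, keepdims=True) + 1e-30)
        if self.activation == "relu":
            return pre.relu()
        return pre.sigmoid()

    def forward(self, symbols: np.ndarray, train: bool = False):
        x = one_hot(symbols)                          # (B, T, 7)
        B, T, _ = x.shape
        h = Tensor(np.zeros((B, self.hidden)))
        hs = []
        for t in range(T):
            pre = Tensor(x[:, t]) @ self.Wxh + h @ self.Whh + self.bh
            h = self._act(pre)
            hs.append(h)
        hidden = ad.stack(hs, axis=1)                 # (B, T, H)
        logits = hidden @ self.Why + self.by
        return logits, hidden

    def fit(self, session: SessionSchedule | None = None, n_epochs: int = 150,
            lr: float = 0.02, checkpoint_every: int = 0,
            n_trials: int = 60, seed_session: int | None = None) -> NetResults:
        """Full-batch BPTT training on half of a session's trials.

        If no session is given, one is sampled with the model seed.
        ``lr`` defaults to the low end of the stable range for softmax
        activations; ReLU/sigmoid variants tolerate the same value.
        """
        if session is None:
            session = sample_session(n_trials, seed=self.seed if seed_session is None
                                     else seed_session, dialect="rnn")
        train, test = _split_session(session, self.rng)
        batch = np.stack([np.asarray(tr.symbols) for tr in train])
        targets = batch[:, 1:]
        opt = ad.Adam(self.params, lr=lr)
        losses = np.empty(n_epochs)
        ck: list = []
        for epoch in range(n_epochs):
            logits, _ = self.forward(batch, train=True)
            loss = ad.cross_entropy(logits[:, :-1], targets)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses[epoch] = loss.data
            self._checkpoint(ck, checkpoint_every, epoch)
        self.trained = True
        if checkpoint_every:
            ck.append(self.pv_pair())
        return NetResults(self, losses, train, test, ck)


class NextSymbolLSTM(SequenceNet):
    """Single-layer LSTM with a linear readout.

    ``regularizer`` is one of None, ``l1_hidden`` (L1 on hidden states),
    ``dropout`` (on hidden states during training) or
    ``correlation_penalty`` (adds lam * mean-squared near/far hidden
    Pearson r to the loss, explicitly encouraging orthogonalized
    representations).  ``track`` selects whether analyses read hidden (h)
    or cell (c) states.
    """

    def __init__(self, hidden: int = 800, regularizer: str | None = None,
                 lam: float = 1.0, dropout_p: float = 0.2, seed: int = 0,
                 track: str = "h"):
        super().__init__(seed)
        if regularizer not in REGULARIZERS:
            raise NetConfigError(f"unknown regularizer {regularizer!r}")
        if track not in ("h", "c"):
            raise NetConfigError("track must be 'h' or 'c'")
        self.hidden = hidden
        self.regularizer = regularizer
        self.lam = lam
        self.dropout_p = dropout_p
        self.track = track
        H = hidden
        # standard 1/sqrt(H) fan-in scaling; the tiny-init convention of the
        # rate RNNs starves LSTM gates of gradient
        self.Wx = self._param((N_SYMBOLS, 4 * H), 1.0 / np.sqrt(H))
        self.Wh = self._param((H, 4 * H), 1.0 / np.sqrt(H))
        self.b = self._param((4 * H,), 0.0)
        self.Why = self._param((H, N_SYMBOLS), 0.1)
        self.by = self._param((N_SYMBOLS,), 0.0)

    def forward(self, symbols: np.ndarray, train: bool = False):
        x = one_hot(symbols)
        B, T, _ = x.shape
        H = self.hidden
        h = Tensor(np.zeros((B, H)))
        c = Tensor(np.zeros((B, H)))
        hs, cs = [], []
        for t in range(T):
            z = Tensor(x[:, t]) @ self.Wx + h @ self.Wh + self.b
            i = z[:, :H].sigmoid()
            f = z[:, H:2 * H].sigmoid()
            g = z[:, 2 * H:3 * H].tanh()
            o = z[:, 3 * H:].sigmoid()
            c = f * c + i * g
            h = o * c.tanh()
            if train and self.regularizer == "dropout":
                mask = (self.rng.random((B, H)) > self.dropout_p) / (1 - self.dropout_p)
                h = h * Tensor(mask)
            hs.append(h)
            cs.append(c)
        hidden = ad.stack(hs if self.track == "h" else cs, axis=1)
        logits = ad.stack(hs, axis=1) @ self.Why + self.by
        return logits, hidden

    def fit(self, session: SessionSchedule | None = None, n_epochs: int = 150,
            lr: float = 4e-4, checkpoint_every: int = 0,
            n_trials: int = 100, seed_session: int | None = None) -> NetResults:
        if session is None:
            session = sample_session(n_trials, seed=self.seed if seed_session is None
                                     else seed_session, dialect="rnn")
        train, test = _split_session(session, self.rng)
        batch = np.stack([np.asarray(tr.symbols) for tr in train])
        targets = batch[:, 1:]
        pair = np.stack([np.asarray(make_trial("near", "rnn").symbols),
                         np.asarray(make_trial("far", "rnn").symbols)])
        opt = ad.Adam(self.params, lr=lr)
        losses = np.empty(n_epochs)
        ck: list = []
        for epoch in range(n_epochs):
            logits, hidden = self.forward(batch, train=True)
            loss = ad.cross_entropy(logits[:, :-1], targets)
            if self.regularizer == "l1_hidden":
                loss = loss + self.lam * hidden.abs().mean()
            elif self.regularizer == "correlation_penalty":
                _, hpair = self.forward(pair, train=False)
                loss = loss + self.lam * correlation_penalty(hpair[0], hpair[1])
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses[epoch] = loss.data
            self._checkpoint(ck, checkpoint_every, epoch)
        self.trained = True
        if checkpoint_every:
            ck.append(self.pv_pair())
        return NetResults(self, losses, train, test, ck)


class MiniTransformer(SequenceNet):
    """Decoder-only transformer (GPT style) with causal self-attention.

    The reference configuration is 4 layers, 4 heads, embedding 256;
    smaller configurations train the same way.  ``context_length`` caps
    the attention window -- the task needs strictly more than 4 symbols of
    context to disambiguate the reward zones (the inter-reward grey gap
    is 3 symbols), so small windows leave those predictions at chance.
    Representations are read from the pre-logit layer (final layer norm).
    """

    def __init__(self, n_layers: int = 4, n_heads: int = 4, embed: int = 256,
                 context_length: int = 100, seed: int = 0):
        super().__init__(seed)
        if embed % n_heads:
            raise NetConfigError("embed must be divisible by n_heads")
        self.n_layers, self.n_heads, self.embed = n_layers, n_heads, embed
        self.context_length = context_length
        E = embed
        sd = 0.02
        self.tok = self._param((N_SYMBOLS, E), sd)
        self.pos = self._param((context_length, E), sd)
        self.blocks = []
        for _ in range(n_layers):
            blk = {
                "ln1_g": self._param((E,), 0.0), "ln1_b": self._param((E,), 0.0),
                "qkv": self._param((E, 3 * E), sd), "proj": self._param((E, E), sd),
                "ln2_g": self._param((E,), 0.0), "ln2_b": self._param((E,), 0.0),
                "fc1": self._param((E, 4 * E), sd), "fc1_b": self._param((4 * E,), 0.0),
                "fc2": self._param((4 * E, E), sd), "fc2_b": self._param((E,), 0.0),
            }
            # layer-norm gains start at 1
            blk["ln1_g"].data += 1.0
            blk["ln2_g"].data += 1.0
            self.blocks.append(blk)
        self.lnf_g = self._param((E,), 0.0)
        self.lnf_b = self._param((E,), 0.0)
        self.lnf_g.data += 1.0
        self.head = self._param((E, N_SYMBOLS), sd)

    def forward(self, symbols: np.ndarray, train: bool = False):
        symbols = np.asarray(symbols, dtype=int)
        B, T = symbols.shape
        if T > self.context_length:
            raise NetConfigError(f"sequence longer than context window "
                                 f"({T} > {self.context_length})")
        E, nh = self.embed, self.n_heads
        dh = E // nh
        x = self.tok[symbols] + self.pos[:T]
        mask = np.triu(np.full((T, T), -1e9), k=1)
        for blk in self.blocks:
            a = ad.layer_norm(x, blk["ln1_g"], blk["ln1_b"])
            qkv = a @ blk["qkv"]                       # (B,T,3E)
            qkv = qkv.reshape(B, T, 3, nh, dh).transpose(2, 0, 3, 1, 4)
            q, k, v = qkv[0], qkv[1], qkv[2]           # (B,nh,T,dh)
            att = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(dh)) + Tensor(mask)
            att = att.softmax()
            y = (att @ v).transpose(0, 2, 1, 3).reshape(B, T, E)
            x = x + y @ blk["proj"]
            m = ad.layer_norm(x, blk["ln2_g"], blk["ln2_b"])
            x = x + ad.gelu(m @ blk["fc1"] + blk["fc1_b"]) @ blk["fc2"] + blk["fc2_b"]
        pre_logit = ad.layer_norm(x, self.lnf_g, self.lnf_b)
        logits = pre_logit @ self.head
        return logits, pre_logit

    def fit(self, n_iters: int = 600, lr: float = 3e-4, batch_size: int = 8,
            chunk: int = 100, n_batches: int = 200, trials_per_batch: int = 10,
            checkpoint_every: int = 0, seed_session: int | None = None) -> NetResults:
        """Train on random chunks cut from streams of randomly assembled
        trials (10 trials per stream), cross-entropy next-token loss."""
        rng = np.random.default_rng(self.seed if seed_session is None else seed_session)
        chunk = min(chunk, self.context_length)
        streams = []
        for _ in range(n_batches):
            sess = sample_session(trials_per_batch, seed=int(rng.integers(2 ** 31)),
                                  dialect="rnn")
            streams.append(sess.symbol_stream())
        opt = ad.Adam(self.params, lr=lr)
        losses = np.empty(n_iters)
        ck: list = []
        for it in range(n_iters):
            rows = []
            for _ in range(batch_size):
                s = streams[rng.integers(len(streams))]
                start = rng.integers(0, len(s) - chunk)
                rows.append(s[start:start + chunk + 1])
            arr = np.stack(rows)
            logits, _ = self.forward(arr[:, :-1], train=True)
            loss = ad.cross_entropy(logits, arr[:, 1:])
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses[it] = loss.data
            self._checkpoint(ck, checkpoint_every, it)
        self.trained = True
        if checkpoint_every:
            ck.append(self.pv_pair())
        # held-out evaluation set
        test = sample_session(20, seed=int(rng.integers(2 ** 31)), dialect="rnn").trials
        return NetResults(self, losses, [], test, ck)

    def hidden_pv(self, trial: TrialSequence) -> PositionPV:
        """Pre-logit representation per trial position, each computed with
        the trailing context window (previous trial prepended)."""
        other = make_trial("far" if trial.trial_type == "near" else "near", "rnn")
        stream = np.concatenate([np.asarray(other.symbols), np.asarray(trial.symbols)])
        T = len(trial.symbols)
        L = self.context_length
        rows = []
        offsets = []
        for pos in range(T):
            end = len(other.symbols) + pos + 1
            start = max(0, end - L)
            rows.append(stream[start:end])
            offsets.append(end - start - 1)
        width = max(len(r) for r in rows)
        batch = np.zeros((T, width), dtype=int)
        for i, r in enumerate(rows):
            batch[i, :len(r)] = r
        _, pre = self.forward(batch)
        mat = pre.data[np.arange(T), offsets]
        return PositionPV(mat, np.arange(T, dtype=float),
                          trial_type=trial.trial_type, source="transformer")

    def predict_logits(self, trial: TrialSequence) -> np.ndarray:
        syms = np.asarray(trial.symbols)
        L = self.context_length
        out = np.empty((len(syms) - 1, N_SYMBOLS))
        for t in range(len(syms) - 1):
            start = max(0, t + 1 - L)
            window = syms[start:t + 1][None, :]
            logits, _ = self.forward(window)
            out[t] = logits.data[0, -1]
        return out


def train(spec: dict, session: SessionSchedule | None = None, **fit_kwargs) -> NetResults:
    """Dictionary-driven constructor + fit, for config-file use.

    ``spec`` carries ``family`` plus family-specific keys (hidden,
    activation, regularizer, context_length, seed).
    """
    family = spec.get("family")
    kwargs = {k: v for k, v in spec.items() if k != "family"}
    if family == "rate_rnn":
        model = RateRNN(**kwargs)
    elif family == "lstm":
        model = NextSymbolLSTM(**kwargs)
    elif family == "transformer":
        if session is not None:
            raise NetConfigError("transformer samples its own training streams")
        return MiniTransformer(**kwargs).fit(**fit_kwargs)
    else:
        raise NetConfigError(f"unknown family {family!r}")
    return model.fit(session, **fit_kwargs)
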