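"""Clone-structured causal graph (CSCG): a cloned hidden Markov model.

A CSCG is an HMM over S hidden states in which each state ("clone")
deterministically emits exactly one observation symbol: p(x=j | z=i) = 1
iff i is a clone of j, else 0.  The emission matrix is fixed; learning
only re-estimates the S x S transition matrix (and the initial
distribution) by Baum-Welch expectation maximization, optionally refined
by hard-assignment Viterbi training.  Because several clones share each
symbol, the model can use temporal context to assign identical sensory
inputs to distinct latent states -- the mechanism by which it builds an
orthogonalized state machine of the cue-delay-choice task.

The deterministic emissions make inference cheap: the forward/backward
messages at step n live only on the clones of the observed symbol x_n, so
all message passing happens in clones_per_symbol-sized blocks.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import networkx as nx

from .tasks import SessionSchedule, SymbolAlphabet, TrialSequence
from .repr_analysis import PositionPV


class CSCGError(ValueError):
    pass


@dataclass
class CloneMap:
    """Partition of hidden-state ids into per-symbol clone blocks."""

    symbols: list[int]                  # observation ids, sorted
    clones_per_symbol: int

    def __post_init__(self):
        if self.clones_per_symbol < 1:
            raise CSCGError("clones_per_symbol must be >= 1")
        self._index = {s: k for k, s in enumerate(self.symbols)}

    @property
    def n_states(self) -> int:
        return len(self.symbols) * self.clones_per_symbol

    def block(self, symbol: int) -> slice:
        """Slice of state ids that emit ``symbol``."""
        try:
            k = self._index[symbol]
        except KeyError:
            raise CSCGError(f"symbol {symbol} outside alphabet") from None
        m = self.clones_per_symbol
        return slice(k * m, (k + 1) * m)

    def state_symbol(self, state: int) -> int:
        return self.symbols[state // self.clones_per_symbol]


@dataclass
class Posterior:
    """Forward-backward result for one observation sequence."""

    gamma: np.ndarray        # (T, S) state posteriors; rows sum to 1
    xi: list | None          # per-step pairwise-marginal blocks (i->j), or None
    loglik: float            # natural-log sequence likelihood


@dataclass
class CSCGResults:
    """Fit result: the trained model, per-iteration log-likelihoods and
    model snapshots taken at checkpoints during the training curriculum."""

    model: "CSCG"
    loglik_curve: np.ndarray          # (n_steps, n_em_iters) per-batch total loglik
    checkpoints: list["CSCG"]
    checkpoint_steps: list[int]
    #: per checkpoint, one occupancy PV per probe trial (when probing)
    checkpoint_pvs: list[list["PositionPV"]] = field(default_factory=list)

    def summary(self) -> str:
        last = self.loglik_curve[-1, -1] if self.loglik_curve.size else float("nan")
        lines = [
            "CSCG fit summary",
            "----------------",
            f"states:            {self.model.clone_map.n_states} "
            f"({len(self.model.clone_map.symbols)} symbols x "
            f"{self.model.clone_map.clones_per_symbol} clones)",
            f"training steps:    {self.loglik_curve.shape[0]}",
            f"EM iters per step: {self.loglik_curve.shape[1]}",
            f"final batch loglik: {last:.3f}",
            f"checkpoints:       {len(self.checkpoint_steps)}",
        ]
        return "\n".join(lines)

    def loglik_to_csv(self, path) -> None:
        """Training curve as CSV: one row per (step, EM iteration)."""
        rows = ["step,em_iter,loglik"]
        for s in range(self.loglik_curve.shape[0]):
            for it in range(self.loglik_curve.shape[1]):
                rows.append(f"{s},{it},{self.loglik_curve[s, it]!r}")
        with open(path, "w") as fh:
            fh.write("\n".join(rows) + "\n")


def export_graph(graph: nx.DiGraph, path) -> None:
    """Write a transition graph as GraphML (``.graphml``) or DOT
    (``.dot``), chosen by file extension."""
    path = str(path)
    if path.endswith(".graphml"):
        nx.write_graphml(graph, path)
    elif path.endswith(".dot"):
        lines = ["digraph cscg {"]
        for n, data in graph.nodes(data=True):
            lines.append(f'  {n} [label="{data.get("symbol", n)}"];')
        for a, b, data in graph.edges(data=True):
            lines.append(f'  {a} -> {b} [weight={data.get("weight", 1.0):.4g}];')
        lines.append("}")
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")
    else:
        raise CSCGError(f"unknown graph format for {path!r} "
                        "(use .graphml or .dot)")


class CSCG:
    """Cloned HMM with fixed deterministic emissions.

    Parameters
    ----------
    alphabet : SymbolAlphabet or iterable of int
        Observation symbols the model can emit.
    clones_per_symbol : int
        Number of hidden states tied to each symbol (100 in the reference
        configuration, giving S = 800 states on the 8-symbol task).
    seed : int
        Seeds the random positive initialisation of the transition matrix
        and the batch sampling during fitting.
    pseudocount : float
        Additive smoothing on transition counts at every M-step; keeps
        rows stochastic when a clone receives no evidence.
    """

    def __init__(self, alphabet: SymbolAlphabet | list[int],
                 clones_per_symbol: int = 100, seed: int = 0,
                 pseudocount: float = 1e-10):
        symbols = alphabet.symbols if isinstance(alphabet, SymbolAlphabet) \
            else sorted(alphabet)
        self.clone_map = CloneMap(symbols, clones_per_symbol)
        self.seed = seed
        self.pseudocount = pseudocount
        rng = np.random.default_rng(seed)
        S = self.clone_map.n_states
        self.T = rng.random((S, S)) + 1e-3
        self.T /= self.T.sum(axis=1, keepdims=True)
        self.pi = np.full(S, 1.0 / S)

    # ------------------------------------------------------------------ #
    # inference

    def _blocks(self, sequence) -> list[slice]:
        return [self.clone_map.block(int(s)) for s in np.asarray(sequence).ravel()]

    def forward_backward(self, sequence, want_xi: bool = False) -> Posterior:
        """Scaled forward-backward under the clone emission constraint.

        Posterior mass at step n is exactly zero outside the clones of the
        observed symbol x_n, so messages are propagated block-to-block.
        """
        seq = np.asarray(sequence).ravel()
        blocks = self._blocks(seq)
        n = len(seq)
        S = self.clone_map.n_states
        T, pi = self.T, self.pi

        alphas, scales = [], np.empty(n)
        a = pi[blocks[0]].copy()
        scales[0] = a.sum()
        a /= scales[0]
        alphas.append(a)
        for t in range(1, n):
            a = a @ T[blocks[t - 1], blocks[t]]
            scales[t] = a.sum()
            if scales[t] <= 0:
                raise CSCGError("zero-probability sequence under current model")
            a = a / scales[t]
            alphas.append(a)
        loglik = float(np.log(scales).sum())

        m = self.clone_map.clones_per_symbol
        betas = [None] * n
        b = np.ones(m)
        betas[-1] = b
        for t in range(n - 2, -1, -1):
            b = (T[blocks[t], blocks[t + 1]] @ b) / scales[t + 1]
            betas[t] = b

        gamma = np.zeros((n, S))
        for t in range(n):
            g = alphas[t] * betas[t]
            gamma[t, blocks[t]] = g / g.sum()

        xi = None
        if want_xi:
            xi = []
            for t in range(n - 1):
                block = T[blocks[t], blocks[t + 1]]
                x = np.outer(alphas[t], betas[t + 1]) * block / scales[t + 1]
                xi.append(x / x.sum())
        return Posterior(gamma, xi, loglik)

    def loglik(self, sequence) -> float:
        seq = np.asarray(sequence).ravel()
        blocks = self._blocks(seq)
        a = self.pi[blocks[0]].copy()
        ll = 0.0
        for t in range(1, len(seq) + 1):
            s = a.sum()
            if s <= 0:
                return -np.inf
            ll += np.log(s)
            if t == len(seq):
                break
            a = (a / s) @ self.T[blocks[t - 1], blocks[t]]
        return float(ll)

    def _em_iteration(self, sequences: list[np.ndarray]) -> float:
        """One Baum-Welch iteration over a batch; returns pre-update loglik."""
        S = self.clone_map.n_states
        counts = np.zeros((S, S))
        pi_counts = np.zeros(S)
        total_ll = 0.0
        for seq in sequences:
            blocks = self._blocks(seq)
            n = len(seq)
            T = self.T
            alphas, scales = [], np.empty(n)
            a = self.pi[blocks[0]].copy()
            scales[0] = a.sum()
            a /= scales[0]
            alphas.append(a)
            for t in range(1, n):
                a = a @ T[blocks[t - 1], blocks[t]]
                scales[t] = a.sum()
                a = a / scales[t]
                alphas.append(a)
            total_ll += float(np.log(scales).sum())
            b = np.ones_like(alphas[-1])
            for t in range(n - 2, -1, -1):
                bi, bj = blocks[t], blocks[t + 1]
                counts[bi, bj] += np.outer(alphas[t], b / scales[t + 1]) * T[bi, bj]
                b = (T[bi, bj] @ b) / scales[t + 1]
            g0 = alphas[0] * b
            pi_counts[blocks[0]] += g0 / g0.sum()
        counts += self.pseudocount
        self.T = counts / counts.sum(axis=1, keepdims=True)
        pi_counts += self.pseudocount
        self.pi = pi_counts / pi_counts.sum()
        return total_ll

    # ------------------------------------------------------------------ #
    # fitting

    def fit(self, schedule: SessionSchedule | list[TrialSequence],
            n_steps: int = 50, n_em_iters: int = 20, batch_trials: int = 20,
            checkpoint_every: int = 1, checkpoint_cadence: str = "step",
            concatenate: bool = True,
            probe_trials: list[TrialSequence] | None = None) -> CSCGResults:
        """Curriculum training: at each step run ``n_em_iters`` EM
        iterations on a freshly sampled batch of ``batch_trials`` trials.

        With ``concatenate`` (default) the batch is joined into one long
        sequence so that teleport-to-start transitions are learned and the
        transition graph closes into a loop.  The per-batch log-likelihood
        is non-decreasing across the EM iterations of every step.

        ``checkpoint_cadence`` is ``"step"`` (snapshot every
        ``checkpoint_every`` training steps) or ``"iteration"`` (snapshot
        after every EM iteration -- fine-grained enough to resolve the
        decorrelation order, since most likelihood improvement happens
        within the first few steps).

        When ``probe_trials`` is given, each checkpoint stores the state
        occupancy PV of every probe trial instead of a full model snapshot
        (a snapshot is an S x S matrix; probing keeps memory flat when
        checkpointing every iteration).
        """
        trials = schedule.trials if isinstance(schedule, SessionSchedule) else list(schedule)
        if not trials:
            raise CSCGError("empty schedule")
        if n_em_iters < 1 or n_steps < 1:
            raise CSCGError("n_steps and n_em_iters must be >= 1")
        rng = np.random.default_rng(self.seed + 1)
        curve = np.empty((n_steps, n_em_iters))
        checkpoints, checkpoint_steps, checkpoint_pvs = [], [], []

        def take_checkpoint(tick: int) -> None:
            checkpoint_steps.append(tick)
            if probe_trials is not None:
                checkpoint_pvs.append([self.state_occupancy_pv(tr)
                                       for tr in probe_trials])
            else:
                checkpoints.append(self.snapshot())

        for step in range(n_steps):
            idx = rng.integers(0, len(trials), size=min(batch_trials, len(trials)))
            batch = [np.asarray(trials[i].symbols) for i in idx]
            if concatenate:
                batch = [np.concatenate(batch)]
            for it in range(n_em_iters):
                curve[step, it] = self._em_iteration(batch)
                if checkpoint_cadence == "iteration":
                    take_checkpoint(step * n_em_iters + it + 1)
            if checkpoint_cadence == "step" and (
                    (step + 1) % checkpoint_every == 0 or step == n_steps - 1):
                take_checkpoint(step + 1)
        return CSCGResults(self, curve, checkpoints, checkpoint_steps, checkpoint_pvs)

    def snapshot(self) -> "CSCG":
        new = copy.copy(self)
        new.T = self.T.copy()
        new.pi = self.pi.copy()
        return new

    # ------------------------------------------------------------------ #
    # Viterbi

    def viterbi(self, sequence) -> tuple[np.ndarray, float]:
        """Most probable state path (ties broken towards the lowest state
        id) and its joint log probability."""
        seq = np.asarray(sequence).ravel()
        blocks = self._blocks(seq)
        n = len(seq)
        with np.errstate(divide="ignore"):
            logT = np.log(self.T)
            logpi = np.log(self.pi)
        delta = logpi[blocks[0]].copy()
        back = []
        for t in range(1, n):
            cand = delta[:, None] + logT[blocks[t - 1], blocks[t]]
            back.append(np.argmax(cand, axis=0))     # first max = lowest id
            delta = np.max(cand, axis=0)
        path = np.empty(n, dtype=int)
        j = int(np.argmax(delta))
        logp = float(delta[j])
        path[-1] = j
        for t in range(n - 2, -1, -1):
            j = int(back[t][j])
            path[t] = j
        # local clone indices -> global state ids
        for t in range(n):
            path[t] += blocks[t].start
        return path, logp

    def viterbi_refine(self, sequences, n_iters: int = 10) -> "CSCG":
        """Hard-assignment (Viterbi) re-estimation of the transition matrix.

        Iterates decode -> count -> renormalise until the joint Viterbi
        log probability stops improving; the smoothing pseudocount keeps
        every path finite.  Returns self (refined in place).
        """
        seqs = [np.asarray(s.symbols if isinstance(s, TrialSequence) else s)
                for s in sequences]
        S = self.clone_map.n_states
        prev = -np.inf
        for _ in range(n_iters):
            counts = np.zeros((S, S))
            pi_counts = np.zeros(S)
            total = 0.0
            for seq in seqs:
                path, logp = self.viterbi(seq)
                total += logp
                np.add.at(counts, (path[:-1], path[1:]), 1.0)
                pi_counts[path[0]] += 1.0
            if total <= prev + 1e-12:
                break
            prev = total
            counts += self.pseudocount
            self.T = counts / counts.sum(axis=1, keepdims=True)
            pi_counts += self.pseudocount
            self.pi = pi_counts / pi_counts.sum()
        return self

    # ------------------------------------------------------------------ #
    # analysis products

    def extract_graph(self, sequences, prob_floor: float = 1e-3) -> nx.DiGraph:
        """Transition graph restricted to the clones actually used.

        Nodes are the states on the Viterbi paths of the given trials
        (labelled by emitted symbol); directed edges carry transition
        probabilities >= ``prob_floor`` between used nodes.
        """
        used: set[int] = set()
        for s in sequences:
            path, _ = self.viterbi(np.asarray(
                s.symbols if isinstance(s, TrialSequence) else s))
            used.update(int(p) for p in path)
        g = nx.DiGraph()
        for i in sorted(used):
            g.add_node(i, symbol=self.clone_map.state_symbol(i))
        for i in sorted(used):
            for j in sorted(used):
                if self.T[i, j] >= prob_floor:
                    g.add_edge(i, j, weight=float(self.T[i, j]))
        return g

    def state_occupancy_pv(self, trial: TrialSequence | np.ndarray,
                           mode: str = "posterior") -> PositionPV:
        """Position-by-state occupancy matrix for one trial.

        ``posterior`` uses forward-backward occupancy probabilities
        (rows sum to 1); ``viterbi`` uses a one-hot indicator of the
        decoded path.
        """
        seq = np.asarray(trial.symbols if isinstance(trial, TrialSequence) else trial)
        trial_type = trial.trial_type if isinstance(trial, TrialSequence) else ""
        if mode == "posterior":
            mat = self.forward_backward(seq).gamma
        elif mode == "viterbi":
            path, _ = self.viterbi(seq)
            mat = np.zeros((len(seq), self.clone_map.n_states))
            mat[np.arange(len(seq)), path] = 1.0
        else:
            raise CSCGError(f"unknown occupancy mode {mode!r}")
        return PositionPV(matrix=mat, positions=np.arange(len(seq), dtype=float),
                          trial_type=trial_type, source="cscg")

    # ------------------------------------------------------------------ #
    # serialization

    def to_hdf5(self, path) -> None:
        import h5py
        with h5py.File(path, "w") as f:
            f.create_dataset("T", data=self.T)
            f.create_dataset("pi", data=self.pi)
            f.create_dataset("symbols", data=np.asarray(self.clone_map.symbols))
            f.attrs["clones_per_symbol"] = self.clone_map.clones_per_symbol
            f.attrs["seed"] = self.seed
            f.attrs["pseudocount"] = self.pseudocount

    @classmethod
    def from_hdf5(cls, path) -> "CSCG":
        import h5py
        with h5py.File(path, "r") as f:
            model = cls(list(map(int, f["symbols"][...])),
                        int(f.attrs["clones_per_symbol"]),
                        seed=int(f.attrs["seed"]),
                        pseudocount=float(f.attrs["pseudocount"]))
            model.T = f["T"][...]
            model.pi = f["pi"][...]
        return model


def init_model(alphabet: SymbolAlphabet | list[int], clones_per_symbol: int = 100,
               seed: int = 0) -> CSCG:
    """Convenience constructor mirroring the reference configuration."""
    return CSCG(alphabet, clones_per_symbol, seed)
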