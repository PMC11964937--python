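"""Spiking recurrent network with soft winner-take-all and local Hebbian
plasticity.

K recurrently connected spiking neurons receive feedforward input from n
Poisson input neurons; each of the 8 task symbols drives its own disjoint
group of 12 input neurons (8 x 12 = 96), so stimuli are orthogonal at the
input.  The membrane potential sums exponentially filtered spike trains
(time constant 20 ms) through nonnegative feedforward (W) and recurrent
(V) weights; firing probabilities are a softmax over membrane potentials
(global feedback inhibition -- soft winner-take-all) and spikes are drawn
per 1-ms step with a 10-ms refractory period.  When a neuron spikes, the
weights onto it move by dw = alpha * (exp(-w) * trace - 0.1), clipped at
zero.  No error signal or task objective is used anywhere; this purely
local rule has been proposed as an online approximation of HMM learning,
and here it learns orthogonalized representations of the cue-delay-choice
task from passive exposure to the symbol stream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .tasks import SessionSchedule, TrialSequence
from .repr_analysis import PositionPV


class HebbianError(ValueError):
    pass


@dataclass(frozen=True)
class SpikingNetParams:
    """Network and plasticity constants.

    Times are in milliseconds.  ``ms_per_symbol`` (how long each track
    segment's stimulus is presented) and ``input_rate_hz`` (Poisson rate
    of the 12 active input neurons) are presentation choices.  The
    defaults balance the feedforward drive against the recurrent drive
    (at much higher input rates the feedforward term dominates the
    membrane potential and context never separates the two trial types)
    and keep each symbol within roughly a trace time constant of the
    next, so filtered activity bridges adjacent symbols and recurrent
    chains can carry trial-type context through the grey gaps.
    """

    K: int = 100                 # recurrent neurons
    group_size: int = 12         # input neurons per stimulus
    dt: float = 1.0              # update interval
    tau: float = 20.0            # trace time constant
    refractory: float = 10.0     # no spike within this window
    alpha: float = 0.1           # learning rate
    offset: float = 0.1          # plasticity offset (the constant in dw)
    w_sd: float = 3.5            # feedforward weight init sd
    v_sd: float = 2.5            # recurrent weight init sd
    input_rate_hz: float = 50.0
    ms_per_symbol: float = 30.0


@dataclass
class HebbianResults:
    """Training outcome: the trained network plus probe PVs taken at
    checkpoints (near, far) for the decorrelation trajectory."""

    model: "HebbianRNN"
    checkpoint_trials: list[int]
    checkpoint_pvs: list[tuple[PositionPV, PositionPV]]
    spike_counts: np.ndarray         # total spikes per recurrent neuron

    def summary(self) -> str:
        p = self.model.params
        return "\n".join([
            "Hebbian-RNN fit summary",
            "-----------------------",
            f"neurons:        K={p.K}, inputs n={self.model.n_inputs} "
            f"({self.model.n_symbols} stimuli x {p.group_size})",
            f"trials seen:    {self.checkpoint_trials[-1] if self.checkpoint_trials else 0}",
            f"checkpoints:    {len(self.checkpoint_pvs)}",
            f"total spikes:   {int(self.spike_counts.sum())}",
        ])


class HebbianRNN:
    """Soft-WTA spiking network trained by a local Hebbian rule.

    Parameters
    ----------
    n_symbols : int
        Number of distinct stimuli (8 for the cscg-dialect task).
    params : SpikingNetParams
    seed : int
        Seeds weight initialisation and all spike sampling.
    """

    def __init__(self, n_symbols: int = 8, params: SpikingNetParams | None = None,
                 seed: int = 0):
        self.params = params or SpikingNetParams()
        self.n_symbols = n_symbols
        self.seed = seed
        p = self.params
        self.n_inputs = n_symbols * p.group_size
        rng = np.random.default_rng(seed)
        # weights are kept excitatory throughout; negative initial draws
        # are projected to zero like every later update
        self.W = np.clip(rng.normal(0.0, p.w_sd, (p.K, self.n_inputs)), 0.0, None)
        self.V = np.clip(rng.normal(0.0, p.v_sd, (p.K, p.K)), 0.0, None)
        self.reset_state()
        self._decay = float(np.exp(-p.dt / p.tau))

    # ------------------------------------------------------------------ #
    # dynamics

    def reset_state(self) -> None:
        p = self.params
        self.x_trace = np.zeros(self.n_inputs)
        self.y_trace = np.zeros(p.K)
        self.refr = np.zeros(p.K)
        self.u = np.zeros(p.K)
        self.f = np.full(p.K, 1.0 / p.K)

    def input_group(self, symbol: int) -> slice:
        if not 0 <= symbol < self.n_symbols:
            raise HebbianError(f"symbol {symbol} outside the {self.n_symbols}-symbol alphabet")
        g = self.params.group_size
        return slice(symbol * g, (symbol + 1) * g)

    def encode_stimulus(self, symbol: int, rng: np.random.Generator) -> np.ndarray:
        """Input spikes for one dt: Poisson spikes confined to the
        symbol's 12-neuron group."""
        p = self.params
        spikes = np.zeros(self.n_inputs)
        grp = self.input_group(symbol)
        prob = p.input_rate_hz * p.dt / 1000.0
        spikes[grp] = rng.random(p.group_size) < prob
        return spikes

    def step(self, input_spikes: np.ndarray, rng: np.random.Generator,
             plastic: bool = True) -> np.ndarray:
        """Advance the network one dt; returns the recurrent spike vector.

        Membrane potentials read the filtered input trace (including the
        current step's input spikes) and the recurrent trace from the
        previous step; plasticity reads the same traces, i.e. the
        triggering spike's own contribution is excluded.
        """
        p = self.params
        self.x_trace = self.x_trace * self._decay + input_spikes
        y_prev = self.y_trace
        self.u = self.W @ self.x_trace + self.V @ y_prev
        e = np.exp(self.u - self.u.max())
        self.f = e / e.sum()
        eligible = self.refr <= 0
        spikes = (rng.random(p.K) < self.f) & eligible
        if plastic and spikes.any():
            k = np.flatnonzero(spikes)
            self.W[k] = np.clip(
                self.W[k] + p.alpha * (np.exp(-self.W[k]) * self.x_trace - p.offset),
                0.0, None)
            self.V[k] = np.clip(
                self.V[k] + p.alpha * (np.exp(-self.V[k]) * y_prev - p.offset),
                0.0, None)
        self.y_trace = y_prev * self._decay + spikes
        self.refr -= p.dt
        self.refr[spikes] = p.refractory
        return spikes.astype(float)

    # ------------------------------------------------------------------ #
    # sessions

    def run_session(self, schedule: SessionSchedule | list[TrialSequence],
                    seed: int | None = None, plastic: bool = True,
                    record: bool = False):
        """Present a symbol schedule (ms_per_symbol of Poisson drive per
        symbol); deterministic given the seed.

        Returns (position_counts, history): ``position_counts`` maps trial
        type to a (n_positions, K) spike-count matrix summed over trials;
        ``history`` is the full (t, neuron) spike raster if ``record``.
        """
        trials = schedule.trials if isinstance(schedule, SessionSchedule) else list(schedule)
        if not trials:
            raise HebbianError("empty schedule")
        p = self.params
        steps_per_symbol = int(round(p.ms_per_symbol / p.dt))
        if steps_per_symbol < 1:
            raise HebbianError("ms_per_symbol must be >= dt")
        rng = np.random.default_rng(self.seed if seed is None else seed)
        counts: dict[str, np.ndarray] = {}
        trial_counts: dict[str, int] = {}
        history = [] if record else None
        for tr in trials:
            mat = counts.setdefault(tr.trial_type,
                                    np.zeros((len(tr.symbols), p.K)))
            trial_counts[tr.trial_type] = trial_counts.get(tr.trial_type, 0) + 1
            for pos, sym in enumerate(tr.symbols):
                for _ in range(steps_per_symbol):
                    spikes = self.step(self.encode_stimulus(int(sym), rng),
                                       rng, plastic=plastic)
                    mat[pos] += spikes
                    if record:
                        history.append(spikes)
        return counts, (np.asarray(history) if record else None)

    def probe_pv(self, n_reps: int = 5, seed: int = 10_000,
                 dialect: str = "cscg_visual_first") -> tuple[PositionPV, PositionPV]:
        """Trial-averaged spike-count PVs for near and far trials with
        plasticity frozen (the network state is reset first)."""
        from .tasks import make_trial
        self.reset_state()
        trials = []
        for _ in range(n_reps):
            trials.append(make_trial("near", dialect))
            trials.append(make_trial("far", dialect))
        counts, _ = self.run_session(trials, seed=seed, plastic=False)
        pvs = {}
        for tt, mat in counts.items():
            pvs[tt] = PositionPV(mat / n_reps, np.arange(mat.shape[0], dtype=float),
                                 trial_type=tt, source="hebbian")
        return pvs["near"], pvs["far"]

    def fit(self, schedule: SessionSchedule, checkpoint_every: int = 20,
            probe_reps: int = 5) -> HebbianResults:
        """Expose the network to a trial schedule under the plasticity
        rule, probing representation PVs every ``checkpoint_every`` trials."""
        trials = schedule.trials
        if not trials:
            raise HebbianError("empty schedule")
        ck_trials, ck_pvs = [0], [self.probe_pv(probe_reps)]
        total = np.zeros(self.params.K)
        rng_offset = 1
        for start in range(0, len(trials), checkpoint_every):
            chunk = trials[start:start + checkpoint_every]
            self.reset_state()
            counts, _ = self.run_session(chunk, seed=self.seed + rng_offset)
            rng_offset += 1
            for mat in counts.values():
                total += mat.sum(axis=0)
            ck_trials.append(min(start + checkpoint_every, len(trials)))
            ck_pvs.append(self.probe_pv(probe_reps))
        return HebbianResults(self, ck_trials, ck_pvs, total)

    # ------------------------------------------------------------------ #
    # serialization

    def to_hdf5(self, path) -> None:
        import h5py
        with h5py.File(path, "w") as f:
            f.create_dataset("W", data=self.W)
            f.create_dataset("V", data=self.V)
            f.attrs["seed"] = self.seed
            f.attrs["n_symbols"] = self.n_symbols
            for k, v in self.params.__dict__.items():
                f.attrs[f"param_{k}"] = v

    @classmethod
    def from_hdf5(cls, path) -> "HebbianRNN":
        import h5py
        with h5py.File(path, "r") as f:
            raw = {k[len("param_"):]: v for k, v in f.attrs.items()
                   if k.startswith("param_")}
            raw["K"] = int(raw["K"])
            raw["group_size"] = int(raw["group_size"])
            net = cls(int(f.attrs["n_symbols"]), SpikingNetParams(**raw),
                      seed=int(f.attrs["seed"]))
            net.W = f["W"][...]
            net.V = f["V"][...]
        return net


def representation_pv(position_counts: dict[str, np.ndarray], trial_type: str,
                      n_trials: int) -> PositionPV:
    """Trial-averaged spike-count PV from a recorded session."""
    if trial_type not in position_counts:
        raise HebbianError(f"no complete {trial_type} trial in history")
    mat = position_counts[trial_type] / max(n_trials, 1)
    return PositionPV(mat, np.arange(mat.shape[0], dtype=float),
                      trial_type=trial_type, source="hebbian")
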