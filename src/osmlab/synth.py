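"""Ground-truthed synthetic sessions: trajectories, stage-dependent
licking and calcium-like dF/F.

The generator emulates the statistical structure the analysis modules
assume, with a known ground truth so every pipeline stage has a recovery
test.  Behaviour passes through four licking-strategy stages (random,
both-rewards, lick-stop, expert).  Neural tuning passes through
representation stages: 0 unstructured, 1 sensory (cells tuned to a cue
class; grey-tuned cells respond in all four grey regions), 2 within-track
decorrelated (grey cells collapse to one region, still shared across
trial types), 3 pre-R2 split (trial-type-specific tuning before the far
reward), and expert (fully split, with a planted
splitter/place/remapping-splitter mixture).  Rates become Poisson events,
convolved with a GCaMP-like exponential kernel, scaled onto a baseline
and corrupted with Gaussian noise at 10 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .neural import CalciumSession
from .tasks import TRACK_CM, STRETCHED_TRACK_CM, sample_session

STAGES = ("0", "1", "2", "3", "expert")
#: strategy used by the behaviour generator at each representation stage
STAGE_STRATEGY = {"0": "random", "1": "both_rewards", "2": "lick_stop",
                  "3": "expert", "expert": "expert"}

GREY_CENTERS = (30.0, 115.0, 165.0, 210.0)       # initial, pre-R1, pre-R2, end
GREY_REGIONS_CM = ((0.0, 60.0), (100.0, 130.0), (150.0, 180.0), (200.0, 220.0))
INDICATOR_CM = (60.0, 100.0)
R1_CM = (130.0, 150.0)
R2_CM = (180.0, 200.0)


class SynthError(ValueError):
    pass


@dataclass
class SynthConfig:
    """Generator settings; defaults give a high-SNR expert-like session."""

    n_cells: int = 400
    stage: str = "expert"
    #: planted phenotype mixture at the fully split stage
    mixture: dict = field(default_factory=lambda: {
        "splitter": 0.6, "place": 0.3, "remapping_splitter": 0.1})
    frame_rate: float = 10.0
    run_speed: float = 30.0          # cm/s
    reward_pause_s: float = 1.0      # slow-down at rewarded zone
    teleport_s: float = 2.0          # dark gap between trials
    event_rate_hz: float = 5.0       # in-field Poisson event rate
    tuning_sd_cm: float = 10.0
    decay_s: float = 0.7             # calcium kernel decay (GCaMP6f-like)
    rise_s: float = 0.05             # sub-frame at 10 Hz; folded into the kernel
    noise_sd: float = 0.03           # dF/F units
    baseline_f: float = 100.0
    licks_per_trial: float = 12.0
    lick_noise_floor: float = 0.05   # fraction of licks placed uniformly
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.mixture.values()) - 1.0) > 1e-9:
            raise SynthError("mixture fractions must sum to 1")
        if self.stage not in STAGES:
            raise SynthError(f"unknown stage {self.stage!r}")


@dataclass
class GroundTruth:
    """Everything needed to score recovery without re-deriving."""

    category: list[str]              # per-cell phenotype at the split stage
    center: np.ndarray               # per-cell home position (cm)
    center_far: np.ndarray           # remapping cells move here on far trials
    gain_near: np.ndarray
    gain_far: np.ndarray
    strategy: str                    # planted licking strategy
    stage: str
    trial_strategy: list[str] = field(default_factory=list)
    #: per-cell overall rate gain (lognormal), shared across regions and
    #: trial types
    amplitude: np.ndarray | None = None
    #: per-cell dF/F per event (expression-level diversity); unlike the
    #: rate gain it is not normalised away by the baseline filter, so it
    #: is the main carrier of cross-region PV correlation
    event_amp: np.ndarray | None = None
    #: scattered firing locations used at the unstructured stage
    multi_centers: np.ndarray | None = None


# ---------------------------------------------------------------------- #
# behaviour

def _strategy_zones(strategy: str, trial_type: str) -> list[tuple[float, float]]:
    lead = 20.0
    z1 = (R1_CM[0] - lead, R1_CM[1])
    z2 = (R2_CM[0] - lead, R2_CM[1])
    if strategy == "random":
        return [(0.0, TRACK_CM)]
    if strategy == "both_rewards":
        return [z1, z2]
    if strategy == "lick_stop":
        return [z1] if trial_type == "near" else [z1, z2]
    if strategy == "expert":
        return [z1] if trial_type == "near" else [z2]
    raise SynthError(f"unknown strategy {strategy!r}")


def simulate_behavior(config: SynthConfig, n_trials: int = 60,
                      strategy: str | None = None,
                      stretched_every: bool = False,
                      seed: int | None = None) -> dict:
    """Position/speed/lick traces for one session.

    The animal runs at ``run_speed`` with jitter, slows at its licking
    zones, and is teleported (2 s of inter-trial gap, trial_id -1)
    after each trial.  Licks are drawn from the active strategy's zones
    plus a uniform noise floor.
    """
    strategy = strategy or STAGE_STRATEGY[config.stage]
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    schedule = sample_session(n_trials, seed=seed, dialect="rnn",
                              stretched_every=stretched_every)
    dt = 1.0 / config.frame_rate
    pos_l, spd_l, lick_l, tid_l = [], [], [], []
    trial_types, trial_variants = {}, {}
    lick_records = []                # (trial_id, position)
    for tid, trial in enumerate(schedule.trials):
        tt = trial.trial_type
        trial_types[tid] = tt
        trial_variants[tid] = trial.variant
        track = STRETCHED_TRACK_CM if trial.variant == "stretched" else TRACK_CM
        zones = _strategy_zones(strategy, tt)
        if trial.variant == "stretched":
            # reward zones move with the stretched geometry
            shift = 50.0
            zones = [(lo + shift, hi + shift) for lo, hi in zones]
        n_licks = rng.poisson(config.licks_per_trial)
        lick_pos = []
        for _ in range(n_licks):
            if rng.random() < config.lick_noise_floor:
                lick_pos.append(rng.uniform(0, track))
            else:
                lo, hi = zones[rng.integers(len(zones))]
                lick_pos.append(rng.uniform(lo, hi))
        lick_pos = np.sort(lick_pos)
        lick_records.append((tid, np.asarray(lick_pos)))
        # integrate position; slow down inside licking zones
        p = 0.0
        next_lick = 0
        while p < track:
            in_zone = any(lo <= p < hi for lo, hi in zones)
            v = config.run_speed * (0.3 if in_zone else 1.0)
            v = max(v + rng.normal(0, 2.0), 6.0)
            lick_here = next_lick < len(lick_pos) and p >= lick_pos[next_lick]
            if lick_here:
                next_lick += 1
            pos_l.append(min(p, track - 1e-6))
            spd_l.append(v)
            lick_l.append(lick_here)
            tid_l.append(tid)
            p += v * dt
        gap = int(round(config.teleport_s * config.frame_rate))
        pos_l.extend([track - 1e-6] * gap)
        spd_l.extend([0.0] * gap)
        lick_l.extend([False] * gap)
        tid_l.extend([-1] * gap)
    return {
        "position": np.asarray(pos_l), "speed": np.asarray(spd_l),
        "licks": np.asarray(lick_l, dtype=bool), "trial_id": np.asarray(tid_l),
        "trial_types": trial_types, "trial_variants": trial_variants,
        "licks_by_trial": lick_records, "strategy": strategy,
        "schedule": schedule,
    }


# ---------------------------------------------------------------------- #
# neural

def _assign_cells(config: SynthConfig, rng) -> GroundTruth:
    """Sample persistent per-cell identities: phenotype, home position and
    trial-type gains at the split stage.

    Place cells concentrate at the track start/end (where representations
    stay correlated even in experts); splitter and remapping cells occupy
    the middle (indicator through reward regions).
    """
    cats = rng.choice(list(config.mixture), size=config.n_cells,
                      p=list(config.mixture.values()))
    center = np.empty(config.n_cells)
    center_far = np.empty(config.n_cells)
    gain_n = np.ones(config.n_cells)
    gain_f = np.ones(config.n_cells)
    for i, cat in enumerate(cats):
        if cat == "place":
            # mostly start/end, some anywhere
            if rng.random() < 0.85:
                center[i] = rng.uniform(0, 60) if rng.random() < 0.5 \
                    else rng.uniform(200, 225)
            else:
                center[i] = rng.uniform(0, 225)
            center_far[i] = center[i]
        elif cat == "splitter":
            center[i] = rng.uniform(60, 195)
            center_far[i] = center[i]
            if rng.random() < 0.5:
                gain_f[i] = rng.uniform(0.0, 0.15)
            else:
                gain_n[i] = rng.uniform(0.0, 0.15)
        else:                       # remapping splitter: same amplitude,
            center[i] = rng.uniform(60, 195)        # different position
            shift = rng.uniform(30, 80) * (1 if rng.random() < 0.5 else -1)
            center_far[i] = float(np.clip(center[i] + shift, 5, 225))
    amp = rng.lognormal(0.0, 0.4, config.n_cells)
    event_amp = rng.lognormal(0.0, 1.1, config.n_cells)
    multi = rng.uniform(5.0, 225.0, (config.n_cells, 5))
    return GroundTruth(list(cats), center, center_far, gain_n, gain_f,
                       STAGE_STRATEGY[config.stage], config.stage,
                       amplitude=amp, event_amp=event_amp, multi_centers=multi)


def _rate_curve(config: SynthConfig, truth: GroundTruth, cell: int,
                trial_type: str, stage: str, positions: np.ndarray) -> np.ndarray:
    """Instantaneous event rate (Hz) of one cell along the track."""
    sd = config.tuning_sd_cm

    def bump(c, gain=1.0, width=sd):
        return gain * np.exp(-0.5 * ((positions - c) / width) ** 2)

    c_near = truth.center[cell]
    amp = truth.amplitude[cell] if truth.amplitude is not None else 1.0
    type_gain = (truth.gain_near[cell] if trial_type == "near"
                 else truth.gain_far[cell])

    def plateau(lo, hi, gain=1.0, edge=10.0):
        rise = np.clip((positions - lo + edge / 2) / edge, 0.0, 1.0)
        fall = np.clip((hi + edge / 2 - positions) / edge, 0.0, 1.0)
        return gain * rise * fall

    home_indicator = INDICATOR_CM[0] <= c_near < INDICATOR_CM[1]
    home_reward = (R1_CM[0] <= c_near < R1_CM[1]
                   or R2_CM[0] <= c_near < R2_CM[1])

    if home_indicator and stage != "expert":
        # the indicator cue differs between trial types, so cue-driven
        # cells split from the first session (sensory, not learned)
        r = plateau(*INDICATOR_CM, gain=type_gain)
    elif stage == "0":
        # unstructured: firing at scattered locations across the track,
        # identical across trial types -> high correlation everywhere
        r = sum(bump(c, 0.8) for c in truth.multi_centers[cell])
    elif stage == "1":
        # sensory: grey-tuned cells fire across all four grey regions
        # (with a mild home preference); reward-cue cells fire at both
        # visually identical reward zones
        if home_reward:
            r = plateau(*R1_CM) + plateau(*R2_CM)
        else:
            r = sum(plateau(lo, hi, 1.0 if lo <= c_near < hi else 0.95)
                    for lo, hi in GREY_REGIONS_CM)
    elif stage == "2":
        # within-track decorrelated, still shared across trial types
        r = bump(c_near, 1.0)
    else:
        split_r1 = stage == "expert"          # stage 3 splits only pre-R2/R2
        c_far = truth.center_far[cell]
        c = c_near if trial_type == "near" else c_far
        in_far_half = c_near >= 150.0
        in_near_half = 60.0 <= c_near < 150.0
        if in_far_half or (split_r1 and in_near_half):
            r = bump(c, type_gain)
        else:
            r = bump(c_near, 1.0)             # not yet split: shared tuning
    return config.event_rate_hz * amp * r


def _sparsify_early_stage(config: SynthConfig, truth: GroundTruth,
                          rates: np.ndarray, pos: np.ndarray,
                          tid: np.ndarray, rng) -> None:
    """Per-trial expression sparsity for the unstructured/sensory stages.

    Each cell expresses each of its firing locations on only ~half the
    trials.  Without this, broadly active cells are elevated most of the
    session, the rolling-minimum baseline swallows their sustained
    component, and dF/F turns into a high-pass of the tuning curve --
    sparse, trial-variable firing is what real early-learning data look
    like and what keeps the baseline estimate honest.
    """
    p_express = 0.65
    sd = config.tuning_sd_cm
    for t in np.unique(tid):
        if t < 0:
            continue
        tf = np.flatnonzero(tid == t)
        ptf = pos[tf]
        if config.stage == "0":
            for j in range(truth.multi_centers.shape[1]):
                silent = rng.random(config.n_cells) >= p_express
                win = np.abs(ptf[None, :] - truth.multi_centers[:, j][:, None]) < 2 * sd
                rates[np.ix_(silent, tf)] *= ~win[silent]
        else:
            for lo, hi in GREY_REGIONS_CM:
                silent = rng.random(config.n_cells) >= p_express
                win = (ptf >= lo - 5) & (ptf < hi + 5)
                rates[np.ix_(silent, tf[win])] = 0.0


def simulate_neural(config: SynthConfig, behavior: dict,
                    noise_seed: int | None = None
                    ) -> tuple[CalciumSession, GroundTruth]:
    """Poisson events through a calcium kernel on top of the behaviour.

    Cell identities always derive from ``config.seed`` (so they persist
    across the sessions of a learning course); ``noise_seed`` varies the
    Poisson events and measurement noise per session.
    """
    truth = _assign_cells(config, np.random.default_rng(config.seed + 1))
    rng = np.random.default_rng(config.seed + 2 if noise_seed is None else noise_seed)
    truth.trial_strategy = [behavior["strategy"]] * len(behavior["trial_types"])
    pos = behavior["position"]
    tid = behavior["trial_id"]
    n_frames = len(pos)
    ttypes = behavior["trial_types"]
    rates = np.zeros((config.n_cells, n_frames))
    frame_type = np.array([ttypes.get(t, "") for t in tid])
    for tt in ("near", "far"):
        m = frame_type == tt
        if not m.any():
            continue
        for cell in range(config.n_cells):
            rates[cell, m] = _rate_curve(config, truth, cell, tt,
                                         config.stage, pos[m])
    if config.stage in ("0", "1"):
        _sparsify_early_stage(config, truth, rates, pos, tid, rng)
    events = rng.poisson(rates / config.frame_rate)
    # kernel: difference of exponentials, unit peak, sampled at frame rate
    t = np.arange(0, 5 * config.decay_s, 1.0 / config.frame_rate)
    kern = (1 - np.exp(-np.maximum(t, 1e-9) / config.rise_s)) * np.exp(-t / config.decay_s)
    if kern.max() > 0:
        kern /= kern.max()
    dff = np.apply_along_axis(lambda row: np.convolve(row, kern)[:n_frames],
                              1, events.astype(float))
    if truth.event_amp is not None:
        dff *= truth.event_amp[:, None]
    dff += rng.normal(0, config.noise_sd, dff.shape)
    F = config.baseline_f * (1.0 + dff)
    session = CalciumSession(
        F=F, frame_rate=config.frame_rate, position=pos,
        speed=behavior["speed"], licks=behavior["licks"], trial_id=tid,
        trial_types=dict(ttypes), trial_variants=dict(behavior["trial_variants"]),
        track_cm=TRACK_CM)
    return session, truth


def simulate_session(config: SynthConfig, n_trials: int = 60,
                     stretched_every: bool = False, behavior_seed: int | None = None,
                     noise_seed: int | None = None
                     ) -> tuple[CalciumSession, GroundTruth, dict]:
    """Behaviour + neural data for one stage in one call."""
    behavior = simulate_behavior(config, n_trials, stretched_every=stretched_every,
                                 seed=behavior_seed)
    session, truth = simulate_neural(config, behavior, noise_seed=noise_seed)
    return session, truth, behavior


def simulate_learning_course(config: SynthConfig | None = None,
                             stage_schedule: tuple[str, ...] = STAGES,
                             n_trials: int = 60) -> list[tuple[CalciumSession, GroundTruth, dict]]:
    """One session per stage with persistent cell identities.

    The planted course decorrelates the off-diagonal grey pairs first
    (stage 2), then pre-R2 (stage 3), then pre-R1 (expert) -- the same
    order the analysis should recover.  The same seed gives identical
    datasets.
    """
    config = config or SynthConfig()
    out = []
    for k, stage in enumerate(stage_schedule):
        if stage not in STAGES:
            raise SynthError(f"unknown stage {stage!r}")
        cfg = SynthConfig(**{**config.__dict__, "stage": stage,
                             "mixture": dict(config.mixture)})
        # cell identities persist (same config seed); behaviour and noise vary
        out.append(simulate_session(cfg, n_trials,
                                    behavior_seed=config.seed + 10 * (k + 1),
                                    noise_seed=config.seed + 10 * (k + 1) + 1))
    return out
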