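"""Symbolic two-alternative cue-delay-choice (2ACDC) task generation.

The task is a 230-cm virtual linear track discretised into 10-cm segments,
each emitting one sensory symbol per time step.  An indicator cue (40 cm)
at the start of the track predicts which of two visually identical reward
zones (R1 "near" at 130-150 cm, R2 "far" at 180-200 cm) delivers water.
Everything else is featureless grey, which makes the four grey regions
sensorially ambiguous within and across trial types.

Two symbol dialects exist.  The ``rnn`` dialect (7 symbols, 23 steps per
trial) is consumed by the gradient-trained networks; the ``cscg`` dialects
(8 symbols, 26 steps, the trial ends with a wall symbol and three teleport
symbols) are consumed by the cloned HMM and the spiking network.  Variant
dialects permute or merge the reward-zone symbols, and the ``stretched``
variant lengthens the two pre-reward grey gaps from 3 to 8 segments
(330-cm track).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np

# symbol ids shared by all dialects
TELEPORT, GREY, NEAR_IND, FAR_IND, R1_VISUAL, R2_VISUAL, WATER, WALL = range(8)

SEGMENT_CM = 10.0
TRACK_CM = 230.0
STRETCHED_TRACK_CM = 330.0

DIALECTS = ("rnn", "cscg_visual_first", "cscg_water_first", "cscg_conjunctive")
NOVEL_PAIRS = ("B", "C", "D", "E")

_SYMBOL_LABELS = {
    TELEPORT: "teleport",
    GREY: "grey",
    NEAR_IND: "near_indicator",
    FAR_IND: "far_indicator",
    R1_VISUAL: "r1_visual",
    R2_VISUAL: "r2_visual",
    WATER: "water",
    WALL: "wall",
}


class TaskConfigError(ValueError):
    """Raised for unknown dialects/variants or invalid sampling parameters."""


@dataclass(frozen=True)
class SymbolAlphabet:
    """Set of integer symbol ids with semantic labels for one dialect."""

    dialect: str
    labels: dict[int, str]

    @property
    def symbols(self) -> list[int]:
        return sorted(self.labels)

    @property
    def n_symbols(self) -> int:
        return len(self.labels)

    def to_json(self) -> str:
        return json.dumps({"dialect": self.dialect,
                           "labels": {str(k): v for k, v in sorted(self.labels.items())}})


def alphabet(dialect: str = "rnn", novel_pair: str | None = None) -> SymbolAlphabet:
    """Return the symbol alphabet of a dialect.

    ``rnn`` uses 7 symbols (0-6; no wall symbol), the cscg dialects use 8
    (0-7).  The conjunctive dialect additionally carries id 8, the combined
    water + R2-visual code (id 6 is reused as the combined water + R1 code),
    so its id range is 0-8.  Novel indicator pairs (B-E) add two fresh ids
    replacing the indicator symbols only.
    """
    if dialect not in DIALECTS:
        raise TaskConfigError(f"unknown dialect {dialect!r}")
    if dialect == "rnn":
        labels = {k: v for k, v in _SYMBOL_LABELS.items() if k != WALL}
        labels[R1_VISUAL] = "r1_visual"
    else:
        labels = dict(_SYMBOL_LABELS)
    if dialect == "cscg_conjunctive":
        labels[WATER] = "water_r1_conjunctive"
        labels[8] = "water_r2_conjunctive"
    if novel_pair is not None:
        near_id, far_id = novel_indicator_ids(dialect, novel_pair)
        del labels[NEAR_IND], labels[FAR_IND]
        labels[near_id] = f"near_indicator_{novel_pair}"
        labels[far_id] = f"far_indicator_{novel_pair}"
    return SymbolAlphabet(dialect, labels)


def novel_indicator_ids(dialect: str, pair: str) -> tuple[int, int]:
    """Fresh symbol-id pair substituted in the indicator block for pair B-E."""
    if pair not in NOVEL_PAIRS:
        raise TaskConfigError(f"unknown novel indicator pair {pair!r}")
    base = {"rnn": 7, "cscg_visual_first": 8, "cscg_water_first": 8,
            "cscg_conjunctive": 9}[dialect]
    k = NOVEL_PAIRS.index(pair)
    return base + 2 * k, base + 2 * k + 1


@dataclass(frozen=True)
class TrialSequence:
    """One symbolic trial: one symbol per 10-cm track segment."""

    symbols: tuple[int, ...]
    trial_type: str                      # "near" | "far"
    dialect: str
    variant: str = "standard"            # "standard" | "stretched" | "novel_B".."novel_E"

    def __len__(self) -> int:
        return len(self.symbols)

    @property
    def segment_positions(self) -> np.ndarray:
        """Per-symbol track position in cm (0-based, half-open 10-cm bins)."""
        return np.arange(len(self.symbols)) * SEGMENT_CM

    @property
    def regions(self) -> dict[str, list[int]]:
        return segment_regions(self.variant, self.dialect)


def segment_regions(variant: str = "standard", dialect: str = "rnn") -> dict[str, list[int]]:
    """Canonical mapping of named track regions to segment indices.

    Standard layout (cm): 0-60 initial grey, 60-100 indicator, 100-130
    pre-R1 grey, 130-150 R1, 150-180 pre-R2 grey, 180-200 R2, 200-220 end
    grey, then wall/teleport.  The stretched variant widens both pre-reward
    gaps to 80 cm, placing R1 at 180-200 cm and R2 at 280-300 cm.
    """
    stretched = variant == "stretched"
    gap = 8 if stretched else 3
    r = {}
    i = 0
    for name, width in (("initial", 6), ("indicator", 4), ("pre_r1", gap),
                        ("r1", 2), ("pre_r2", gap), ("r2", 2), ("end", 2)):
        r[name] = list(range(i, i + width))
        i += width
    if dialect == "rnn":
        r["teleport"] = [i]
    else:
        r["wall"] = [i]
        r["teleport"] = [i + 1, i + 2, i + 3]
    return r


def _reward_zone_symbols(trial_type: str, dialect: str) -> tuple[tuple[int, int], tuple[int, int]]:
    """(R1 pair, R2 pair) of symbols for a trial type under a dialect.

    In the visual-first encoding the reward-zone visual cue is seen one
    segment ahead of the water symbol; the water-first variant swaps the
    order in the rewarded zone; the conjunctive variant merges water and
    reward visual into a single combined code in the rewarded zone.
    """
    near = trial_type == "near"
    if dialect in ("rnn", "cscg_visual_first"):
        return ((R1_VISUAL, WATER), (R2_VISUAL, R2_VISUAL)) if near else \
               ((R1_VISUAL, R1_VISUAL), (R2_VISUAL, WATER))
    if dialect == "cscg_water_first":
        return ((WATER, R1_VISUAL), (R2_VISUAL, R2_VISUAL)) if near else \
               ((R1_VISUAL, R1_VISUAL), (WATER, R2_VISUAL))
    if dialect == "cscg_conjunctive":
        # 6 = combined water+R1 code, 8 = combined water+R2 code
        return ((R1_VISUAL, 6), (R2_VISUAL, R2_VISUAL)) if near else \
               ((R1_VISUAL, R1_VISUAL), (R2_VISUAL, 8))
    raise TaskConfigError(f"unknown dialect {dialect!r}")


def make_trial(trial_type: str, dialect: str = "rnn", variant: str = "standard") -> TrialSequence:
    """Build the symbolic sequence of one trial.

    Standard rnn trials are 23 symbols long, standard cscg trials 26
    (ending wall, teleport x3).  ``variant`` may be ``standard``,
    ``stretched`` (rnn dialect only) or ``novel_B`` .. ``novel_E``.
    """
    if trial_type not in ("near", "far"):
        raise TaskConfigError(f"unknown trial type {trial_type!r}")
    if dialect not in DIALECTS:
        raise TaskConfigError(f"unknown dialect {dialect!r}")
    novel_pair = None
    if variant.startswith("novel_"):
        novel_pair = variant.split("_", 1)[1]
        if novel_pair not in NOVEL_PAIRS:
            raise TaskConfigError(f"unknown variant {variant!r}")
    elif variant == "stretched":
        if dialect != "rnn":
            raise TaskConfigError(
                "stretched trials are defined for the rnn dialect only")
    elif variant != "standard":
        raise TaskConfigError(f"unknown variant {variant!r}")

    gap = 8 if variant == "stretched" else 3
    if novel_pair is None:
        ind = NEAR_IND if trial_type == "near" else FAR_IND
    else:
        near_id, far_id = novel_indicator_ids(dialect, novel_pair)
        ind = near_id if trial_type == "near" else far_id
    (rz1, rz2) = _reward_zone_symbols(trial_type, dialect)

    seq = [GREY] * 6 + [ind] * 4 + [GREY] * gap + list(rz1) + \
          [GREY] * gap + list(rz2) + [GREY] * 2
    if dialect == "rnn":
        seq += [TELEPORT]
    else:
        seq += [WALL, TELEPORT, TELEPORT, TELEPORT]
    return TrialSequence(tuple(seq), trial_type, dialect, variant)


@dataclass
class SessionSchedule:
    """An ordered list of trials sampled for one session."""

    trials: list[TrialSequence]
    lam: float
    max_repeats: int
    seed: int

    @property
    def trial_types(self) -> list[str]:
        return [t.trial_type for t in self.trials]

    def __len__(self) -> int:
        return len(self.trials)

    def symbol_stream(self) -> np.ndarray:
        """All trial symbols concatenated into one 1-D array."""
        return np.concatenate([np.asarray(t.symbols) for t in self.trials])

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["trial_id", "t", "symbol", "label", "position_cm"])
            for i, tr in enumerate(self.trials):
                labels = alphabet(tr.dialect,
                                  tr.variant.split("_")[1] if tr.variant.startswith("novel_") else None).labels
                for t, (s, p) in enumerate(zip(tr.symbols, tr.segment_positions)):
                    w.writerow([i, t, s, labels.get(s, str(s)), p])

    def manifest(self) -> dict:
        return {"n_trials": len(self), "lambda": self.lam,
                "max_repeats": self.max_repeats, "seed": self.seed,
                "trial_types": self.trial_types,
                "variants": [t.variant for t in self.trials]}


def _truncated_poisson(rng: np.random.Generator, lam: float, max_repeats: int) -> int:
    """Poisson(lam) draw conditioned on the range [1, max_repeats]."""
    while True:
        k = int(rng.poisson(lam))
        if 1 <= k <= max_repeats:
            return k


def sample_session(n_trials: int, lam: float = 0.7, max_repeats: int = 3,
                   seed: int = 0, dialect: str = "rnn", variant: str = "standard",
                   stretched_every: bool = False) -> SessionSchedule:
    """Sample a trial schedule with limited-Poisson run lengths.

    Runs of identical trial types have lengths drawn from Poisson(lam)
    truncated to [1, max_repeats]; types alternate between runs, so neither
    type can repeat more than ``max_repeats`` times and long-run frequency
    of each type is 1/2.  With ``stretched_every`` set, every 5th/6th trial
    (alternating deterministically) is replaced by its stretched variant.
    """
    if n_trials < 1:
        raise TaskConfigError("n_trials must be >= 1")
    if max_repeats < 1:
        raise TaskConfigError("max_repeats must be >= 1")
    rng = np.random.default_rng(seed)
    types: list[str] = []
    current = "near" if rng.random() < 0.5 else "far"
    while len(types) < n_trials:
        run = _truncated_poisson(rng, lam, max_repeats)
        types.extend([current] * min(run, n_trials - len(types)))
        current = "far" if current == "near" else "near"
    trials = [make_trial(tt, dialect, variant) for tt in types]
    if stretched_every:
        interval, i = 5, 4
        while i < len(trials):
            trials[i] = make_trial(trials[i].trial_type, dialect, "stretched")
            interval = 11 - interval            # alternate 5 and 6
            i += interval
    return SessionSchedule(trials, lam, max_repeats, seed)


@dataclass
class ContextMap:
    """All length-L within-trial contexts and their observed next symbols.

    ``entries`` maps a context tuple to a dict with the observed next
    symbols, per-trial-type provenance, and whether the next symbol is
    trial-type-determined (a reward-zone position) rather than inherently
    random (indicator onset, trial boundary).
    """

    L: int
    entries: dict[tuple[int, ...], dict]

    def ambiguous_contexts(self) -> list[tuple[int, ...]]:
        """Determined contexts whose next symbol differs across trial types."""
        out = []
        for ctx, e in self.entries.items():
            d = e["determined_next"]
            if len(d) < 2:
                continue
            near, far = d.get("near", set()), d.get("far", set())
            if any(a != b for a in near for b in far):
                out.append(ctx)
        return out


def context_ambiguity(sequences: Sequence[TrialSequence], L_max: int = 10
                      ) -> tuple[dict[int, ContextMap], int]:
    """Exhaustive n-gram analysis of trial sequences.

    For every L in 1..L_max, enumerate all within-trial length-L contexts
    (no wrap across the teleport boundary) and collect the next symbols
    following each context.  A position is *trial-type-determined* when it
    lies in a reward zone: there the next symbol is a function of trial type
    given full within-trial history, unlike the indicator onset or the
    post-teleport trial start which are sampled at random.  Returns the map
    per L and the largest L at which some determined context still maps to
    different next symbols in near versus far trials (0 if none).
    """
    if not sequences:
        raise TaskConfigError("need at least one sequence")
    if L_max < 1:
        raise TaskConfigError("L_max must be >= 1")
    maps: dict[int, ContextMap] = {}
    max_ambiguous_L = 0
    for L in range(1, L_max + 1):
        entries: dict[tuple[int, ...], dict] = {}
        for seq in sequences:
            reward_zone = set(seq.regions["r1"]) | set(seq.regions["r2"])
            syms = seq.symbols
            for nxt in range(L, len(syms)):
                ctx = tuple(syms[nxt - L:nxt])
                e = entries.setdefault(ctx, {"next_symbols": set(),
                                             "trial_types": set(),
                                             "determined": False,
                                             "determined_next": {}})
                e["next_symbols"].add(syms[nxt])
                e["trial_types"].add(seq.trial_type)
                if nxt in reward_zone:
                    e["determined"] = True
                    e["determined_next"].setdefault(seq.trial_type, set()).add(syms[nxt])
        cmap = ContextMap(L, entries)
        if cmap.ambiguous_contexts():
            max_ambiguous_L = L
        maps[L] = cmap
    return maps, max_ambiguous_L
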