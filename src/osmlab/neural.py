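"""Calcium-trace analysis: dF/F baseline, transients, tuning curves,
place fields, dispersion entropy and splitter-cell metrics.

The processing chain mirrors standard two-photon practice for GCaMP
recordings at 10 Hz: a slow baseline F0 is estimated by Gaussian
smoothing followed by a rolling-max-of-rolling-min ("maximin") filter,
dF/F = (F - F0)/F0, and significant transients are epochs that rise 5
baseline noise sd above zero and last until they return within 1 sd.
Positional tuning uses 5-cm bins, frames with running speed > 5 cm/s,
and "active" trials only (licking in a reward zone).  Place-field
significance uses a circular 10-s block shuffle of activity against
position.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d, maximum_filter1d, minimum_filter1d

from .tasks import TRACK_CM, STRETCHED_TRACK_CM

BIN_CM = 5.0
SPEED_THRESHOLD = 5.0        # cm/s; slower frames are excluded
FIELD_WIDTH_CM = (15.0, 120.0)
IN_OUT_RATIO = 4.0
TRANSIENT_OCCUPANCY = 0.2
SHUFFLE_BLOCK_S = 10.0
TRANSIENT_ONSET_SD = 5.0
TRANSIENT_OFFSET_SD = 1.0

#: reward-zone cm windows (standard layout), used for "active trial" licking
REWARD_ZONES_CM = {"r1": (130.0, 150.0), "r2": (180.0, 200.0)}


class NeuralError(ValueError):
    pass


@dataclass
class CalciumSession:
    """Time-aligned imaging session container.

    ``F`` is cells x frames raw fluorescence; position/speed/licks are
    per-frame; ``trial_id`` maps frames to trials and the two dicts map
    trial ids to their type (near/far) and variant (standard/stretched).
    """

    F: np.ndarray
    frame_rate: float
    position: np.ndarray          # cm
    speed: np.ndarray             # cm/s
    licks: np.ndarray             # boolean per frame
    trial_id: np.ndarray          # int per frame (-1 = inter-trial)
    trial_types: dict[int, str]
    trial_variants: dict[int, str] = field(default_factory=dict)
    track_cm: float = TRACK_CM

    def __post_init__(self):
        n = self.F.shape[1]
        for name in ("position", "speed", "licks", "trial_id"):
            if len(getattr(self, name)) != n:
                raise NeuralError(f"{name} not aligned with F ({n} frames)")

    @property
    def n_cells(self) -> int:
        return self.F.shape[0]

    def active_trials(self) -> set[int]:
        """Trials with at least one lick inside either reward zone."""
        ok = set()
        for tid in self.trial_types:
            m = (self.trial_id == tid) & self.licks.astype(bool)
            pos = self.position[m]
            for lo, hi in REWARD_ZONES_CM.values():
                if np.any((pos >= lo) & (pos < hi)):
                    ok.add(tid)
                    break
        return ok

    def to_hdf5(self, path) -> None:
        import h5py
        with h5py.File(path, "w") as f:
            for name in ("F", "position", "speed", "licks", "trial_id"):
                f.create_dataset(name, data=np.asarray(getattr(self, name)))
            f.attrs["frame_rate"] = self.frame_rate
            f.attrs["track_cm"] = self.track_cm
            ids = sorted(self.trial_types)
            f.create_dataset("trial_ids", data=np.asarray(ids))
            f.create_dataset("trial_type_codes", data=np.asarray(
                [1 if self.trial_types[i] == "near" else 2 for i in ids]))
            f.create_dataset("trial_variant_codes", data=np.asarray(
                [1 if self.trial_variants.get(i, "standard") == "standard" else 2
                 for i in ids]))

    @classmethod
    def from_hdf5(cls, path) -> "CalciumSession":
        import h5py
        with h5py.File(path, "r") as f:
            ids = [int(i) for i in f["trial_ids"][...]]
            tt = {i: ("near" if c == 1 else "far")
                  for i, c in zip(ids, f["trial_type_codes"][...])}
            tv = {i: ("standard" if c == 1 else "stretched")
                  for i, c in zip(ids, f["trial_variant_codes"][...])}
            return cls(F=f["F"][...], frame_rate=float(f.attrs["frame_rate"]),
                       position=f["position"][...], speed=f["speed"][...],
                       licks=f["licks"][...], trial_id=f["trial_id"][...],
                       trial_types=tt, trial_variants=tv,
                       track_cm=float(f.attrs["track_cm"]))


@dataclass
class DffTrace:
    F0: np.ndarray                # cells x frames baseline
    dff: np.ndarray               # cells x frames
    sigma: np.ndarray             # per-cell baseline noise sd (dff units)
    sigma_floored: np.ndarray     # cells where a zero sd was floored


@dataclass
class TransientSet:
    """Per-cell significant transients and a per-frame mask."""

    intervals: list[list[tuple[int, int]]]     # per cell: (onset, offset) frames
    mask: np.ndarray                           # cells x frames boolean


def compute_baseline(F: np.ndarray, frame_rate: float,
                     gauss_s: float = 5.0, maximin_s: float = 30.0) -> np.ndarray:
    """Slow baseline: Gaussian filter (full width ~ ``gauss_s`` seconds,
    i.e. sigma = gauss_s/4) followed by rolling min then rolling max."""
    sigma = gauss_s / 4.0 * frame_rate
    w = max(int(round(maximin_s * frame_rate)), 1)
    smooth = gaussian_filter1d(np.asarray(F, dtype=float), sigma, axis=-1)
    return maximum_filter1d(minimum_filter1d(smooth, w, axis=-1), w, axis=-1)


def _baseline_sigma(F: np.ndarray, dff: np.ndarray, frame_rate: float,
                    bin_s: float = 5.0, pct: float = 25.0) -> tuple[np.ndarray, np.ndarray]:
    """Noise sd per cell from the quietest quarter of 5-s bins.

    The trace is cut into 5-s bins and all frames of the bins whose mean
    fluorescence lies in the lower quartile are kept; the sd of dF/F over
    those frames estimates the baseline noise without the downward bias
    of keeping only each bin's lowest frames.
    """
    n_cells, n_frames = F.shape
    w = max(int(round(bin_s * frame_rate)), 1)
    n_bins = int(np.ceil(n_frames / w))
    sigma = np.empty(n_cells)
    floored = np.zeros(n_cells, dtype=bool)
    for c in range(n_cells):
        bin_means = np.array([F[c, s:s + w].mean()
                              for s in range(0, n_frames, w)])
        thr = np.percentile(bin_means, pct)
        keep = np.zeros(n_frames, dtype=bool)
        for b, s in enumerate(range(0, n_frames, w)):
            if bin_means[b] <= thr:
                keep[s:s + w] = True
        s_ = float(np.std(dff[c, keep])) if keep.any() else 0.0
        if s_ <= 0:
            s_, floored[c] = 1e-6, True
        sigma[c] = s_
    return sigma, floored


def detect_transients(dff: np.ndarray, sigma: np.ndarray,
                      onset_sd: float = TRANSIENT_ONSET_SD,
                      offset_sd: float = TRANSIENT_OFFSET_SD) -> TransientSet:
    """Significant transients: start when dff deviates ``onset_sd`` x sigma
    from baseline (zero), end on return within ``offset_sd`` x sigma."""
    n_cells, n_frames = dff.shape
    intervals, mask = [], np.zeros((n_cells, n_frames), dtype=bool)
    for c in range(n_cells):
        hi, lo = onset_sd * sigma[c], offset_sd * sigma[c]
        cell = []
        t = 0
        while t < n_frames:
            if dff[c, t] >= hi:
                end = t
                while end < n_frames and dff[c, end] > lo:
                    end += 1
                cell.append((t, end))
                mask[c, t:end] = True
                t = end
            else:
                t += 1
        intervals.append(cell)
    return TransientSet(intervals, mask)


def preprocess(session: CalciumSession) -> tuple[DffTrace, TransientSet]:
    """Baseline, dF/F, noise sd and significant transients for a session."""
    F = np.asarray(session.F, dtype=float)
    if not np.all(np.isfinite(F)):
        raise NeuralError("fluorescence must be finite")
    F0 = compute_baseline(F, session.frame_rate)
    F0 = np.where(F0 <= 0, np.maximum(F.mean(axis=-1, keepdims=True), 1e-6), F0)
    dff = (F - F0) / F0
    sigma, floored = _baseline_sigma(F, dff, session.frame_rate)
    transients = detect_transients(dff, sigma)
    return DffTrace(F0, dff, sigma, floored), transients


# ---------------------------------------------------------------------- #
# tuning

@dataclass
class TuningCurve:
    curves: np.ndarray            # cells x bins, mean dff
    occupancy: np.ndarray         # frames per bin
    bin_edges: np.ndarray         # cm
    trial_type: str

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def _qualifying_frames(session: CalciumSession, trial_type: str | None,
                       variant: str = "standard",
                       active_only: bool = True) -> np.ndarray:
    keep = session.speed > SPEED_THRESHOLD
    sel_ids = [tid for tid in session.trial_types
               if (trial_type is None or session.trial_types[tid] == trial_type)
               and session.trial_variants.get(tid, "standard") == variant]
    if active_only:
        act = session.active_trials()
        sel_ids = [tid for tid in sel_ids if tid in act]
    keep &= np.isin(session.trial_id, sel_ids)
    return keep


def tuning_curve(dff: np.ndarray, session: CalciumSession, trial_type: str | None,
                 bin_cm: float = BIN_CM, variant: str = "standard",
                 active_only: bool = True, track_cm: float | None = None) -> TuningCurve:
    """Occupancy-weighted mean dF/F per position bin for one trial type."""
    dff = np.atleast_2d(dff)
    track = track_cm if track_cm is not None else \
        (STRETCHED_TRACK_CM if variant == "stretched" else session.track_cm)
    keep = _qualifying_frames(session, trial_type, variant, active_only)
    if not keep.any():
        raise NeuralError(f"no qualifying frames for trial type {trial_type!r}")
    edges = np.arange(0.0, track + bin_cm / 2, bin_cm)
    which = np.digitize(session.position[keep], edges) - 1
    which = np.clip(which, 0, len(edges) - 2)
    occ = np.bincount(which, minlength=len(edges) - 1).astype(float)
    sums = np.vstack([np.bincount(which, weights=row, minlength=len(edges) - 1)
                      for row in dff[:, keep]])
    with np.errstate(invalid="ignore"):
        curves = np.where(occ > 0, sums / occ, 0.0)
    return TuningCurve(curves, occ, edges, trial_type or "all")


def spatial_dispersion(curve: np.ndarray) -> float:
    """Shannon entropy (bits) of the area-normalised tuning curve.

    0 bits for a single-bin response, log2(n_bins) for uniform tuning.
    """
    curve = np.asarray(curve, dtype=float)
    if np.any(curve < 0):
        raise NeuralError("tuning curve must be nonnegative")
    total = curve.sum()
    if total <= 0:
        raise NeuralError("tuning curve is all zero")
    p = curve / total
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


# ---------------------------------------------------------------------- #
# place fields

@dataclass
class PlaceFieldResult:
    fields: list[tuple[float, float]]     # cm intervals passing all criteria
    significant: bool
    p_value: float
    n_shuffles: int
    details: dict = field(default_factory=dict)


def _candidate_fields(curve: np.ndarray, bin_cm: float) -> list[tuple[int, int]]:
    """Contiguous bins above 25% of (peak - lower-quartile baseline),
    filtered by the 15-120 cm width rule."""
    base = np.percentile(curve, 25.0)
    peak = curve.max()
    if peak <= base:
        return []
    thr = base + 0.25 * (peak - base)
    above = curve > thr
    fields = []
    start = None
    for i, a in enumerate(np.append(above, False)):
        if a and start is None:
            start = i
        elif not a and start is not None:
            width = (i - start) * bin_cm
            if FIELD_WIDTH_CM[0] <= width <= FIELD_WIDTH_CM[1]:
                fields.append((start, i))
            start = None
    return fields


def _passing_fields(curve: np.ndarray, which: np.ndarray, dff_frames: np.ndarray,
                    transient_frames: np.ndarray, bin_cm: float) -> list[tuple[int, int]]:
    out = []
    for lo, hi in _candidate_fields(curve, bin_cm):
        inside = (which >= lo) & (which < hi)
        mean_in = curve[lo:hi].mean()
        outside_curve = np.concatenate([curve[:lo], curve[hi:]])
        mean_out = outside_curve.mean() if outside_curve.size else 0.0
        if mean_out > 0 and mean_in / mean_out < IN_OUT_RATIO:
            continue
        if mean_out <= 0 and mean_in <= 0:
            continue
        if inside.any():
            frac = transient_frames[inside].mean()
            if frac < TRANSIENT_OCCUPANCY:
                continue
        out.append((lo, hi))
    return out


def detect_place_fields(dff_cell: np.ndarray, transient_mask_cell: np.ndarray,
                        session: CalciumSession, trial_type: str | None = None,
                        n_shuffles: int = 1000, seed: int = 0,
                        bin_cm: float = BIN_CM) -> PlaceFieldResult:
    """Full place-field test for one cell.

    Candidate fields from the 25%-of-range contiguity rule must satisfy
    the width window, the in/out >= 4 mean-activity ratio, and >= 20%
    significant-transient occupancy; significance then requires that
    shuffling 10-s blocks of activity against position yields a passing
    field in fewer than 5% of shuffles.
    """
    if n_shuffles < 1:
        raise NeuralError("n_shuffles must be >= 1")
    keep = _qualifying_frames(session, trial_type)
    if not keep.any():
        raise NeuralError("no qualifying frames")
    track = session.track_cm
    edges = np.arange(0.0, track + bin_cm / 2, bin_cm)
    which = np.clip(np.digitize(session.position[keep], edges) - 1, 0, len(edges) - 2)
    occ = np.bincount(which, minlength=len(edges) - 1).astype(float)
    d = dff_cell[keep]
    tmask = transient_mask_cell[keep].astype(float)

    def curve_of(values):
        s = np.bincount(which, weights=values, minlength=len(edges) - 1)
        with np.errstate(invalid="ignore"):
            return np.where(occ > 0, s / occ, 0.0)

    fields = _passing_fields(curve_of(d), which, d, tmask, bin_cm)

    block = max(int(round(SHUFFLE_BLOCK_S * session.frame_rate)), 1)
    n = len(d)
    if n < block:
        raise NeuralError("session shorter than one shuffle block")
    n_blocks = int(np.ceil(n / block))
    rng = np.random.default_rng(seed)
    hits = 0
    pad = n_blocks * block
    d_pad = np.resize(d, pad).reshape(n_blocks, block)
    t_pad = np.resize(tmask, pad).reshape(n_blocks, block)
    for _ in range(n_shuffles):
        perm = rng.permutation(n_blocks)
        ds = d_pad[perm].ravel()[:n]
        ts = t_pad[perm].ravel()[:n]
        if _passing_fields(curve_of(ds), which, ds, ts, bin_cm):
            hits += 1
    p = hits / n_shuffles
    return PlaceFieldResult(
        fields=[(lo * bin_cm, hi * bin_cm) for lo, hi in fields],
        significant=bool(fields) and p < 0.05, p_value=p, n_shuffles=n_shuffles,
        details={"n_candidates": len(fields)})


# ---------------------------------------------------------------------- #
# splitter metrics

SPLITTER_R_THRESHOLD = 0.2
SPLITTER_D_THRESHOLD = 0.5


@dataclass
class SplitterScore:
    r: float                  # near/far tuning-curve Pearson correlation
    D: float                  # |A_near - A_far| / max(A_near, A_far)
    A_near: float
    A_far: float
    category: str             # place | splitter | remapping_splitter
    excluded: bool = False


def splitter_score(curve_near: np.ndarray, curve_far: np.ndarray) -> SplitterScore:
    """Correlation/difference-score phenotype of one cell.

    Thresholds r = 0.2 and D = 0.5 partition cells into place (and
    place-splitter) responses, splitter responses (amplitude difference),
    and remapping-splitter responses (equal amplitudes at different
    positions, hence low correlation and low D).
    """
    cn, cf = np.asarray(curve_near, float), np.asarray(curve_far, float)
    a_n, a_f = float(cn.max(initial=0.0)), float(cf.max(initial=0.0))
    if max(a_n, a_f) <= 0:
        return SplitterScore(np.nan, np.nan, a_n, a_f, "undefined", excluded=True)
    D = abs(a_n - a_f) / max(a_n, a_f)
    sn, sf = cn.std(), cf.std()
    r = float(np.corrcoef(cn, cf)[0, 1]) if sn > 0 and sf > 0 else 0.0
    if D >= SPLITTER_D_THRESHOLD:
        cat = "splitter"
    elif r >= SPLITTER_R_THRESHOLD:
        cat = "place"
    else:
        cat = "remapping_splitter"
    return SplitterScore(r, D, a_n, a_f, cat)


def classify_cells(curves_near: np.ndarray, curves_far: np.ndarray,
                   activity_sd: float = 2.0,
                   traces: np.ndarray | None = None) -> tuple[list[SplitterScore], dict]:
    """Splitter classification over a population.

    Cells whose peak tuning does not exceed ``activity_sd`` standard
    deviations above the mean are excluded (too weakly active to
    phenotype).  When per-cell dF/F ``traces`` are supplied, mean and sd
    come from the full trace -- the scale-aware criterion; otherwise the
    concatenated tuning curves are used.
    """
    curves_near = np.atleast_2d(curves_near)
    curves_far = np.atleast_2d(curves_far)
    scores = []
    for i, (cn, cf) in enumerate(zip(curves_near, curves_far)):
        both = np.concatenate([cn, cf])
        ref = traces[i] if traces is not None else both
        if both.max(initial=0.0) <= ref.mean() + activity_sd * ref.std():
            scores.append(SplitterScore(np.nan, np.nan, float(cn.max(initial=0)),
                                        float(cf.max(initial=0)), "inactive",
                                        excluded=True))
            continue
        scores.append(splitter_score(cn, cf))
    included = [s for s in scores if not s.excluded]
    fractions = {}
    for cat in ("place", "splitter", "remapping_splitter"):
        fractions[cat] = (sum(s.category == cat for s in included) / len(included)
                          if included else np.nan)
    return scores, fractions


def field_shift_analysis(curves_normal: np.ndarray, curves_stretched: np.ndarray,
                         bin_cm: float = BIN_CM) -> dict:
    """Paired tuning-peak locations in normal versus stretched trials.

    Cells with no activity in either condition are excluded and counted.
    Returns peak-location pairs (cm) plus the exclusion count; on the
    unmodified initial track portion, peaks should fall on the identity
    line.
    """
    cn = np.atleast_2d(curves_normal)
    cs = np.atleast_2d(curves_stretched)
    pairs, excluded = [], 0
    for a, b in zip(cn, cs):
        if a.max(initial=0.0) <= 0 or b.max(initial=0.0) <= 0:
            excluded += 1
            continue
        pairs.append(((np.argmax(a) + 0.5) * bin_cm, (np.argmax(b) + 0.5) * bin_cm))
    pairs = np.asarray(pairs, dtype=float).reshape(-1, 2)
    edges = np.arange(0.0, STRETCHED_TRACK_CM + bin_cm, 2 * bin_cm)
    hist = np.histogram(pairs[:, 1], bins=edges)[0] if len(pairs) else \
        np.zeros(len(edges) - 1, dtype=int)
    return {"pairs": pairs, "n_excluded": excluded,
            "stretched_hist": hist, "stretched_hist_edges": edges}
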