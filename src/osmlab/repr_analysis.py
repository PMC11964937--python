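"""Population-vector comparison of near versus far trial representations.

A population vector (PV) is the mean activity of all units at one track
position bin: model states, network units, or cell dF/F means all fit the
same container.  Near and far trial PVs are compared by the Pearson
correlation between every pair of positions (the cross-correlation
matrix), averaged over named track regions.  During learning, region
correlations fall; the order in which the off-diagonal grey pairs, the
pre-R2 region and the pre-R1 region first cross a threshold (0.3) is the
discriminating statistic between candidate learning models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import tasks

#: regions compared on the diagonal of the cross-correlation matrix
DIAGONAL_REGIONS = ("initial", "indicator", "pre_r1", "r1", "pre_r2", "r2", "end")
#: visually identical grey regions entering the off-diagonal statistic
GREY_REGIONS = ("initial", "pre_r1", "pre_r2", "end")

DEFAULT_THRESHOLD = 0.3


class ReprError(ValueError):
    pass


@dataclass
class PositionPV:
    """Position-binned population vector matrix (positions x units)."""

    matrix: np.ndarray
    positions: np.ndarray               # bin centres (cm) or symbol indices
    trial_type: str = ""
    source: str = ""

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.matrix.ndim != 2:
            raise ReprError("PV matrix must be 2-D (positions x units)")
        if not np.all(np.isfinite(self.matrix)):
            raise ReprError("PV matrix must be finite")

    @property
    def n_positions(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_units(self) -> int:
        return self.matrix.shape[1]


@dataclass
class CrossCorrMatrix:
    """Near-positions x far-positions matrix of Pearson r."""

    matrix: np.ndarray
    degenerate: np.ndarray              # True where a zero-variance PV forced r = 0

    def __post_init__(self):
        if np.nanmax(np.abs(self.matrix), initial=0.0) > 1 + 1e-9:
            raise ReprError("correlations must lie in [-1, 1]")


@dataclass
class RegionSpec:
    """Named position-index sets on the track, plus the off-diagonal
    grey-pair list used for the earliest-decorrelating statistic."""

    regions: dict[str, list[int]]
    grey_regions: tuple[str, ...] = GREY_REGIONS

    @classmethod
    def for_model(cls, dialect: str = "rnn", variant: str = "standard") -> "RegionSpec":
        """Symbol-step regions: one 10-cm segment per matrix row/column."""
        return cls({k: v for k, v in tasks.segment_regions(variant, dialect).items()
                    if k in DIAGONAL_REGIONS})

    @classmethod
    def for_track(cls, bin_cm: float = 5.0, variant: str = "standard") -> "RegionSpec":
        """Spatial-bin regions for neural data binned at ``bin_cm``."""
        seg = tasks.segment_regions(variant, "rnn")
        factor = tasks.SEGMENT_CM / bin_cm
        out = {}
        for name in DIAGONAL_REGIONS:
            idx = seg[name]
            lo, hi = idx[0] * factor, (idx[-1] + 1) * factor
            out[name] = list(range(int(round(lo)), int(round(hi))))
        return cls(out)

    def off_diagonal_pairs(self) -> list[tuple[str, str]]:
        """Ordered pairs of distinct grey regions."""
        return [(a, b) for a in self.grey_regions for b in self.grey_regions
                if a != b]


def _standardize_rows(mat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rows centred and scaled to unit norm; flags zero-variance rows."""
    centred = mat - mat.mean(axis=1, keepdims=True)
    norm = np.linalg.norm(centred, axis=1)
    degenerate = norm < 1e-300
    safe = np.where(degenerate, 1.0, norm)
    return centred / safe[:, None], degenerate


def pv_cross_correlation(pv_near: PositionPV, pv_far: PositionPV) -> CrossCorrMatrix:
    """Pearson r between every (near-position, far-position) PV pair.

    A position whose PV has zero variance across units cannot be
    correlated; such entries are set to 0 and flagged.
    """
    if pv_near.n_units != pv_far.n_units:
        raise ReprError("PVs must have the same unit count and order")
    zn, dn = _standardize_rows(pv_near.matrix)
    zf, df = _standardize_rows(pv_far.matrix)
    r = np.clip(zn @ zf.T, -1.0, 1.0)
    degenerate = dn[:, None] | df[None, :]
    r[degenerate] = 0.0
    return CrossCorrMatrix(r, degenerate)


def pv_angles(pv_near: PositionPV, pv_far: PositionPV) -> np.ndarray:
    """Per-position angle (degrees) between paired near/far PVs.

    The angle is arccos of the cosine similarity of the raw (uncentred)
    vectors; orthogonal nonnegative PVs sit at 90 degrees.
    """
    if pv_near.n_positions != pv_far.n_positions:
        raise ReprError("paired PVs must cover the same positions")
    a, b = pv_near.matrix, pv_far.matrix
    na = np.linalg.norm(a, axis=1)
    nb = np.linalg.norm(b, axis=1)
    denom = na * nb
    cos = np.where(denom > 0, (a * b).sum(axis=1) / np.where(denom > 0, denom, 1.0), 0.0)
    return np.degrees(np.arccos(np.clip(cos, -1.0, 1.0)))


def region_correlations(matrix: CrossCorrMatrix | np.ndarray, regions: RegionSpec,
                        pv_near: PositionPV | None = None,
                        pv_far: PositionPV | None = None) -> dict:
    """Mean correlation per named diagonal region plus the off-diagonal
    grey statistic; optionally also per-region mean PV angles."""
    mat = matrix.matrix if isinstance(matrix, CrossCorrMatrix) else np.asarray(matrix)
    out: dict = {"region_means": {}, "off_diagonal": np.nan}
    for name, idx in regions.regions.items():
        if not idx:
            raise ReprError(f"empty region {name!r}")
        if max(idx) >= mat.shape[0] or max(idx) >= mat.shape[1]:
            raise ReprError(f"region {name!r} outside matrix bounds")
        out["region_means"][name] = float(mat[np.ix_(idx, idx)].mean())
    vals = [mat[np.ix_(regions.regions[a], regions.regions[b])].mean()
            for a, b in regions.off_diagonal_pairs()]
    out["off_diagonal"] = float(np.mean(vals))
    if pv_near is not None and pv_far is not None:
        ang = pv_angles(pv_near, pv_far)
        out["angles_deg"] = ang
        out["region_angles"] = {name: float(ang[idx].mean())
                                for name, idx in regions.regions.items()}
    return out


@dataclass
class DecorrTrajectory:
    """Per-region correlation series over training checkpoints."""

    times: np.ndarray                      # normalized to [0, 1] (or raw indices)
    series: dict[str, np.ndarray]          # region -> correlation per checkpoint
    threshold: float
    crossings: dict[str, float | None]     # region -> first crossing time, or None

    def crossed(self, region: str) -> bool:
        return self.crossings.get(region) is not None


def _first_crossing(times: np.ndarray, series: np.ndarray, threshold: float) -> float | None:
    """First downward crossing below threshold, linearly interpolated."""
    if series[0] < threshold:
        return float(times[0])
    for k in range(1, len(series)):
        if series[k] < threshold:
            y0, y1 = series[k - 1], series[k]
            frac = (y0 - threshold) / (y0 - y1)
            return float(times[k - 1] + frac * (times[k] - times[k - 1]))
    return None


def decorrelation_trajectory(checkpoint_pvs: list[tuple[PositionPV, PositionPV]],
                             regions: RegionSpec,
                             threshold: float = DEFAULT_THRESHOLD,
                             normalize: bool = True) -> DecorrTrajectory:
    """Region-correlation series over training and time-to-threshold.

    ``checkpoint_pvs`` is the (near, far) PV pair at each checkpoint in
    training order.  Crossing times use the first downward crossing with
    linear interpolation between checkpoints; with ``normalize`` the time
    axis is the checkpoint index divided by the training duration, so a
    crossing at 0.5 means halfway through training.
    """
    if len(checkpoint_pvs) < 2:
        raise ReprError("need at least two checkpoints")
    names = list(regions.regions) + ["off_diagonal"]
    series = {n: [] for n in names}
    for pv_n, pv_f in checkpoint_pvs:
        rc = region_correlations(pv_cross_correlation(pv_n, pv_f), regions)
        for n in regions.regions:
            series[n].append(rc["region_means"][n])
        series["off_diagonal"].append(rc["off_diagonal"])
    k = len(checkpoint_pvs)
    times = np.arange(k, dtype=float)
    if normalize:
        times /= (k - 1)
    series = {n: np.asarray(v) for n, v in series.items()}
    crossings = {n: _first_crossing(times, v, threshold) for n, v in series.items()}
    return DecorrTrajectory(times, series, threshold, crossings)


def decorrelation_order(trajectory: DecorrTrajectory,
                        regions: tuple[str, str, str] = ("off_diagonal", "pre_r2", "pre_r1")
                        ) -> dict:
    """Rank the threshold-crossing times of the three key regions.

    The match flag is true iff off-diagonal <= pre-R2 <= pre-R1 (ties
    allowed) -- the ordering observed in hippocampus and reproduced by the
    CSCG but not by the other model families.  Any region that never
    crosses the threshold fails the match with a reason.
    """
    t = [trajectory.crossings.get(r) for r in regions]
    if any(v is None for v in t):
        missing = [r for r, v in zip(regions, t) if v is None]
        return {"times": dict(zip(regions, t)), "order": None,
                "match": False, "reason": f"not crossed: {missing}"}
    order = [regions[i] for i in np.argsort(t, kind="stable")]
    match = t[0] <= t[1] <= t[2]
    return {"times": dict(zip(regions, t)), "order": order,
            "match": bool(match), "reason": None}
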