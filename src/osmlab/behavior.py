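"""Licking-behaviour analysis: strategy regression and task performance.

Learning mice pass through four licking strategies: random licking
everywhere, licking at both reward zones, "lick-stop" (lick at reward
zones but stop after collecting a reward), and expert (lick only at the
correct zone).  Each strategy is a nonnegative basis function over
(position x trial type); regressing the observed lick density on all
four and removing one at a time yields the coefficient of partial
determination CPD_i = (SSE_without_i - SSE_full) / SSE_without_i, the
unique contribution of strategy i.  The dominant strategy per session
half tracks learning.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .tasks import TRACK_CM

STRATEGIES = ("random", "both_rewards", "lick_stop", "expert")

#: reward zones and the anticipatory lead-in (cm) used for basis supports
R1_CM = (130.0, 150.0)
R2_CM = (180.0, 200.0)
LEAD_IN_CM = 20.0


class BehaviorError(ValueError):
    pass


@dataclass
class LickProfile:
    """Lick density per position bin, per trial type and session half."""

    density: dict                  # (trial_type, half) -> per-bin density
    bin_edges: np.ndarray
    n_trials: dict                 # (trial_type, half) -> trial count
    empty: bool = False


def lick_density(position_per_lick: np.ndarray, trial_type_per_lick: np.ndarray,
                 half_per_lick: np.ndarray, n_trials: dict,
                 bin_cm: float = 10.0, track_cm: float = TRACK_CM) -> LickProfile:
    """Bin licks by position, normalised by trial count.

    ``n_trials`` maps (trial_type, half) to the number of trials in that
    cell, so density is licks per trial per bin.
    """
    edges = np.arange(0.0, track_cm + bin_cm / 2, bin_cm)
    density = {}
    pos = np.asarray(position_per_lick, dtype=float)
    empty = pos.size == 0
    for key, n in n_trials.items():
        tt, half = key
        m = (np.asarray(trial_type_per_lick) == tt) & (np.asarray(half_per_lick) == half)
        counts = np.histogram(pos[m], bins=edges)[0].astype(float)
        density[key] = counts / max(n, 1)
    return LickProfile(density, edges, dict(n_trials), empty=empty)


@dataclass
class StrategyBasis:
    """The four strategy regressors over (position x trial type).

    Each regressor is nonnegative and normalised to unit area over its
    concatenated (near, far) support.  Supports come from the canonical
    track layout with a 20-cm anticipatory lead-in before each reward
    zone (mice lick at the rewarded location or just before it).
    """

    bin_edges: np.ndarray
    regressors: dict[str, dict[str, np.ndarray]]   # name -> trial_type -> density

    def design_matrix(self, trial_types=("near", "far")) -> np.ndarray:
        """(n_bins * n_types) x 4 design, column order = STRATEGIES."""
        cols = []
        for name in STRATEGIES:
            cols.append(np.concatenate([self.regressors[name][tt]
                                        for tt in trial_types]))
        return np.column_stack(cols)


def strategy_basis(bin_cm: float = 10.0, track_cm: float = TRACK_CM,
                   lead_in_cm: float = LEAD_IN_CM) -> StrategyBasis:
    """Build the four licking-strategy regressors.

    random: uniform over the track on both trial types.
    both_rewards: mass at both reward zones (with lead-in) on both types.
    lick_stop: both zones on far trials, but on near trials only the near
        zone -- licking stops after the reward is collected there.
    expert: only the correct zone per trial type.
    """
    edges = np.arange(0.0, track_cm + bin_cm / 2, bin_cm)
    centers = 0.5 * (edges[:-1] + edges[1:])

    def zone(lo, hi):
        return ((centers >= lo - lead_in_cm) & (centers < hi)).astype(float)

    r1 = zone(*R1_CM)
    r2 = zone(*R2_CM)
    uniform = np.ones_like(centers)
    reg = {
        "random": {"near": uniform.copy(), "far": uniform.copy()},
        "both_rewards": {"near": r1 + r2, "far": r1 + r2},
        "lick_stop": {"near": r1.copy(), "far": r1 + r2},
        "expert": {"near": r1.copy(), "far": r2.copy()},
    }
    for name, d in reg.items():
        area = sum(v.sum() for v in d.values())
        for tt in d:
            d[tt] = d[tt] / area
    return StrategyBasis(edges, reg)


@dataclass
class CPDResult:
    cpd: dict[str, float]
    sse_full: float
    sse_without: dict[str, float]
    r_squared: float
    dominant: str
    collinear: bool = False


def cpd(observed: np.ndarray, design: np.ndarray,
        names=STRATEGIES, intercept: bool = False) -> CPDResult:
    """Coefficient of partial determination per regressor.

    Fits ordinary least squares on the full design, then refits leaving
    out each regressor; CPD_i = (SSE_~i - SSE_full)/SSE_~i.  No intercept
    is included by default: the random-licking regressor is itself a
    constant over the track, so an intercept would absorb it and zero its
    CPD.  Rank-deficient designs are fitted by pseudoinverse and flagged.
    """
    y = np.asarray(observed, dtype=float).ravel()
    X = np.asarray(design, dtype=float)
    if y.shape[0] != X.shape[0]:
        raise BehaviorError("observations and design misaligned")
    if y.shape[0] < X.shape[1]:
        raise BehaviorError("need at least as many observations as regressors")

    def sse(cols):
        Xc = X[:, cols]
        if intercept:
            Xc = sm.add_constant(Xc, has_constant="add")
        fit = sm.OLS(y, Xc).fit()
        return float(fit.ssr), fit

    all_cols = list(range(X.shape[1]))
    sse_full, full_fit = sse(all_cols)
    collinear = np.linalg.matrix_rank(X) < X.shape[1]
    sst = float(((y - y.mean()) ** 2).sum())
    tol = 1e-12 * max(sst, 1.0)       # an SSE this small is a perfect fit
    out, sse_wo = {}, {}
    for i, name in enumerate(names):
        s, _ = sse(all_cols[:i] + all_cols[i + 1:])
        sse_wo[name] = s
        out[name] = max((s - sse_full) / s, 0.0) if s > tol else 0.0
    dominant = max(out, key=out.get)
    return CPDResult(out, sse_full, sse_wo, float(full_fit.rsquared),
                     dominant, collinear)


def cpd_from_profile(profile: LickProfile, basis: StrategyBasis) -> dict[str, CPDResult]:
    """CPD per session half, concatenating (near, far) densities."""
    halves = sorted({h for (_, h) in profile.density})
    results = {}
    for h in halves:
        y = np.concatenate([profile.density[(tt, h)] for tt in ("near", "far")])
        results[h] = cpd(y, basis.design_matrix())
    return results


# ---------------------------------------------------------------------- #
# performance

def trial_accuracy(lick_positions: np.ndarray, trial_type: str) -> int:
    """Binary score: 1 iff the animal licked in the correct reward zone
    and nowhere in the incorrect one."""
    pos = np.asarray(lick_positions, dtype=float)
    correct_zone = R1_CM if trial_type == "near" else R2_CM
    wrong_zone = R2_CM if trial_type == "near" else R1_CM
    in_correct = np.any((pos >= correct_zone[0]) & (pos < correct_zone[1]))
    in_wrong = np.any((pos >= wrong_zone[0]) & (pos < wrong_zone[1]))
    return int(in_correct and not in_wrong)


@dataclass
class PerformanceResult:
    per_trial: np.ndarray
    accuracy: float
    correct_lick_fraction: float
    expert: bool                      # >= 75% for three consecutive sessions


def performance(trials: list[tuple[str, np.ndarray]],
                history: list[float] = (), criterion: float = 0.75) -> PerformanceResult:
    """Session performance metrics.

    ``trials`` is a list of (trial_type, lick positions); ``history`` is
    the accuracy of preceding sessions, used for the expert criterion
    (this session plus the previous two all >= criterion).
    """
    per_trial = np.array([trial_accuracy(p, tt) for tt, p in trials], dtype=float)
    acc = float(per_trial.mean()) if per_trial.size else 0.0
    n_correct = n_total = 0
    for tt, pos in trials:
        pos = np.asarray(pos, dtype=float)
        zone = R1_CM if tt == "near" else R2_CM
        n_total += pos.size
        n_correct += int(np.sum((pos >= zone[0]) & (pos < zone[1])))
    frac = n_correct / n_total if n_total else 0.0
    recent = list(history)[-2:] + [acc]
    expert = len(recent) == 3 and all(a >= criterion for a in recent)
    return PerformanceResult(per_trial, acc, frac, expert)
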