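"""Population-vector correlation, region statistics and decorrelation order."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from osmlab import repr_analysis as ra


def make_pv(matrix, trial_type=""):
    matrix = np.atleast_2d(matrix)
    return ra.PositionPV(matrix, np.arange(matrix.shape[0], dtype=float),
                         trial_type)


class TestCrossCorrelation:
    def test_self_correlation_has_unit_diagonal(self, rng):
        pv = make_pv(rng.normal(size=(10, 30)))
        mat = ra.pv_cross_correlation(pv, pv).matrix
        np.testing.assert_allclose(np.diag(mat), 1.0, atol=1e-12)

    def test_disjoint_one_hot_pvs_closed_form(self):
        """PVs that are one-hot on disjoint units correlate at -1/(n-1)."""
        n = 100
        pv_a = make_pv(np.eye(1, n, 3))
        pv_b = make_pv(np.eye(1, n, 57))
        r = ra.pv_cross_correlation(pv_a, pv_b).matrix[0, 0]
        assert abs(r - (-1.0 / (n - 1))) < 1e-12

    def test_agrees_with_textbook_pearson(self, rng):
        a, b = rng.normal(size=(6, 40)), rng.normal(size=(5, 40))
        mat = ra.pv_cross_correlation(make_pv(a), make_pv(b)).matrix
        for i in range(6):
            for j in range(5):
                ai, bj = a[i] - a[i].mean(), b[j] - b[j].mean()
                r = (ai @ bj) / np.sqrt((ai @ ai) * (bj @ bj))
                assert abs(mat[i, j] - r) < 1e-12

    def test_zero_variance_rows_flagged_as_zero(self, rng):
        a = rng.normal(size=(3, 10))
        a[1] = 5.0                                    # constant PV
        out = ra.pv_cross_correlation(make_pv(a), make_pv(rng.normal(size=(3, 10))))
        assert np.all(out.matrix[1] == 0.0)
        assert out.degenerate[1].all()

    def test_unit_mismatch_errors(self, rng):
        with pytest.raises(ra.ReprError):
            ra.pv_cross_correlation(make_pv(rng.normal(size=(3, 10))),
                                    make_pv(rng.normal(size=(3, 11))))

    @given(st.integers(0, 1000))
    @settings(max_examples=20, deadline=None)
    def test_entries_bounded(self, seed):
        r = np.random.default_rng(seed)
        mat = ra.pv_cross_correlation(make_pv(r.normal(size=(4, 12))),
                                      make_pv(r.normal(size=(4, 12)))).matrix
        assert np.all(np.abs(mat) <= 1 + 1e-12)


class TestAnglesAndRegions:
    def test_identical_pvs_zero_angle_unit_region_means(self):
        pv = make_pv(np.abs(np.random.default_rng(0).normal(size=(23, 40))) + 0.1)
        regions = ra.RegionSpec.for_model("rnn")
        out = ra.region_correlations(ra.pv_cross_correlation(pv, pv), regions,
                                     pv, pv)
        for name, idx in regions.regions.items():
            # diagonal of each region block is exactly 1
            assert out["region_means"][name] <= 1.0
        assert np.allclose(out["angles_deg"], 0.0, atol=1e-5)

    def test_orthogonal_nonnegative_pvs_at_ninety_degrees(self):
        a = np.zeros((1, 10)); a[0, :5] = 1.0
        b = np.zeros((1, 10)); b[0, 5:] = 1.0
        ang = ra.pv_angles(make_pv(a), make_pv(b))
        assert abs(ang[0] - 90.0) < 1e-9

    def test_angle_correlation_consistency_for_centered_pvs(self, rng):
        a = rng.normal(size=(8, 50))
        a -= a.mean(axis=1, keepdims=True)
        b = rng.normal(size=(8, 50))
        b -= b.mean(axis=1, keepdims=True)
        mat = ra.pv_cross_correlation(make_pv(a), make_pv(b)).matrix
        ang = ra.pv_angles(make_pv(a), make_pv(b))
        np.testing.assert_allclose(np.diag(mat), np.cos(np.radians(ang)),
                                   atol=1e-9)

    def test_checkerboard_block_means(self):
        """Region means equal hand-computed block averages."""
        mat = np.indices((23, 23)).sum(axis=0) % 2 * 1.0
        regions = ra.RegionSpec.for_model("rnn")
        out = ra.region_correlations(mat, regions)
        for name, idx in regions.regions.items():
            block = mat[np.ix_(idx, idx)]
            assert out["region_means"][name] == pytest.approx(block.mean())

    def test_off_diagonal_excludes_same_region_pairs(self):
        regions = ra.RegionSpec.for_model("rnn")
        pairs = regions.off_diagonal_pairs()
        assert all(a != b for a, b in pairs)
        assert len(pairs) == 12                      # 4 grey regions, ordered

    def test_empty_region_errors(self):
        spec = ra.RegionSpec({"empty": []})
        with pytest.raises(ra.ReprError):
            ra.region_correlations(np.ones((5, 5)), spec)


class TestDecorrelation:
    def _traj(self, series, threshold=0.3):
        """Build a trajectory from a planted correlation series by
        synthesising PVs with exactly that correlation at every position."""
        spec = ra.RegionSpec({"a": [0, 1]}, grey_regions=("a",))
        # cheat: construct DecorrTrajectory directly for crossing tests
        times = np.linspace(0, 1, len(series))
        arr = np.asarray(series, dtype=float)
        crossings = {"a": ra._first_crossing(times, arr, threshold)}
        return ra.DecorrTrajectory(times, {"a": arr}, threshold, crossings)

    def test_interpolated_crossing_time(self):
        traj = self._traj([0.9, 0.6, 0.2, 0.1])
        assert traj.crossings["a"] == pytest.approx(0.5833333, abs=1e-6)

    def test_constant_series_never_crosses(self):
        traj = self._traj([0.9, 0.9, 0.9])
        assert traj.crossings["a"] is None

    def test_order_match_and_mismatch(self):
        def traj_with(times):
            series = {r: np.array([1.0, 0.0]) for r in times}
            return ra.DecorrTrajectory(np.array([0.0, 1.0]), series, 0.3,
                                       dict(times))
        ok = ra.decorrelation_order(traj_with(
            {"off_diagonal": 0.2, "pre_r2": 0.5, "pre_r1": 0.8}))
        assert ok["match"] and ok["order"] == ["off_diagonal", "pre_r2", "pre_r1"]
        bad = ra.decorrelation_order(traj_with(
            {"off_diagonal": 0.2, "pre_r2": 0.8, "pre_r1": 0.5}))
        assert not bad["match"]
        tie = ra.decorrelation_order(traj_with(
            {"off_diagonal": 0.4, "pre_r2": 0.4, "pre_r1": 0.4}))
        assert tie["match"]                          # ties allowed

    def test_uncrossed_region_fails_match_with_reason(self):
        series = {"off_diagonal": np.array([1.0, 0.0]),
                  "pre_r2": np.array([1.0, 0.0]),
                  "pre_r1": np.array([0.9, 0.9])}
        traj = ra.DecorrTrajectory(np.array([0.0, 1.0]), series, 0.3,
                                   {"off_diagonal": 0.3, "pre_r2": 0.5,
                                    "pre_r1": None})
        out = ra.decorrelation_order(traj)
        assert not out["match"]
        assert "pre_r1" in out["reason"]

    def test_trajectory_from_pvs(self, rng):
        """End-to-end: PV pairs that morph from identical to independent
        activity produce a falling series that crosses the threshold."""
        regions = ra.RegionSpec({"pre_r1": [10], "initial": [2]},
                                grey_regions=("pre_r1", "initial"))
        base = np.abs(rng.normal(size=(23, 60))) + 0.05
        other = np.abs(rng.normal(size=(23, 60))) + 0.05
        pairs = []
        for w in np.linspace(0.0, 1.0, 6):
            far = (1 - w) * base + w * other
            pairs.append((make_pv(base, "near"), make_pv(far, "far")))
        traj = ra.decorrelation_trajectory(pairs, regions, threshold=0.5)
        assert traj.series["pre_r1"][0] > 0.99
        assert traj.crossings["pre_r1"] is not None
        assert 0.0 < traj.crossings["pre_r1"] <= 1.0

    def test_too_few_checkpoints_error(self):
        with pytest.raises(ra.ReprError):
            ra.decorrelation_trajectory([], ra.RegionSpec.for_model("rnn"))
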