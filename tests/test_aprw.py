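"""APRW inference chain: MSD, axes, model fits, diffusivities."""

import numpy as np
import pytest

from hydromig import aprw
from hydromig.aprw import (
    APRWFit,
    MSDCurve,
    angular_displacements,
    aprw_msd,
    axis_msds,
    fit_alpha,
    fit_aprw,
    motility_metrics,
    orientation_profile,
    population_msd,
    population_summary,
    svd_axes,
    track_msd,
)
from hydromig.tracks import Track, TrackSet

from conftest import random_trackset


def make_track(id_, positions, dt=1.0):
    positions = np.asarray(positions, dtype=float)
    return Track(id_, np.arange(len(positions)) * dt, positions)


def brute_force_msd(pos, dt, max_lag_fraction=0.5):
    """O(N^2) double loop over all (t, t+tau) pairs."""
    n = len(pos)
    kmax = max(int(np.floor(max_lag_fraction * (n - 1))), 1)
    lags, vals = [], []
    for k in range(1, kmax + 1):
        sq = [np.sum((pos[i + k] - pos[i]) ** 2) for i in range(n - k)]
        lags.append(k * dt)
        vals.append(np.mean(sq))
    return np.array(lags), np.array(vals)


class TestTrackMSD:
    def test_stationary_track_is_zero(self):
        tr = make_track("s", np.zeros((10, 2)))
        assert np.all(track_msd(tr).values == 0)

    def test_ballistic_closed_form(self):
        v = np.array([3.0, -4.0])  # |v| = 5
        pos = np.outer(np.arange(20.0), v)
        msd = track_msd(make_track("b", pos))
        np.testing.assert_allclose(msd.values, 25.0 * msd.lags**2, rtol=1e-12)

    @pytest.mark.parametrize("n_samples", [5, 20, 50])
    def test_matches_bruteforce(self, rng, n_samples):
        ts = random_trackset(rng, n_tracks=2, n_samples=n_samples)
        for tr in ts:
            msd = track_msd(tr)
            lags, vals = brute_force_msd(tr.positions, ts.dt)
            np.testing.assert_allclose(msd.lags, lags)
            np.testing.assert_allclose(msd.values, vals, rtol=1e-10)

    def test_nonuniform_sampling_rejected(self):
        tr = Track("x", [0.0, 1.0, 3.0], np.zeros((3, 2)))
        with pytest.raises(ValueError, match="non-uniform"):
            track_msd(tr)

    def test_translation_invariance(self, rng):
        ts = random_trackset(rng, n_tracks=1, n_samples=15)
        tr = ts.tracks[0]
        shifted = Track(tr.id, tr.times, tr.positions + np.array([123.4, -56.7]))
        np.testing.assert_allclose(
            track_msd(tr).values, track_msd(shifted).values, rtol=1e-9
        )


class TestPopulationMSD:
    def test_identical_tracks_equal_single(self, rng):
        ts = random_trackset(rng, n_tracks=1, n_samples=20)
        tr = ts.tracks[0]
        twin = TrackSet((tr, Track("b", tr.times, tr.positions.copy())), dt=ts.dt)
        np.testing.assert_allclose(
            population_msd(twin).values, track_msd(tr).values, rtol=1e-12
        )

    def test_mean_semantics_stationary_plus_ballistic(self):
        ball = make_track("b", np.outer(np.arange(12.0), [2.0, 0.0]))
        still = make_track("s", np.zeros((12, 2)))
        ts = TrackSet((ball, still), dt=1.0)
        pop = population_msd(ts)
        np.testing.assert_allclose(pop.values, 0.5 * track_msd(ball).values, rtol=1e-12)

    def test_matches_bruteforce_average(self, rng):
        ts = random_trackset(rng, n_tracks=5, n_samples=16)
        pop = population_msd(ts)
        per_track = np.array([brute_force_msd(tr.positions, ts.dt)[1] for tr in ts])
        np.testing.assert_allclose(pop.values, per_track.mean(axis=0), rtol=1e-10)


class TestFitAlpha:
    def test_linear_msd_gives_alpha_one(self):
        lags = np.arange(1.0, 21)
        msd = MSDCurve(lags, 7.0 * lags, np.ones(20, int))
        assert fit_alpha(msd, (1, 20)).alpha == pytest.approx(1.0, abs=1e-12)

    def test_quadratic_msd_gives_alpha_two(self):
        lags = np.arange(1.0, 21)
        msd = MSDCurve(lags, 0.3 * lags**2, np.ones(20, int))
        fit = fit_alpha(msd, (1, 20))
        assert fit.alpha == pytest.approx(2.0, abs=1e-12)
        assert fit.prefactor == pytest.approx(0.3, rel=1e-9)

    def test_zero_values_rejected(self):
        lags = np.arange(1.0, 11)
        msd = MSDCurve(lags, np.r_[0.0, np.ones(9)], np.ones(10, int))
        with pytest.raises(ValueError, match="log"):
            fit_alpha(msd, (1, 10))


class TestAngularDisplacements:
    def test_straight_motion_all_mass_at_zero(self):
        pos = np.outer(np.arange(15.0), [1.0, 2.0])
        ts = TrackSet((make_track("a", pos),), dt=1.0)
        dist = angular_displacements(ts, lag=1.0, n_bins=18)
        assert dist.density[0] > 0 and np.all(dist.density[1:] == 0)

    def test_back_and_forth_all_mass_at_180(self):
        x = np.array([0.0, 1.0] * 8)
        pos = np.column_stack([x, np.zeros_like(x)])
        ts = TrackSet((make_track("a", pos),), dt=1.0)
        dist = angular_displacements(ts, lag=1.0, n_bins=18)
        assert dist.density[-1] > 0 and np.all(dist.density[:-1] == 0)

    def test_hand_computed_three_step_path(self):
        # steps: +x, +y, -x  ->  angles: 90, 90
        pos = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
        ts = TrackSet((make_track("a", pos),), dt=1.0)
        dist = angular_displacements(ts, lag=1.0, n_bins=180)
        centred = 0.5 * (dist.bin_edges[:-1] + dist.bin_edges[1:])
        assert centred[np.argmax(dist.density)] == pytest.approx(90.5)
        assert dist.n_pairs == 2

    def test_zero_velocity_pairs_skipped(self):
        # steps: +x, pause, +x, +x -> pairs (v0,v1) and (v1,v2) involve the
        # zero step and are skipped; (v2,v3) survives
        pos = np.array([[0, 0], [1, 0], [1, 0], [2, 0], [3, 0]], dtype=float)
        ts = TrackSet((make_track("a", pos),), dt=1.0)
        dist = angular_displacements(ts, lag=1.0)
        assert dist.n_skipped == 2 and dist.n_pairs == 1

    def test_all_pairs_degenerate_raises(self):
        pos = np.array([[0, 0], [1, 0], [1, 0], [2, 0]], dtype=float)
        ts = TrackSet((make_track("a", pos),), dt=1.0)
        with pytest.raises(ValueError, match="non-zero"):
            angular_displacements(ts, lag=1.0)

    def test_lag_exceeding_tracks_raises(self, small_trackset):
        with pytest.raises(ValueError):
            angular_displacements(small_trackset, lag=100.0)


class TestSvdAxes:
    def test_pure_x_motion(self):
        pos = np.column_stack([np.cumsum(np.r_[0, 1, 2, 1, 3.0]), np.zeros(5)])
        axes = svd_axes(make_track("x", pos))
        assert abs(axes.p_axis @ [1, 0]) == pytest.approx(1.0, abs=1e-12)
        assert axes.singular_values[1] == pytest.approx(0.0, abs=1e-12)

    def test_rotation_equivariance(self, rng):
        ts = random_trackset(rng, n_tracks=1, n_samples=20)
        tr = ts.tracks[0]
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        tr_rot = Track("r", tr.times, tr.positions @ rot.T)
        p0 = svd_axes(tr).p_axis
        p1 = svd_axes(tr_rot).p_axis
        assert abs(p1 @ (rot @ p0)) == pytest.approx(1.0, abs=1e-9)

    def test_rotated_velocities_preserve_energy(self, rng):
        ts = random_trackset(rng, n_tracks=1, n_samples=20)
        axes = svd_axes(ts.tracks[0], ts.dt)
        v = ts.tracks[0].velocities(ts.dt)
        assert np.sum(axes.rotated_velocities**2) == pytest.approx(np.sum(v**2), rel=1e-12)

    def test_rotating_back_reproduces_velocities(self, rng):
        ts = random_trackset(rng, n_tracks=1, n_samples=12)
        axes = svd_axes(ts.tracks[0], ts.dt)
        basis = np.column_stack([axes.p_axis, axes.np_axis])
        np.testing.assert_allclose(
            axes.rotated_velocities @ basis.T, ts.tracks[0].velocities(ts.dt), atol=1e-9
        )

    def test_degenerate_track_raises(self):
        with pytest.raises(ValueError, match="degenerate"):
            svd_axes(make_track("z", np.zeros((5, 2))))


class TestAxisMSDs:
    def test_sum_rule(self, rng):
        ts = random_trackset(rng, n_tracks=3, n_samples=30)
        for tr in ts:
            axes = svd_axes(tr, ts.dt)
            mp, mn = axis_msds(tr, axes)
            total = track_msd(tr)
            np.testing.assert_allclose(mp.values + mn.values, total.values, rtol=1e-9)

    def test_motion_along_primary_only(self):
        pos = np.column_stack([np.cumsum(np.r_[0, 1, 2, 1, 3.0]), np.zeros(5)])
        tr = make_track("x", pos)
        mp, mn = axis_msds(tr, svd_axes(tr))
        assert np.all(mn.values == pytest.approx(0.0, abs=1e-18))
        assert np.all(mp.values > 0)


class TestFitAPRW:
    def test_noiseless_roundtrip(self):
        lags = np.arange(1, 41) * 0.25
        n = np.ones(40, int)
        truth = (30.0, 1.0, 15.0, 0.5, 0.25)
        msd_p = MSDCurve(lags, aprw_msd(lags, 30, 1.0, 0.25), n)
        msd_np = MSDCurve(lags, aprw_msd(lags, 15, 0.5, 0.25), n)
        fit = fit_aprw(msd_p, msd_np)
        assert fit.converged
        for got, want in zip((fit.S_p, fit.P_p, fit.S_np, fit.P_np, fit.sigma2), truth):
            assert got == pytest.approx(want, rel=1e-4)

    @pytest.mark.parametrize("residuals", ["log", "linear"])
    def test_roundtrip_both_residual_modes(self, residuals):
        lags = np.arange(1, 31) * 0.5
        n = np.ones(30, int)
        msd_p = MSDCurve(lags, aprw_msd(lags, 20, 2.0, 0.1), n)
        msd_np = MSDCurve(lags, aprw_msd(lags, 10, 1.0, 0.1), n)
        fit = fit_aprw(msd_p, msd_np, residuals=residuals)
        assert fit.S_p == pytest.approx(20, rel=1e-3)
        assert fit.P_p == pytest.approx(2.0, rel=1e-3)

    def test_zero_speed_returns_half_noise_floor(self):
        lags = np.arange(1, 41) * 0.25
        n = np.ones(40, int)
        flat = MSDCurve(lags, np.full(40, 0.5), n)
        fit = fit_aprw(flat, flat)
        assert fit.sigma2 == pytest.approx(0.25, rel=1e-3)
        assert fit.S_p**2 * fit.P_p == pytest.approx(0.0, abs=1e-6)

    def test_axis_swap_enforces_primary_faster(self):
        lags = np.arange(1, 41) * 0.25
        n = np.ones(40, int)
        slow = MSDCurve(lags, aprw_msd(lags, 10, 0.5, 0.1), n)
        fast = MSDCurve(lags, aprw_msd(lags, 30, 1.0, 0.1), n)
        fit = fit_aprw(slow, fast)  # primary curve deliberately the slow one
        assert fit.swapped
        assert fit.S_p**2 * fit.P_p >= fit.S_np**2 * fit.P_np

    def test_mismatched_lags_rejected(self):
        n5 = np.ones(5, int)
        a = MSDCurve(np.arange(1, 6.0), np.ones(5), n5)
        b = MSDCurve(np.arange(1, 6.0) * 2, np.ones(5), n5)
        with pytest.raises(ValueError):
            fit_aprw(a, b)


class TestMotilityMetrics:
    def test_formulas(self):
        fit = APRWFit(2.0, 1.0, 1.0, 1.0, 0.0, 0.0, True)
        m = motility_metrics(fit)
        assert m.D_p == pytest.approx(1.0)
        assert m.D_np == pytest.approx(0.25)
        assert m.D_t == pytest.approx(1.25)
        assert m.phi == pytest.approx(4.0)

    def test_symmetric_axes_give_phi_one(self):
        fit = APRWFit(10.0, 0.5, 10.0, 0.5, 0.1, 0.0, True)
        assert motility_metrics(fit).phi == pytest.approx(1.0)

    def test_zero_nonprimary_flags_phi(self):
        fit = APRWFit(10.0, 0.5, 0.0, 0.5, 0.1, 0.0, True)
        assert np.isnan(motility_metrics(fit).phi)


class TestPopulationSummary:
    def _fit(self, s_p, p_p=1.0, s_np=1.0, p_np=1.0):
        return APRWFit(s_p, p_p, s_np, p_np, 0.0, 0.0, True)

    def test_single_fit_identity(self):
        s = population_summary([self._fit(10.0)])
        assert s["S_p"] == 10.0 and s["n_cells"] == 1

    def test_two_fit_mean(self):
        s = population_summary([self._fit(10.0), self._fit(20.0)])
        assert s["S_p"] == pytest.approx(15.0)

    def test_mean_of_ratios_differs_from_ratio_of_means(self):
        # cell A: D_p = 25, D_np = 0.25; cell B: D_p = 1, D_np = 1
        a = APRWFit(10.0, 1.0, 1.0, 1.0, 0.0, 0.0, True)
        b = APRWFit(2.0, 1.0, 2.0, 1.0, 0.0, 0.0, True)
        s = population_summary([a, b])
        assert s["phi"] == pytest.approx((100.0 + 1.0) / 2)
        assert s["phi_of_means"] == pytest.approx((25.0 + 1.0) / (0.25 + 1.0))
        assert s["phi"] != pytest.approx(s["phi_of_means"])

    def test_non_converged_excluded_and_counted(self):
        bad = APRWFit(np.nan, np.nan, np.nan, np.nan, np.nan, np.inf, False)
        s = population_summary([self._fit(10.0), bad])
        assert s["n_cells"] == 1 and s["n_excluded"] == 1

    def test_all_failed_raises(self):
        bad = APRWFit(np.nan, np.nan, np.nan, np.nan, np.nan, np.inf, False)
        with pytest.raises(ValueError):
            population_summary([bad])


class TestOrientationProfile:
    def test_one_dimensional_motion_occupies_only_two_bins(self, rng):
        x = np.cumsum(rng.normal(0, 3, 40))
        pos = np.column_stack([np.r_[0, x], np.zeros(41)])
        ts = TrackSet((make_track("a", pos),), dt=1.0)
        prof = orientation_profile(ts, n_bins=8)
        occupied = np.where(prof.n_steps > 0)[0]
        centres = 0.5 * (prof.angle_bins[:-1] + prof.angle_bins[1:])
        assert set(np.round(centres[occupied])) <= {22.0, 202.0}  # 0 and 180 bins
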