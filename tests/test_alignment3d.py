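import numpy as np
import pytest

from clutchscope.alignment3d import (AffineTransform2D, DriftTrajectory,
                                     PolynomialWarp2D, align_z_rigid, assign_z,
                                     correct_drift, estimate_drift,
                                     fit_polynomial_warp, fit_z_calibration,
                                     group_fiducials, load_transforms,
                                     match_beads, refine_affine, regroup_frames,
                                     registration_report, save_transforms)
from clutchscope.locdata_io import LocalizationTable
from clutchscope.synthdata import default_z_calibration


def bead_scan_table(calib, z_values, noise_sd=0.0, rng=None):
    wx = calib.wx(z_values)
    wy = calib.wy(z_values)
    if noise_sd and rng is not None:
        wx = wx + rng.normal(0, noise_sd, len(z_values))
        wy = wy + rng.normal(0, noise_sd, len(z_values))
    frames = np.arange(len(z_values))
    return LocalizationTable.from_arrays(
        np.zeros_like(z_values), np.zeros_like(z_values),
        frame=frames, wx=wx, wy=wy)


class TestZCalibration:
    def test_generative_round_trip(self):
        truth = default_z_calibration()
        z = np.arange(-800.0, 800.0, 10.0)
        # extend validity by using the truth curves directly over +-800
        wx, wy = truth.wx(z), truth.wy(z)
        t = LocalizationTable.from_arrays(np.zeros_like(z), np.zeros_like(z),
                                          frame=np.arange(len(z)), wx=wx, wy=wy)
        calib = fit_z_calibration(t, z=z)
        np.testing.assert_allclose(calib.cx, truth.cx, rtol=1e-6, atol=1e-9)
        np.testing.assert_allclose(calib.cy, truth.cy, rtol=1e-6, atol=1e-9)
        assert calib.rms < 1e-6

    def test_symmetric_widths_rejected(self):
        z = np.arange(-400.0, 400.0, 10.0)
        w = 350.0 + 6e-4 * z ** 2
        t = LocalizationTable.from_arrays(np.zeros_like(z), np.zeros_like(z),
                                          frame=np.arange(len(z)), wx=w, wy=w)
        with pytest.raises(ValueError, match="monotone"):
            fit_z_calibration(t, z=z)

    def test_too_few_positions(self):
        truth = default_z_calibration()
        z = np.arange(-50.0, 50.0, 10.0)
        t = bead_scan_table(truth, z)
        with pytest.raises(ValueError, match="20 distinct"):
            fit_z_calibration(t, z=z)


class TestAssignZ:
    def test_exact_inversion(self, rng):
        calib = default_z_calibration()
        z0 = rng.uniform(-350, 350, 500)
        t = LocalizationTable.from_arrays(
            rng.uniform(0, 1000, 500), rng.uniform(0, 1000, 500),
            wx=calib.wx(z0), wy=calib.wy(z0))
        out, dropped = assign_z(t, calib)
        assert dropped == 0
        assert np.max(np.abs(out.column("z") - z0)) <= 1.0

    def test_noise_degrades_monotonically(self, rng):
        calib = default_z_calibration()
        z0 = rng.uniform(-300, 300, 800)
        errs = []
        for sigma in (2.0, 5.0, 15.0):
            t = LocalizationTable.from_arrays(
                np.zeros(800), np.zeros(800),
                wx=calib.wx(z0) + rng.normal(0, sigma, 800),
                wy=calib.wy(z0) + rng.normal(0, sigma, 800))
            out, _ = assign_z(t, calib, reject=np.inf)
            # match retained records by position in the kept order
            errs.append(np.median(np.abs(out.column("z") - z0)))
        assert errs[0] < errs[1] < errs[2]
        assert errs[1] < 50.0

    def test_focal_plane_symmetry(self):
        calib = default_z_calibration()
        t = LocalizationTable.from_arrays([0.0], [0.0],
                                          wx=[calib.wx(0.0)], wy=[calib.wy(0.0)])
        out, _ = assign_z(t, calib)
        assert abs(out.column("z")[0]) <= 1.0

    def test_bad_widths_dropped(self):
        calib = default_z_calibration()
        t = LocalizationTable.from_arrays([0.0, 1.0], [0.0, 1.0],
                                          wx=[calib.wx(0.0), 1e6],
                                          wy=[calib.wy(0.0), 1e6])
        out, dropped = assign_z(t, calib)
        assert len(out) == 1 and dropped == 1


class TestRegroupFrames:
    def test_integer_division(self):
        t = LocalizationTable.from_arrays(np.arange(10.0), np.zeros(10),
                                          frame=np.arange(10))
        out = regroup_frames(t, 5)
        assert set(out.column("frame")) == {0, 1}
        np.testing.assert_array_equal(out.column("x"), t.column("x"))

    def test_identity(self):
        t = LocalizationTable.from_arrays([1.0], [2.0], frame=[9])
        assert regroup_frames(t, 1) is t

    def test_default_group_five(self):
        import inspect

        assert inspect.signature(regroup_frames).parameters["group"].default == 5


def known_warp():
    cx = np.array([5.0, 1.001, 2e-4, 1e-8, -2e-8, 3e-9])
    cy = np.array([-3.0, -1e-4, 0.999, 2e-8, 1e-8, -1e-8])
    return PolynomialWarp2D(cx, cy)


class TestPolynomialWarp:
    def test_identity_fit(self, rng):
        pts = rng.uniform(0, 40000, (25, 2))
        warp = fit_polynomial_warp(pts, pts)
        assert warp.rms < 1e-9
        np.testing.assert_allclose(warp.apply(pts), pts, atol=1e-9)

    def test_generative_round_trip(self, rng):
        truth = known_warp()
        grid = np.array([(i * 10000.0, j * 10000.0)
                         for i in range(5) for j in range(5)])
        warp = fit_polynomial_warp(grid, truth.apply(grid))
        probe = rng.uniform(0, 40000, (200, 2))
        np.testing.assert_allclose(warp.apply(probe), truth.apply(probe),
                                   atol=1e-6)
        assert warp.rms < 1e-6

    def test_noise_residual_scale(self, rng):
        """Least-squares residual RMS under isotropic noise sigma follows the
        sqrt(2 * (1 - p/n)) law (p = 6 parameters per axis, n = 25 beads)."""
        truth = known_warp()
        grid = np.array([(i * 10000.0, j * 10000.0)
                         for i in range(5) for j in range(5)])
        sigma = 2.0
        rms = []
        for _ in range(50):
            noisy = truth.apply(grid) + rng.normal(0, sigma, grid.shape)
            rms.append(fit_polynomial_warp(grid, noisy).rms)
        expected = sigma * np.sqrt(2 * (1 - 6 / 25))
        assert np.mean(rms) == pytest.approx(expected, rel=0.1)

    def test_too_few_pairs(self, rng):
        pts = rng.uniform(0, 100, (5, 2))
        with pytest.raises(ValueError):
            fit_polynomial_warp(pts, pts)


class TestRefineAffine:
    def test_identity(self, rng):
        pts = rng.uniform(0, 1000, (8, 2))
        tf = refine_affine(pts, pts)
        np.testing.assert_allclose(tf.linear, np.eye(2), atol=1e-12)
        np.testing.assert_allclose(tf.translation, 0, atol=1e-9)

    def test_rotation_translation_recovery(self, rng):
        theta = np.deg2rad(0.5)
        R = np.array([[np.cos(theta), -np.sin(theta)],
                      [np.sin(theta), np.cos(theta)]])
        t = np.array([10.0, -7.0])
        pts = rng.uniform(0, 20000, (8, 2))
        tf = refine_affine(pts, pts @ R.T + t)
        np.testing.assert_allclose(tf.linear, R, atol=1e-9)
        np.testing.assert_allclose(tf.translation, t, atol=1e-6)

    def test_noise_residual(self, rng):
        pts = rng.uniform(0, 20000, (40, 2))
        sigma = 3.0
        tf = refine_affine(pts, pts + rng.normal(0, sigma, pts.shape))
        assert tf.rms == pytest.approx(sigma * np.sqrt(2), rel=0.35)

    def test_collinear_rejected(self):
        pts = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]])
        with pytest.raises(ValueError, match="collinear"):
            refine_affine(pts, pts)


class TestAlignZRigid:
    def test_exact_offset(self):
        assert align_z_rigid([100.0, 50.0], [60.0, 10.0]) == 40.0

    def test_mean_of_offsets(self):
        assert align_z_rigid([38.0, 42.0], [0.0, 0.0]) == 40.0

    def test_noisy_offsets(self, rng):
        z_b = rng.uniform(-100, 100, 10)
        z_a = z_b + 40.0 + rng.normal(0, 10.0, 10)
        assert align_z_rigid(z_a, z_b) == pytest.approx(40.0, abs=2 * 10 / np.sqrt(10))

    def test_no_beads(self):
        with pytest.raises(ValueError):
            align_z_rigid([], [])


def make_bead_table(rng, positions, n_frames, noise_sd=0.0, drift=None,
                    visible_frac=1.0):
    rows_x, rows_y, rows_z, rows_f = [], [], [], []
    for p in positions:
        frames = np.arange(n_frames)
        if visible_frac < 1.0:
            frames = frames[rng.random(n_frames) < visible_frac]
        pos = np.tile(np.asarray(p, float), (len(frames), 1))
        if drift is not None:
            pos = pos + drift[frames]
        pos = pos + rng.normal(0, noise_sd, pos.shape)
        rows_x.append(pos[:, 0]); rows_y.append(pos[:, 1])
        rows_z.append(pos[:, 2]); rows_f.append(frames)
    return LocalizationTable.from_arrays(
        np.concatenate(rows_x), np.concatenate(rows_y),
        z=np.concatenate(rows_z), frame=np.concatenate(rows_f))


class TestGroupFiducials:
    def test_three_stationary_beads(self, rng):
        pos = np.array([[0, 0, 0], [20000, 0, 10], [0, 20000, -10]], float)
        t = make_bead_table(rng, pos, 1000, noise_sd=3.0)
        clusters = group_fiducials(t)
        assert len(clusters) == 3
        assert all(c.n_frames > 990 for c in clusters)

    def test_transient_bead_discarded(self, rng):
        pos = np.array([[0, 0, 0], [20000, 0, 0]], float)
        t1 = make_bead_table(rng, pos[:1], 1000, noise_sd=3.0)
        t2 = make_bead_table(rng, pos[1:], 1000, noise_sd=3.0, visible_frac=0.1)
        import pandas as pd

        t = LocalizationTable(pd.concat([t1.data, t2.data], ignore_index=True))
        clusters = group_fiducials(t)
        assert len(clusters) == 1

    def test_distant_beads_never_merged(self, rng):
        pos = np.array([[0, 0, 0], [10000, 0, 0]], float)
        t = make_bead_table(rng, pos, 200, noise_sd=3.0)
        clusters = group_fiducials(t)
        assert len(clusters) == 2

    def test_no_beads_error(self, rng):
        t = make_bead_table(rng, np.array([[0.0, 0.0, 0.0]]), 100,
                            visible_frac=0.05)
        with pytest.raises(ValueError, match="persistent"):
            group_fiducials(t)


class TestDrift:
    def test_linear_drift_recovery(self, rng):
        n_frames = 2000
        drift = np.column_stack([0.1 * np.arange(n_frames),
                                 np.zeros(n_frames), np.zeros(n_frames)])
        pos = rng.uniform(0, 40000, (5, 3))
        t = make_bead_table(rng, pos, n_frames, noise_sd=5.0, drift=drift)
        clusters = group_fiducials(t)
        traj = estimate_drift(t, clusters)
        rmse = np.sqrt(np.mean((traj.displacement[:, 0] - drift[:, 0]) ** 2))
        assert rmse <= 2.0

    def test_zero_drift(self, rng):
        pos = rng.uniform(0, 40000, (5, 3))
        t = make_bead_table(rng, pos, 500, noise_sd=5.0)
        traj = estimate_drift(t, group_fiducials(t))
        assert np.abs(traj.displacement).max() < 5.0 / np.sqrt(5)

    def test_step_drift_recovered_within_window(self, rng):
        n_frames = 1000
        drift = np.zeros((n_frames, 3))
        drift[500:, 0] = 20.0
        t = make_bead_table(rng, np.array([[0.0, 0.0, 0.0]]), n_frames,
                            noise_sd=0.0, drift=drift)
        traj = estimate_drift(t, group_fiducials(t), smooth_window=50)
        assert traj.displacement[400, 0] == pytest.approx(0.0, abs=0.5)
        assert traj.displacement[600, 0] == pytest.approx(20.0, abs=0.5)
        mid = traj.displacement[450:550, 0]
        assert np.all(np.diff(mid) >= -1e-9)  # monotone ramp through the step

    def test_correct_drift_inverse(self, rng):
        n_frames = 300
        drift = np.column_stack([np.linspace(0, 30, n_frames),
                                 np.linspace(0, -12, n_frames),
                                 np.zeros(n_frames)])
        traj = DriftTrajectory(np.arange(n_frames), drift, 0)
        t = LocalizationTable.from_arrays(
            rng.uniform(0, 1000, 500), rng.uniform(0, 1000, 500),
            z=rng.uniform(-50, 50, 500), frame=rng.integers(0, n_frames, 500))
        drifted = LocalizationTable(t.data.assign(
            x=t.column("x") + traj.at(t.column("frame"))[:, 0],
            y=t.column("y") + traj.at(t.column("frame"))[:, 1],
            z=t.column("z") + traj.at(t.column("frame"))[:, 2]))
        back = correct_drift(drifted, traj)
        np.testing.assert_allclose(back.xy, t.xy, atol=1e-9)

    def test_zero_trajectory_identity(self, rng):
        traj = DriftTrajectory(np.arange(10), np.zeros((10, 3)), 0)
        t = LocalizationTable.from_arrays([1.0], [2.0], frame=[5])
        out = correct_drift(t, traj)
        assert out.column("x")[0] == 1.0

    def test_post_correction_cluster_sd(self, rng):
        n_frames = 1000
        drift = np.column_stack([np.linspace(0, 80, n_frames),
                                 np.linspace(0, 40, n_frames),
                                 np.zeros(n_frames)])
        noise = 5.0
        t = make_bead_table(rng, np.array([[0.0, 0.0, 0.0],
                                           [30000.0, 0.0, 0.0]]),
                            n_frames, noise_sd=noise, drift=drift)
        clusters = group_fiducials(t)
        corrected = correct_drift(t, estimate_drift(t, clusters))
        first = clusters[0].indices
        sd = corrected.data.iloc[first][["x", "y"]].to_numpy().std(axis=0).mean()
        assert sd == pytest.approx(noise, rel=0.12)


class TestRegistrationReport:
    def test_perfect(self):
        pts = np.random.default_rng(0).uniform(0, 100, (5, 3))
        rep = registration_report(pts, pts)
        assert rep.mean == 0.0 and rep.sd == 0.0

    def test_constant_offset(self):
        pts = np.zeros((4, 3))
        shifted = pts + np.array([5.0, 0.0, 0.0])
        rep = registration_report(pts, shifted)
        assert rep.mean == 5.0 and rep.sd == 0.0


class TestEndToEndRegistration:
    @pytest.mark.parametrize("seed", [0, 1])
    def test_full_workflow_recovery(self, seed):
        """Known warp + drift + z offset reduced below 2x bead noise."""
        rng = np.random.default_rng(seed)
        noise = 3.0
        n_frames = 600
        truth_warp = known_warp()
        drift = np.column_stack([np.linspace(0, 40, n_frames),
                                 np.linspace(0, -25, n_frames),
                                 np.linspace(0, 10, n_frames)])
        z_off = 40.0
        pos = np.column_stack([rng.uniform(0, 40000, (10, 2)),
                               rng.uniform(-200, 200, 10)])
        beads_a = make_bead_table(rng, pos, n_frames, noise_sd=noise, drift=drift)
        # channel b sees warped lateral positions, a z offset and the same drift
        pos_b = np.column_stack([truth_warp.apply(pos[:, :2]), pos[:, 2] + z_off])
        beads_b = make_bead_table(rng, pos_b, n_frames, noise_sd=noise, drift=drift)

        ca = group_fiducials(beads_a)
        cb = group_fiducials(beads_b)
        a_corr = correct_drift(beads_a, estimate_drift(beads_a, ca))
        b_corr = correct_drift(beads_b, estimate_drift(beads_b, cb))
        ca = group_fiducials(a_corr)
        cb = group_fiducials(b_corr)
        pa = np.array([c.position for c in ca])
        pb = np.array([c.position for c in cb])
        pairs = match_beads(pa, pb, radius=2000.0)
        assert len(pairs) == 10
        warp = fit_polynomial_warp(pb[pairs[:, 1], :2], pa[pairs[:, 0], :2])
        b_xy = warp.apply(pb[pairs[:, 1], :2])
        affine = refine_affine(b_xy, pa[pairs[:, 0], :2])
        b_xy = affine.apply(b_xy)
        dz = align_z_rigid(pa[pairs[:, 0], 2], pb[pairs[:, 1], 2])
        assert dz == pytest.approx(-z_off, abs=2.0)
        b_aligned = np.column_stack([b_xy, pb[pairs[:, 1], 2] + dz])
        rep = registration_report(pa[pairs[:, 0]], b_aligned, z_offset=dz)
        assert rep.mean < 2 * noise


class TestSerialization:
    def test_bit_exact_round_trip(self, tmp_path, rng):
        warp = known_warp()
        affine = AffineTransform2D(np.array([[1.0, 1e-5], [-1e-5, 1.0]]),
                                   np.array([3.0, -2.0]))
        traj = DriftTrajectory(np.arange(100), rng.normal(0, 1, (100, 3)), 0)
        calib = default_z_calibration()
        p = tmp_path / "tf.json"
        save_transforms(p, warp=warp, affine=affine, z_offset=12.5,
                        drift_a=traj, calibration=calib)
        back = load_transforms(p)
        pts = rng.uniform(0, 40000, (50, 2))
        np.testing.assert_array_equal(back["warp"].apply(pts), warp.apply(pts))
        np.testing.assert_array_equal(back["affine"].apply(pts), affine.apply(pts))
        assert back["z_offset"] == 12.5
        np.testing.assert_array_equal(back["drift_a"].displacement,
                                      traj.displacement)
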