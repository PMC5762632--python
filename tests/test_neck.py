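import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from impactkit.io import DT_S, GRAVITY, N_SAMPLES
from impactkit import neck
from impactkit.preprocess import five_point_derivative
from tests.conftest import make_signals


def _stationary_params(lever=None):
    return neck.NeckModelParams(lever_arm=np.zeros(3) if lever is None else lever)


class TestCogTransform:
    def test_zero_lever_arm_is_identity(self, rng):
        sig = make_signals(lin_acc=rng.normal(size=(3, 100)),
                           ang_vel=rng.normal(size=(3, 100)))
        out = neck.transform_acc_to_cog(sig, _stationary_params())
        np.testing.assert_array_equal(out, sig.lin_acc)

    def test_centripetal_term_for_constant_spin(self):
        # constant spin about IS, lever along AP: a_cog = -|w|^2 r on AP
        w = 10.0
        ang = np.zeros((3, 100)); ang[2] = w
        sig = make_signals(ang_vel=ang)
        r = np.array([0.05, 0.0, 0.0])
        out = neck.transform_acc_to_cog(sig, neck.NeckModelParams(lever_arm=r))
        np.testing.assert_allclose(out[0], -w ** 2 * 0.05 / GRAVITY, atol=1e-9)
        np.testing.assert_allclose(out[2], 0.0, atol=1e-9)

    def test_matches_rigid_body_point_simulation(self, time_s):
        # smooth omega(t); compare against numerically differentiating the
        # trajectory of a lever-arm point on the rotating body
        omega = np.zeros((3, 100))
        omega[2] = 3.0 * np.sin(2 * np.pi * 8 * time_s)
        omega[0] = 1.5 * np.cos(2 * np.pi * 5 * time_s)
        sig = make_signals(ang_vel=omega)
        r = np.array([0.03, -0.01, 0.04])
        out = neck.transform_acc_to_cog(
            sig, neck.NeckModelParams(lever_arm=r)) * GRAVITY

        # body-frame acceleration of the point: alpha x r + w x (w x r)
        alpha = five_point_derivative(omega, DT_S)
        expected = (np.cross(alpha.T, r) + np.cross(
            omega.T, np.cross(omega.T, r))).T
        np.testing.assert_allclose(out[:, 5:-5], expected[:, 5:-5],
                                   atol=1e-6 * np.abs(expected).max())


class TestHeadPose:
    def test_zero_signals(self, zero_signals):
        traj = neck.integrate_head_pose(zero_signals, _stationary_params())
        np.testing.assert_allclose(traj.orientations[-1], np.eye(3), atol=1e-12)
        assert np.all(traj.cog_pos == 0.0)

    def test_constant_spin_closed_form(self):
        ang = np.zeros((3, 100)); ang[2] = np.pi
        traj = neck.integrate_head_pose(make_signals(ang_vel=ang),
                                        _stationary_params())
        expected = Rotation.from_rotvec([0, 0, np.pi * 0.099]).as_matrix()
        np.testing.assert_allclose(traj.orientations[-1], expected, atol=1e-6)

    def test_round_trip_of_analytic_trajectory(self, time_s):
        # prescribe a smooth pose, differentiate analytically to signals,
        # re-integrate, compare
        theta = 0.3 * np.sin(2 * np.pi * 5 * time_s)   # rotation about LR
        omega = np.zeros((3, 100))
        omega[1] = 0.3 * 2 * np.pi * 5 * np.cos(2 * np.pi * 5 * time_s)
        acc_world = np.zeros((3, 100))
        acc_world[0] = 2.0 * np.sin(2 * np.pi * 6 * time_s)  # m/s^2
        R = np.stack([Rotation.from_rotvec([0, a, 0]).as_matrix() for a in theta])
        acc_body = np.einsum("nij,jn->in", R.transpose(0, 2, 1), acc_world)
        sig = make_signals(lin_acc=acc_body / GRAVITY, ang_vel=omega)
        traj = neck.integrate_head_pose(sig, _stationary_params())

        ang_err = max(np.linalg.norm(Rotation.from_matrix(
            traj.orientations[k] @ R[k].T).as_rotvec()) for k in range(100))
        assert ang_err < 1e-3
        # analytic double integral of the world acceleration
        w = 2 * np.pi * 6
        pos = 2.0 * (time_s / w - np.sin(w * time_s) / w ** 2)
        assert np.abs(traj.cog_pos[0] - pos).max() < 1e-3


class TestLinkage:
    def test_stationary_head(self, zero_signals):
        params = _stationary_params()
        traj = neck.integrate_head_pose(zero_signals, params)
        nmt = neck.solve_linkage(traj, params)
        assert np.abs(nmt.theta_lr).max() == 0.0
        assert np.abs(nmt.theta_is).max() == 0.0
        assert np.abs(nmt.d).max() == 0.0

    def test_forward_kinematics_round_trip(self, time_s):
        # prescribe theta_lr(t) with the torso base fixed and the neck
        # orientation held at identity; the implied head pose must be
        # solved back to the planted angles
        params = _stationary_params()
        L, h = params.neck_length, params.cog_height
        theta = 0.4 * np.sin(2 * np.pi * 7 * time_s)
        J0 = np.array([0.0, 0.0, -h])
        R = np.stack([neck._universal_joint(a, 0.0) for a in theta])
        cog = J0[:, None] + np.einsum("nij,j->in", R, np.array([0, 0, h]))
        traj = neck.HeadTrajectory(orientations=R, cog_pos=cog,
                                   cog_vel=np.zeros((3, 100)),
                                   cog_acc=np.zeros((3, 100)))
        nmt = neck.solve_linkage(traj, params)
        rms = np.sqrt(np.mean((nmt.theta_lr - theta) ** 2))
        assert rms <= 1e-3
        assert np.abs(nmt.d).max() < 1e-4
        # link lengths conserved along the whole trajectory
        neck_len = np.linalg.norm(nmt.head_base - nmt.base_pos, axis=0)
        head_len = np.linalg.norm(nmt.head_cog - nmt.head_base, axis=0)
        np.testing.assert_allclose(neck_len, L, rtol=1e-9)
        np.testing.assert_allclose(head_len, h, rtol=1e-9)

    def test_pure_translation_gives_positive_offset(self):
        # head slides along AP with fixed orientation: the optimal neck tilt
        # leaves a residual base offset sqrt(L^2 + x^2) - L > 0
        params = _stationary_params()
        L = params.neck_length
        x = np.linspace(0, 0.05, 100)
        cog = np.zeros((3, 100)); cog[0] = x
        traj = neck.HeadTrajectory(
            orientations=np.broadcast_to(np.eye(3), (100, 3, 3)).copy(),
            cog_pos=cog, cog_vel=np.zeros((3, 100)), cog_acc=np.zeros((3, 100)))
        nmt = neck.solve_linkage(traj, params)
        expected = np.sqrt(L ** 2 + x ** 2) - L
        np.testing.assert_allclose(nmt.d, expected, atol=1e-12)
        assert nmt.d[-1] > 0

    def test_offset_invariant_to_global_rotation(self, time_s):
        params = _stationary_params()
        rng = np.random.default_rng(3)
        omega = rng.normal(scale=2.0, size=(3, 100))
        acc = rng.normal(scale=1.0, size=(3, 100))
        sig = make_signals(lin_acc=acc, ang_vel=omega)
        traj = neck.integrate_head_pose(sig, params)
        d0 = neck.solve_linkage(traj, params).d

        Q = Rotation.random(random_state=11).as_matrix()
        rotated = neck.HeadTrajectory(
            orientations=np.einsum("ij,njk->nik", Q, traj.orientations),
            cog_pos=Q @ traj.cog_pos, cog_vel=Q @ traj.cog_vel,
            cog_acc=Q @ traj.cog_acc)
        d1 = neck.solve_linkage(rotated, params).d
        np.testing.assert_allclose(d1, d0, atol=1e-10)


class TestModelFeatures:
    def _stationary_nmt(self):
        params = _stationary_params()
        sig = make_signals()
        return neck.solve_linkage(neck.integrate_head_pose(sig, params), params)

    def test_stationary_trajectory(self):
        out = neck.model_features(self._stationary_nmt())
        assert len(out) == 33
        assert out["nm_signmatch_lr"] == 100.0
        assert out["nm_signmatch_is"] == 100.0
        peaks = [v for k, v in out.items() if k.startswith("nm_peak")]
        # stencil differentiation of constant positions leaves only
        # floating-point dust
        assert all(abs(v) < 1e-9 for v in peaks)

    def test_signmatch_construction(self):
        nmt = self._stationary_nmt()
        nmt.theta_lr = np.full(N_SAMPLES, 0.2)
        nmt.neck_angles[1] = 0.1
        assert neck.model_features(nmt)["nm_signmatch_lr"] == 100.0
        nmt.neck_angles[1] = -0.1
        assert neck.model_features(nmt)["nm_signmatch_lr"] == 0.0

    def test_peaks_match_brute_force(self, rng):
        params = _stationary_params()
        sig = make_signals(lin_acc=rng.normal(size=(3, 100)),
                           ang_vel=rng.normal(scale=2, size=(3, 100)))
        nmt = neck.solve_linkage(neck.integrate_head_pose(sig, params), params)
        out = neck.model_features(nmt)
        assert out["nm_peak_angle_uj_lr"] == np.abs(nmt.theta_lr).max()
        assert out["nm_peak_base_offset"] == nmt.d.max()
        disp = np.linalg.norm(nmt.head_cog - nmt.head_cog[:, [0]], axis=0)
        assert out["nm_peak_disp_head_cog"] == disp.max()
        vel = five_point_derivative(nmt.theta_is, DT_S)
        assert out["nm_peak_angvel_uj_is"] == np.abs(vel).max()


class TestCouplingRatios:
    def test_proportional_channels(self):
        lin = np.zeros((3, 100)); lin[0] = 1.0          # 1 g AP
        sig = make_signals(lin_acc=lin)
        sig.ang_acc = np.zeros((3, 100)); sig.ang_acc[1] = 2.0  # sagittal
        out = neck.coupling_ratios(sig)
        assert out["cr_sag_ap_mean"] == pytest.approx(2.0)
        assert out["cr_sag_ap_std"] == pytest.approx(0.0, abs=1e-12)
        assert out["cr_sag_ap_peak"] == pytest.approx(2.0)

    def test_all_zero_signals_deadband(self, zero_signals):
        out = neck.coupling_ratios(zero_signals)
        assert len(out) == 18
        assert all(v == 0.0 for v in out.values())

    def test_statistics_match_brute_force(self, rng):
        sig = make_signals(lin_acc=rng.normal(scale=2, size=(3, 100)),
                           ang_vel=rng.normal(size=(3, 100)))
        out = neck.coupling_ratios(sig)
        denom = sig.lin_acc[2]                           # IS
        keep = np.abs(denom) >= 0.5
        ratio = sig.ang_acc[0][keep] / denom[keep]       # coronal / IS
        assert out["cr_cor_is_mean"] == pytest.approx(ratio.mean())
        assert out["cr_cor_is_std"] == pytest.approx(ratio.std())
        assert out["cr_cor_is_peak"] == pytest.approx(np.abs(ratio).max())


def test_model_feature_block_is_complete(rng):
    from impactkit.registry import BLOCKS
    sig = make_signals(lin_acc=rng.normal(size=(3, 100)),
                       ang_vel=rng.normal(size=(3, 100)))
    out = neck.model_feature_block(sig, _stationary_params(np.array([0.02, 0, 0.03])))
    assert set(out) == set(BLOCKS["model"])
    assert all(np.isfinite(v) for v in out.values())
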