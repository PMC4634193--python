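"""Tip kinematics: classification, velocity, territory, arrival, extent."""

import numpy as np
import pytest

from micromot import motility
from micromot.motility import ReferencePoint, TipTrajectory


def _traj(points, dt=45.0, ref=None, tip_id="t0"):
    points = np.asarray(points, float)
    return TipTrajectory(
        tip_id=tip_id, t_s=np.arange(len(points)) * dt, xy_um=points, reference=ref
    )


class TestStepKinematics:
    @pytest.mark.parametrize(
        "kind,r0,r1,dt,theta,expected",
        [
            # parent origin: growing away is elongation (+1.33 μm/min > 0.5)
            ("parent_origin", 5.0, 6.0, 45.0, 0.5, "elongation"),
            ("parent_origin", 6.0, 5.0, 45.0, 0.5, "retraction"),
            # target reference: approaching is elongation (4 μm/min approach)
            ("lesion_site", 20.0, 18.0, 30.0, 0.5, "elongation"),
            ("pipette_tip", 18.0, 20.0, 30.0, 0.5, "retraction"),
            # below threshold -> stationary
            ("parent_origin", 5.0, 5.2, 45.0, 0.5, "stationary"),
        ],
    )
    def test_sign_conventions(self, kind, r0, r1, dt, theta, expected):
        ref = ReferencePoint(kind, (0.0, 0.0))
        traj = _traj([[r0, 0.0], [r1, 0.0]], dt=dt, ref=ref)
        steps = motility.step_kinematics(traj, theta_um_min=theta)
        assert len(steps) == 1
        assert steps[0].label == expected

    def test_tie_goes_to_stationary(self):
        """|Δr/Δt| exactly equal to θ is stationary."""
        ref = ReferencePoint("parent_origin", (0.0, 0.0))
        theta = 0.5
        dr = theta * 45.0 / 60.0  # exactly θ over one frame
        traj = _traj([[5.0, 0.0], [5.0 + dr, 0.0]], ref=ref)
        steps = motility.step_kinematics(traj, theta_um_min=theta)
        assert steps[0].label == "stationary"

    def test_negative_theta_rejected(self):
        ref = ReferencePoint("parent_origin", (0.0, 0.0))
        with pytest.raises(ValueError):
            motility.step_kinematics(_traj([[1, 0], [2, 0]], ref=ref), theta_um_min=-0.1)

    def test_partition_property(self, basal_gt, lesion_gt):
        """Every interval of every trajectory gets exactly one label."""
        labels = {"elongation", "retraction", "stationary"}
        for gt in (basal_gt, lesion_gt):
            for traj in motility.from_ground_truth(gt):
                steps = motility.step_kinematics(traj)
                assert len(steps) == len(traj) - 1
                assert all(s.label in labels for s in steps)

    def test_radial_velocity_bounded_by_displacement(self, basal_gt):
        for traj in motility.from_ground_truth(basal_gt):
            for s in motility.step_kinematics(traj):
                dt_min = (s.t1_s - s.t0_s) / 60.0
                assert abs(s.radial_velocity_um_min) <= s.displacement_um / dt_min + 1e-9


class TestMeanTipVelocity:
    def test_constant_step(self):
        """1.5 μm per 45 s step is 2.0 μm/min."""
        pts = [[0, 0], [1.5, 0], [3.0, 0], [4.5, 0]]
        assert motility.mean_tip_velocity(_traj(pts)) == pytest.approx(2.0)

    def test_matches_bruteforce_path_over_time(self, basal_gt):
        """For equal-Δt tracks the mean equals total path length / total time."""
        for traj in motility.from_ground_truth(basal_gt):
            d = sum(
                float(np.hypot(*(traj.xy_um[i + 1] - traj.xy_um[i])))
                for i in range(len(traj) - 1)
            )
            brute = d / ((traj.t_s[-1] - traj.t_s[0]) / 60.0)
            assert motility.mean_tip_velocity(traj) == pytest.approx(brute)

    def test_time_reversal_invariance(self, basal_gt):
        traj = motility.from_ground_truth(basal_gt)[0]
        rev = _traj(traj.xy_um[::-1], dt=45.0)
        assert motility.mean_tip_velocity(rev) == pytest.approx(
            motility.mean_tip_velocity(traj)
        )


class TestTerritory:
    def test_known_radii(self):
        """r ∈ {3.0, 7.5, 5.0} gives a territory of 4.5 μm."""
        ref = ReferencePoint("parent_origin", (0.0, 0.0))
        traj = _traj([[3.0, 0.0], [7.5, 0.0], [5.0, 0.0]], ref=ref)
        assert motility.territory(traj) == pytest.approx(4.5)

    def test_stationary_tip_zero(self):
        ref = ReferencePoint("parent_origin", (0.0, 0.0))
        traj = _traj([[4.0, 0.0]] * 5, ref=ref)
        assert motility.territory(traj) == 0.0

    def test_time_reversal_invariance(self, basal_gt):
        for traj in motility.from_ground_truth(basal_gt)[:3]:
            rev = _traj(traj.xy_um[::-1], dt=45.0, ref=traj.reference)
            assert motility.territory(rev) == pytest.approx(motility.territory(traj))

    def test_nonnegative(self, basal_gt, lesion_gt):
        for gt in (basal_gt, lesion_gt):
            for traj in motility.from_ground_truth(gt):
                assert motility.territory(traj) >= 0.0


class TestTimeToTarget:
    def test_linear_approach(self):
        """60 μm at 1.30 μm/min with a 2 μm disk: about (60-2)/1.30 min."""
        v = 1.30 / 60.0  # μm/s
        t = np.arange(0, 3600, 30.0)
        r = np.maximum(60.0 - v * t, 0.0)
        traj = TipTrajectory("t", t, np.column_stack([r, np.zeros_like(r)]))
        got = motility.time_to_target([traj], (0.0, 0.0), arrival_radius_um=2.0)
        assert got == pytest.approx((60.0 - 2.0) / 1.30, abs=0.5)

    def test_censored_when_no_arrival(self):
        traj = _traj([[30.0, 0.0]] * 4)
        assert motility.time_to_target([traj], (0.0, 0.0), 2.0) is None

    def test_invalid_radius(self):
        with pytest.raises(ValueError):
            motility.time_to_target([], (0, 0), 0.0)


class TestResponseExtent:
    def test_stationary_tips_flag_no_responders(self):
        trajs = [_traj([[20.0, 0.0]] * 6)]
        with pytest.warns(UserWarning, match="no responding"):
            ext = motility.response_extent(trajs, (0.0, 0.0))
        assert ext.max_responding_um is None
        assert ext.n_responding == 0

    def test_responder_and_arriver_distances(self, lesion_gt):
        trajs = motility.from_ground_truth(lesion_gt)
        ext = motility.response_extent(trajs, (0.0, 0.0))
        # responders are exactly the tips within the 35.8 μm response radius
        assert ext.max_responding_um == pytest.approx(34.0, abs=0.1)
        assert ext.max_arriving_um <= ext.max_responding_um + 1e-9

    def test_short_approach_not_a_response(self):
        """A net approach below δ over the required run is not a response."""
        r = [20.0, 19.5, 19.2, 19.0, 19.0, 19.0]  # 1.0 μm total, < δ = 2
        traj = _traj([[x, 0.0] for x in r], dt=30.0)
        with pytest.warns(UserWarning):
            ext = motility.response_extent([traj], (0.0, 0.0))
        assert ext.n_responding == 0


class TestTracking:
    def test_stationary_tip_constant_track(self, registered_mip):
        proj, cfg = registered_mip
        # synthetic constant bright dot movie
        data = np.full((5, 1, 64, 64), 10.0)
        data[:, 0, 30, 40] = 200.0
        from micromot.series import ImageSeries

        series = ImageSeries(data=data, dx_nm=200.0, dy_nm=200.0, dz_nm=1000.0, dt_s=45.0)
        tracks = motility.track_tips(series, [("a", 40 * 0.2, 30 * 0.2)], search_radius_um=1.0)
        assert len(tracks[0]) == 5
        assert np.allclose(tracks[0].xy_um, tracks[0].xy_um[0], atol=0.21)

    def test_recovers_groundtruth_positions(self, registered_mip, basal_gt, basal_movie):
        proj, cfg = registered_mip
        origin = np.asarray(cfg.origin_um[:2])
        seeds = [
            (tip.tip_id, tip.pos_um[0, 0] - origin[0], tip.pos_um[0, 1] - origin[1])
            for tip in basal_gt.tips
        ]
        tracks = motility.track_tips(proj, seeds, search_radius_um=3.5)
        errs = []
        for tip, tr in zip(basal_gt.tips, tracks):
            true_xy = tip.pos_um[: len(tr), :2] - origin
            errs.append(np.linalg.norm(tr.xy_um - true_xy, axis=1).mean())
        assert np.mean(errs) < 0.2  # within one pixel of the truth

    def test_track_ends_when_tip_lost(self):
        from micromot.series import ImageSeries

        data = np.full((4, 1, 64, 64), 10.0)
        for k, x in enumerate([40, 45, 50]):  # dot leaves after frame 2
            data[k, 0, 30, x] = 200.0
        series = ImageSeries(data=data, dx_nm=200.0, dy_nm=200.0, dz_nm=1000.0, dt_s=45.0)
        tracks = motility.track_tips(series, [("a", 8.0, 6.0)], search_radius_um=1.5)
        assert len(tracks[0]) == 3
        assert any(f.startswith("terminated") for f in tracks[0].flags)
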