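"""Sector segmentation, regional velocities, tracking and strain."""

import numpy as np
import pytest

from cstpm import (
    Trajectories,
    analyze,
    circumferential_strain,
    midwall_contour,
    regional_velocities,
    sectorize,
    track_displacement,
)
from cstpm.velocity import VelocityField


def annulus_mask(n=64, r_in=10, r_out=20):
    c = (n - 1) / 2
    yy, xx = np.mgrid[0:n, 0:n]
    r = np.hypot(yy - c, xx - c)
    return (r >= r_in) & (r <= r_out)


def make_field(v, frame_interval=10.0, spacing=(1.0, 1.0)):
    return VelocityField(
        v=v,
        magnitude=np.ones(v.shape[:3]),
        venc=13.9,
        frame_interval=frame_interval,
        pixel_spacing=spacing,
    )


class TestSectorize:
    def test_six_sectors_of_an_annulus_are_balanced(self):
        seg = sectorize(annulus_mask(), n_segments=6)
        counts = np.bincount(seg.labels[seg.mask], minlength=6)
        assert counts.min() > 0
        assert counts.max() - counts.min() <= 0.05 * counts.mean() + 2

    def test_single_segment_covers_whole_mask(self):
        mask = annulus_mask()
        seg = sectorize(mask, n_segments=1)
        assert np.all(seg.labels[mask] == 0)

    def test_rotating_reference_angle_permutes_labels(self):
        mask = annulus_mask()
        seg0 = sectorize(mask, n_segments=6, reference_angle=0.0)
        seg1 = sectorize(mask, n_segments=6, reference_angle=np.pi / 3)
        # a rotation by one sector width shifts every label by one (cyclically)
        shifted = np.mod(seg0.labels[mask] - 1, 6)
        assert np.array_equal(seg1.labels[mask], shifted)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            sectorize(np.zeros((8, 8), bool))

    def test_mask_missing_an_angular_range_rejected(self):
        mask = np.zeros((32, 32), bool)
        mask[2:6, 2:6] = True  # blob in one corner relative to forced centroid
        with pytest.raises(ValueError):
            sectorize(mask, centroid=(16.0, 16.0), n_segments=6)


class TestRegionalVelocities:
    def test_uniform_converging_flow_reads_its_speed(self):
        mask = annulus_mask()
        seg = sectorize(mask)
        c = (mask.shape[0] - 1) / 2
        yy, xx = np.mgrid[0 : mask.shape[0], 0 : mask.shape[1]].astype(float)
        norm = np.hypot(c - yy, c - xx)
        norm[norm == 0] = 1
        v = np.zeros((3,) + mask.shape + (3,))
        v[..., 0] = 2.5 * (c - xx) / norm  # unit vectors toward the centroid
        v[..., 1] = 2.5 * (c - yy) / norm
        out = regional_velocities(make_field(v), seg)
        assert out["v_rad_global"] == pytest.approx([2.5] * 3, abs=1e-10)
        assert out["v_rad_seg"] == pytest.approx(np.full((6, 3), 2.5), abs=1e-10)

    def test_zero_field_gives_zero_curves(self):
        seg = sectorize(annulus_mask())
        out = regional_velocities(make_field(np.zeros((2, 64, 64, 3))), seg)
        for key in out:
            assert np.all(out[key] == 0)

    def test_rigid_rotation_has_no_radial_component(self):
        mask = annulus_mask()
        seg = sectorize(mask)
        c = (mask.shape[0] - 1) / 2
        yy, xx = np.mgrid[0:64, 0:64].astype(float)
        v = np.zeros((1, 64, 64, 3))
        v[0, ..., 0] = -(yy - c)  # tangential field about the centroid
        v[0, ..., 1] = xx - c
        out = regional_velocities(make_field(v), seg)
        assert np.abs(out["v_rad_global"]).max() <= 1e-8
        assert np.abs(out["v_rad_seg"]).max() <= 1e-8
        assert np.all(out["v_long_global"] == 0)

    def test_global_equals_weighted_segment_mean(self):
        rng = np.random.default_rng(7)
        mask = annulus_mask()
        seg = sectorize(mask)
        v = rng.normal(size=(4, 64, 64, 3))
        out = regional_velocities(make_field(v), seg)
        counts = np.bincount(seg.labels[mask], minlength=6).astype(float)
        weighted = (out["v_rad_seg"] * counts[:, None]).sum(axis=0) / counts.sum()
        assert out["v_rad_global"] == pytest.approx(weighted, abs=1e-10)

    def test_extent_mismatch_rejected(self):
        seg = sectorize(annulus_mask(64))
        with pytest.raises(ValueError):
            regional_velocities(make_field(np.zeros((2, 32, 32, 3))), seg)


class TestTrackDisplacement:
    def test_zero_field_is_stationary(self):
        field = make_field(np.zeros((5, 32, 32, 3)))
        traj = track_displacement(field, np.array([[10.0, 12.0]]))
        assert np.all(traj.positions == traj.positions[:, :1])
        assert not traj.clamped.any()

    def test_uniform_velocity_displaces_exactly(self):
        # 1 cm/s = 0.01 mm/ms; with 1 mm pixels and 10 ms frames each step
        # moves 0.1 px along +x; RK2 is exact for a constant field
        v = np.zeros((6, 32, 32, 3))
        v[..., 0] = 1.0
        field = make_field(v, frame_interval=10.0, spacing=(1.0, 1.0))
        traj = track_displacement(field, np.array([[16.0, 10.0]]))
        expected_x = 10.0 + 0.1 * np.arange(6)
        assert traj.positions[0, :, 1] == pytest.approx(expected_x, abs=1e-12)
        assert traj.positions[0, :, 0] == pytest.approx(16.0, abs=1e-12)

    def test_out_of_bounds_seed_rejected(self):
        field = make_field(np.zeros((2, 16, 16, 3)))
        with pytest.raises(ValueError):
            track_displacement(field, np.array([[40.0, 5.0]]))

    def test_escaping_trajectory_clamped_and_flagged(self):
        v = np.zeros((8, 16, 16, 3))
        v[..., 0] = 500.0  # deliberately absurd speed
        field = make_field(v, frame_interval=10.0)
        traj = track_displacement(field, np.array([[8.0, 8.0]]))
        assert traj.clamped[0]
        assert traj.positions[0, :, 1].max() <= 15.0

    def test_phantom_contraction_tracks_analytic_radius(self, phantom64_clean):
        # material radius r(t) = rho * s(t); tracked midwall points must stay
        # within 2% of the wall thickness of the analytic radius
        data = phantom64_clean
        spec = data.spec
        traj = track_displacement(data.truth_velocity, data.contour_seeds)
        c = (spec.matrix - 1) / 2
        radii_px = np.hypot(
            traj.positions[..., 0] - c, traj.positions[..., 1] - c
        )
        times = np.arange(spec.n_frames) * spec.frame_interval
        from cstpm import analytic_motion

        s, *_ = analytic_motion(spec, times)
        expected = (spec.r_mid / spec.pixel_spacing) * s
        wall_px = (spec.r_outer - spec.r_inner) / spec.pixel_spacing
        assert np.abs(radii_px - expected[None, :]).max() <= 0.02 * wall_px


class TestCircumferentialStrain:
    def _seg(self):
        return sectorize(annulus_mask(), n_segments=6)

    def _traj(self, positions):
        return Trajectories(
            positions=positions,
            seeds=positions[:, 0],
            clamped=np.zeros(positions.shape[0], bool),
        )

    def test_stationary_contour_has_zero_strain(self):
        contour = midwall_contour((31.5, 31.5), 15.0, 36)
        pos = np.repeat(contour[:, None], 4, axis=1)
        out = circumferential_strain(self._traj(pos), self._seg())
        assert np.all(out["strain_circ_global"] == 0)
        assert np.all(out["strain_circ_seg"] == 0)

    def test_uniform_scaling_gives_uniform_strain(self):
        contour = midwall_contour((31.5, 31.5), 15.0, 36)
        scales = np.array([1.0, 1.1, 0.9])
        centre = np.array([31.5, 31.5])
        pos = np.stack(
            [centre + s * (contour - centre) for s in scales], axis=1
        )
        out = circumferential_strain(self._traj(pos), self._seg())
        assert out["strain_circ_global"] == pytest.approx([0, 10, -10], abs=1e-9)
        for s in range(6):
            assert out["strain_circ_seg"][s] == pytest.approx([0, 10, -10], abs=1e-9)

    def test_rigid_translation_strain_negligible(self):
        contour = midwall_contour((31.5, 31.5), 15.0, 72)
        pos = np.stack([contour, contour + [1.3, -0.8]], axis=1)
        out = circumferential_strain(self._traj(pos), self._seg())
        assert np.abs(out["strain_circ_global"][1]) <= 1e-9

    def test_strain_starts_at_exactly_zero(self, phantom64_clean):
        data = phantom64_clean
        res = analyze(data.truth_velocity, data.segmentation(), data.contour_seeds)
        assert res.strain_circ_global[0] == 0.0
        assert np.all(res.strain_circ_seg[:, 0] == 0.0)

    def test_global_strain_is_length_weighted_segment_mean(self, phantom64_clean):
        data = phantom64_clean
        seg = data.segmentation()
        traj = track_displacement(data.truth_velocity, data.contour_seeds)
        out = circumferential_strain(
            traj, seg, pixel_spacing=data.truth_velocity.pixel_spacing
        )
        w = out["segment_lengths0"]
        weighted = (out["strain_circ_seg"] * w[:, None]).sum(axis=0) / w.sum()
        assert out["strain_circ_global"] == pytest.approx(weighted, abs=1e-9)

    def test_phantom_strain_matches_closed_form(self, phantom64_clean):
        # tracked circumference shrinks with s(t): strain = -100 a w(t)
        data = phantom64_clean
        res = analyze(data.truth_velocity, data.segmentation(), data.contour_seeds)
        assert np.abs(res.strain_circ_global - data.truth_strain).max() <= 0.5

    def test_sparse_contour_rejected(self):
        contour = midwall_contour((31.5, 31.5), 15.0, 8)  # < 3 points/segment
        pos = np.repeat(contour[:, None], 2, axis=1)
        with pytest.raises(ValueError):
            circumferential_strain(self._traj(pos), self._seg())


class TestResultTable:
    def test_tidy_export_covers_all_scopes(self, phantom64_clean):
        data = phantom64_clean
        res = analyze(data.truth_velocity, data.segmentation(), data.contour_seeds)
        df = res.to_frame()
        assert set(df["scope"]) == {"global"} | {f"seg{i}" for i in range(1, 7)}
        assert len(df) == data.truth_velocity.n_frames * 7
        assert {"v_rad_cm_s", "v_long_cm_s", "strain_circ_pct"} <= set(df.columns)
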