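"""Helical-axis extraction, Cardan decomposition and axis averaging."""

import numpy as np
import pytest
from scipy import stats
from scipy.spatial.transform import Rotation

from wristkin.frames import AnatomicalFrame
from wristkin.helical import (
    BonePose,
    decompose_rotation,
    helical_axis,
    mean_axis,
    recompose_rotation,
    relative_transform,
    screw_transform,
)
from wristkin.transforms import RigidTransform, random_rotation, rotation_about_axis

Z = np.array([0.0, 0.0, 1.0])


def random_screw(rng, max_angle=90.0, max_slide=5.0):
    n = rng.normal(size=3)
    n /= np.linalg.norm(n)
    p = rng.normal(scale=20.0, size=3)
    p -= (p @ n) * n
    angle = rng.uniform(-max_angle, max_angle)
    slide = rng.uniform(-max_slide, max_slide)
    return n, p, angle, slide


class TestHelicalAxis:
    def test_simple_rotation_about_z(self):
        t = screw_transform(Z, np.zeros(3), 30.0, 0.0)
        ha = helical_axis(t, Z)
        assert ha.angle_deg == pytest.approx(30.0, abs=1e-12)
        assert ha.direction == pytest.approx(Z, abs=1e-12)
        assert ha.translation_along == pytest.approx(0.0, abs=1e-12)
        assert ha.axis_point == pytest.approx([0, 0, 0], abs=1e-12)
        assert not ha.degenerate

    def test_pure_translation_degenerate(self):
        t = RigidTransform(np.eye(3), [0.0, 0.0, 2.0])
        ha = helical_axis(t, Z, degenerate_point=[1.0, 1.0, 0.0])
        assert ha.degenerate
        assert ha.translation_along == pytest.approx(2.0)
        assert ha.direction == pytest.approx(Z)
        assert ha.axis_point == pytest.approx([1.0, 1.0, 0.0])

    def test_identity_degenerate_zero(self):
        ha = helical_axis(RigidTransform.identity(), Z)
        assert ha.degenerate
        assert ha.angle_deg == 0.0
        assert ha.translation_along == 0.0

    def test_specific_screw_recovered(self):
        n = np.array([0.36, -0.48, 0.8])
        n /= np.linalg.norm(n)
        p = np.array([10.0, 5.0, -3.0])
        p -= (p @ n) * n
        t = screw_transform(n, p, 47.0, 1.3)
        ha = helical_axis(t, n)
        assert ha.direction == pytest.approx(n, abs=1e-9)
        assert ha.angle_deg == pytest.approx(47.0, abs=1e-9)
        assert ha.translation_along == pytest.approx(1.3, abs=1e-9)
        assert ha.axis_point == pytest.approx(p, abs=1e-9)

    @pytest.mark.parametrize("seed", range(25))
    def test_round_trip_random_screws(self, seed):
        rng = np.random.default_rng(seed)
        n, p, angle, slide = random_screw(rng)
        t = screw_transform(n, p, angle, slide)
        ha = helical_axis(t, n)
        back = ha.to_transform()
        assert np.abs(back.rotation - t.rotation).max() < 1e-9
        assert np.abs(back.translation - t.translation).max() < 1e-9
        # oriented toward the reference: parameters match with matching sign
        assert ha.angle_deg == pytest.approx(angle, abs=1e-9)
        assert ha.translation_along == pytest.approx(slide, abs=1e-9)

    def test_reference_axis_orients_sign(self):
        t = screw_transform(Z, np.zeros(3), 30.0, 1.0)
        ha = helical_axis(t, -Z)
        assert ha.direction == pytest.approx(-Z)
        assert ha.angle_deg == pytest.approx(-30.0)
        assert ha.translation_along == pytest.approx(-1.0)

    def test_coordinate_invariance_under_conjugation(self, rng):
        n, p, angle, slide = random_screw(rng)
        t = screw_transform(n, p, angle, slide)
        g = RigidTransform(random_rotation(rng), rng.uniform(-30, 30, 3))
        conj = g.compose(t).compose(g.inverse())
        ha = helical_axis(t, n)
        ha_c = helical_axis(conj, g.rotation @ n)
        assert ha_c.angle_deg == pytest.approx(ha.angle_deg, abs=1e-9)
        assert ha_c.translation_along == pytest.approx(ha.translation_along, abs=1e-9)
        assert ha_c.direction == pytest.approx(g.rotation @ ha.direction, abs=1e-9)
        # mapped axis point lies on the mapped axis
        mapped = g.apply(ha.axis_point)
        offset = ha_c.axis_point - mapped
        assert np.abs(offset - (offset @ ha_c.direction) * ha_c.direction).max() < 1e-8

    def test_inverse_symmetry(self, rng):
        n, p, angle, slide = random_screw(rng)
        t = screw_transform(n, p, angle, slide)
        ha = helical_axis(t, n)
        ha_inv = helical_axis(t.inverse(), n)
        assert ha_inv.direction == pytest.approx(ha.direction, abs=1e-9)
        assert ha_inv.angle_deg == pytest.approx(-ha.angle_deg, abs=1e-9)
        assert ha_inv.translation_along == pytest.approx(-ha.translation_along, abs=1e-9)

    def test_near_pi_branch(self):
        t = screw_transform(Z, np.array([3.0, 4.0, 0.0]), 180.0 - 1e-8, 0.7)
        ha = helical_axis(t, Z)
        assert abs(ha.angle_deg) == pytest.approx(180.0, abs=1e-6)
        assert np.abs(ha.direction) == pytest.approx(np.abs(Z), abs=1e-6)
        assert ha.translation_along == pytest.approx(0.7, abs=1e-6)


class TestRelativeTransform:
    def make_pose(self, axes, origin, **meta):
        return BonePose(AnatomicalFrame.from_axes(origin, axes), **meta)

    def test_same_pose_gives_identity(self, rng):
        pose = self.make_pose(random_rotation(rng), rng.normal(size=3))
        t = relative_transform(pose, pose)
        assert t.rotation_angle_deg() < 1e-9
        assert np.linalg.norm(t.translation) < 1e-9

    def test_chain_rule(self, rng):
        a0 = random_rotation(rng)
        o0 = rng.normal(size=3) * 10
        ra = rotation_about_axis(rng.normal(size=3), 20.0)
        rb = rotation_about_axis(rng.normal(size=3), 35.0)
        pose0 = self.make_pose(a0, o0)
        pose_a = self.make_pose(ra @ a0, ra @ o0 + [1, 2, 3], nominal_angle_deg=30.0)
        pose_b = self.make_pose(rb @ a0, rb @ o0 + [4, -1, 0], nominal_angle_deg=60.0)
        t_0a = relative_transform(pose0, pose_a)
        t_ab = relative_transform(pose_a, pose_b)
        t_0b = relative_transform(pose0, pose_b)
        chained = t_ab.compose(t_0a)
        assert np.abs(chained.rotation - t_0b.rotation).max() < 1e-9
        assert np.abs(chained.translation - t_0b.translation).max() < 1e-9

    def test_matches_procrustes_marker_oracle(self, rng):
        """Frame-product transform equals the least-squares rigid fit of the
        4-marker clouds {centroid, centroid + axis tips}."""
        a0 = random_rotation(rng)
        o0 = rng.normal(size=3) * 10
        r = rotation_about_axis(rng.normal(size=3), 25.0)
        shift = rng.normal(size=3) * 5
        pose0 = self.make_pose(a0, o0)
        pose1 = self.make_pose(r @ a0, r @ o0 + shift, nominal_angle_deg=30.0)
        t = relative_transform(pose0, pose1)

        markers0 = np.vstack([o0] + [o0 + a0.T[i] for i in range(3)])
        markers1 = np.vstack(
            [pose1.frame.origin]
            + [pose1.frame.origin + pose1.frame.axes.T[i] for i in range(3)]
        )
        mu0, mu1 = markers0.mean(axis=0), markers1.mean(axis=0)
        h = (markers1 - mu1).T @ (markers0 - mu0)
        u, _, vt = np.linalg.svd(h)
        rot = u @ np.diag([1, 1, np.sign(np.linalg.det(u @ vt))]) @ vt
        trans = mu1 - rot @ mu0
        assert np.abs(t.rotation - rot).max() < 1e-9
        assert np.abs(t.translation - trans).max() < 1e-9

    def test_mismatched_metadata_rejected(self, rng):
        p1 = self.make_pose(np.eye(3), [0, 0, 0], subject="s1")
        p2 = self.make_pose(np.eye(3), [1, 0, 0], subject="s2", nominal_angle_deg=30.0)
        with pytest.raises(ValueError, match="different scans"):
            relative_transform(p1, p2)

    def test_unverified_signs_warn(self, rng):
        a0 = np.eye(3)
        pose0 = self.make_pose(a0, [0, 0, 0])
        flipped = a0 * np.array([1.0, -1.0, -1.0])  # 180 deg apart
        pose1 = self.make_pose(flipped, [0, 0, 0], nominal_angle_deg=30.0)
        with pytest.warns(UserWarning, match="unified"):
            relative_transform(pose0, pose1)


class TestDecomposeRotation:
    frame = AnatomicalFrame(np.zeros(3), [1, 0, 0], [0, 1, 0], [0, 0, 1])

    def test_identity(self):
        d = decompose_rotation(np.eye(3), self.frame)
        assert (d.fe_deg, d.rud_deg, d.ps_deg) == (0.0, 0.0, 0.0)

    def test_pure_flexion(self):
        r = rotation_about_axis([0, 1, 0], 30.0)
        d = decompose_rotation(r, self.frame)
        assert d.fe_deg == pytest.approx(30.0, abs=1e-9)
        assert d.rud_deg == pytest.approx(0.0, abs=1e-9)
        assert d.ps_deg == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("seed", range(10))
    def test_forward_compose_oracle(self, seed):
        rng = np.random.default_rng(seed)
        fe, rud, ps = rng.uniform(-60, 60, 3)
        r_local = Rotation.from_euler("YZX", [fe, rud, ps], degrees=True).as_matrix()
        frame = AnatomicalFrame.from_axes(rng.normal(size=3), random_rotation(rng))
        r_world = frame.axes @ r_local @ frame.axes.T
        d = decompose_rotation(r_world, frame)
        assert (d.fe_deg, d.rud_deg, d.ps_deg) == pytest.approx((fe, rud, ps), abs=1e-9)
        assert np.abs(recompose_rotation(d, frame) - r_world).max() < 1e-9

    def test_gimbal_region_refused(self):
        r = rotation_about_axis([0, 1, 0], 95.0)
        with pytest.raises(ValueError, match="gimbal"):
            decompose_rotation(r, self.frame)


class TestMeanAxis:
    def test_identical_axes(self):
        n = np.array([0.0, 0.6, 0.8])
        assert mean_axis(np.tile(n, (5, 1)), Z) == pytest.approx(n)

    def test_sign_invariance(self):
        n = np.array([0.0, 0.6, 0.8])
        out = mean_axis(np.vstack([n, -n]), Z)
        assert out == pytest.approx(n, abs=1e-12)

    def test_von_mises_fisher_recovery(self):
        mu = np.array([0.2, 0.5, 0.84])
        mu /= np.linalg.norm(mu)
        samples = stats.vonmises_fisher(mu, 50.0).rvs(100, random_state=5)
        # randomly flip half the signs: the mean must not care
        signs = np.where(np.arange(100) % 2 == 0, 1.0, -1.0)
        out = mean_axis(samples * signs[:, None], mu)
        assert np.degrees(np.arccos(np.clip(out @ mu, -1, 1))) < 3.0
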