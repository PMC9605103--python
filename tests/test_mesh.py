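"""Mesh I/O, homogeneous-solid mass properties and axis-sign unification."""

import numpy as np
import pytest
import trimesh

from wristkin.mesh import (
    NearSymmetricWarning,
    TriMesh,
    load_mesh,
    mass_properties,
    save_mesh,
    unify_axis_signs,
)
from wristkin.transforms import RigidTransform, random_rotation


def unit_cube() -> TriMesh:
    return trimesh.creation.box(extents=[1.0, 1.0, 1.0])


class TestLoadMesh:
    @pytest.mark.parametrize("ext", ["stl", "ply", "off"])
    def test_format_round_trip(self, tmp_path, ext):
        cube = unit_cube()
        path = save_mesh(cube, tmp_path / f"cube.{ext}")
        loaded = load_mesh(path)
        assert len(loaded.faces) == 12
        assert len(loaded.vertices) == 8
        assert loaded.volume == pytest.approx(1.0, abs=1e-6)
        assert loaded.center_mass == pytest.approx(cube.center_mass, abs=1e-6)

    def test_inverted_winding_repaired(self, tmp_path):
        cube = unit_cube()
        inverted = TriMesh(
            vertices=cube.vertices.copy(), faces=cube.faces[:, ::-1].copy(), process=False
        )
        assert inverted.volume < 0
        path = save_mesh(inverted, tmp_path / "inv.off")
        loaded = load_mesh(path)
        assert loaded.volume > 0
        assert loaded.volume == pytest.approx(1.0, rel=1e-9)

    def test_open_surface_rejected(self, tmp_path):
        cube = unit_cube()
        holed = TriMesh(vertices=cube.vertices.copy(), faces=cube.faces[:-1].copy(),
                        process=False)
        path = tmp_path / "open.off"
        path.write_text(holed.export(file_type="off"))
        with pytest.raises(ValueError, match="watertight"):
            load_mesh(path)

    def test_missing_file_and_bad_format(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_mesh(tmp_path / "nope.stl")
        bad = tmp_path / "mesh.obj"
        bad.write_text("o nothing\n")
        with pytest.raises(ValueError, match="format"):
            load_mesh(bad)


class TestMassProperties:
    def test_unit_cube(self):
        # trimesh boxes are centred; shift to [0,1]^3 for the canonical check
        cube = trimesh.creation.box(extents=[1, 1, 1])
        cube.apply_translation([0.5, 0.5, 0.5])
        with pytest.warns(NearSymmetricWarning):  # all three moments equal
            props = mass_properties(cube)
        assert props.volume == pytest.approx(1.0, rel=1e-12)
        assert props.centroid == pytest.approx([0.5, 0.5, 0.5], abs=1e-12)

    def test_box_principal_moments_closed_form(self):
        a, b, c = 4.0, 2.0, 1.0
        box = trimesh.creation.box(extents=[a, b, c])
        props = mass_properties(box)
        v = a * b * c
        expected = sorted(
            [v * (b**2 + c**2) / 12, v * (a**2 + c**2) / 12, v * (a**2 + b**2) / 12],
            reverse=True,
        )
        assert props.principal_moments == pytest.approx(expected, rel=1e-12)
        # axes are the coordinate axes: largest moment about z (1x... smallest
        # extent), column order follows descending moments
        expected_axes = {0: 2, 1: 1, 2: 0}  # moment rank -> coordinate axis
        for rank, axis in expected_axes.items():
            assert abs(props.principal_axes[axis, rank]) == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize(
        "semi_axes", [(1.0, 1.0, 1.0), (15.0, 10.0, 6.0)], ids=["sphere", "ellipsoid"]
    )
    def test_curved_solids_match_analytic(self, semi_axes):
        # >= 20k faces: inscribed-polyhedron volume within 0.1% of analytic
        sphere = trimesh.creation.icosphere(subdivisions=5, radius=1.0)
        a, b, c = semi_axes
        mesh = TriMesh(vertices=sphere.vertices * np.array(semi_axes),
                       faces=sphere.faces, process=False)
        with pytest.warns(NearSymmetricWarning) if a == b == c else _nullcontext():
            props = mass_properties(mesh)
        v_true = 4.0 * np.pi * a * b * c / 3.0
        assert props.volume == pytest.approx(v_true, rel=1e-3)
        moments_true = sorted(
            [v_true * (b**2 + c**2) / 5, v_true * (a**2 + c**2) / 5,
             v_true * (a**2 + b**2) / 5],
            reverse=True,
        )
        assert props.principal_moments == pytest.approx(moments_true, rel=2e-3)

    def test_sphere_volume_convergence_monotone(self):
        errors = []
        for level in (2, 3, 4, 5):
            mesh = trimesh.creation.icosphere(subdivisions=level, radius=1.0)
            with pytest.warns(NearSymmetricWarning):
                props = mass_properties(mesh)
            errors.append(abs(props.volume - 4 * np.pi / 3))
        assert all(e1 >= e2 for e1, e2 in zip(errors, errors[1:]))

    def test_rigid_invariance(self, rng):
        sphere = trimesh.creation.icosphere(subdivisions=3, radius=1.0)
        mesh = TriMesh(vertices=sphere.vertices * np.array([15.0, 10.0, 6.0]),
                       faces=sphere.faces, process=False)
        props = mass_properties(mesh)
        t = RigidTransform(random_rotation(rng), rng.uniform(-50, 50, 3))
        moved = TriMesh(vertices=t.apply(mesh.vertices), faces=mesh.faces, process=False)
        props2 = mass_properties(moved)
        assert props2.volume == pytest.approx(props.volume, rel=1e-9)
        assert props2.principal_moments == pytest.approx(props.principal_moments, rel=1e-9)
        assert props2.centroid == pytest.approx(t.apply(props.centroid), abs=1e-9)
        mapped = t.rotation @ props.principal_axes
        aligned = unify_axis_signs(props2.principal_axes, mapped)[0]
        assert aligned == pytest.approx(mapped, abs=1e-7)

    def test_monte_carlo_centroid_oracle(self, rng):
        a, b, c = 15.0, 10.0, 6.0
        sphere = trimesh.creation.icosphere(subdivisions=4, radius=1.0)
        mesh = TriMesh(vertices=sphere.vertices * np.array([a, b, c]) + np.array([3, -2, 1]),
                       faces=sphere.faces, process=False)
        props = mass_properties(mesh)
        n = 100_000
        pts = rng.uniform(-1, 1, size=(n, 3)) * np.array([a, b, c]) + np.array([3, -2, 1])
        local = (pts - np.array([3, -2, 1])) / np.array([a, b, c])
        inside = (local**2).sum(axis=1) <= 1.0
        sample = pts[inside]
        se = sample.std(axis=0, ddof=1) / np.sqrt(len(sample))
        assert np.all(np.abs(props.centroid - sample.mean(axis=0)) < 3.0 * se + 1e-2)

    def test_open_and_degenerate_rejected(self):
        cube = unit_cube()
        holed = TriMesh(vertices=cube.vertices, faces=cube.faces[:-1], process=False)
        with pytest.raises(ValueError, match="watertight"):
            mass_properties(holed)


class _nullcontext:
    def __enter__(self):
        return self

    def __exit__(self, *exc):
        return False


class TestUnifyAxisSigns:
    def brute_force(self, frame, reference):
        patterns = [np.diag(s) for s in
                    [(1, 1, 1), (1, -1, -1), (-1, 1, -1), (-1, -1, 1)]]
        return max((frame @ p for p in patterns),
                   key=lambda f: np.trace(reference.T @ f))

    def test_identity_unchanged(self, rng):
        ref = random_rotation(rng)
        assert unify_axis_signs(ref.copy(), ref)[0] == pytest.approx(ref)

    def test_double_flip_restored(self, rng):
        ref = random_rotation(rng)
        flipped = ref * np.array([1.0, -1.0, -1.0])
        assert unify_axis_signs(flipped, ref)[0] == pytest.approx(ref)

    def test_small_rotation_unchanged(self, rng):
        from wristkin.transforms import rotation_about_axis

        ref = random_rotation(rng)
        frame = rotation_about_axis(rng.normal(size=3), 5.0) @ ref
        assert unify_axis_signs(frame, ref)[0] == pytest.approx(frame)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force(self, seed):
        r = np.random.default_rng(seed)
        ref = random_rotation(r)
        frame = random_rotation(r) * np.array(
            [(1, 1, 1), (1, -1, -1), (-1, 1, -1), (-1, -1, 1)][seed % 4], dtype=float
        )
        out = unify_axis_signs(frame, ref)[0]
        assert out == pytest.approx(self.brute_force(frame, ref))
        assert np.linalg.det(out) == pytest.approx(1.0)
        # only column signs changed
        assert np.abs(np.abs(out) - np.abs(frame)).max() < 1e-12

    def test_tie_warns_and_prefers_fewer_flips(self):
        from wristkin.transforms import rotation_about_axis

        ref = np.eye(3)
        frame = rotation_about_axis([0, 0, 1.0], 90.0)
        with pytest.warns(UserWarning, match="ambiguous"):
            out = unify_axis_signs(frame, ref)[0]
        assert out == pytest.approx(frame)  # zero flips preferred
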