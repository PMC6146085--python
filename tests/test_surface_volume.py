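"""Surface construction and divergence-theorem volumes.

trimesh serves as the independent mesh oracle: it builds the analytic
test bodies (box, icosphere) and cross-checks enclosed volumes.
"""

import numpy as np
import pytest
import trimesh
from hypothesis import given, strategies as st

import chestwall as cw
from chestwall.surface_volume import SurfaceModel


def as_model(mesh: trimesh.Trimesh) -> SurfaceModel:
    tags = np.full(len(mesh.faces), "closure", object)
    return SurfaceModel(np.asarray(mesh.vertices, float), np.asarray(mesh.faces), tags)


class TestEnclosedVolume:
    def test_unit_cube_is_exactly_one_cubic_meter(self):
        box = trimesh.creation.box(extents=(1.0, 1.0, 1.0))
        v = cw.enclosed_volume(as_model(box))
        assert v == pytest.approx(1000.0, rel=1e-12)

    def test_icosphere_matches_analytic_sphere(self):
        r = 0.1
        sphere = trimesh.creation.icosphere(subdivisions=4, radius=r)
        v = cw.enclosed_volume(as_model(sphere))
        analytic = 4.0 / 3.0 * np.pi * r**3 * 1000.0
        assert v == pytest.approx(analytic, rel=5e-3)
        # and agrees with the independent mesh library on the same mesh
        assert v == pytest.approx(sphere.volume * 1000.0, rel=1e-12)

    def test_translation_invariance(self):
        box = trimesh.creation.box(extents=(0.3, 0.2, 0.1))
        m = as_model(box)
        v0 = cw.enclosed_volume(m)
        m.vertices = m.vertices + np.array([1.0, 2.0, 3.0])
        assert cw.enclosed_volume(m) == pytest.approx(v0, abs=1e-9)

    def test_rotation_invariance(self):
        sphere = trimesh.creation.icosphere(subdivisions=2, radius=0.2)
        m = as_model(sphere)
        v0 = cw.enclosed_volume(m)
        rng = np.random.default_rng(7)
        q = rng.normal(size=(3, 3))
        rot, _ = np.linalg.qr(q)
        rot *= np.sign(np.linalg.det(rot))
        m.vertices = m.vertices @ rot.T
        assert cw.enclosed_volume(m) == pytest.approx(v0, rel=1e-12)

    @given(k=st.floats(min_value=0.1, max_value=5.0))
    def test_uniform_scaling_scales_volume_cubically(self, k):
        box = trimesh.creation.box(extents=(0.3, 0.2, 0.1))
        m = as_model(box)
        v0 = cw.enclosed_volume(m)
        m.vertices = m.vertices * k
        assert cw.enclosed_volume(m) == pytest.approx(v0 * k**3, rel=1e-9)

    def test_open_mesh_raises_topology_error(self):
        box = trimesh.creation.box()
        m = as_model(box)
        m.faces = m.faces[:-1]
        m.compartment_tag = m.compartment_tag[:-1]
        with pytest.raises(cw.TopologyError):
            cw.enclosed_volume(m)


class TestBuildSurface:
    def test_planar_grid_closes_into_box_like_mesh(self, layout):
        # 6x6 planar grid at z = 0.1; closure onto the bed plane below
        frame = np.zeros((36, 3))
        for i, m in enumerate(layout.marker_ids):
            r, c = layout.grid[m]
            frame[i] = (c * 0.05, (5 - r) * 0.08, 0.1)
        s = cw.build_surface(frame, layout, bed_z=0.0)
        assert s.euler_characteristic() == 2
        assert s.is_closed()
        # exactly width * length * height
        assert cw.enclosed_volume(s) == pytest.approx(0.25 * 0.40 * 0.1 * 1000, rel=1e-9)

    def test_synthetic_torso_mesh_is_closed(self, torso_frame, layout):
        s = cw.build_surface(torso_frame, layout)
        assert s.is_closed()
        assert s.euler_characteristic() == 2
        # every edge shared by exactly two faces
        edges = np.sort(s.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1)
        _, counts = np.unique(edges, axis=0, return_counts=True)
        assert (counts == 2).all()

    def test_volume_agrees_with_trimesh_oracle(self, torso_frame, layout):
        s = cw.build_surface(torso_frame, layout)
        mesh = trimesh.Trimesh(s.vertices, s.faces, process=False)
        assert cw.enclosed_volume(s) == pytest.approx(
            abs(mesh.volume) * 1000.0, rel=1e-12
        )

    def test_anterior_faces_carry_compartment_tags(self, torso_frame, layout):
        s = cw.build_surface(torso_frame, layout)
        tags = set(s.compartment_tag)
        assert tags == {"pulmonary_ribcage", "abdominal_ribcage", "abdomen", "closure"}

    def test_coincident_markers_raise_geometry_error(self, torso_frame, layout):
        bad = torso_frame.copy()
        bad[1] = bad[0]
        with pytest.raises(cw.GeometryError, match="coincident"):
            cw.build_surface(bad, layout)

    def test_non_monotonic_rows_raise_geometry_error(self, torso_frame, layout):
        bad = torso_frame.copy()
        bad[:, 1] *= -1.0  # flips cranio-caudal ordering
        with pytest.raises(cw.GeometryError, match="monotonic"):
            cw.build_surface(bad, layout)

    def test_obj_export_round_trips_through_trimesh(self, torso_frame, layout, tmp_path):
        s = cw.build_surface(torso_frame, layout)
        path = tmp_path / "torso.obj"
        cw.export_obj(s, path)
        mesh = trimesh.load(path, process=False)
        assert len(mesh.faces) == len(s.faces)
        np.testing.assert_allclose(mesh.vertices, s.vertices, atol=1e-6)


class TestCompartmentVolumes:
    def test_partition_conservation(self, quiet_series):
        resid = np.abs(
            quiet_series.v_cw
            - (quiet_series.v_rcp + quiet_series.v_rca + quiet_series.v_ab)
        )
        assert resid.max() < 1e-9

    def test_static_torso_gives_constant_series(self, torso_frame, layout):
        traj = cw.TrajectorySet(
            np.repeat(torso_frame[None], 10, axis=0), 60.0, layout.marker_ids
        )
        s = cw.compartment_volumes(traj, layout)
        for v in (s.v_cw, s.v_rcp, s.v_rca, s.v_ab):
            assert np.ptp(v) < 1e-12
            assert (v > 0).all()

    def test_abdominal_only_motion_leaves_ribcage_constant(self, torso):
        traj, _ = cw.simulate_breathing(
            torso, cw.BreathSpec(split=(0.0, 0.0, 1.0), duration_s=5.0)
        )
        s = cw.compartment_volumes(traj, cw.default_layout())
        assert np.ptp(s.v_rcp) < 1e-12
        assert np.ptp(s.v_ab) > 1e-3

    def test_invalid_frames_raise_with_frame_index(self, torso_frame, layout):
        pos = np.repeat(torso_frame[None], 5, axis=0)
        pos[3, 0] = np.nan
        traj = cw.TrajectorySet(pos, 60.0, layout.marker_ids)
        with pytest.raises(cw.GeometryError, match="frame 3"):
            cw.compartment_volumes(traj, layout)

    def test_refinement_convergence_on_analytic_torso(self):
        # same smooth analytic surface sampled at 6x6 and 12x12
        def sample(rows, cols):
            lay = cw.default_layout(rows, cols)
            frame = np.zeros((rows * cols, 3))
            for i, m in enumerate(lay.marker_ids):
                r, c = lay.grid[m]
                s = r / (rows - 1)
                u = 2.0 * c / (cols - 1) - 1.0
                width = 0.18 - 0.02 * s
                frame[i] = (
                    0.5 * width * u,
                    0.35 * (1.0 - s),
                    0.07 + 0.015 * np.sin(np.pi * s) * (1.0 - 0.3 * u**2),
                )
            return cw.enclosed_volume(cw.build_surface(frame, lay, bed_z=0.0))

        v6, v12 = sample(6, 6), sample(12, 12)
        assert abs(v12 - v6) / v6 < 5e-3

    def test_series_csv_export(self, quiet_series, tmp_path):
        path = tmp_path / "series.csv"
        quiet_series.to_csv(path)
        header = path.read_text().splitlines()[0]
        assert header == "time,V_cw,V_rcp,V_rca,V_ab"
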