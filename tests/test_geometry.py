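"""Mesh I/O, point-to-surface distance, contact detection, setpoint rendering."""

import numpy as np
import pytest
import trimesh

import thermotouch as tt
from thermotouch.geometry import surface_distances


def brute_force_distance(point, vertices, faces):
    """Independent point-to-triangle minimum distance (Ericson's region test).

    Oracle for the mesh proximity query: plain per-triangle barycentric
    clamping, no acceleration, no shared code with the implementation.
    """
    p = np.asarray(point, float)
    best = np.inf
    for tri in faces:
        a, b, c = vertices[tri]
        ab, ac, ap = b - a, c - a, p - a
        d1, d2 = ab @ ap, ac @ ap
        if d1 <= 0 and d2 <= 0:
            q = a
        else:
            bp = p - b
            d3, d4 = ab @ bp, ac @ bp
            if d3 >= 0 and d4 <= d3:
                q = b
            else:
                vc = d1 * d4 - d3 * d2
                if vc <= 0 and d1 >= 0 and d3 <= 0:
                    q = a + ab * (d1 / (d1 - d3))
                else:
                    cp = p - c
                    d5, d6 = ab @ cp, ac @ cp
                    if d6 >= 0 and d5 <= d6:
                        q = c
                    else:
                        vb = d5 * d2 - d1 * d6
                        if vb <= 0 and d2 >= 0 and d6 <= 0:
                            q = a + ac * (d2 / (d2 - d6))
                        else:
                            va = d3 * d6 - d5 * d4
                            if va <= 0 and (d4 - d3) >= 0 and (d5 - d6) >= 0:
                                q = b + (c - b) * ((d4 - d3) / ((d4 - d3) + (d5 - d6)))
                            else:
                                denom = va + vb + vc
                                v, w = vb / denom, vc / denom
                                q = a + ab * v + ac * w
        best = min(best, float(np.linalg.norm(p - q)))
    return best


def radial_trajectory(distances, dt=0.1):
    """Trajectory moving along +x with given center distances per tick."""
    d = np.asarray(distances, float)
    times = dt * np.arange(d.size)
    return tt.FingertipTrajectory(times=times, positions=np.column_stack([d, 0 * d, 0 * d]))


class TestMeshIO:
    def test_obj_and_stl_roundtrip_identical_vertices(self, sphere, tmp_path):
        obj_path, stl_path = tmp_path / "s.obj", tmp_path / "s.stl"
        sphere.mesh.export(obj_path)
        sphere.mesh.export(stl_path)
        loaded_obj = tt.load_mesh(obj_path)
        loaded_stl = tt.load_mesh(stl_path)
        assert loaded_obj.label == "s"
        key = lambda v: np.lexsort((v[:, 2], v[:, 1], v[:, 0]))
        v_obj = loaded_obj.vertices[key(loaded_obj.vertices)]
        v_stl = np.unique(loaded_stl.vertices, axis=0)
        v_stl = v_stl[key(v_stl)]
        assert v_obj.shape == v_stl.shape
        assert np.abs(v_obj - v_stl).max() < 1e-6  # STL stores float32 vertices

    def test_unit_scale_converts_to_meters(self, tmp_path):
        unit = tt.make_sphere_surface(radius=1.0, subdivisions=2)
        path = tmp_path / "unit.obj"
        unit.mesh.export(path)
        loaded = tt.load_mesh(path, unit_scale=0.001)
        diagonal = np.linalg.norm(loaded.mesh.bounds[1] - loaded.mesh.bounds[0])
        assert diagonal == pytest.approx(2 * np.sqrt(3) * 0.001, rel=0.05)

    def test_empty_file_is_parse_error(self, tmp_path):
        path = tmp_path / "empty.obj"
        path.write_text("")
        with pytest.raises(ValueError):
            tt.load_mesh(path)

    def test_unknown_format_rejected(self, tmp_path):
        path = tmp_path / "mesh.ply"
        path.write_text("ply")
        with pytest.raises(ValueError, match="format"):
            tt.load_mesh(path)

    def test_generated_sphere_is_watertight(self, sphere):
        assert sphere.mesh.is_watertight
        assert sphere.mesh.area == pytest.approx(4 * np.pi * 0.01**2, rel=0.01)


class TestSurfaceDistance:
    def test_center_of_sphere_is_radius(self, sphere):
        d = tt.surface_distance([0.0, 0.0, 0.0], sphere)
        assert 0.995 * 0.01 <= d <= 0.01

    def test_point_on_vertex_is_zero(self, sphere):
        assert tt.surface_distance(sphere.vertices[17], sphere) == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_oracle_on_random_points(self):
        # coarse mesh keeps the pure-python oracle loop affordable at n=1000
        coarse = tt.make_sphere_surface(radius=0.01, subdivisions=1)
        rng = np.random.default_rng(42)
        points = rng.uniform(-0.02, 0.02, size=(1000, 3))
        got = surface_distances(points, coarse)
        expected = np.array(
            [brute_force_distance(p, coarse.vertices, coarse.triangles) for p in points]
        )
        assert np.abs(got - expected).max() < 1e-12

    def test_cross_check_against_trimesh_proximity(self, sphere):
        # independent library route; trimesh's edge projections are only
        # accurate to ~1e-8, hence the looser band
        from trimesh.proximity import closest_point_naive

        rng = np.random.default_rng(1)
        points = rng.uniform(-0.02, 0.02, size=(100, 3))
        got = surface_distances(points, sphere)
        _, reference, _ = closest_point_naive(sphere.mesh, points)
        assert np.abs(got - reference).max() < 1e-6
        radial = np.abs(np.linalg.norm(points, axis=1) - 0.01)
        # tessellation chord depth bounds the deviation from the true sphere
        assert np.abs(got - radial).max() < 5e-5


class TestDetectContact:
    def test_far_trajectory_has_no_events(self, sphere):
        traj = radial_trajectory([0.2, 0.19, 0.18, 0.2])
        assert tt.detect_contact(traj, [sphere], epsilon=0.002) == []

    def test_empty_surface_list(self):
        traj = radial_trajectory([0.1, 0.2])
        assert tt.detect_contact(traj, [], epsilon=0.002) == []

    def test_linear_approach_crossing_indices(self, sphere):
        # center distances: ticks 0..5; contact shell at 0.012 (chord-adjusted)
        dist = np.array([0.020, 0.016, 0.0119, 0.011, 0.0119, 0.016])
        traj = radial_trajectory(dist, dt=0.5)
        events = tt.detect_contact(traj, [sphere], epsilon=0.002)
        assert len(events) == 1
        (event,) = events
        assert event.start_time == pytest.approx(1.0)  # tick 2
        assert event.end_time == pytest.approx(2.5)  # first out-of-contact tick
        assert event.surface_label == "tumor"
        assert np.linalg.norm(event.contact_point) == pytest.approx(0.01, rel=5e-3)

    def test_open_event_when_still_in_contact(self, sphere):
        traj = radial_trajectory([0.02, 0.011, 0.011])
        (event,) = tt.detect_contact(traj, [sphere], epsilon=0.002)
        assert event.end_time is None

    def test_concentric_spheres_attribute_to_nearer(self):
        inner = tt.make_sphere_surface(radius=0.010, label="inner", subdivisions=2)
        outer = tt.make_sphere_surface(radius=0.012, label="outer", subdivisions=2)
        traj = radial_trajectory([0.05, 0.0105, 0.05])
        (event,) = tt.detect_contact(traj, [outer, inner], epsilon=0.002)
        assert event.surface_label == "inner"

    def test_event_ticks_partition_contact_ticks(self, sphere):
        rng = np.random.default_rng(7)
        dist = rng.uniform(0.009, 0.016, size=40)
        traj = radial_trajectory(dist)
        events = tt.detect_contact(traj, [sphere], epsilon=0.002)
        in_contact = surface_distances(traj.positions, sphere) <= 0.002
        covered = np.zeros(40, dtype=bool)
        for event in events:
            start = np.searchsorted(traj.times, event.start_time)
            stop = (
                np.searchsorted(traj.times, event.end_time)
                if event.end_time is not None
                else 40
            )
            assert not covered[start:stop].any()  # no tick in two events
            covered[start:stop] = True
        assert np.array_equal(covered, in_contact)

    def test_rigid_motion_invariance(self, sphere):
        rng = np.random.default_rng(3)
        traj = radial_trajectory([0.05, 0.013, 0.011, 0.011, 0.05])
        rotation = trimesh.transformations.rotation_matrix(0.7, [1, 2, 3], [0, 0, 0])
        rotation[:3, 3] = [0.04, -0.02, 0.01]
        moved_mesh = sphere.mesh.copy()
        moved_mesh.apply_transform(rotation)
        moved_sphere = tt.TumorSurface(label="tumor", mesh=moved_mesh, slab=sphere.slab)
        homog = np.column_stack([traj.positions, np.ones(traj.times.size)])
        moved_traj = tt.FingertipTrajectory(
            times=traj.times, positions=(rotation @ homog.T).T[:, :3]
        )
        d0 = surface_distances(traj.positions, sphere)
        d1 = surface_distances(moved_traj.positions, moved_sphere)
        assert np.abs(d0 - d1).max() < 1e-9
        ev0 = tt.detect_contact(traj, [sphere], epsilon=0.002)
        ev1 = tt.detect_contact(moved_traj, [moved_sphere], epsilon=0.002)
        assert [(e.start_time, e.end_time) for e in ev0] == [
            (e.start_time, e.end_time) for e in ev1
        ]


class TestRenderTimeline:
    def test_no_contact_gives_constant_baseline(self, sphere, scheme):
        traj = radial_trajectory([0.2, 0.2, 0.2])
        timeline = tt.render_timeline(traj, [sphere], scheme=scheme, dt=0.05)
        assert not timeline.in_contact.any()
        assert np.all(timeline.setpoints == 33.0)
        assert all(label is None for label in timeline.surface_labels)

    def test_onset_setpoint_is_tumor_initial_temperature(self, sphere, scheme):
        traj = radial_trajectory([0.05, 0.011, 0.011, 0.011, 0.05], dt=0.5)
        timeline = tt.render_timeline(traj, [sphere], scheme=scheme, dt=0.5)
        contact_setpoints = timeline.setpoints[timeline.in_contact]
        assert contact_setpoints[0] == sphere.slab.initial_temperature
        assert np.all(np.diff(contact_setpoints) >= 0)

    def test_hold_setpoints_match_direct_model_calls(self, sphere, scheme):
        traj = radial_trajectory([0.05, 0.011, 0.011, 0.011, 0.011, 0.05], dt=0.5)
        timeline = tt.render_timeline(traj, [sphere], scheme=scheme, dt=0.5)
        (event,) = tt.detect_contact(traj.resample(0.5), [sphere], tt.geometry.DEFAULT_EPSILON)
        for i in np.flatnonzero(timeline.in_contact):
            tau = timeline.times[i] - event.start_time
            assert timeline.setpoints[i] == tt.temperature(sphere.slab, 0.0, tau, scheme)

    def test_setpoint_continuity_within_episode(self, sphere, scheme):
        traj = radial_trajectory(np.concatenate([[0.05], np.full(60, 0.011), [0.05]]), dt=0.1)
        timeline = tt.render_timeline(traj, [sphere], scheme=scheme, dt=0.1)
        sp = timeline.setpoints[timeline.in_contact]
        assert np.abs(np.diff(sp)).max() < 5.0

    def test_contact_clock_resets_between_events(self, sphere, scheme):
        dist = [0.05, 0.011, 0.011, 0.05, 0.05, 0.011, 0.011, 0.05]
        traj = radial_trajectory(dist, dt=0.5)
        timeline = tt.render_timeline(traj, [sphere], scheme=scheme, dt=0.5)
        onsets = np.flatnonzero(
            timeline.in_contact & ~np.roll(timeline.in_contact, 1)
        )
        assert len(onsets) == 2
        assert np.all(timeline.setpoints[onsets] == sphere.slab.initial_temperature)


class TestTrajectory:
    def test_validation(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            tt.FingertipTrajectory(times=[0.0, 0.0], positions=np.zeros((2, 3)))
        with pytest.raises(ValueError, match="two time samples"):
            tt.FingertipTrajectory(times=[0.0], positions=np.zeros((1, 3)))
        with pytest.raises(ValueError, match="shape"):
            tt.FingertipTrajectory(times=[0.0, 1.0], positions=np.zeros((3, 3)))

    def test_csv_roundtrip(self, tmp_path):
        traj = tt.make_approach_trajectory(seed=5)
        path = tmp_path / "traj.csv"
        traj.to_csv(path)
        loaded = tt.FingertipTrajectory.from_csv(path)
        assert np.allclose(loaded.times, traj.times)
        assert np.allclose(loaded.positions, traj.positions)

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("t_seconds,x,y\n0,0,0\n1,1,1\n")
        with pytest.raises(ValueError, match="missing columns"):
            tt.FingertipTrajectory.from_csv(path)

    def test_resample_interpolates_linearly(self):
        traj = radial_trajectory([0.0, 0.01], dt=1.0)
        fine = traj.resample(0.25)
        assert np.allclose(fine.positions[:, 0], [0.0, 0.0025, 0.005, 0.0075, 0.01])
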