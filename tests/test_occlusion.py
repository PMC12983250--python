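"""Ray-cast visibility labeling against independent geometric oracles."""

import numpy as np
import pytest
import trimesh

from canopycomplete.occlusion import (_segments_blocked, label_visibility,
                                      segment_triangle_intersect)
from canopycomplete.scene import (CameraRig, PlotLayout, PopulationScene,
                                  build_camera_rig)

TRI = np.array([[-1, -1, 0], [1, -1, 0], [0, 1, 0.0]])


def _scene_from(points, vertices, triangles):
    return PopulationScene(
        plants=[], merged_points=np.asarray(points, float),
        merged_labels=np.zeros(len(points), np.uint8),
        point_plant_ids=np.zeros(len(points), np.int32),
        merged_vertices=np.asarray(vertices, float),
        merged_triangles=np.asarray(triangles, np.int64),
        stage="test", layout=PlotLayout())


def test_segment_crossing_interior_hits():
    assert segment_triangle_intersect([0, 0, -1], [0, 0, 1], TRI)
    assert not segment_triangle_intersect([5, 0, -1], [5, 0, 1], TRI)
    # hit beyond the endpoint does not count (finite segment)
    assert not segment_triangle_intersect([0, 0, -3], [0, 0, -2], TRI)
    # epsilon suppresses hits adjacent to the origin
    assert not segment_triangle_intersect([0, 0, 0], [0, 0, 1], TRI,
                                          epsilon=1e-3)


def test_segment_degenerate_inputs_rejected():
    with pytest.raises(ValueError):
        segment_triangle_intersect([0, 0, 0], [0, 0, 0], TRI)
    bad = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0.0]])
    with pytest.raises(ValueError):
        segment_triangle_intersect([0, 0, -1], [0, 0, 1], bad)


def _plane_barycentric_oracle(origin, endpoint, tri, epsilon):
    """Independent test: intersect the segment with the triangle plane and
    check barycentric coordinates.  Returns (hit, margin)."""
    n = np.cross(tri[1] - tri[0], tri[2] - tri[0])
    d = endpoint - origin
    denom = n @ d
    if denom == 0:
        return False, np.inf
    t = (n @ (tri[0] - origin)) / denom
    seg_len = np.linalg.norm(d)
    p = origin + t * d
    # solve for barycentric coordinates in the triangle plane
    a, b = tri[1] - tri[0], tri[2] - tri[0]
    m = np.array([[a @ a, a @ b], [b @ a, b @ b]])
    rhs = np.array([a @ (p - tri[0]), b @ (p - tri[0])])
    u, v = np.linalg.solve(m, rhs)
    margin = min(u, v, 1 - u - v, abs(t - epsilon / seg_len), abs(1 - t))
    hit = (u >= 0 and v >= 0 and u + v <= 1
           and epsilon / seg_len < t <= 1.0)
    return hit, margin


def test_intersection_agrees_with_plane_barycentric_oracle(rng):
    mismatches = 0
    for _ in range(10_000):
        origin = rng.normal(size=3)
        endpoint = rng.normal(size=3) * 2
        tri = rng.normal(size=(3, 3))
        if np.linalg.norm(np.cross(tri[1] - tri[0], tri[2] - tri[0])) < 1e-6:
            continue
        want, margin = _plane_barycentric_oracle(origin, endpoint, tri, 1e-6)
        if margin <= 1e-9:  # borderline cases are policy-dependent
            continue
        got = segment_triangle_intersect(origin, endpoint, tri, epsilon=1e-6)
        mismatches += got != want
    assert mismatches == 0


def _brute_force_labels(scene, rig, epsilon):
    """Literal triple loop over points, cameras and triangles."""
    tris = scene.merged_vertices[scene.merged_triangles]
    counts = np.zeros(len(scene.merged_points), dtype=int)
    for i, p in enumerate(scene.merged_points):
        for cam in rig.positions:
            for tri in tris:
                if segment_triangle_intersect(p, cam, tri, epsilon=epsilon):
                    counts[i] += 1
                    break
    return counts


def test_visibility_matches_triple_loop_brute_force(rng):
    for trial in range(3):
        n_pts, n_tri = 60, 40
        points = rng.uniform(-10, 10, size=(n_pts, 3))
        verts = rng.uniform(-12, 12, size=(n_tri * 3, 3))
        tris = np.arange(n_tri * 3).reshape(n_tri, 3)
        scene = _scene_from(points, verts, tris)
        rig = build_camera_rig(np.zeros(3), distance_m=0.5,
                               azimuth_step_deg=30)
        labels = label_visibility(scene, rig, epsilon=1e-6)
        counts = _brute_force_labels(scene, rig, 1e-6)
        np.testing.assert_array_equal(labels.blocked_views, counts)
        np.testing.assert_array_equal(labels.occluded, counts == len(rig))


def test_vectorized_fallback_matches_compiled_path(rng):
    points = rng.uniform(-5, 5, size=(80, 3))
    verts = rng.uniform(-6, 6, size=(90, 3))
    tris = np.arange(90).reshape(30, 3)
    cam = np.array([0.0, 0.0, 50.0])
    from canopycomplete.occlusion import _blocked_for_camera
    got = _blocked_for_camera(points, cam, verts[tris], 1e-6)
    want = _segments_blocked(points, cam, verts[tris], 1e-6)
    np.testing.assert_array_equal(got, want)


def test_point_with_empty_mesh_is_surface():
    scene = _scene_from([[0, 0, 0.0]], np.zeros((0, 3)),
                        np.zeros((0, 3), dtype=int))
    labels = label_visibility(scene, build_camera_rig(np.zeros(3)))
    assert not labels.occluded[0]
    assert labels.blocked_views[0] == 0


def test_point_inside_closed_sphere_is_occluded():
    sphere = trimesh.creation.icosphere(subdivisions=2, radius=5.0)
    scene = _scene_from([[0, 0, 0.0]], sphere.vertices, sphere.faces)
    rig = build_camera_rig(np.zeros(3), distance_m=1.0)  # cameras at 100 cm
    labels = label_visibility(scene, rig, epsilon=1e-4)
    assert labels.occluded[0]
    assert labels.blocked_views[0] == len(rig)


def test_empty_rig_rejected(tiny_scene):
    rig = CameraRig(positions=np.zeros((0, 3)), look_at=np.zeros(3),
                    azimuth_step=10, distance=5, view_angle=-60)
    with pytest.raises(ValueError):
        label_visibility(tiny_scene, rig)


def test_adding_triangles_never_reveals_points(rng, tiny_scene):
    rig = build_camera_rig(tiny_scene.layout.center, azimuth_step_deg=60)
    n_tri = len(tiny_scene.merged_triangles)
    half = _scene_from(tiny_scene.merged_points, tiny_scene.merged_vertices,
                       tiny_scene.merged_triangles[: n_tri // 2])
    full = _scene_from(tiny_scene.merged_points, tiny_scene.merged_vertices,
                       tiny_scene.merged_triangles)
    eps = 1e-3
    l_half = label_visibility(half, rig, epsilon=eps)
    l_full = label_visibility(full, rig, epsilon=eps)
    assert np.all(l_full.blocked_views >= l_half.blocked_views)
    assert not np.any(l_half.occluded & ~l_full.occluded)


def test_denser_planting_does_not_reduce_occlusion(bolting_pool):
    """Qualitative mirror of the occlusion-vs-spacing relationship."""
    from canopycomplete.scene import assemble_population

    def mean_occluded(spacing_scale):
        layout = PlotLayout(rows=2, cols=2,
                            row_spacing=28.0 * spacing_scale,
                            plant_spacing=25.0 * spacing_scale)
        fracs = []
        for seed in range(10):
            scene = assemble_population(bolting_pool, layout, seed=seed)
            rig = build_camera_rig(layout.center, azimuth_step_deg=60)
            fracs.append(label_visibility(scene, rig).occluded.mean())
        return np.mean(fracs)

    assert mean_occluded(0.5) >= mean_occluded(1.0)
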