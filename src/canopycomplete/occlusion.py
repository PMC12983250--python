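"""Visibility labeling of canopy points by segment/triangle ray casting.

Each scene point is tested against every camera of the rig: the point is
*blocked* for a camera when at least one mesh triangle intersects the open
segment from the point to that camera.  A point blocked from every camera
is *occluded* (invisible to multi-view reconstruction and therefore a
completion target); a point visible from at least one camera is a
*surface* point (network input).

Self-intersection is suppressed by discarding hits closer to the point
than an epsilon offset (default 1e-4 of the scene bounding-box diagonal),
because the points lie exactly on the mesh.  Hits on a triangle edge count
as blocking (inclusive test).  Geometry beyond the camera position cannot
block: the test uses the finite segment, not an infinite ray.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .scene import CameraRig, PopulationScene

try:  # compiled kernel; the numpy path below is the fallback
    import numba as _numba
except ImportError:  # pragma: no cover
    _numba = None

_BARY_TOL = 1e-12


@dataclass
class VisibilityLabels:
    occluded: np.ndarray       # (N,) bool
    blocked_views: np.ndarray  # (N,) int, number of cameras blocked
    n_views: int

    @property
    def surface(self) -> np.ndarray:
        return ~self.occluded


def segment_triangle_intersect(origin, endpoint, triangle, epsilon: float = 1e-6) -> bool:
    """Moller-Trumbore test of the open segment (origin, endpoint].

    ``epsilon`` is an absolute distance (same units as the coordinates):
    hits closer than ``epsilon`` to the origin are ignored so that a point
    lying on the mesh does not block itself.
    """
    origin = np.asarray(origin, dtype=float)
    endpoint = np.asarray(endpoint, dtype=float)
    tri = np.asarray(triangle, dtype=float)
    d = endpoint - origin
    seg_len = np.linalg.norm(d)
    if seg_len == 0:
        raise ValueError("origin and endpoint coincide")
    e1 = tri[1] - tri[0]
    e2 = tri[2] - tri[0]
    if np.linalg.norm(np.cross(e1, e2)) == 0:
        raise ValueError("degenerate (zero-area) triangle")
    pvec = np.cross(d, e2)
    det = e1 @ pvec
    if det == 0:
        return False  # segment parallel to triangle plane
    inv = 1.0 / det
    tvec = origin - tri[0]
    u = (tvec @ pvec) * inv
    if u < -_BARY_TOL or u > 1 + _BARY_TOL:
        return False
    qvec = np.cross(tvec, e1)
    v = (d @ qvec) * inv
    if v < -_BARY_TOL or u + v > 1 + _BARY_TOL:
        return False
    t = (e2 @ qvec) * inv
    return epsilon / seg_len < t <= 1.0


def _segments_blocked(points: np.ndarray, camera: np.ndarray,
                      triangles: np.ndarray, epsilon: float,
                      chunk: int = 262144) -> np.ndarray:
    """Vectorized blocked flags for segments point->camera vs all triangles.

    ``triangles`` is (T, 3, 3).  Processes (point, triangle) pairs in
    chunks, masking out points already known to be blocked, so the common
    dense-canopy case exits early.
    """
    n = len(points)
    blocked = np.zeros(n, dtype=bool)
    if len(triangles) == 0 or n == 0:
        return blocked
    e1 = triangles[:, 1] - triangles[:, 0]
    e2 = triangles[:, 2] - triangles[:, 0]
    t0 = triangles[:, 0]
    tri_chunk = max(1, chunk // max(1, n))
    for start in range(0, len(triangles), tri_chunk):
        alive = np.flatnonzero(~blocked)
        if alive.size == 0:
            break
        o = points[alive]                              # (P, 3)
        d = camera[None, :] - o                        # (P, 3)
        seg_len = np.linalg.norm(d, axis=1)
        E1 = e1[start:start + tri_chunk]               # (C, 3)
        E2 = e2[start:start + tri_chunk]
        T0 = t0[start:start + tri_chunk]
        pvec = np.cross(d[:, None, :], E2[None, :, :])         # (P, C, 3)
        det = np.einsum("cj,pcj->pc", E1, pvec)
        safe = np.abs(det) > 1e-300
        inv = np.where(safe, 1.0 / np.where(safe, det, 1.0), 0.0)
        tvec = o[:, None, :] - T0[None, :, :]
        u = np.einsum("pcj,pcj->pc", tvec, pvec) * inv
        qvec = np.cross(tvec, E1[None, :, :])
        v = np.einsum("pj,pcj->pc", d, qvec) * inv
        t = np.einsum("cj,pcj->pc", E2, qvec) * inv
        hit = (safe
               & (u >= -_BARY_TOL) & (v >= -_BARY_TOL)
               & (u + v <= 1 + _BARY_TOL)
               & (t > (epsilon / seg_len)[:, None]) & (t <= 1.0))
        blocked[alive[hit.any(axis=1)]] = True
    return blocked


if _numba is not None:

    @_numba.njit(cache=False)
    def _blocked_kernel(points, cam, t0, e1, e2, epsilon, out):  # pragma: no cover
        n_tri = t0.shape[0]
        for i in range(points.shape[0]):
            ox, oy, oz = points[i, 0], points[i, 1], points[i, 2]
            dx, dy, dz = cam[0] - ox, cam[1] - oy, cam[2] - oz
            seg_len = (dx * dx + dy * dy + dz * dz) ** 0.5
            t_min = epsilon / seg_len
            blocked = False
            for j in range(n_tri):
                e2x, e2y, e2z = e2[j, 0], e2[j, 1], e2[j, 2]
                px = dy * e2z - dz * e2y
                py = dz * e2x - dx * e2z
                pz = dx * e2y - dy * e2x
                det = e1[j, 0] * px + e1[j, 1] * py + e1[j, 2] * pz
                if det == 0.0:
                    continue
                inv = 1.0 / det
                tx, ty, tz = ox - t0[j, 0], oy - t0[j, 1], oz - t0[j, 2]
                u = (tx * px + ty * py + tz * pz) * inv
                if u < -_BARY_TOL or u > 1.0 + _BARY_TOL:
                    continue
                qx = ty * e1[j, 2] - tz * e1[j, 1]
                qy = tz * e1[j, 0] - tx * e1[j, 2]
                qz = tx * e1[j, 1] - ty * e1[j, 0]
                v = (dx * qx + dy * qy + dz * qz) * inv
                if v < -_BARY_TOL or u + v > 1.0 + _BARY_TOL:
                    continue
                t = (e2x * qx + e2y * qy + e2z * qz) * inv
                if t_min < t <= 1.0:
                    blocked = True
                    break
            out[i] = blocked


def _blocked_for_camera(points: np.ndarray, camera: np.ndarray,
                        triangles: np.ndarray, epsilon: float) -> np.ndarray:
    if _numba is not None and len(triangles):
        out = np.zeros(len(points), dtype=np.bool_)
        t0 = np.ascontiguousarray(triangles[:, 0])
        e1 = np.ascontiguousarray(triangles[:, 1] - triangles[:, 0])
        e2 = np.ascontiguousarray(triangles[:, 2] - triangles[:, 0])
        _blocked_kernel(np.ascontiguousarray(points, dtype=np.float64),
                        np.asarray(camera, dtype=np.float64), t0, e1, e2,
                        float(epsilon), out)
        return out
    return _segments_blocked(points, camera, triangles, epsilon)


def label_visibility(scene: PopulationScene, rig: CameraRig,
                     epsilon: float | None = None) -> VisibilityLabels:
    """Box-style occlusion detection over a whole scene.

    A point is occluded iff it is blocked for *all* rig cameras.  With an
    empty mesh nothing can block and every point is a surface point.
    """
    if len(rig) == 0:
        raise ValueError("camera rig is empty")
    points = np.asarray(scene.merged_points, dtype=float)
    tris = scene.merged_vertices[scene.merged_triangles]
    if epsilon is None:
        lo = points.min(axis=0)
        hi = points.max(axis=0)
        epsilon = 1e-4 * float(np.linalg.norm(hi - lo))
        if epsilon == 0:
            epsilon = 1e-8
    counts = np.zeros(len(points), dtype=np.int64)
    for cam in rig.positions:
        counts += _blocked_for_camera(points, np.asarray(cam, float), tris, epsilon)
    occluded = counts == len(rig)
    return VisibilityLabels(occluded=occluded, blocked_views=counts,
                            n_views=len(rig))
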