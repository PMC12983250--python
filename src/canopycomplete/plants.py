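"""Procedural single-plant models for four rapeseed growth stages.

Individual plants are built from parametric organ primitives: tapered
generalized cylinders for the main stem and branches, curved quadrilateral
strips for leaves, small spheres for flowers and prolate spheroids for
siliques.  Each plant carries a triangle mesh, an area-uniform labeled
surface point cloud, and a base anchor (the stem/ground intersection).

Conventions (inherited by every downstream module): units are centimeters,
the z axis points up, the ground plane is z = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

STAGES = ("seedling", "bolting", "flowering", "silique")

#: organ label encoding used in every labeled cloud of the package
ORGAN_CODES = {"stem": 0, "leaf": 1, "flower": 2, "silique": 3}
ORGAN_NAMES = {v: k for k, v in ORGAN_CODES.items()}


@dataclass(frozen=True)
class PlantArchetype:
    """Parameter ranges describing one growth-stage archetype.

    All geometric ranges are ``(low, high)`` in cm; organ-count ranges are
    inclusive integer intervals.  The archetype ``seed`` is mixed with the
    per-plant seed so that two archetypes with identical ranges but
    different seeds produce distinct plant populations.
    """

    stage: str
    height_range: tuple[float, float]
    n_leaves: tuple[int, int] = (0, 0)
    n_branches: tuple[int, int] = (0, 0)
    n_flowers: tuple[int, int] = (0, 0)
    n_siliques: tuple[int, int] = (0, 0)
    stem_radius: tuple[float, float] = (0.2, 0.4)
    leaf_length: tuple[float, float] = (5.0, 12.0)
    leaf_width: tuple[float, float] = (2.0, 5.0)
    silique_length: tuple[float, float] = (5.0, 8.0)
    silique_radius: tuple[float, float] = (0.25, 0.35)
    seed: int = 0
    n_surface_points: int = 2000
    mesh_sides: int = 6          # ring resolution of tube primitives

    def validate(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown growth stage {self.stage!r}")
        for name in ("height_range", "stem_radius", "leaf_length",
                     "leaf_width", "silique_length", "silique_radius"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} must satisfy 0 < low <= high, got ({lo}, {hi})")
        for name in ("n_leaves", "n_branches", "n_flowers", "n_siliques"):
            lo, hi = getattr(self, name)
            if not (0 <= lo <= hi):
                raise ValueError(f"{name} must satisfy 0 <= low <= high, got ({lo}, {hi})")
        if self.stage == "seedling" and (self.n_flowers[1] > 0 or self.n_siliques[1] > 0):
            raise ValueError("seedling archetype must have zero flowers and zero siliques")
        if self.n_surface_points < 1:
            raise ValueError("n_surface_points must be >= 1")


#: default archetypes; geometric ranges are repository fixtures chosen to
#: reproduce plausible rapeseed morphology, not measured values.
#: at 25 x 28 cm spacing field canopies close over almost completely from
#: bolting on, so foliage is dense enough that plot interiors are heavily
#: self-occluded under oblique multi-view imaging.
DEFAULT_ARCHETYPES: dict[str, PlantArchetype] = {
    "seedling": PlantArchetype(
        stage="seedling", height_range=(8.0, 15.0), n_leaves=(6, 10),
        stem_radius=(0.2, 0.3), leaf_length=(6.0, 12.0), leaf_width=(3.0, 6.0)),
    "bolting": PlantArchetype(
        stage="bolting", height_range=(30.0, 60.0), n_leaves=(16, 26),
        n_branches=(1, 4), stem_radius=(0.3, 0.5),
        leaf_length=(14.0, 24.0), leaf_width=(6.0, 10.0)),
    "flowering": PlantArchetype(
        stage="flowering", height_range=(70.0, 110.0), n_leaves=(10, 18),
        n_branches=(4, 8), n_flowers=(15, 50), stem_radius=(0.35, 0.55),
        leaf_length=(12.0, 20.0), leaf_width=(5.0, 8.0)),
    "silique": PlantArchetype(
        stage="silique", height_range=(90.0, 140.0), n_leaves=(6, 12),
        n_branches=(5, 9), n_siliques=(40, 100), stem_radius=(0.35, 0.6),
        leaf_length=(10.0, 16.0), leaf_width=(4.0, 7.0)),
}


@dataclass
class PlantModel:
    """One plant: triangle mesh + organ-labeled surface cloud + base anchor."""

    vertices: np.ndarray        # (V, 3) float64, cm, z-up
    triangles: np.ndarray       # (T, 3) int32 vertex indices
    surface_points: np.ndarray  # (N, 3) float64, cm
    organ_labels: np.ndarray    # (N,) uint8, see ORGAN_CODES
    base_anchor: np.ndarray     # (3,) stem/ground intersection
    stage: str = "seedling"
    triangle_organs: np.ndarray | None = None  # (T,) uint8, per-triangle organ

    def translated(self, offset: np.ndarray) -> "PlantModel":
        offset = np.asarray(offset, dtype=float)
        return replace(
            self,
            vertices=self.vertices + offset,
            surface_points=self.surface_points + offset,
            base_anchor=self.base_anchor + offset,
        )


# ---------------------------------------------------------------------------
# mesh primitives
# ---------------------------------------------------------------------------

def _frame(direction: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two unit vectors orthogonal to ``direction``."""
    d = direction / np.linalg.norm(direction)
    helper = np.array([1.0, 0.0, 0.0]) if abs(d[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(d, helper)
    u /= np.linalg.norm(u)
    v = np.cross(d, u)
    return u, v


def _tube(path: np.ndarray, radii: np.ndarray, n_side: int = 6):
    """Generalized cylinder along ``path`` with per-ring radius."""
    m = len(path)
    verts = np.empty((m * n_side, 3))
    ang = 2 * np.pi * np.arange(n_side) / n_side
    circ = np.stack([np.cos(ang), np.sin(ang)], axis=1)
    for i in range(m):
        if i == 0:
            d = path[1] - path[0]
        elif i == m - 1:
            d = path[-1] - path[-2]
        else:
            d = path[i + 1] - path[i - 1]
        u, v = _frame(d)
        verts[i * n_side:(i + 1) * n_side] = (
            path[i] + radii[i] * (circ[:, :1] * u + circ[:, 1:] * v))
    tris = []
    for i in range(m - 1):
        a = i * n_side
        b = (i + 1) * n_side
        for j in range(n_side):
            jn = (j + 1) % n_side
            tris.append((a + j, a + jn, b + j))
            tris.append((b + j, a + jn, b + jn))
    return verts, np.asarray(tris, dtype=np.int32)


def _leaf_strip(attach: np.ndarray, azimuth: float, length: float,
                width: float, tilt: float, n_seg: int = 4):
    """Curved lanceolate blade: a strip that rises then droops."""
    t = np.linspace(0.0, 1.0, n_seg + 1)
    direction = np.array([np.cos(azimuth), np.sin(azimuth), 0.0])
    # center line: initial climb at `tilt`, parabolic droop toward the tip
    rise = np.sin(tilt) * t - 0.8 * np.sin(tilt) * t ** 2
    center = (attach + np.outer(t * length * np.cos(tilt), direction)
              + np.outer(rise * length, [0.0, 0.0, 1.0]))
    half = 0.5 * width * np.sin(np.pi * np.clip(t, 0.02, 0.98))
    side = np.array([-direction[1], direction[0], 0.0])
    left = center + np.outer(half, side)
    right = center - np.outer(half, side)
    verts = np.concatenate([left, right])
    n = n_seg + 1
    tris = []
    for i in range(n_seg):
        tris.append((i, n + i, i + 1))
        tris.append((i + 1, n + i, n + i + 1))
    return verts, np.asarray(tris, dtype=np.int32)


def _spheroid(center: np.ndarray, axis: np.ndarray, length: float,
              radius: float, n_u: int = 6, n_v: int = 4):
    """Prolate spheroid with long semi-axis length/2 along ``axis``."""
    d = axis / np.linalg.norm(axis)
    u, v = _frame(d)
    phis = np.linspace(0.0, np.pi, n_v + 1)
    thetas = 2 * np.pi * np.arange(n_u) / n_u
    verts = []
    for phi in phis:
        z = 0.5 * length * np.cos(phi)
        r = radius * np.sin(phi)
        for th in thetas:
            verts.append(center + z * d + r * (np.cos(th) * u + np.sin(th) * v))
    verts = np.asarray(verts)
    tris = []
    for i in range(n_v):
        a, b = i * n_u, (i + 1) * n_u
        for j in range(n_u):
            jn = (j + 1) % n_u
            tris.append((a + j, b + j, a + jn))
            tris.append((a + jn, b + j, b + jn))
    return verts, np.asarray(tris, dtype=np.int32)


def triangle_areas(vertices: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    p = vertices[triangles]
    return 0.5 * np.linalg.norm(
        np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]), axis=1)


def sample_mesh_surface(vertices: np.ndarray, triangles: np.ndarray,
                        n: int, seed: int) -> np.ndarray:
    """Sample ``n`` points uniformly over the mesh surface.

    Triangle selection is proportional to area; placement within a triangle
    is uniform in barycentric coordinates.  Deterministic given ``seed``.
    """
    points, _ = _sample_mesh_surface(vertices, triangles, n, seed)
    return points


def _sample_mesh_surface(vertices, triangles, n, seed):
    if n < 1:
        raise ValueError("n must be >= 1")
    vertices = np.asarray(vertices, dtype=float)
    triangles = np.asarray(triangles, dtype=np.int64)
    areas = triangle_areas(vertices, triangles)
    total = areas.sum()
    if total <= 0:
        raise ValueError("mesh has zero total surface area")
    rng = np.random.default_rng(seed)
    tri_idx = rng.choice(len(triangles), size=n, p=areas / total)
    r1 = rng.random(n)
    r2 = rng.random(n)
    # fold the unit square onto the triangle
    flip = r1 + r2 > 1.0
    r1[flip] = 1.0 - r1[flip]
    r2[flip] = 1.0 - r2[flip]
    p = vertices[triangles[tri_idx]]
    points = p[:, 0] + r1[:, None] * (p[:, 1] - p[:, 0]) + r2[:, None] * (p[:, 2] - p[:, 0])
    return points, tri_idx


# ---------------------------------------------------------------------------
# plant assembly
# ---------------------------------------------------------------------------

def _uniform(rng, lo_hi):
    return rng.uniform(lo_hi[0], lo_hi[1])


def _randint(rng, lo_hi):
    return int(rng.integers(lo_hi[0], lo_hi[1] + 1))


def generate_plant(archetype: PlantArchetype, seed: int) -> PlantModel:
    """Build one plant deterministically from ``(archetype, seed)``."""
    archetype.validate()
    rng = np.random.default_rng([archetype.seed & 0x7FFFFFFF, seed & 0x7FFFFFFF])

    parts: list[tuple[np.ndarray, np.ndarray, int]] = []
    height = _uniform(rng, archetype.height_range)
    r0 = _uniform(rng, archetype.stem_radius)

    # main stem: slightly drifting vertical tube tapering to 30% at the top
    n_ring = 7
    z = np.linspace(0.0, height, n_ring)
    drift = np.cumsum(rng.normal(0.0, 0.01 * height, size=(n_ring, 2)), axis=0)
    drift -= drift[0]
    path = np.column_stack([drift, z])
    radii = r0 * (1.0 - 0.7 * z / height)
    parts.append((*_tube(path, radii, archetype.mesh_sides), ORGAN_CODES["stem"]))

    def stem_point(frac: float) -> np.ndarray:
        i = frac * (n_ring - 1)
        lo = int(np.floor(i))
        hi = min(lo + 1, n_ring - 1)
        return path[lo] + (i - lo) * (path[hi] - path[lo])

    branch_tips = []
    for _ in range(_randint(rng, archetype.n_branches)):
        base = stem_point(rng.uniform(0.45, 0.9))
        az = rng.uniform(0.0, 2 * np.pi)
        elev = rng.uniform(np.deg2rad(40), np.deg2rad(70))  # from horizontal
        length = rng.uniform(0.2, 0.4) * height
        d = np.array([np.cos(az) * np.cos(elev),
                      np.sin(az) * np.cos(elev), np.sin(elev)])
        bp = base + np.outer(np.linspace(0, 1, 4), d * length)
        br = 0.5 * r0 * (1.0 - 0.6 * np.linspace(0, 1, 4))
        parts.append((*_tube(bp, br, archetype.mesh_sides), ORGAN_CODES["stem"]))
        branch_tips.append(bp[-1])
    branch_tips.append(path[-1])

    for _ in range(_randint(rng, archetype.n_leaves)):
        attach = stem_point(rng.uniform(0.05, 0.75))
        verts, tris = _leaf_strip(
            attach, rng.uniform(0, 2 * np.pi),
            _uniform(rng, archetype.leaf_length),
            _uniform(rng, archetype.leaf_width),
            tilt=rng.uniform(np.deg2rad(10), np.deg2rad(35)))
        parts.append((verts, tris, ORGAN_CODES["leaf"]))

    tips = np.asarray(branch_tips)
    for _ in range(_randint(rng, archetype.n_flowers)):
        tip = tips[rng.integers(len(tips))]
        center = tip + rng.normal(0.0, 2.0, 3) * [1, 1, 0.5] + [0, 0, 1.0]
        verts, tris = _spheroid(center, np.array([0.0, 0.0, 1.0]),
                                length=1.2, radius=0.5, n_u=5, n_v=3)
        parts.append((verts, tris, ORGAN_CODES["flower"]))

    for _ in range(_randint(rng, archetype.n_siliques)):
        frac = rng.uniform(0.55, 1.0)
        anchor = (tips[rng.integers(len(tips))] if rng.random() < 0.6
                  else stem_point(frac))
        az = rng.uniform(0, 2 * np.pi)
        elev = rng.uniform(np.deg2rad(-20), np.deg2rad(50))
        axis = np.array([np.cos(az) * np.cos(elev),
                         np.sin(az) * np.cos(elev), np.sin(elev)])
        length = _uniform(rng, archetype.silique_length)
        center = anchor + axis * 0.5 * length + rng.normal(0, 1.5, 3) * [1, 1, 0.6]
        verts, tris = _spheroid(center, axis, length,
                                _uniform(rng, archetype.silique_radius),
                                n_u=5, n_v=3)
        parts.append((verts, tris, ORGAN_CODES["silique"]))

    all_verts, all_tris, tri_organs = [], [], []
    offset = 0
    for verts, tris, organ in parts:
        all_verts.append(verts)
        all_tris.append(tris + offset)
        tri_organs.append(np.full(len(tris), organ, dtype=np.uint8))
        offset += len(verts)
    vertices = np.concatenate(all_verts)
    vertices[:, 2] = np.maximum(vertices[:, 2], 0.0)  # nothing below ground
    triangles = np.concatenate(all_tris)
    tri_organs = np.concatenate(tri_organs)

    sample_seed = int(rng.integers(0, 2**31 - 1))
    points, tri_idx = _sample_mesh_surface(vertices, triangles,
                                           archetype.n_surface_points, sample_seed)
    return PlantModel(
        vertices=vertices,
        triangles=triangles,
        surface_points=points,
        organ_labels=tri_organs[tri_idx],
        base_anchor=np.zeros(3),
        stage=archetype.stage,
        triangle_organs=tri_organs,
    )
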