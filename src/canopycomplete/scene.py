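"""Population plot assembly (virtual-real integration), overlap
de-duplication and the simulated UAV camera ring.

A plot places plants sampled (with replacement) from a same-stage pool on a
regular grid — default 16 plants, 25 cm plant spacing within rows, 28 cm
between rows — anchoring each plant's stem/ground intersection at its grid
position.  Overlapping regions between neighboring plants are thinned by
distance-based de-duplication so the merged cloud keeps a realistic density.
The camera rig mirrors the oblique UAV orbit used for field imaging: one
viewpoint every 10 degrees of azimuth on a circle 5 m from the plot center
at a -60 degree viewing angle, i.e. 36 views per plot.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .plants import PlantModel


@dataclass(frozen=True)
class PlotLayout:
    rows: int = 4
    cols: int = 4
    row_spacing: float = 28.0    # cm between rows (y)
    plant_spacing: float = 25.0  # cm between plants within a row (x)
    position_jitter: float = 0.0  # cm, uniform +/- jitter of grid positions

    def validate(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ValueError("rows and cols must be >= 1")
        if self.row_spacing <= 0 or self.plant_spacing <= 0:
            raise ValueError("spacings must be > 0")
        if self.position_jitter < 0:
            raise ValueError("position_jitter must be >= 0")

    @property
    def n_plants(self) -> int:
        return self.rows * self.cols

    def grid_positions(self) -> np.ndarray:
        """(rows*cols, 2) nominal anchor positions; x along the plant axis."""
        xs = np.arange(self.cols) * self.plant_spacing
        ys = np.arange(self.rows) * self.row_spacing
        gx, gy = np.meshgrid(xs, ys)
        return np.column_stack([gx.ravel(), gy.ravel()])

    @property
    def center(self) -> np.ndarray:
        return np.array([(self.cols - 1) * self.plant_spacing / 2.0,
                         (self.rows - 1) * self.row_spacing / 2.0, 0.0])


@dataclass
class PopulationScene:
    plants: list[tuple[PlantModel, np.ndarray]]  # (model, applied translation)
    merged_points: np.ndarray    # (M, 3) cm
    merged_labels: np.ndarray    # (M,) uint8 organ codes
    point_plant_ids: np.ndarray  # (M,) int32 source plant index
    merged_vertices: np.ndarray
    merged_triangles: np.ndarray
    stage: str
    layout: PlotLayout

    def subset(self, keep: np.ndarray) -> "PopulationScene":
        """Scene with only the ``keep`` point indices retained (mesh intact)."""
        return PopulationScene(
            plants=self.plants,
            merged_points=self.merged_points[keep],
            merged_labels=self.merged_labels[keep],
            point_plant_ids=self.point_plant_ids[keep],
            merged_vertices=self.merged_vertices,
            merged_triangles=self.merged_triangles,
            stage=self.stage,
            layout=self.layout,
        )


@dataclass
class CameraRig:
    positions: np.ndarray    # (K, 3) cm
    look_at: np.ndarray      # (3,) plot center, cm
    azimuth_step: float      # degrees
    distance: float          # m, camera to plot center
    view_angle: float        # degrees, negative = looking down

    def __len__(self) -> int:
        return len(self.positions)


def assemble_population(plant_pool: list[PlantModel], layout: PlotLayout,
                        seed: int, yaw_rotation: bool = False) -> PopulationScene:
    """Place pool plants (sampled with replacement) on the plot grid.

    ``yaw_rotation`` optionally spins each plant around its own vertical
    axis (uniform 0-360 degrees, seeded) for extra scene diversity; off by
    default.
    """
    if not plant_pool:
        raise ValueError("plant pool is empty")
    stages = {p.stage for p in plant_pool}
    if len(stages) != 1:
        raise ValueError(f"plant pool mixes growth stages: {sorted(stages)}")
    layout.validate()

    rng = np.random.default_rng(seed)
    choice = rng.integers(0, len(plant_pool), size=layout.n_plants)
    grid = layout.grid_positions()
    if layout.position_jitter > 0:
        grid = grid + rng.uniform(-layout.position_jitter,
                                  layout.position_jitter, size=grid.shape)

    placed, pts, labels, ids, verts, tris = [], [], [], [], [], []
    v_off = 0
    for i, (pool_idx, (gx, gy)) in enumerate(zip(choice, grid)):
        plant = plant_pool[pool_idx]
        if yaw_rotation:
            ang = rng.uniform(0.0, 2 * np.pi)
            c, s = np.cos(ang), np.sin(ang)
            rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
            anchor = plant.base_anchor
            plant = PlantModel(
                vertices=(plant.vertices - anchor) @ rot.T + anchor,
                triangles=plant.triangles,
                surface_points=(plant.surface_points - anchor) @ rot.T + anchor,
                organ_labels=plant.organ_labels,
                base_anchor=anchor,
                stage=plant.stage,
                triangle_organs=plant.triangle_organs,
            )
        offset = np.array([gx, gy, 0.0]) - plant.base_anchor
        moved = plant.translated(offset)
        placed.append((moved, offset))
        pts.append(moved.surface_points)
        labels.append(moved.organ_labels)
        ids.append(np.full(len(moved.surface_points), i, dtype=np.int32))
        verts.append(moved.vertices)
        tris.append(moved.triangles + v_off)
        v_off += len(moved.vertices)

    return PopulationScene(
        plants=placed,
        merged_points=np.concatenate(pts),
        merged_labels=np.concatenate(labels),
        point_plant_ids=np.concatenate(ids),
        merged_vertices=np.concatenate(verts),
        merged_triangles=np.concatenate(tris),
        stage=plant_pool[0].stage,
        layout=layout,
    )


def deduplicate_overlap(merged_points: np.ndarray, source_plant_ids: np.ndarray,
                        threshold: float = 0.1) -> np.ndarray:
    """Indices of points retained after cross-plant de-duplication.

    Greedy sweep in (plant index, point index) order: a point is dropped if
    an already-retained point of a *different* plant lies within
    ``threshold`` (cm).  Lower plant index wins ties; within-plant density
    is never touched.  Idempotent.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    points = np.asarray(merged_points, dtype=float)
    ids = np.asarray(source_plant_ids)
    n = len(points)
    if n == 0:
        return np.empty(0, dtype=np.int64)

    order = np.lexsort((np.arange(n), ids))
    rank = np.empty(n, dtype=np.int64)
    rank[order] = np.arange(n)

    tree = cKDTree(points)
    pairs = tree.query_pairs(threshold, output_type="ndarray")
    if len(pairs):
        pairs = pairs[ids[pairs[:, 0]] != ids[pairs[:, 1]]]
    neighbors: list[list[int]] = [[] for _ in range(n)]
    for a, b in pairs:
        neighbors[a].append(b)
        neighbors[b].append(a)

    kept = np.zeros(n, dtype=bool)
    for idx in order:
        if any(kept[j] and rank[j] < rank[idx] for j in neighbors[idx]):
            continue
        kept[idx] = True
    return np.flatnonzero(kept)


def build_camera_rig(plot_center: np.ndarray, distance_m: float = 5.0,
                     view_angle_deg: float = -60.0,
                     azimuth_step_deg: float = 10.0) -> CameraRig:
    """Simulated UAV orbit: viewpoints on a ring around the plot center.

    The camera sits ``distance_m`` from the plot center along a viewing ray
    depressed ``|view_angle_deg|`` below the horizontal, so the horizontal
    radius is ``d*cos`` and the height above the center is ``d*sin``.
    """
    if not (0 < azimuth_step_deg <= 360):
        raise ValueError("azimuth step must be in (0, 360]")
    n_views = 360.0 / azimuth_step_deg
    if abs(n_views - round(n_views)) > 1e-9:
        raise ValueError("azimuth step must divide 360")
    n_views = int(round(n_views))
    if distance_m <= 0:
        raise ValueError("distance must be > 0")

    center = np.asarray(plot_center, dtype=float)
    dist_cm = distance_m * 100.0
    dep = np.deg2rad(abs(view_angle_deg))
    radius = dist_cm * np.cos(dep)
    height = dist_cm * np.sin(dep)
    az = np.deg2rad(azimuth_step_deg * np.arange(n_views))
    positions = np.column_stack([
        center[0] + radius * np.cos(az),
        center[1] + radius * np.sin(az),
        center[2] + np.full(n_views, height),
    ])
    return CameraRig(positions=positions, look_at=center,
                     azimuth_step=azimuth_step_deg, distance=distance_m,
                     view_angle=view_angle_deg)
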