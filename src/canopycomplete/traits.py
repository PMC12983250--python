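"""Canopy traits: voxel-based silique volume, the silique efficiency index
(SEI = total silique volume per unit ground area), canopy-layer partition
and yield regression.

Volumes use occupied-voxel counting at a fixed 3 mm voxel size (about half
a silique diameter, so voxelization fills the pod interior without
morphological closing).  Canopy layers split the silique zone's vertical
extent into three equal-height intervals (lower/middle/upper).
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
from scipy import stats

from .plants import ORGAN_CODES

CM_TO_MM = 10.0


@dataclass
class VoxelGrid:
    voxel_size: float            # mm
    origin: np.ndarray           # (3,) mm, the cloud's min corner
    occupied: np.ndarray         # (n, 3) unique integer voxel indices

    @property
    def count(self) -> int:
        return len(self.occupied)

    @property
    def volume(self) -> float:
        return self.count * self.voxel_size ** 3


@dataclass
class TraitReport:
    silique_volume_mm3: float
    layer_volumes_mm3: dict      # {"lower"/"middle"/"upper": mm^3}
    plane_area_m2: float
    sei: float                   # mm^3 per m^2
    layer_sei: dict
    layer_bounds: tuple | None   # z interval boundaries (mm)
    voxel_size_mm: float


def voxelize(points_mm: np.ndarray, voxel_size: float) -> VoxelGrid:
    """Occupied voxels of a point cloud (coordinates in mm)."""
    if voxel_size <= 0:
        raise ValueError("voxel_size must be > 0")
    points_mm = np.asarray(points_mm, dtype=float)
    if len(points_mm) == 0:
        return VoxelGrid(voxel_size, np.zeros(3), np.empty((0, 3), dtype=np.int64))
    origin = points_mm.min(axis=0)
    idx = np.floor((points_mm - origin) / voxel_size).astype(np.int64)
    occupied = np.unique(idx, axis=0)
    return VoxelGrid(voxel_size, origin, occupied)


def voxel_volume(points_mm: np.ndarray, voxel_size: float) -> tuple[int, float]:
    """(occupied voxel count, volume in mm^3); empty input gives (0, 0)."""
    grid = voxelize(points_mm, voxel_size)
    return grid.count, grid.volume


def partition_layers(points: np.ndarray) -> dict[str, np.ndarray]:
    """Index sets of the lower/middle/upper thirds of the z extent.

    Bins are half-open (boundary points fall in the lower interval); a
    degenerate z range puts every point in the middle layer.
    """
    points = np.asarray(points, dtype=float)
    if len(points) < 3:
        raise ValueError("need at least 3 points to partition layers")
    z = points[:, 2]
    lo, hi = z.min(), z.max()
    if hi == lo:
        return {"lower": np.empty(0, np.int64),
                "middle": np.arange(len(points)),
                "upper": np.empty(0, np.int64)}
    b1 = lo + (hi - lo) / 3.0
    b2 = lo + 2.0 * (hi - lo) / 3.0
    lower = np.flatnonzero(z <= b1)
    middle = np.flatnonzero((z > b1) & (z <= b2))
    upper = np.flatnonzero(z > b2)
    return {"lower": lower, "middle": middle, "upper": upper}


def compute_sei(points_cm: np.ndarray, organ_labels: np.ndarray,
                plot_area_m2: float, voxel_size_mm: float = 3.0,
                layers: bool = True) -> TraitReport:
    """Silique efficiency index from an organ-labeled cloud (cm units).

    Silique-labeled points are voxelized at ``voxel_size_mm``; SEI is the
    occupied volume divided by the plot ground area, per canopy layer and
    in total.  Layer volumes partition the occupied voxels by voxel-center
    height, so they sum exactly to the total.
    """
    if plot_area_m2 <= 0:
        raise ValueError("plot_area must be > 0")
    points_cm = np.asarray(points_cm, dtype=float)
    organ_labels = np.asarray(organ_labels)
    if len(points_cm) != len(organ_labels):
        raise ValueError("points and labels length mismatch")
    sil = points_cm[organ_labels == ORGAN_CODES["silique"]] * CM_TO_MM

    if len(sil) == 0:
        warnings.warn("no silique-labeled points; SEI is zero", stacklevel=2)
        empty = {"lower": 0.0, "middle": 0.0, "upper": 0.0}
        return TraitReport(0.0, dict(empty), plot_area_m2, 0.0, dict(empty),
                           None, voxel_size_mm)

    grid = voxelize(sil, voxel_size_mm)
    total_volume = grid.volume
    layer_volumes = {"lower": 0.0, "middle": 0.0, "upper": 0.0}
    bounds = None
    if layers:
        z_lo, z_hi = sil[:, 2].min(), sil[:, 2].max()
        centers_z = grid.origin[2] + (grid.occupied[:, 2] + 0.5) * voxel_size_mm
        if z_hi == z_lo:
            layer_volumes["middle"] = total_volume
        else:
            b1 = z_lo + (z_hi - z_lo) / 3.0
            b2 = z_lo + 2.0 * (z_hi - z_lo) / 3.0
            bounds = (float(b1), float(b2))
            v = voxel_size_mm ** 3
            layer_volumes["lower"] = float(np.sum(centers_z <= b1)) * v
            layer_volumes["middle"] = float(np.sum((centers_z > b1) & (centers_z <= b2))) * v
            layer_volumes["upper"] = float(np.sum(centers_z > b2)) * v
    else:
        layer_volumes["middle"] = total_volume

    return TraitReport(
        silique_volume_mm3=float(total_volume),
        layer_volumes_mm3=layer_volumes,
        plane_area_m2=float(plot_area_m2),
        sei=float(total_volume / plot_area_m2),
        layer_sei={k: v / plot_area_m2 for k, v in layer_volumes.items()},
        layer_bounds=bounds,
        voxel_size_mm=voxel_size_mm,
    )


def plot_ground_area_m2(layout) -> float:
    """Plot footprint: grid extent plus a half-spacing margin on each side."""
    width_cm = layout.cols * layout.plant_spacing
    depth_cm = layout.rows * layout.row_spacing
    return (width_cm / 100.0) * (depth_cm / 100.0)


def fit_yield_regression(sei_values: np.ndarray, yields: np.ndarray):
    """OLS of yield on SEI; returns (slope, intercept, r_squared)."""
    sei_values = np.asarray(sei_values, dtype=float)
    yields = np.asarray(yields, dtype=float)
    if len(sei_values) != len(yields):
        raise ValueError("sei and yield vectors must have equal length")
    if len(sei_values) < 3:
        raise ValueError("need at least 3 observations")
    if np.allclose(sei_values, sei_values[0]):
        raise ValueError("constant SEI predictor: regression is undefined")
    res = stats.linregress(sei_values, yields)
    r2 = 0.0 if np.isnan(res.rvalue) else float(res.rvalue ** 2)
    return float(res.slope), float(res.intercept), r2
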