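"""End-to-end annotated dataset generation.

For each growth stage a pool of procedural plants is generated; scenes
are assembled on the plot grid, de-duplicated, visibility-labeled against
the simulated camera rig, and split into spatial blocks.  Surface points
become network inputs and occluded points the completion targets.  All
stages are pooled and split 80/20 into train/validation *by scene*, so no
scene's blocks straddle the split.  A scene that happens to have no
occluded point is regenerated with a fresh derived seed (and the event
logged).  Everything is deterministic under the top-level seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .archive import AnnotatedSample, write_archive
from .blocks import partition_blocks, resample_block
from .occlusion import label_visibility
from .plants import DEFAULT_ARCHETYPES, PlantArchetype, generate_plant
from .scene import (PlotLayout, PopulationScene, assemble_population,
                    build_camera_rig, deduplicate_overlap)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DatasetConfig:
    stages: tuple = ("seedling", "bolting", "flowering", "silique")
    n_scenes_per_stage: int = 1000    # full study scale; tests use fewer
    pool_size: int = 100              # plants per stage pool
    layout: PlotLayout = field(default_factory=PlotLayout)
    rig_distance_m: float = 5.0
    rig_view_angle_deg: float = -60.0
    rig_azimuth_step_deg: float = 10.0
    dedup_threshold_cm: float = 0.1
    n_blocks: int = 8
    block_size: int = 8192            # fixed input size per block
    train_fraction: float = 0.8
    archetypes: dict | None = None    # overrides of DEFAULT_ARCHETYPES
    max_regenerations: int = 5

    def validate(self) -> None:
        if self.n_scenes_per_stage < 1 or self.pool_size < 1:
            raise ValueError("n_scenes_per_stage and pool_size must be >= 1")
        if not (0 < self.train_fraction < 1):
            raise ValueError("train_fraction must lie in (0, 1)")

    def archetype(self, stage: str) -> PlantArchetype:
        if self.archetypes and stage in self.archetypes:
            return self.archetypes[stage]
        return DEFAULT_ARCHETYPES[stage]


def simulate_scene(config: DatasetConfig, stage: str, seed: int) -> PopulationScene:
    """One de-duplicated population scene of the given stage."""
    rng = np.random.default_rng(seed)
    arch = config.archetype(stage)
    pool = [generate_plant(arch, int(rng.integers(2**31 - 1)))
            for _ in range(config.pool_size)]
    scene = assemble_population(pool, config.layout, int(rng.integers(2**31 - 1)))
    keep = deduplicate_overlap(scene.merged_points, scene.point_plant_ids,
                               config.dedup_threshold_cm)
    return scene.subset(keep)


def annotate_scene(config: DatasetConfig, scene: PopulationScene):
    rig = build_camera_rig(scene.layout.center, config.rig_distance_m,
                           config.rig_view_angle_deg, config.rig_azimuth_step_deg)
    return label_visibility(scene, rig)


def _scene_samples(config: DatasetConfig, scene: PopulationScene,
                   occluded: np.ndarray, scene_id: str, seed: int):
    surface_pts = scene.merged_points[~occluded]
    target_pts = scene.merged_points[occluded]
    surf_blocks = partition_blocks(surface_pts, n_blocks=config.n_blocks)
    windows = [b.window for b in surf_blocks]
    tgt_blocks = partition_blocks(target_pts, n_blocks=config.n_blocks,
                                  windows=windows)
    samples = []
    for sb, tb in zip(surf_blocks, tgt_blocks):
        if len(sb.points) == 0 or len(tb.points) == 0:
            continue
        fixed = resample_block(sb, n_target=config.block_size,
                               seed=seed + sb.block_index)
        samples.append(AnnotatedSample(
            input_points=fixed.points,
            target_points=tb.points,
            stage=scene.stage,
            scene_id=scene_id,
            block_index=sb.block_index,
            transform=sb.origin_transform,
            surface_full=sb.points,
        ))
    return samples


def build_dataset(config: DatasetConfig, seed: int, out_path=None):
    """Simulate, annotate, block-partition and split the dataset.

    Returns ``(splits, meta)`` and, when ``out_path`` is given, writes the
    HDF5 archive there.
    """
    config.validate()
    root = np.random.SeedSequence(seed)
    scene_seeds = root.spawn(len(config.stages))

    per_scene_samples = []  # list of lists, one per scene
    scene_meta = []
    for stage, stage_ss in zip(config.stages, scene_seeds):
        child = stage_ss.generate_state(2 * config.n_scenes_per_stage
                                        + 2 * config.max_regenerations) >> 1
        cursor = 0
        for k in range(config.n_scenes_per_stage):
            for attempt in range(config.max_regenerations + 1):
                s = int(child[cursor])
                cursor += 1
                scene = simulate_scene(config, stage, s)
                labels = annotate_scene(config, scene)
                if labels.occluded.any():
                    break
                logger.warning("scene %s/%d had zero occluded points; "
                               "regenerating with a fresh seed", stage, k)
            else:
                raise RuntimeError(
                    f"could not generate an occluded scene for stage {stage}")
            scene_id = f"{stage}_{k:03d}"
            samples = _scene_samples(config, scene, labels.occluded, scene_id,
                                     seed=s & 0x7FFFFFFF)
            if samples:
                per_scene_samples.append(samples)
                scene_meta.append(scene_id)

    # pooled stages, split by scene
    rng = np.random.default_rng(root.spawn(1)[0])
    order = rng.permutation(len(per_scene_samples))
    n_train = int(round(config.train_fraction * len(per_scene_samples)))
    if len(per_scene_samples) >= 2:  # keep both splits non-empty
        n_train = min(max(n_train, 1), len(per_scene_samples) - 1)
    train_scenes = set(order[:n_train])
    splits = {"train": [], "val": []}
    for i, samples in enumerate(per_scene_samples):
        splits["train" if i in train_scenes else "val"].extend(samples)

    meta = {
        "seed": seed,
        "n_scenes": len(per_scene_samples),
        "scene_ids": scene_meta,
        "train_scenes": sorted(scene_meta[i] for i in train_scenes),
        "block_size": config.block_size,
        "stages": list(config.stages),
    }
    if out_path is not None:
        write_archive(out_path, splits, meta)
    return splits, meta
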