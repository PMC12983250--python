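"""HDF5 dataset archive for annotated completion samples.

Layout::

    /meta                     attrs: config (JSON), seed, version
    /<split>/sample_<k>/input   (n, 3) float32, local cm coordinates
    /<split>/sample_<k>/target  (m, 3) float32
                              attrs: stage, scene_id, block_index,
                                     transform (3,) translation to plot frame

One container file per dataset keeps writes atomic (temp file + rename); a
plain-directory export of PLY pairs is available for debugging.
"""

from __future__ import annotations

import json
import os
import tempfile
from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np

ARCHIVE_VERSION = 1


@dataclass
class AnnotatedSample:
    """One training sample: surface input and occluded target of a block."""

    input_points: np.ndarray   # (n, 3) cm, block-local frame
    target_points: np.ndarray  # (m, 3) cm, same frame
    stage: str
    scene_id: str
    block_index: int
    transform: np.ndarray      # (3,) translation back to plot coordinates
    #: full-resolution surface cloud of the block (before fixed-size
    #: resampling); evaluation against the complete ground truth uses it
    surface_full: np.ndarray | None = None

    def validate(self) -> None:
        if len(self.input_points) == 0 or len(self.target_points) == 0:
            raise ValueError("training samples need non-empty input and target")


def write_archive(path, splits: dict[str, list[AnnotatedSample]],
                  meta: dict | None = None):
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".h5.tmp")
    os.close(fd)
    try:
        with h5py.File(tmp, "w") as fh:
            g = fh.create_group("meta")
            g.attrs["config"] = json.dumps(meta or {})
            g.attrs["version"] = ARCHIVE_VERSION
            for split, samples in splits.items():
                sg = fh.create_group(split)
                for k, s in enumerate(samples):
                    s.validate()
                    grp = sg.create_group(f"sample_{k:05d}")
                    grp.create_dataset("input", data=np.asarray(s.input_points, np.float32))
                    grp.create_dataset("target", data=np.asarray(s.target_points, np.float32))
                    if s.surface_full is not None:
                        grp.create_dataset(
                            "surface_full", data=np.asarray(s.surface_full, np.float32))
                    grp.attrs["stage"] = s.stage
                    grp.attrs["scene_id"] = s.scene_id
                    grp.attrs["block_index"] = int(s.block_index)
                    grp.attrs["transform"] = np.asarray(s.transform, np.float64)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def read_archive(path) -> tuple[dict[str, list[AnnotatedSample]], dict]:
    splits: dict[str, list[AnnotatedSample]] = {}
    with h5py.File(path, "r") as fh:
        meta = json.loads(fh["meta"].attrs["config"])
        for split in fh:
            if split == "meta":
                continue
            samples = []
            for key in sorted(fh[split]):
                grp = fh[split][key]
                samples.append(AnnotatedSample(
                    input_points=grp["input"][()],
                    target_points=grp["target"][()],
                    surface_full=(grp["surface_full"][()]
                                  if "surface_full" in grp else None),
                    stage=str(grp.attrs["stage"]),
                    scene_id=str(grp.attrs["scene_id"]),
                    block_index=int(grp.attrs["block_index"]),
                    transform=np.asarray(grp.attrs["transform"]),
                ))
            splits[split] = samples
    return splits, meta
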