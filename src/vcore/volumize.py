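"""Assemble aligned sections into a volumetric core and cut patches.

The co-registered z-stack is cropped to the bounding box of the stacked
rigid mask and tiled on a non-overlapping grid anchored at the frame origin.
A tile is kept only when its mean-over-depth tissue fraction strictly
exceeds the threshold (default 0.6, i.e. "more than 60% tissue"); partial
edge tiles are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import warnings

import h5py
import numpy as np
import pandas as pd

from . import imageops
from .preprocess import TissueMask, build_tissue_mask

DEFAULT_PATCH_SIZE = 256
DEFAULT_TISSUE_THRESHOLD = 0.6


@dataclass
class VolumetricCore:
    """Co-registered RGB z-stack with per-section tissue masks."""

    sections: list[np.ndarray]
    masks: list[np.ndarray]
    microns_per_pixel: float = 0.5
    core_id: str = ""
    label: int | None = None

    def __post_init__(self) -> None:
        shapes = {s.shape[:2] for s in self.sections}
        if len(shapes) != 1:
            raise ValueError(f"sections disagree in shape: {shapes}")
        if len(self.masks) != len(self.sections):
            raise ValueError("one mask per section required")

    @property
    def n_sections(self) -> int:
        return len(self.sections)

    @property
    def shape(self) -> tuple[int, int]:
        return self.sections[0].shape[:2]


@dataclass
class VolumetricPatch:
    """F x S x S x 3 sub-volume of a core."""

    voxels: np.ndarray  # (F, S, S, 3) uint8
    origin: tuple[int, int]  # (row, col) in the core frame
    depth_range: tuple[int, int]  # half-open section-index range
    tissue_fraction: float
    core_id: str = ""
    label: int | None = None


def assemble_core(
    sections: list[np.ndarray],
    masks: list[np.ndarray] | None = None,
    microns_per_pixel: float = 0.5,
    core_id: str = "",
    label: int | None = None,
    z_order: list[int] | None = None,
    crop_to_mask: bool = True,
) -> VolumetricCore:
    """Stack aligned sections into a core, cropped to the stacked-mask box.

    Masks are recomputed on the aligned images when not supplied; an
    explicit ``z_order`` reorders sections by their depth indices.
    """
    sections = [np.asarray(s) for s in sections]
    if z_order is not None:
        order = np.argsort(z_order)
        sections = [sections[i] for i in order]
        if masks is not None:
            masks = [masks[i] for i in order]
    shapes = {s.shape[:2] for s in sections}
    if len(shapes) != 1:
        raise ValueError(f"sections disagree in shape: {shapes}")
    if masks is None:
        masks = [build_tissue_mask(imageops.to_uint8(imageops.to_float(s))).mask
                 for s in sections]
    masks = [np.asarray(m, bool) for m in masks]

    if crop_to_mask:
        stacked = np.any(np.stack(masks), axis=0)
        rows, cols = np.nonzero(stacked)
        if len(rows):
            r0, r1 = int(rows.min()), int(rows.max()) + 1
            c0, c1 = int(cols.min()), int(cols.max()) + 1
            sections = [s[r0:r1, c0:c1] for s in sections]
            masks = [m[r0:r1, c0:c1] for m in masks]

    sections = [
        imageops.to_uint8(imageops.to_float(s)) for s in sections
    ]
    return VolumetricCore(
        sections=sections,
        masks=masks,
        microns_per_pixel=microns_per_pixel,
        core_id=core_id,
        label=label,
    )


def extract_volumetric_patches(
    core: VolumetricCore,
    patch_size: int = DEFAULT_PATCH_SIZE,
    tissue_threshold: float = DEFAULT_TISSUE_THRESHOLD,
    depth_aggregation: str = "mean",
) -> list[VolumetricPatch]:
    """Non-overlapping tissue-filtered tiles in row-major grid order.

    The per-tile tissue fraction is aggregated over depth by the mean of the
    per-section fractions (or their minimum with
    ``depth_aggregation='min'``); retention requires the aggregate to be
    *strictly* greater than ``tissue_threshold``.
    """
    h, w = core.shape
    if h < patch_size or w < patch_size:
        warnings.warn(
            f"core extent {h}x{w} smaller than patch size {patch_size}; "
            "no patches extracted",
            stacklevel=2,
        )
        return []
    if depth_aggregation not in ("mean", "min"):
        raise ValueError("depth_aggregation must be 'mean' or 'min'")

    vol = np.stack(core.sections)  # (F, H, W, 3)
    msk = np.stack(core.masks).astype(float)  # (F, H, W)
    patches = []
    for r0 in range(0, h - patch_size + 1, patch_size):
        for c0 in range(0, w - patch_size + 1, patch_size):
            per_section = msk[:, r0:r0 + patch_size, c0:c0 + patch_size].mean(
                axis=(1, 2)
            )
            frac = per_section.mean() if depth_aggregation == "mean" else per_section.min()
            if frac > tissue_threshold:
                patches.append(
                    VolumetricPatch(
                        voxels=vol[:, r0:r0 + patch_size, c0:c0 + patch_size].copy(),
                        origin=(r0, c0),
                        depth_range=(0, core.n_sections),
                        tissue_fraction=float(frac),
                        core_id=core.core_id,
                        label=core.label,
                    )
                )
    return patches


def fit_depth(patch_voxels: np.ndarray, depth: int) -> np.ndarray:
    """Adapt a (F, S, S, 3) volume to the encoder depth.

    Deeper volumes are center-cropped in z; shallower ones are edge
    replicated.
    """
    f = patch_voxels.shape[0]
    if f == depth:
        return patch_voxels
    if f > depth:
        start = (f - depth) // 2
        return patch_voxels[start:start + depth]
    pad_before = (depth - f) // 2
    pad_after = depth - f - pad_before
    return np.concatenate(
        [patch_voxels[:1]] * pad_before
        + [patch_voxels]
        + [patch_voxels[-1:]] * pad_after
    )


def save_patches_h5(
    patches: list[VolumetricPatch], path: str | Path, depth: int | None = None
) -> None:
    """Store patches as an HDF5 container (dataset ``voxels`` + metadata)."""
    if not patches:
        raise ValueError("no patches to save")
    if depth is not None:
        vox = np.stack([fit_depth(p.voxels, depth) for p in patches])
    else:
        vox = np.stack([p.voxels for p in patches])
    with h5py.File(path, "w") as f:
        f.create_dataset("voxels", data=vox, compression="gzip")
        f.create_dataset(
            "origins", data=np.array([p.origin for p in patches], dtype=np.int64)
        )
        f.create_dataset(
            "labels",
            data=np.array(
                [-1 if p.label is None else p.label for p in patches],
                dtype=np.int64,
            ),
        )
        ids = [p.core_id.encode() for p in patches]
        f.create_dataset("core_ids", data=ids)


def load_patches_h5(path: str | Path) -> list[VolumetricPatch]:
    with h5py.File(path, "r") as f:
        vox = f["voxels"][:]
        origins = f["origins"][:]
        labels = f["labels"][:]
        ids = [s.decode() for s in f["core_ids"][:]]
    return [
        VolumetricPatch(
            voxels=vox[i],
            origin=tuple(int(v) for v in origins[i]),
            depth_range=(0, vox.shape[1]),
            tissue_fraction=float("nan"),
            core_id=ids[i],
            label=None if labels[i] < 0 else int(labels[i]),
        )
        for i in range(len(vox))
    ]


def patch_manifest(patches: list[VolumetricPatch]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "core_id": [p.core_id for p in patches],
            "row0": [p.origin[0] for p in patches],
            "col0": [p.origin[1] for p in patches],
            "tissue_fraction": [p.tissue_fraction for p in patches],
            "label": [p.label for p in patches],
        }
    )
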