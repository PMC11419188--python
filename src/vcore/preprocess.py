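"""Slide models, HSV tissue masking, and ribbon extraction.

A slide is represented as a resolution pyramid; tissue is detected by
thresholding the HSV hue channel inside an H&E band plus a saturation floor,
followed by morphological closing to bridge small gaps. Connected components
of the tissue mask above a minimum area are the "ribbons" — the individual
serial sections mounted on the slide — ordered top-to-bottom as cut.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile
from scipy import ndimage
from skimage.color import rgb2hsv

from . import imageops

DEFAULT_HUE_BAND = (0.55, 0.95)
DEFAULT_SATURATION_FLOOR = 0.15
DEFAULT_CLOSING_RADIUS = 2
#: working level = smallest raster with at least 1/16 of full resolution
MAX_WORKING_DOWNSAMPLE = 16.0

_EIGHT_CONN = np.ones((3, 3), dtype=bool)


@dataclass
class SlideImage:
    """A multi-resolution RGB slide raster."""

    levels: list[np.ndarray]
    downsample_factor_per_level: list[float]
    microns_per_pixel_level0: float = 0.5

    def __post_init__(self) -> None:
        f = self.downsample_factor_per_level
        if len(f) != len(self.levels):
            raise ValueError("one downsample factor per level required")
        if not np.isclose(f[0], 1.0):
            raise ValueError("level-0 downsample must be 1")
        if any(b <= a for a, b in zip(f, f[1:])):
            raise ValueError("downsample factors must be strictly increasing")

    def microns_per_pixel(self, level: int) -> float:
        return self.microns_per_pixel_level0 * self.downsample_factor_per_level[level]

    @property
    def working_level(self) -> int:
        """Smallest level whose downsample is still <= 16 (thumbnail work)."""
        ok = [
            i
            for i, f in enumerate(self.downsample_factor_per_level)
            if f <= MAX_WORKING_DOWNSAMPLE
        ]
        return max(ok) if ok else 0

    @classmethod
    def from_array(
        cls,
        image: np.ndarray,
        microns_per_pixel: float = 0.5,
        n_levels: int = 1,
    ) -> "SlideImage":
        """Build a pyramid from a single full-resolution raster by 2x steps."""
        levels = [np.asarray(image)]
        factors = [1.0]
        for _ in range(1, n_levels):
            prev = imageops.to_float(levels[-1])
            h, w = prev.shape[:2]
            ds = prev[: h - h % 2, : w - w % 2]
            pooled = 0.25 * (
                ds[0::2, 0::2] + ds[1::2, 0::2] + ds[0::2, 1::2] + ds[1::2, 1::2]
            )
            levels.append(imageops.to_uint8(pooled))
            factors.append(factors[-1] * 2.0)
        return cls(levels, factors, microns_per_pixel)

    @classmethod
    def from_file(
        cls, path: str | Path, microns_per_pixel: float = 0.5
    ) -> "SlideImage":
        """Read a plain/pyramidal TIFF or a PNG."""
        path = Path(path)
        if path.suffix.lower() in {".tif", ".tiff"}:
            with tifffile.TiffFile(path) as tf:
                series = tf.series[0]
                rasters = [lvl.asarray() for lvl in series.levels]
            base_w = rasters[0].shape[1]
            factors = [base_w / r.shape[1] for r in rasters]
            return cls(rasters, factors, microns_per_pixel)
        return cls([np.asarray(iio.imread(path))], [1.0], microns_per_pixel)


@dataclass
class TissueMask:
    """Binary tissue raster aligned to one pyramid level."""

    mask: np.ndarray
    level_index: int = 0

    @property
    def tissue_fraction(self) -> float:
        return float(self.mask.mean())


@dataclass
class Ribbon:
    """One connected tissue section on a slide, with its crop."""

    ribbon_index: int
    bounding_box: tuple[int, int, int, int]  # (row0, col0, row1, col1) half-open
    mask: np.ndarray  # full-frame binary raster of this component
    image_crop: np.ndarray
    source_slide: str = ""

    @property
    def mask_crop(self) -> np.ndarray:
        r0, c0, r1, c1 = self.bounding_box
        return self.mask[r0:r1, c0:c1]

    def meta(self) -> dict:
        return {
            "ribbon_index": self.ribbon_index,
            "bounding_box": list(self.bounding_box),
            "area": int(self.mask.sum()),
            "source_slide": self.source_slide,
        }


def build_tissue_mask(
    image: np.ndarray,
    hue_band: tuple[float, float] = DEFAULT_HUE_BAND,
    closing_radius: int = DEFAULT_CLOSING_RADIUS,
    saturation_floor: float = DEFAULT_SATURATION_FLOOR,
    level_index: int = 0,
) -> TissueMask:
    """HSV hue-band threshold plus morphological closing.

    The closing uses a square structuring element of side
    ``2 * closing_radius + 1``.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[-1] != 3:
        raise ValueError("build_tissue_mask expects an RGB image")
    hsv = rgb2hsv(imageops.to_float(image))
    hue, sat = hsv[..., 0], hsv[..., 1]
    mask = (hue >= hue_band[0]) & (hue <= hue_band[1]) & (sat >= saturation_floor)
    if closing_radius > 0:
        se = np.ones((2 * closing_radius + 1,) * 2, dtype=bool)
        mask = ndimage.binary_closing(mask, structure=se)
    return TissueMask(mask=mask, level_index=level_index)


def extract_ribbons(
    slide: SlideImage | np.ndarray,
    mask: TissueMask,
    min_area: int | None = None,
) -> list[Ribbon]:
    """Connected components of the tissue mask, top-to-bottom.

    Components below ``min_area`` (default 0.5% of the raster) are dropped;
    ordering is by bounding-box centroid row, ties broken by centroid column.
    """
    if isinstance(slide, SlideImage):
        level = mask.level_index
        image = slide.levels[level]
        name = ""
    else:
        image = np.asarray(slide)
        name = ""
    if image.shape[:2] != mask.mask.shape:
        raise ValueError("mask does not match the slide level raster")
    if min_area is None:
        min_area = int(0.005 * mask.mask.size)

    labels, n = ndimage.label(mask.mask, structure=_EIGHT_CONN)
    comps = []
    for lbl in range(1, n + 1):
        comp = labels == lbl
        area = int(comp.sum())
        if area < min_area:
            continue
        rows, cols = np.nonzero(comp)
        bbox = (int(rows.min()), int(cols.min()), int(rows.max()) + 1,
                int(cols.max()) + 1)
        centroid = (rows.mean(), cols.mean())
        comps.append((centroid, bbox, comp))
    comps.sort(key=lambda c: (c[0][0], c[0][1]))

    ribbons = []
    for idx, (centroid, bbox, comp) in enumerate(comps):
        r0, c0, r1, c1 = bbox
        ribbons.append(
            Ribbon(
                ribbon_index=idx,
                bounding_box=bbox,
                mask=comp,
                image_crop=image[r0:r1, c0:c1].copy(),
                source_slide=name,
            )
        )
    return ribbons


def save_mask(mask: TissueMask, path: str | Path) -> None:
    iio.imwrite(Path(path), (mask.mask.astype(np.uint8) * 255))


def save_ribbon_meta(ribbons: list[Ribbon], path: str | Path) -> None:
    Path(path).write_text(json.dumps([r.meta() for r in ribbons], indent=2))
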