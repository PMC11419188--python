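"""Resampling helpers shared by the phantom generator and the aligners.

All warps are *inverse* warps: the output pixel at ``x`` is sampled from the
input at the mapped coordinate. Images are float arrays in [0, 1] or uint8;
out-of-domain samples are filled white for images and False for masks.
Bilinear interpolation for images, nearest for masks.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .transforms import SimilarityTransform

WHITE = 1.0


def _coord_grid(shape: tuple[int, int]) -> np.ndarray:
    """(2, H, W) array of (row, col) coordinates."""
    rr, cc = np.meshgrid(
        np.arange(shape[0], dtype=float),
        np.arange(shape[1], dtype=float),
        indexing="ij",
    )
    return np.stack([rr, cc])


def sample_image(
    image: np.ndarray,
    coords: np.ndarray,
    order: int = 1,
    fill: float = WHITE,
) -> np.ndarray:
    """Sample ``image`` at (2, ...) (row, col) coordinates, channel-wise."""
    if image.ndim == 2:
        return ndimage.map_coordinates(
            image.astype(float), coords, order=order, cval=fill, mode="constant"
        )
    out = [
        ndimage.map_coordinates(
            image[..., c].astype(float), coords, order=order, cval=fill,
            mode="constant",
        )
        for c in range(image.shape[-1])
    ]
    return np.stack(out, axis=-1)


def resample_similarity(
    image: np.ndarray,
    transform: SimilarityTransform,
    output_shape: tuple[int, int] | None = None,
    order: int = 1,
    fill: float = WHITE,
) -> np.ndarray:
    """Render ``image`` under ``transform`` (input coords -> output coords).

    The output pixel at ``x`` is ``image[transform^{-1}(x)]``.
    """
    if output_shape is None:
        output_shape = image.shape[:2]
    inv = transform.inverse()
    grid = _coord_grid(output_shape)
    flat = grid.reshape(2, -1).T
    src = inv.apply(flat).T.reshape(2, *output_shape)
    return sample_image(image, src, order=order, fill=fill)


def resample_mask(
    mask: np.ndarray,
    transform: SimilarityTransform,
    output_shape: tuple[int, int] | None = None,
) -> np.ndarray:
    out = resample_similarity(
        mask.astype(float), transform, output_shape, order=0, fill=0.0
    )
    return out > 0.5


def warp_by_field(
    image: np.ndarray,
    field: np.ndarray,
    order: int = 1,
    fill: float = WHITE,
) -> np.ndarray:
    """Inverse-warp by a dense displacement field.

    ``field`` has shape (2, H, W): output(x) = input(x + field(x)).
    """
    if field.shape[0] != 2 or field.shape[1:] != image.shape[:2]:
        raise ValueError(
            f"field shape {field.shape} does not match image {image.shape[:2]}"
        )
    coords = _coord_grid(image.shape[:2]) + field
    return sample_image(image, coords, order=order, fill=fill)


def dense_from_lattice(
    lattice: np.ndarray, spacing: float, shape: tuple[int, int]
) -> np.ndarray:
    """Bilinearly interpolate a (2, gh, gw) control lattice to a dense field.

    Control point (i, j) sits at pixel (i * spacing, j * spacing).
    """
    grid = _coord_grid(shape) / spacing
    out = np.empty((2, *shape))
    for c in range(2):
        out[c] = ndimage.map_coordinates(
            lattice[c], grid, order=1, mode="nearest"
        )
    return out


def lattice_shape_for(shape: tuple[int, int], spacing: float) -> tuple[int, int]:
    """Number of control points covering ``shape`` at ``spacing``."""
    return (
        int(np.ceil((shape[0] - 1) / spacing)) + 1,
        int(np.ceil((shape[1] - 1) / spacing)) + 1,
    )


def to_float(image: np.ndarray) -> np.ndarray:
    if image.dtype == np.uint8:
        return image.astype(float) / 255.0
    return np.asarray(image, dtype=float)


def to_uint8(image: np.ndarray) -> np.ndarray:
    return (np.clip(image, 0.0, 1.0) * 255.0 + 0.5).astype(np.uint8)


def rgb_to_gray(image: np.ndarray) -> np.ndarray:
    img = to_float(image)
    return img @ np.array([0.2125, 0.7154, 0.0721])
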