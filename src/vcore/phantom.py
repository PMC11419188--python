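"""Synthetic serial-section phantoms with known ground truth.

Real volumetric-core cohorts are not publicly deposited, so every stage of
the pipeline is exercised on generated data: ribbon-shaped tissue with
gland-like lumens in H&E-like colors, sectioned into a z-stack where each
section is the shared base tissue under a known similarity transform plus a
smooth non-rigid warp. The generator stores those transforms, the warp
lattices, and dense point correspondences, so alignment accuracy can be
measured against exact ground truth.

For classification fixtures, a per-section gland-density signal encodes
the class: extra lumens are painted to a target hole area per section. With
``depth_signal`` enabled the per-slice density marginals are matched across
classes (every class pattern has the same mean and the random per-core
offset dominates single-slice variation); only the *joint* statistic across
consecutive slices — the signed density increment — identifies the class.
This emulates grading cues that exist only in the z-structure of a
volumetric core, not in any single cut.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage.color import hsv2rgb

from . import imageops
from .transforms import SimilarityTransform, identity

# H&E-like palette (HSV, unit scale). Hues sit inside the default tissue
# mask band [0.55, 0.95] with saturation above the 0.15 floor.
_STROMA_HSV = (0.87, 0.35, 0.78)
_NUCLEI_HSV = (0.72, 0.55, 0.50)
_BACKGROUND = 0.97

# Brightness encoding of the per-section class signal: tissue pixels of
# section k are scaled by 0.70 + 0.30 * v_k with v_k in [0, 1].
_BRIGHT_LO, _BRIGHT_SPAN = 0.70, 0.30

# Depth-signal parameters: v_k = offset + DELTA * pattern_class(k) + noise.
# The offset range dominates DELTA so single-slice separation stays weak.
_SIGNAL_DELTA = 0.30
_OFFSET_RANGE = (0.05, 0.65)
_SIGNAL_NOISE = 0.01


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic serial-section stack."""

    image_size: tuple[int, int] = (256, 256)
    n_sections: int = 6
    n_ribbons_per_section: int = 1
    max_rotation: float = 10.0  # degrees
    max_translation: float = 15.0  # pixels
    max_scale_dev: float = 0.05  # fraction
    warp_amplitude: float = 0.0  # pixels
    warp_smoothness: float = 48.0  # control-point spacing, pixels
    class_label: int = 0
    signal_strength: float = 1.0
    seed: int = 0
    ribbon_fill: float = 0.62  # band height as a fraction of its allotted slot
    texture: float = 1.0  # stromal texture amplitude scale
    noise_sigma: float = 0.008  # per-section additive intensity noise

    def __post_init__(self) -> None:
        if self.n_sections < 2:
            raise ValueError("n_sections must be >= 2")
        if min(self.image_size) <= 0:
            raise ValueError("image_size must be positive")
        if self.warp_amplitude < 0:
            raise ValueError("warp_amplitude must be >= 0")
        if not 0 <= self.max_scale_dev < 0.5:
            raise ValueError("max_scale_dev must be in [0, 0.5)")
        if self.n_ribbons_per_section < 1:
            raise ValueError("n_ribbons_per_section must be >= 1")
        if self.warp_smoothness <= 0:
            raise ValueError("warp_smoothness must be positive")


@dataclass
class SerialSectionStack:
    """Ordered RGB section images of one core at a single level."""

    sections: list[np.ndarray]
    microns_per_pixel: float = 2.0
    level_downsample: float = 1.0
    core_id: str = "phantom"

    def __post_init__(self) -> None:
        if len(self.sections) < 2:
            raise ValueError("a stack needs at least 2 sections")

    @property
    def n_sections(self) -> int:
        return len(self.sections)

    @property
    def shape(self) -> tuple[int, int]:
        return self.sections[0].shape[:2]

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for k, img in enumerate(self.sections):
            iio.imwrite(out / f"section_{k:03d}.png", img)
        meta = {
            "microns_per_pixel": self.microns_per_pixel,
            "level_downsample": self.level_downsample,
            "core_id": self.core_id,
            "n_sections": self.n_sections,
        }
        (out / "stack.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, in_dir: str | Path) -> "SerialSectionStack":
        p = Path(in_dir)
        meta = json.loads((p / "stack.json").read_text())
        sections = [
            np.asarray(iio.imread(p / f"section_{k:03d}.png"))
            for k in range(meta["n_sections"])
        ]
        return cls(
            sections=sections,
            microns_per_pixel=meta["microns_per_pixel"],
            level_downsample=meta["level_downsample"],
            core_id=meta["core_id"],
        )


@dataclass
class GroundTruth:
    """Exact generative parameters of a phantom stack.

    ``transforms[k]`` maps section-k coordinates into the shared base frame;
    ``warp_lattices[k]`` is the control lattice of the additive displacement
    (evaluated in the section frame), so the full section->base map is
    ``m_k(x) = T_k(x) + u_k(x)``. ``points[k]`` holds the section-k pixel
    coordinates of a common set of base tissue points (NaN where the point
    left the canvas), giving exact correspondences between any two sections.
    """

    transforms: list[SimilarityTransform]
    warp_lattices: list[np.ndarray]
    warp_spacing: float
    points: np.ndarray  # (n_sections, n_points, 2), NaN = invalid
    class_label: int = 0
    microns_per_pixel: float = 2.0

    def map_to_base(self, k: int, pts: np.ndarray) -> np.ndarray:
        """Apply the stored section-k -> base map to (n, 2) points."""
        disp = _lattice_at(self.warp_lattices[k], self.warp_spacing, pts)
        return self.transforms[k].apply(pts) + disp

    def correspondences(self, i: int) -> tuple[np.ndarray, np.ndarray]:
        """Matched point pairs between sections i and i+1."""
        a, b = self.points[i], self.points[i + 1]
        ok = ~(np.isnan(a).any(axis=1) | np.isnan(b).any(axis=1))
        return a[ok], b[ok]

    def points_valid_in(self, ks: list[int]) -> np.ndarray:
        """Boolean mask of points valid in every listed section."""
        ok = np.ones(self.points.shape[1], dtype=bool)
        for k in ks:
            ok &= ~np.isnan(self.points[k]).any(axis=1)
        return ok

    def to_json(self) -> str:
        return json.dumps(
            {
                "transforms": [t.to_dict() for t in self.transforms],
                "warp_lattices": [lat.tolist() for lat in self.warp_lattices],
                "warp_spacing": self.warp_spacing,
                "points": np.where(np.isnan(self.points), None, self.points).tolist(),
                "class_label": self.class_label,
                "microns_per_pixel": self.microns_per_pixel,
            }
        )

    @classmethod
    def from_json(cls, s: str) -> "GroundTruth":
        d = json.loads(s)
        pts = np.array(
            [[[np.nan if v is None else v for v in p] for p in sec]
             for sec in d["points"]],
            dtype=float,
        )
        return cls(
            transforms=[SimilarityTransform.from_dict(t) for t in d["transforms"]],
            warp_lattices=[np.array(w) for w in d["warp_lattices"]],
            warp_spacing=d["warp_spacing"],
            points=pts,
            class_label=d["class_label"],
            microns_per_pixel=d["microns_per_pixel"],
        )


def _lattice_at(lattice: np.ndarray, spacing: float, pts: np.ndarray) -> np.ndarray:
    """Evaluate a (2, gh, gw) displacement lattice at (n, 2) points."""
    from scipy import ndimage

    coords = np.asarray(pts, dtype=float).T / spacing
    out = np.empty_like(np.asarray(pts, dtype=float))
    for c in range(2):
        out[:, c] = ndimage.map_coordinates(
            lattice[c], coords, order=1, mode="nearest"
        )
    return out


def _base_tissue(spec: PhantomSpec, rng: np.random.Generator):
    """Render the shared base tissue: RGB image + tissue mask."""
    h, w = spec.image_size
    rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    mask = np.zeros((h, w), dtype=bool)
    n_rib = spec.n_ribbons_per_section
    band_h = h / (n_rib + 1) * spec.ribbon_fill
    for i in range(n_rib):
        center = h * (i + 1) / (n_rib + 1)
        # wavy band edges: low-frequency sinusoids along the columns
        phase = rng.uniform(0, 2 * np.pi, size=2)
        freq = rng.uniform(1.0, 2.5, size=2)
        wobble = band_h * 0.18 * (
            np.sin(2 * np.pi * freq[0] * cc / w + phase[0])
            + 0.5 * np.sin(2 * np.pi * freq[1] * cc / w + phase[1])
        )
        margin = 0.08 * w
        inside = (np.abs(rr - center - wobble) < band_h / 2) & (
            (cc > margin) & (cc < w - margin)
        )
        mask |= inside

    img = np.full((h, w, 3), _BACKGROUND)
    stroma = hsv2rgb(np.array(_STROMA_HSV)[None, None, :])[0, 0]
    nuclei = hsv2rgb(np.array(_NUCLEI_HSV)[None, None, :])[0, 0]
    img[mask] = stroma

    # stromal texture: smooth intensity field plus fine speckle, so the
    # tissue carries trackable structure at several scales (as real H&E does)
    from scipy import ndimage as _ndi

    smooth = _ndi.gaussian_filter(rng.normal(0, 1.0, size=(h, w)), 6.0)
    speckle = _ndi.gaussian_filter(rng.normal(0, 1.0, size=(h, w)), 1.2)
    texture = 1.0 + spec.texture * (
        0.35 * smooth / max(np.abs(smooth).max(), 1e-9)
        + 0.25 * speckle / max(np.abs(speckle).max(), 1e-9)
    )
    img[mask] *= np.clip(texture, 0.55, 1.45)[mask, None]

    # gland-like lumens: white ellipses with a purple epithelial rim.
    # The hole area is driven to a fixed fraction of the tissue so the
    # baseline gland density is comparable across cores.
    area = mask.sum()
    base_target = 0.05 * area
    tissue_idx = np.argwhere(mask)
    lumen = np.zeros((h, w), dtype=bool)
    rim = np.zeros((h, w), dtype=bool)
    tries = 0
    while lumen.sum() < base_target and tries < 200:
        tries += 1
        cy, cx = tissue_idx[rng.integers(len(tissue_idx))]
        a, b = rng.uniform(4, 11, size=2)
        ang = rng.uniform(0, np.pi)
        dy, dx = rr - cy, cc - cx
        u = dy * np.cos(ang) + dx * np.sin(ang)
        v = -dy * np.sin(ang) + dx * np.cos(ang)
        r2 = (u / a) ** 2 + (v / b) ** 2
        new = (r2 < 1.0) & mask & ~lumen
        remaining = base_target - lumen.sum()
        if new.sum() > remaining:  # shrink the last gland to hit the target
            shrink = np.sqrt(max(remaining, 9) / max(new.sum(), 1))
            r2 = (u / (a * shrink)) ** 2 + (v / (b * shrink)) ** 2
        lumen |= (r2 < 1.0) & mask
        rim |= (r2 >= 1.0) & (r2 < 1.7) & mask
    img[rim] = nuclei
    img[lumen] = _BACKGROUND

    # scattered nuclei dots on stroma
    n_dots = int(area * 0.02)
    if n_dots and len(tissue_idx):
        picks = tissue_idx[rng.integers(len(tissue_idx), size=n_dots)]
        for dy in (0, 1):
            for dx in (0, 1):
                ys = np.clip(picks[:, 0] + dy, 0, h - 1)
                xs = np.clip(picks[:, 1] + dx, 0, w - 1)
                img[ys, xs] = nuclei
    img[lumen] = _BACKGROUND
    return img, mask


def _draw_transform(spec: PhantomSpec, rng: np.random.Generator, h: int, w: int
                    ) -> SimilarityTransform:
    """Random section->base similarity, rotation/scale about the canvas center."""
    theta = rng.uniform(-spec.max_rotation, spec.max_rotation)
    scale = 1.0 + rng.uniform(-spec.max_scale_dev, spec.max_scale_dev)
    t = rng.uniform(-spec.max_translation, spec.max_translation, size=2)
    center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    about_origin = SimilarityTransform(theta_deg=theta, scale=scale)
    shift = center + t - about_origin.apply(center[None, :])[0]
    return SimilarityTransform(
        theta_deg=theta, scale=scale, t_row=shift[0], t_col=shift[1]
    )


def _draw_warp(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    gh, gw = imageops.lattice_shape_for(spec.image_size, spec.warp_smoothness)
    amp = min(spec.warp_amplitude, spec.warp_smoothness / 2 - 1e-9)
    return rng.uniform(-amp, amp, size=(2, gh, gw)) if amp > 0 else np.zeros(
        (2, gh, gw)
    )


def generate_phantom_stack(
    spec: PhantomSpec,
    section_values: np.ndarray | None = None,
    signal_mode: str = "none",
) -> tuple[SerialSectionStack, GroundTruth]:
    """Generate one serial-section stack plus its exact ground truth.

    ``section_values`` gives a per-section scalar in [0, 1] driving the
    classification signal channel: with ``signal_mode='glands'`` it sets the
    density of extra gland-like lumens in that section (structural, visible
    to a layer-normalizing encoder); with ``'brightness'`` it scales tissue
    intensity; ``'none'`` (default, used for alignment phantoms) renders no
    class signal.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_size
    base_img, base_mask = _base_tissue(spec, rng)

    transforms: list[SimilarityTransform] = []
    lattices: list[np.ndarray] = []
    for k in range(spec.n_sections):
        if k == 0:
            transforms.append(identity())
            lattices.append(np.zeros_like(_draw_warp(spec, rng)))
        else:
            transforms.append(_draw_transform(spec, rng, h, w))
            lattices.append(_draw_warp(spec, rng))

    if section_values is None:
        section_values = np.full(spec.n_sections, 0.5)
    section_values = np.clip(np.asarray(section_values, dtype=float), 0, 1)
    if signal_mode not in ("brightness", "glands", "none"):
        raise ValueError(f"unknown signal_mode {signal_mode!r}")

    grid = imageops._coord_grid((h, w))
    rr_g, cc_g = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    sections: list[np.ndarray] = []
    for k in range(spec.n_sections):
        disp = imageops.dense_from_lattice(lattices[k], spec.warp_smoothness, (h, w))
        flat = grid.reshape(2, -1).T
        src = transforms[k].apply(flat).T.reshape(2, h, w) + disp
        img = imageops.sample_image(base_img, src, order=1, fill=_BACKGROUND)
        tissue = imageops.sample_image(
            base_mask.astype(float), src, order=0, fill=0.0
        ) > 0.5
        if signal_mode == "brightness":
            img[tissue] *= _BRIGHT_LO + _BRIGHT_SPAN * section_values[k]
        elif signal_mode == "glands":
            # per-section extra lumens: the class signature is the density
            # of gland-like holes, which drifts coherently with depth.
            # Lumens are added until a target hole AREA is reached, so the
            # rendered signal tracks section_values with little count noise.
            target = section_values[k] * tissue.sum() * 0.12
            if target > 0 and tissue.any():
                from scipy import ndimage as _ndi2

                nuclei = hsv2rgb(np.array(_NUCLEI_HSV)[None, None, :])[0, 0]
                # existing holes (base-gland lumens): avoid them so every
                # new lumen contributes its full area
                holes = tissue & (img[..., 1] > 0.9)
                blocked = _ndi2.binary_dilation(holes, np.ones((7, 7)))
                # keep lumens clear of the ribbon edge so each one is a
                # closed hole (open notches would not read as gland lumens)
                blocked |= ~_ndi2.binary_erosion(tissue, np.ones((9, 9)))
                extra = np.zeros((h, w), dtype=bool)
                painted = 0.0
                tries = 0
                while painted < target - 4 and tries < 2000:
                    tries += 1
                    cand = np.argwhere(tissue & ~blocked & ~extra)
                    if not len(cand):
                        break
                    cy, cx = cand[rng.integers(len(cand))]
                    a, b = rng.uniform(1.6, 2.1, size=2)
                    r2 = ((rr_g - cy) / a) ** 2 + ((cc_g - cx) / b) ** 2
                    lum = (r2 < 1.0) & tissue & ~extra
                    remaining = target - painted
                    if lum.sum() > remaining:  # trim the final lumen to fit
                        shrink = np.sqrt(max(remaining, 9) / max(lum.sum(), 1))
                        r2 = ((rr_g - cy) / (a * shrink)) ** 2 + (
                            (cc_g - cx) / (b * shrink)) ** 2
                        lum = (r2 < 1.0) & tissue & ~extra
                    img[(r2 < 1.7) & (r2 >= 1.0) & tissue] = nuclei
                    img[lum] = _BACKGROUND
                    painted += lum.sum()
                    extra |= lum
        img += rng.normal(0.0, spec.noise_sigma, size=img.shape)
        sections.append(imageops.to_uint8(img))

    # ground-truth correspondences: common base points traced into each section
    from scipy import ndimage as ndi

    interior = ndi.binary_erosion(base_mask, np.ones((9, 9)))
    cand = np.argwhere(interior)
    n_pts = min(150, len(cand))
    if n_pts == 0:
        raise RuntimeError("phantom produced no interior tissue")
    base_pts = cand[rng.choice(len(cand), size=n_pts, replace=False)].astype(float)

    points = np.full((spec.n_sections, n_pts, 2), np.nan)
    for k in range(spec.n_sections):
        inv = transforms[k].inverse()
        x = inv.apply(base_pts)
        for _ in range(60):  # fixed-point inversion of T(x) + u(x) = p
            disp = _lattice_at(lattices[k], spec.warp_smoothness, x)
            x = inv.apply(base_pts - disp)
        resid = np.linalg.norm(
            transforms[k].apply(x)
            + _lattice_at(lattices[k], spec.warp_smoothness, x)
            - base_pts,
            axis=1,
        )
        ok = (
            (resid < 1e-6)
            & (x[:, 0] >= 0) & (x[:, 0] <= h - 1)
            & (x[:, 1] >= 0) & (x[:, 1] <= w - 1)
        )
        points[k, ok] = x[ok]

    stack = SerialSectionStack(
        sections=sections, core_id=f"phantom_{spec.seed}"
    )
    gt = GroundTruth(
        transforms=transforms,
        warp_lattices=lattices,
        warp_spacing=spec.warp_smoothness,
        points=points,
        class_label=spec.class_label,
        microns_per_pixel=stack.microns_per_pixel,
    )
    return stack, gt


# ---------------------------------------------------------------------------
# labeled datasets


_PATTERN_BANK = ("ramp_up", "ramp_down", "zigzag", "zigzag_inv", "vee", "hat")


def class_pattern(label: int, n_sections: int) -> np.ndarray:
    """Depth pattern of class ``label``; every pattern has mean 0.5."""
    if label >= len(_PATTERN_BANK):
        raise ValueError(
            f"at most {len(_PATTERN_BANK)} classes supported, got label {label}"
        )
    kind = _PATTERN_BANK[label]
    k = np.arange(n_sections)
    if kind == "ramp_up":
        p = k / (n_sections - 1)
    elif kind == "ramp_down":
        p = 1 - k / (n_sections - 1)
    elif kind == "zigzag":
        p = (k % 2).astype(float)
    elif kind == "zigzag_inv":
        p = 1.0 - (k % 2)
    elif kind == "vee":
        p = np.abs(k - (n_sections - 1) / 2) / ((n_sections - 1) / 2)
    else:  # hat
        p = 1 - np.abs(k - (n_sections - 1) / 2) / ((n_sections - 1) / 2)
    return p - p.mean() + 0.5


def _section_values(
    label: int, n_sections: int, depth_signal: bool, n_classes: int,
    rng: np.random.Generator,
) -> np.ndarray:
    if depth_signal:
        offset = rng.uniform(*_OFFSET_RANGE)
        v = offset + _SIGNAL_DELTA * class_pattern(label, n_sections)
    else:
        # class encoded directly in the per-slice level
        base = 0.05 + 0.9 * label / max(1, n_classes - 1)
        v = np.full(n_sections, base) + rng.uniform(-0.05, 0.05)
    return np.clip(v + rng.normal(0, _SIGNAL_NOISE, size=n_sections), 0, 1)


def allocate_counts(n: int, proportions: np.ndarray) -> np.ndarray:
    """Largest-remainder allocation of n items to the given proportions."""
    p = np.asarray(proportions, dtype=float)
    raw = n * p
    counts = np.floor(raw).astype(int)
    short = n - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:short]] += 1
    return counts


def stratified_split(
    labels: np.ndarray,
    fractions: tuple[float, float, float] = (0.7, 0.1, 0.2),
    seed: int = 0,
) -> np.ndarray:
    """Per-label 'train'/'val'/'test' assignment with the given fractions."""
    rng = np.random.default_rng(seed)
    labels = np.asarray(labels)
    out = np.empty(len(labels), dtype=object)
    for lbl in np.unique(labels):
        idx = np.where(labels == lbl)[0]
        rng.shuffle(idx)
        counts = allocate_counts(len(idx), np.array(fractions))
        names = np.repeat(["train", "val", "test"], counts)
        out[idx] = names
    return out.astype(str)


def generate_labeled_dataset(
    n_cores: int,
    class_proportions,
    depth_signal: bool = True,
    seed: int = 0,
    n_sections: int = 4,
    image_size: tuple[int, int] = (160, 160),
    aligned: bool = True,
    out_dir: str | Path | None = None,
):
    """Generate a labeled multi-core dataset with a split manifest.

    Returns ``(manifest, stacks, truths)`` where the manifest is a DataFrame
    with columns core_id, label, split, path. When ``aligned`` (default) the
    sections carry identity transforms, emulating an already co-registered
    core so classification can be studied independently of alignment.
    """
    props = np.asarray(class_proportions, dtype=float)
    if not np.isclose(props.sum(), 1.0):
        raise ValueError("class_proportions must sum to 1")
    n_classes = len(props)
    if n_cores < n_classes:
        raise ValueError("n_cores must be >= number of classes")

    counts = allocate_counts(n_cores, props)
    labels = np.repeat(np.arange(n_classes), counts)
    rng = np.random.default_rng(seed)

    stacks, truths, rows = [], [], []
    for i, lbl in enumerate(labels):
        core_seed = int(rng.integers(0, 2**31 - 1))
        geo = dict(max_rotation=6.0, max_translation=8.0, max_scale_dev=0.03)
        if aligned:
            geo = dict(max_rotation=0.0, max_translation=0.0, max_scale_dev=0.0)
        spec = PhantomSpec(
            image_size=image_size,
            n_sections=n_sections,
            class_label=int(lbl),
            seed=core_seed,
            warp_amplitude=0.0,
            ribbon_fill=0.85,
            **geo,
        )
        values = _section_values(int(lbl), n_sections, depth_signal, n_classes,
                                 rng)
        stack, gt = generate_phantom_stack(spec, section_values=values,
                                           signal_mode="glands")
        stack.core_id = f"core_{i:04d}"
        stacks.append(stack)
        truths.append(gt)
        rows.append({"core_id": stack.core_id, "label": int(lbl)})

    manifest = pd.DataFrame(rows)
    manifest["split"] = stratified_split(manifest["label"].to_numpy(), seed=seed)
    manifest["path"] = ""

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for stack, gt in zip(stacks, truths):
            d = out / stack.core_id
            stack.save(d)
            (d / "ground_truth.json").write_text(gt.to_json())
            manifest.loc[
                manifest["core_id"] == stack.core_id, "path"
            ] = str(d)
        manifest.to_csv(out / "manifest.csv", index=False)

    return manifest, stacks, truths


def per_slice_statistic(stack: SerialSectionStack) -> np.ndarray:
    """Per-section gland (lumen) fraction — the generator's own signal
    channel: the fraction of hole pixels inside the filled tissue
    footprint. With ``depth_signal`` the per-slice values barely separate
    classes while consecutive differences do."""
    from scipy import ndimage

    from .preprocess import build_tissue_mask

    vals = []
    for img in stack.sections:
        m = build_tissue_mask(img, closing_radius=1).mask
        filled = ndimage.binary_fill_holes(m)
        vals.append((filled & ~m).sum() / max(filled.sum(), 1))
    return np.array(vals)


def depth_pair_statistic(stack: SerialSectionStack) -> np.ndarray:
    """Signed consecutive-slice brightness increments (a 2-slice joint
    statistic that exposes the depth-coherent class pattern)."""
    return np.diff(per_slice_statistic(stack))
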