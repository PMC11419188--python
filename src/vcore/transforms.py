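"""Similarity transforms between serial sections.

Coordinates are 0-based ``(row, col)`` pixel positions at a stated resolution
level; bounding boxes are half-open. A similarity transform maps a point ``p``
to ``scale * R(theta) @ p + t`` where ``R`` is a rotation in the (row, col)
plane. Shear is never introduced, so composing transforms stays in the family.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np


def rotation_matrix(theta_deg: float) -> np.ndarray:
    """2x2 rotation acting on (row, col) column vectors."""
    th = np.deg2rad(theta_deg)
    c, s = np.cos(th), np.sin(th)
    return np.array([[c, -s], [s, c]])


@dataclass(frozen=True)
class SimilarityTransform:
    """Rotation + isotropic scale + translation at a given pyramid level.

    Parameters
    ----------
    theta_deg : rotation angle in degrees (counter-clockwise in (row, col)).
    scale : isotropic scale factor, > 0.
    t_row, t_col : translation in pixels at the transform's level.
    level_downsample : downsample factor of the level the translation refers
        to (level-0 pixels per pixel at this level).
    """

    theta_deg: float = 0.0
    scale: float = 1.0
    t_row: float = 0.0
    t_col: float = 0.0
    level_downsample: float = 1.0

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError(f"scale must be positive, got {self.scale}")
        if self.level_downsample <= 0:
            raise ValueError("level_downsample must be positive")

    # -- linear algebra -----------------------------------------------------

    @property
    def linear(self) -> np.ndarray:
        """The 2x2 linear part, scale * R(theta)."""
        return self.scale * rotation_matrix(self.theta_deg)

    @property
    def translation(self) -> np.ndarray:
        return np.array([self.t_row, self.t_col])

    def matrix(self) -> np.ndarray:
        """3x3 homogeneous matrix acting on (row, col, 1) columns."""
        m = np.eye(3)
        m[:2, :2] = self.linear
        m[:2, 2] = self.translation
        return m

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map an (n, 2) array of (row, col) points."""
        pts = np.asarray(points, dtype=float)
        return pts @ self.linear.T + self.translation

    # -- group operations ---------------------------------------------------

    def compose(self, other: "SimilarityTransform") -> "SimilarityTransform":
        """Return ``self o other`` (apply ``other`` first)."""
        if not np.isclose(self.level_downsample, other.level_downsample):
            raise ValueError(
                "cannot compose transforms at different levels: "
                f"{self.level_downsample} vs {other.level_downsample}"
            )
        t = self.apply(other.translation[None, :])[0]
        return SimilarityTransform(
            theta_deg=self.theta_deg + other.theta_deg,
            scale=self.scale * other.scale,
            t_row=t[0],
            t_col=t[1],
            level_downsample=self.level_downsample,
        )

    def inverse(self) -> "SimilarityTransform":
        inv_lin = rotation_matrix(-self.theta_deg) / self.scale
        t = -inv_lin @ self.translation
        return SimilarityTransform(
            theta_deg=-self.theta_deg,
            scale=1.0 / self.scale,
            t_row=t[0],
            t_col=t[1],
            level_downsample=self.level_downsample,
        )

    def almost_equal(self, other: "SimilarityTransform", atol: float = 1e-6) -> bool:
        return bool(
            np.allclose(self.matrix(), other.matrix(), atol=atol)
            and np.isclose(self.level_downsample, other.level_downsample)
        )

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "theta_deg": float(self.theta_deg),
            "scale": float(self.scale),
            "t_row": float(self.t_row),
            "t_col": float(self.t_col),
            "level_downsample": float(self.level_downsample),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimilarityTransform":
        return cls(**d)

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "SimilarityTransform":
        return cls.from_dict(json.loads(s))


def identity(level_downsample: float = 1.0) -> SimilarityTransform:
    return SimilarityTransform(level_downsample=level_downsample)


def propagate_to_resolution(
    t: SimilarityTransform, target_downsample: float
) -> SimilarityTransform:
    """Re-express a transform at another pyramid level.

    The rotation angle and scale are resolution independent; only the
    translation is rescaled by the ratio of downsample factors.
    """
    if target_downsample <= 0:
        raise ValueError("target_downsample must be positive")
    factor = t.level_downsample / target_downsample
    return SimilarityTransform(
        theta_deg=t.theta_deg,
        scale=t.scale,
        t_row=t.t_row * factor,
        t_col=t.t_col * factor,
        level_downsample=target_downsample,
    )


def fit_similarity_lsq(src: np.ndarray, dst: np.ndarray) -> SimilarityTransform:
    """Closed-form least-squares similarity fit (Umeyama) mapping src -> dst.

    Both inputs are (n, 2) arrays of (row, col) points, n >= 2.
    """
    src = np.asarray(src, dtype=float)
    dst = np.asarray(dst, dtype=float)
    if src.shape != dst.shape or src.ndim != 2 or src.shape[0] < 2:
        raise ValueError("need matching (n, 2) arrays with n >= 2")
    mu_s = src.mean(axis=0)
    mu_d = dst.mean(axis=0)
    xs = src - mu_s
    xd = dst - mu_d
    cov = xd.T @ xs / len(src)
    u, s, vt = np.linalg.svd(cov)
    d = np.sign(np.linalg.det(u @ vt))
    sgn = np.diag([1.0, d])
    rot = u @ sgn @ vt
    var_s = (xs**2).sum() / len(src)
    if var_s == 0:
        raise ValueError("degenerate source points (zero variance)")
    scale = float((s * np.diag(sgn)).sum() / var_s)
    t = mu_d - scale * rot @ mu_s
    theta = float(np.rad2deg(np.arctan2(rot[1, 0], rot[0, 0])))
    return SimilarityTransform(theta_deg=theta, scale=scale, t_row=t[0], t_col=t[1])
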