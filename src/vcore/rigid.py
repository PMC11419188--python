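"""Similarity-only stack alignment via OT keypoint matching.

SIFT keypoints from neighboring sections are matched by solving an entropic
optimal transport problem over descriptor costs, augmented with a "dustbin"
row/column that absorbs unmatchable points (features present in only one of
the two sections). A robust consensus loop then fits a similarity transform
— rotation, isotropic scale, translation, nothing else — so tissue
morphology is never sheared. Alignment is sequential: the first section is
the reference and each later section is registered to the rendered,
already-registered previous one. Estimated transforms propagate across
pyramid levels by rescaling only the translation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp
from skimage.feature import SIFT

from . import imageops
from .preprocess import Ribbon, build_tissue_mask
from .transforms import (
    SimilarityTransform,
    fit_similarity_lsq,
    identity,
    propagate_to_resolution,
)

__all__ = [
    "KeypointSet",
    "MatchSet",
    "AlignmentError",
    "detect_keypoints",
    "match_descriptors_ot",
    "fit_similarity_robust",
    "RobustFitResult",
    "align_stack_rigid",
    "RigidAlignment",
    "propagate_to_resolution",
]


class AlignmentError(RuntimeError):
    """Raised when a section pair cannot be aligned."""


@dataclass
class KeypointSet:
    positions: np.ndarray  # (n, 2) (row, col)
    descriptors: np.ndarray  # (n, d), unit Euclidean norm rows
    scales: np.ndarray = field(default_factory=lambda: np.empty(0))
    orientations: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __len__(self) -> int:
        return len(self.positions)


@dataclass
class MatchSet:
    pairs: np.ndarray  # (m, 2) indices (index_in_A, index_in_B)
    scores: np.ndarray  # (m,) transport mass in (0, 1]

    @property
    def n_matched(self) -> int:
        return len(self.pairs)


def _empty_keypoints() -> KeypointSet:
    return KeypointSet(
        positions=np.empty((0, 2)), descriptors=np.empty((0, 128))
    )


def detect_keypoints(
    image: np.ndarray,
    max_keypoints: int = 800,
    mask: np.ndarray | None = None,
    c_dog: float = 0.009,
) -> KeypointSet:
    """SIFT keypoints with unit-normalized descriptors.

    When a tissue mask is given, the background is flattened to white before
    detection and off-tissue keypoints are discarded, so scanner background
    texture can never produce matches.
    """
    gray = imageops.rgb_to_gray(image) if image.ndim == 3 else imageops.to_float(image)
    if mask is not None:
        gray = np.where(mask, gray, 1.0)
    det = SIFT(upsampling=1, c_dog=c_dog)
    try:
        det.detect_and_extract(gray)
    except RuntimeError:  # featureless image
        return _empty_keypoints()
    pos = det.keypoints.astype(float)
    desc = det.descriptors.astype(float)
    scales = det.scales.astype(float)
    orients = det.orientations.astype(float)
    if mask is not None:
        rr = np.clip(np.round(pos[:, 0]).astype(int), 0, mask.shape[0] - 1)
        cc = np.clip(np.round(pos[:, 1]).astype(int), 0, mask.shape[1] - 1)
        keep = mask[rr, cc]
        pos, desc, scales, orients = pos[keep], desc[keep], scales[keep], orients[keep]
    if len(pos) > max_keypoints:
        pos, desc = pos[:max_keypoints], desc[:max_keypoints]
        scales, orients = scales[:max_keypoints], orients[:max_keypoints]
    norms = np.linalg.norm(desc, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return KeypointSet(pos, desc / norms, scales, orients)


def sinkhorn_with_dustbin(
    cost: np.ndarray,
    epsilon: float = 0.02,
    n_iter: int = 100,
    dustbin_cost: float = 0.3,
) -> np.ndarray:
    """Entropic OT plan for an (nA, nB) cost with an unmatched-point dustbin.

    The cost matrix is augmented with one extra row and column at
    ``dustbin_cost``; each real point carries unit mass and each dustbin the
    mass of the opposite side, so every point can either match or opt out.
    Returns the full (nA+1, nB+1) transport plan.
    """
    na, nb = cost.shape
    c = np.full((na + 1, nb + 1), dustbin_cost)
    c[:na, :nb] = cost
    log_a = np.log(np.r_[np.ones(na), nb])
    log_b = np.log(np.r_[np.ones(nb), na])
    f = np.zeros(na + 1)
    g = np.zeros(nb + 1)
    mc = -c / epsilon
    for _ in range(n_iter):
        f = epsilon * (log_a - logsumexp(mc + g / epsilon, axis=1))
        g = epsilon * (log_b - logsumexp(mc + f[:, None] / epsilon, axis=0))
    return np.exp(mc + (f[:, None] + g) / epsilon)


def match_descriptors_ot(
    a: KeypointSet,
    b: KeypointSet,
    epsilon: float = 0.02,
    n_iter: int = 100,
    score_threshold: float = 0.2,
    dustbin_cost: float = 0.3,
) -> MatchSet:
    """One-to-one descriptor matching via the entropic-OT plan.

    Cost is one minus the descriptor dot product. Accepted pairs are mutual
    row/column argmaxes of the plan (dustbin included as a candidate) whose
    transported mass reaches ``score_threshold``.
    """
    if len(a) == 0 or len(b) == 0:
        raise AlignmentError("no features: cannot match empty keypoint sets")
    cost = 1.0 - a.descriptors @ b.descriptors.T
    plan = sinkhorn_with_dustbin(cost, epsilon, n_iter, dustbin_cost)
    na, nb = cost.shape
    row_best = plan.argmax(axis=1)[:na]
    col_best = plan.argmax(axis=0)[:nb]
    pairs, scores = [], []
    for i in range(na):
        j = row_best[i]
        if j < nb and col_best[j] == i and plan[i, j] >= score_threshold:
            pairs.append((i, j))
            scores.append(plan[i, j])
    return MatchSet(
        pairs=np.array(pairs, dtype=int).reshape(-1, 2),
        scores=np.array(scores),
    )


@dataclass
class RobustFitResult:
    transform: SimilarityTransform
    inliers: np.ndarray  # boolean mask over the matches
    residuals: np.ndarray  # per-match residual in pixels under the final fit

    @property
    def n_inliers(self) -> int:
        return int(self.inliers.sum())

    @property
    def rms_residual(self) -> float:
        r = self.residuals[self.inliers]
        return float(np.sqrt(np.mean(r**2))) if len(r) else float("nan")


def fit_similarity_robust(
    matches: MatchSet,
    positions_a: np.ndarray,
    positions_b: np.ndarray,
    inlier_tol: float = 3.0,
    n_trials: int = 1000,
    seed: int = 0,
) -> RobustFitResult:
    """Consensus similarity fit mapping matched A points onto B points.

    Minimal two-point subsets give candidate similarities; the candidate with
    the most inliers at ``inlier_tol`` wins and is refined by a closed-form
    least-squares fit on its inlier set.
    """
    if matches.n_matched < 4:
        raise AlignmentError(
            f"insufficient matches: {matches.n_matched} < 4"
        )
    src = np.asarray(positions_a, float)[matches.pairs[:, 0]]
    dst = np.asarray(positions_b, float)[matches.pairs[:, 1]]
    rng = np.random.default_rng(seed)
    m = len(src)
    best_count, best_inliers = 0, None
    for _ in range(n_trials):
        i, j = rng.choice(m, size=2, replace=False)
        if np.allclose(src[i], src[j]) or np.allclose(dst[i], dst[j]):
            continue
        try:
            t = fit_similarity_lsq(src[[i, j]], dst[[i, j]])
        except ValueError:
            continue
        resid = np.linalg.norm(t.apply(src) - dst, axis=1)
        inl = resid < inlier_tol
        if inl.sum() > best_count:
            best_count, best_inliers = int(inl.sum()), inl
    if best_inliers is None or best_count < 4:
        raise AlignmentError(f"no consensus: best inlier count {best_count} < 4")
    t = fit_similarity_lsq(src[best_inliers], dst[best_inliers])
    resid = np.linalg.norm(t.apply(src) - dst, axis=1)
    inl = resid < inlier_tol
    if inl.sum() >= 4:  # one refinement round on the refit's own inliers
        t = fit_similarity_lsq(src[inl], dst[inl])
        resid = np.linalg.norm(t.apply(src) - dst, axis=1)
        inl = resid < inlier_tol
    return RobustFitResult(transform=t, inliers=inl, residuals=resid)


@dataclass
class RigidAlignment:
    """Result of sequential similarity alignment of a stack."""

    transforms: list[SimilarityTransform]  # section k coords -> reference frame
    aligned_images: list[np.ndarray]
    aligned_masks: list[np.ndarray]
    stacked_mask: np.ndarray  # union of aligned tissue masks
    bounding_box: tuple[int, int, int, int]
    pair_reports: list[dict]


def _stack_bbox(mask: np.ndarray) -> tuple[int, int, int, int]:
    rows, cols = np.nonzero(mask)
    if len(rows) == 0:
        return (0, 0, mask.shape[0], mask.shape[1])
    return (int(rows.min()), int(cols.min()), int(rows.max()) + 1,
            int(cols.max()) + 1)


def align_stack_rigid(
    sections: list[np.ndarray] | list[Ribbon],
    masks: list[np.ndarray] | None = None,
    level_downsample: float = 1.0,
    max_keypoints: int = 800,
    epsilon: float = 0.02,
    n_iter: int = 100,
    score_threshold: float = 0.2,
    inlier_tol: float = 3.0,
    n_trials: int = 1000,
    seed: int = 0,
    skip_on_failure: bool = False,
) -> RigidAlignment:
    """Sequentially register a stack of sections to the first one.

    Each section is matched against the rendered registered version of its
    predecessor, so only features shared by the two neighbors drive the fit.
    The union of the aligned tissue masks (the non-rigid registration mask)
    and its bounding box are returned for the downstream stages.
    """
    if sections and isinstance(sections[0], Ribbon):
        ribbons: list[Ribbon] = sections  # type: ignore[assignment]
        h = max(r.image_crop.shape[0] for r in ribbons)
        w = max(r.image_crop.shape[1] for r in ribbons)
        imgs, msks = [], []
        for r in ribbons:
            img = np.full((h, w, 3), 255, dtype=np.uint8)
            msk = np.zeros((h, w), dtype=bool)
            ch, cw = r.image_crop.shape[:2]
            r0, c0 = (h - ch) // 2, (w - cw) // 2
            img[r0:r0 + ch, c0:c0 + cw] = r.image_crop
            msk[r0:r0 + ch, c0:c0 + cw] = r.mask_crop
            imgs.append(img)
            msks.append(msk)
        sections, masks = imgs, msks
    if len(sections) < 2:
        raise ValueError("need at least 2 sections")
    if masks is None:
        masks = [build_tissue_mask(img).mask for img in sections]

    transforms = [identity(level_downsample)]
    aligned = [imageops.to_float(sections[0])]
    aligned_masks = [np.asarray(masks[0], bool)]
    reports: list[dict] = []
    for k in range(1, len(sections)):
        prev_kp = detect_keypoints(aligned[k - 1], max_keypoints,
                                   mask=aligned_masks[k - 1])
        cur_kp = detect_keypoints(sections[k], max_keypoints,
                                  mask=np.asarray(masks[k], bool))
        try:
            if len(prev_kp) == 0 or len(cur_kp) == 0:
                raise AlignmentError(
                    f"no features on pair ({k - 1}, {k})"
                )
            ms = match_descriptors_ot(
                cur_kp, prev_kp, epsilon, n_iter, score_threshold
            )
            fit = fit_similarity_robust(
                ms, cur_kp.positions, prev_kp.positions,
                inlier_tol=inlier_tol, n_trials=n_trials, seed=seed + k,
            )
        except AlignmentError as err:
            if not skip_on_failure:
                raise AlignmentError(
                    f"alignment failed on section pair ({k - 1}, {k}): {err}"
                ) from err
            transforms.append(transforms[-1])
            aligned.append(
                imageops.resample_similarity(
                    imageops.to_float(sections[k]), transforms[-1]
                )
            )
            aligned_masks.append(
                imageops.resample_mask(np.asarray(masks[k], bool), transforms[-1])
            )
            reports.append({"pair": (k - 1, k), "status": "skipped"})
            continue
        t = SimilarityTransform(
            theta_deg=fit.transform.theta_deg,
            scale=fit.transform.scale,
            t_row=fit.transform.t_row,
            t_col=fit.transform.t_col,
            level_downsample=level_downsample,
        )
        transforms.append(t)
        aligned.append(
            imageops.resample_similarity(imageops.to_float(sections[k]), t)
        )
        aligned_masks.append(
            imageops.resample_mask(np.asarray(masks[k], bool), t)
        )
        reports.append(
            {
                "pair": (k - 1, k),
                "status": "ok",
                "n_matches": ms.n_matched,
                "n_inliers": fit.n_inliers,
                "rms_residual_px": fit.rms_residual,
            }
        )
    stacked = np.any(np.stack(aligned_masks), axis=0)
    return RigidAlignment(
        transforms=transforms,
        aligned_images=aligned,
        aligned_masks=aligned_masks,
        stacked_mask=stacked,
        bounding_box=_stack_bbox(stacked),
        pair_reports=reports,
    )
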