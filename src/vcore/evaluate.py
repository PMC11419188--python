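"""Space-time attention rollout, heatmap overlays, and evaluation statistics.

Rollout treats per-block attention as the fraction of information flowing
between tokens: within one block the divided attention factorizes as
``W[i,j,p,q] = S[i,j,p] * T[p,j,q]`` — query token (spatial i, depth j)
reaches source token (p, q) through the spatial hop to position p in its
own section followed by the temporal hop along depth at position p. Blocks
are combined by cumulative matrix multiplication. Because transformer
blocks carry residual connections, each stage's attention can optionally be
mixed with the identity before combining (``residual_alpha``, default 0.5);
``residual_alpha=0`` reproduces the bare factorization.

The statistics mirror a grading study's toolkit: macro one-vs-rest AUC,
support-weighted precision/recall/F1, quadratic weighted kappa for ordinal
agreement, and McNemar's paired test (exact binomial for small discordant
counts, continuity-corrected chi-square otherwise).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.metrics import (
    confusion_matrix as _sk_confusion,
    precision_recall_fscore_support,
    roc_auc_score,
)

from .encoder import AttentionRecord

__all__ = [
    "RolloutTensor",
    "AgreementTable",
    "attention_rollout",
    "overlay_heatmaps",
    "abmil_heat_rasters",
    "classification_metrics",
    "quadratic_weighted_kappa",
    "mcnemar_test",
]


@dataclass
class RolloutTensor:
    """Combined space-time attention, per block and cumulative.

    ``per_block[l]`` and ``cumulative`` are (N*F, N*F) row-stochastic
    matrices over patch tokens; token (spatial p, depth t) maps to flat
    index ``t * N + p``. ``w(l)`` exposes block l as the four-index tensor
    W[i, j, p, q].
    """

    per_block: np.ndarray  # (L, N*F, N*F)
    cumulative: np.ndarray  # (N*F, N*F)
    space: np.ndarray  # (L, N, F, N): S[l, i, j, p], identity-mixed
    time: np.ndarray  # (L, N, F, F): T[l, p, j, q], identity-mixed
    cls_heat: np.ndarray  # (F, gh, gw)
    n_spatial: int
    depth: int

    def w(self, block: int) -> np.ndarray:
        n, f = self.n_spatial, self.depth
        m = self.per_block[block].reshape(f, n, f, n)
        return m.transpose(1, 0, 3, 2)  # -> W[i, j, p, q]


@dataclass
class AgreementTable:
    """K x K confusion counts between two ordinal raters."""

    counts: np.ndarray
    categories: list | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("agreement table must be square")
        if (self.counts < 0).any():
            raise ValueError("agreement counts must be nonnegative")

    @property
    def n(self) -> float:
        return float(self.counts.sum())


def _mix_identity(a: np.ndarray, alpha: float) -> np.ndarray:
    """Row-wise (1-alpha)*A + alpha*I followed by renormalization."""
    eye = np.eye(a.shape[-1])
    mixed = (1.0 - alpha) * a + alpha * eye
    return mixed / mixed.sum(axis=-1, keepdims=True)


def attention_rollout(
    records: list[AttentionRecord], residual_alpha: float = 0.5
) -> RolloutTensor:
    """Combine per-block divided attention into input-token attributions.

    Per block: average heads, drop the cls column and renormalize to get
    row-stochastic S (spatial) and T (temporal) over patch tokens, mix each
    with the identity by ``residual_alpha``, combine via the factorized
    space-time product, then multiply cumulatively across blocks. The cls
    heat map comes from the last block's cls attention row pushed through
    the preceding blocks' cumulative attention.
    """
    if not records:
        raise ValueError("need at least one block's attention record")
    if not 0.0 <= residual_alpha < 1.0:
        raise ValueError("residual_alpha must lie in [0, 1)")
    n, f = records[0].n_spatial, records[0].depth
    for r in records:
        if (r.n_spatial, r.depth) != (n, f):
            raise ValueError("attention records disagree in N or F")

    blocks, s_all, t_all = [], [], []
    for rec in records:
        # T[p, j, q]: temporal attention, heads averaged, cls column dropped
        t_raw = rec.alpha_time.mean(axis=0)[..., 1:]  # (N, F, F)
        t_mat = _mix_identity(t_raw / t_raw.sum(axis=-1, keepdims=True),
                              residual_alpha)
        # S[i, j, p]: alpha_space is (A, F, N, N+1) indexed [a, j, i, col]
        s_raw = rec.alpha_space.mean(axis=0)[..., 1:]  # (F, N, N)
        s_raw = s_raw / s_raw.sum(axis=-1, keepdims=True)
        s_mat = _mix_identity(s_raw, residual_alpha).transpose(1, 0, 2)  # (N,F,N)
        # W[i,j,p,q] = S[i,j,p] * T[p,j,q]
        w4 = np.einsum("ijp,pjq->ijpq", s_mat, t_mat)
        # flatten: row (i,j) -> j*N+i, col (p,q) -> q*N+p
        flat = w4.transpose(1, 0, 3, 2).reshape(n * f, n * f)
        blocks.append(flat)
        s_all.append(s_mat)
        t_all.append(t_mat)

    cumulative = blocks[0]
    for b in blocks[1:]:
        cumulative = b @ cumulative

    # cls attribution: last block's cls row through the earlier blocks
    cls_row = records[-1].alpha_cls.mean(axis=0)[1:]  # over patch tokens
    cls_row = cls_row / cls_row.sum()
    pre = np.eye(n * f)
    for b in blocks[:-1]:
        pre = b @ pre
    heat = cls_row @ pre
    gh = int(round(np.sqrt(n)))
    cls_heat = heat.reshape(f, gh, gh) if gh * gh == n else heat.reshape(f, 1, n)

    return RolloutTensor(
        per_block=np.stack(blocks),
        cumulative=cumulative,
        space=np.stack(s_all),
        time=np.stack(t_all),
        cls_heat=cls_heat,
        n_spatial=n,
        depth=f,
    )


def _nn_upsample(weights: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    h, w = shape
    gh, gw = weights.shape
    rows = np.minimum((np.arange(h) * gh) // h, gh - 1)
    cols = np.minimum((np.arange(w) * gw) // w, gw - 1)
    return weights[np.ix_(rows, cols)]


def abmil_heat_rasters(
    shape: tuple[int, int],
    origins: list[tuple[int, int]],
    weights: np.ndarray,
    patch_size: int,
    n_sections: int,
) -> list[np.ndarray]:
    """Paint per-patch MIL attention onto the core frame (same map per
    section, since bag instances are whole volumetric patches)."""
    heat = np.zeros(shape)
    for (r0, c0), w in zip(origins, weights):
        if not (0 <= r0 <= shape[0] - patch_size
                and 0 <= c0 <= shape[1] - patch_size):
            raise ValueError(f"unknown patch origin {(r0, c0)} for frame {shape}")
        heat[r0:r0 + patch_size, c0:c0 + patch_size] = w
    return [heat.copy() for _ in range(n_sections)]


def overlay_heatmaps(
    sections: list[np.ndarray],
    heats: list[np.ndarray] | np.ndarray,
    alpha: float = 0.45,
) -> list[np.ndarray]:
    """Alpha-blend normalized heat rasters over each section.

    ``heats`` is one 2D weight array per section (any resolution; nearest
    upsampled), or a single array reused for all sections. Weights are
    normalized jointly to [0, 1]; the overlay channel is red.
    """
    if isinstance(heats, np.ndarray) and heats.ndim == 2:
        heats = [heats] * len(sections)
    heats = [np.asarray(h, float) for h in heats]
    if len(heats) != len(sections):
        raise ValueError("need one heat raster per section")
    hi = max(h.max() for h in heats)
    lo = min(h.min() for h in heats)
    span = (hi - lo) if hi > lo else 1.0
    out = []
    for img, h in zip(sections, heats):
        img_f = img.astype(float) / (255.0 if img.dtype == np.uint8 else 1.0)
        hh = _nn_upsample((h - lo) / span, img_f.shape[:2])
        overlay = np.zeros_like(img_f)
        overlay[..., 0] = 1.0
        blend = img_f * (1 - alpha * hh[..., None]) + overlay * (
            alpha * hh[..., None]
        )
        out.append(np.clip(blend, 0, 1))
    return out


def classification_metrics(
    y_true: np.ndarray,
    probabilities: np.ndarray,
    normalize_confusion: bool = False,
) -> dict:
    """Macro one-vs-rest AUC plus weighted (and macro) P/R/F1 and confusion.

    Classes absent from ``y_true`` are excluded from the AUC average with a
    warning.
    """
    y_true = np.asarray(y_true)
    probs = np.asarray(probabilities, dtype=float)
    k = probs.shape[1]
    present = np.unique(y_true)
    if len(present) < 2:
        raise ValueError("need at least 2 observed classes")
    aucs = []
    for c in range(k):
        if c not in present:
            warnings.warn(
                f"class {c} absent from y_true; excluded from macro AUC",
                stacklevel=2,
            )
            continue
        aucs.append(roc_auc_score((y_true == c).astype(int), probs[:, c]))
    y_pred = probs.argmax(axis=1)
    labels = np.arange(k)
    wp, wr, wf, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=labels, average="weighted", zero_division=0
    )
    mp, mr, mf, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=labels, average="macro", zero_division=0
    )
    conf = _sk_confusion(y_true, y_pred, labels=labels).astype(float)
    if normalize_confusion:
        row = conf.sum(axis=1, keepdims=True)
        conf = np.divide(conf, row, out=np.zeros_like(conf), where=row > 0)
    return {
        "macro_auc": float(np.mean(aucs)),
        "weighted_precision": float(wp),
        "weighted_recall": float(wr),
        "weighted_f1": float(wf),
        "macro_precision": float(mp),
        "macro_recall": float(mr),
        "macro_f1": float(mf),
        "confusion": conf,
    }


def quadratic_weighted_kappa(table: AgreementTable | np.ndarray) -> float:
    """Chance-corrected ordinal agreement with squared-distance weights.

    kappa = 1 - sum(w_ij O_ij) / sum(w_ij E_ij), with
    w_ij = (i - j)^2 / (K - 1)^2 and E the outer product of the marginals.
    """
    if not isinstance(table, AgreementTable):
        table = AgreementTable(table)
    o = table.counts
    k = o.shape[0]
    if k < 2:
        raise ValueError("need at least 2 ordered categories")
    n = o.sum()
    if n == 0:
        raise ValueError("empty agreement table")
    idx = np.arange(k)
    w = (idx[:, None] - idx[None, :]) ** 2 / (k - 1) ** 2
    row = o.sum(axis=1)
    col = o.sum(axis=0)
    e = np.outer(row, col) / n
    denom = (w * e).sum()
    if denom == 0:
        raise ValueError(
            "kappa undefined: a rater's marginal is concentrated in one category"
        )
    return float(1.0 - (w * o).sum() / denom)


def mcnemar_test(
    correct_a: np.ndarray,
    correct_b: np.ndarray,
    force_chi2: bool = False,
) -> dict:
    """Paired accuracy comparison of two classifiers.

    ``b`` counts cases A got right and B wrong; ``c`` the reverse. The
    exact two-sided binomial test is used when b + c < 25 (unless
    ``force_chi2``), otherwise the continuity-corrected chi-square
    (|b - c| - 1)^2 / (b + c) on 1 df.
    """
    a = np.asarray(correct_a, dtype=bool)
    bvec = np.asarray(correct_b, dtype=bool)
    if a.shape != bvec.shape:
        raise ValueError("paired vectors must have equal length")
    b = int(np.sum(a & ~bvec))
    c = int(np.sum(~a & bvec))
    if b + c == 0:
        return {
            "statistic": 0.0, "p_value": 1.0, "b": b, "c": c,
            "method": "degenerate", "degenerate": True,
        }
    if b + c < 25 and not force_chi2:
        p = stats.binomtest(b, b + c, 0.5).pvalue
        return {
            "statistic": float(min(b, c)), "p_value": float(p),
            "b": b, "c": c, "method": "exact", "degenerate": False,
        }
    statistic = (abs(b - c) - 1) ** 2 / (b + c)
    p = float(stats.chi2.sf(statistic, df=1))
    return {
        "statistic": float(statistic), "p_value": p, "b": b, "c": c,
        "method": "chi2", "degenerate": False,
    }
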