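"""Divided space-time attention encoder for volumetric patches.

A volumetric patch (F sections of S x S RGB pixels) is cut into N = (S/P)^2
non-overlapping P x P tiles per section; each tile is flattened, linearly
embedded and given a learned position embedding indexed by (spatial
position, depth). A classification token is prepended. Every encoder block
applies *temporal* self-attention first — each patch token attends to the
cls token and to the tokens at the same spatial position across depth —
then *spatial* self-attention over the cls token and the tokens of the same
section, each stage with its own per-head q/k/v projections computed from
layer-normed inputs and scores scaled by 1/sqrt(D_h). Heads are
concatenated, projected and residual-added; a two-layer GELU MLP with
residual closes the block. The cls token is carried through the temporal
stage unchanged and attends jointly over every token in the spatial stage;
its final layer-normed state is the patch feature.

Token layout: index 0 is the cls token; token (p, t) with spatial index
p in [0, N) and depth t in [0, F) lives at 1 + t*N + p.

A deliberately naive quadruple-loop implementation of the same equations is
provided as an independent numerical oracle for the vectorized forward.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import (
    Adam,
    Parameter,
    Tensor,
    concat,
    layer_norm,
    softmax,
)

__all__ = [
    "EncoderConfig",
    "EncoderParams",
    "TokenGrid",
    "AttentionRecord",
    "tokenize_volume",
    "divided_attention_block",
    "encoder_forward",
    "encoder_forward_naive",
]


@dataclass(frozen=True)
class EncoderConfig:
    """Desk-scale defaults; the production preset is ``EncoderConfig.full_scale()``."""

    image_size: int = 64
    patch_size: int = 16  # P
    depth: int = 4  # F
    embed_dim: int = 64  # D
    n_heads: int = 4  # A
    n_blocks: int = 2  # L
    mlp_ratio: int = 4
    pos_init_std: float = 0.5  # strong positional init: see docs/methods.md

    def __post_init__(self) -> None:
        if self.image_size % self.patch_size:
            raise ValueError("image_size must be divisible by patch_size")
        if self.embed_dim % self.n_heads:
            raise ValueError("embed_dim must be divisible by n_heads")

    @property
    def n_spatial(self) -> int:  # N
        return (self.image_size // self.patch_size) ** 2

    @property
    def head_dim(self) -> int:  # D_h
        return self.embed_dim // self.n_heads

    @property
    def n_tokens(self) -> int:
        return self.n_spatial * self.depth + 1

    @classmethod
    def full_scale(cls) -> "EncoderConfig":
        return cls(image_size=256, patch_size=16, depth=4, embed_dim=768,
                   n_heads=12, n_blocks=12, pos_init_std=0.02)


def _linear_init(rng: np.random.Generator, fan_in: int, shape) -> np.ndarray:
    return rng.normal(0.0, 1.0 / np.sqrt(fan_in), size=shape)


@dataclass
class BlockParams:
    """Per-block weights: temporal stage, spatial stage, MLP."""

    ln_t_g: Parameter
    ln_t_b: Parameter
    wq_t: Parameter
    wk_t: Parameter
    wv_t: Parameter
    wo_t: Parameter
    ln_s_g: Parameter
    ln_s_b: Parameter
    wq_s: Parameter
    wk_s: Parameter
    wv_s: Parameter
    wo_s: Parameter
    ln_m_g: Parameter
    ln_m_b: Parameter
    w1: Parameter
    b1: Parameter
    w2: Parameter
    b2: Parameter

    @classmethod
    def init(cls, cfg: EncoderConfig, rng: np.random.Generator) -> "BlockParams":
        d = cfg.embed_dim
        hid = cfg.mlp_ratio * d

        def lin(n_in, n_out):
            return Parameter(_linear_init(rng, n_in, (n_in, n_out)))

        return cls(
            ln_t_g=Parameter(np.ones(d)), ln_t_b=Parameter(np.zeros(d)),
            wq_t=lin(d, d), wk_t=lin(d, d), wv_t=lin(d, d), wo_t=lin(d, d),
            ln_s_g=Parameter(np.ones(d)), ln_s_b=Parameter(np.zeros(d)),
            wq_s=lin(d, d), wk_s=lin(d, d), wv_s=lin(d, d), wo_s=lin(d, d),
            ln_m_g=Parameter(np.ones(d)), ln_m_b=Parameter(np.zeros(d)),
            w1=lin(d, hid), b1=Parameter(np.zeros(hid)),
            w2=lin(hid, d), b2=Parameter(np.zeros(d)),
        )

    def params(self) -> list[Parameter]:
        return [getattr(self, f.name) for f in
                self.__dataclass_fields__.values()]  # type: ignore[attr-defined]


@dataclass
class EncoderParams:
    config: EncoderConfig
    embed: Parameter  # (3P^2, D)
    pos: Parameter  # (N*F + 1, D)
    cls: Parameter  # (D,)
    blocks: list[BlockParams]
    ln_f_g: Parameter
    ln_f_b: Parameter

    @classmethod
    def init(cls, cfg: EncoderConfig, seed: int = 0) -> "EncoderParams":
        rng = np.random.default_rng(seed)
        d = cfg.embed_dim
        in_dim = 3 * cfg.patch_size**2
        return cls(
            config=cfg,
            embed=Parameter(_linear_init(rng, in_dim, (in_dim, d))),
            pos=Parameter(rng.normal(0, cfg.pos_init_std,
                                     size=(cfg.n_tokens, d))),
            cls=Parameter(rng.normal(0, 0.02, size=d)),
            blocks=[BlockParams.init(cfg, rng) for _ in range(cfg.n_blocks)],
            ln_f_g=Parameter(np.ones(d)),
            ln_f_b=Parameter(np.zeros(d)),
        )

    def params(self) -> list[Parameter]:
        out = [self.embed, self.pos, self.cls, self.ln_f_g, self.ln_f_b]
        for b in self.blocks:
            out.extend(b.params())
        return out

    def copy(self) -> "EncoderParams":
        import copy as _copy

        new = EncoderParams.init(self.config, seed=0)
        for pn, po in zip(new.params(), self.params()):
            pn.data = po.data.copy()
        return new


@dataclass
class TokenGrid:
    tokens: Tensor  # (1 + N*F, D); row 0 = cls
    n_spatial: int
    depth: int


@dataclass
class AttentionRecord:
    """Head-resolved attention weights of one block (detached numpy)."""

    alpha_time: np.ndarray  # (A, N, F, F+1); column 0 attends the cls token
    alpha_space: np.ndarray  # (A, F, N, N+1); column 0 attends the cls token
    alpha_cls: np.ndarray  # (A, 1 + N*F); cls-query row of the spatial stage
    n_spatial: int
    depth: int


def patchify(voxels: np.ndarray, patch_size: int) -> np.ndarray:
    """(F, S, S, 3) volume -> (F, N, 3P^2) flattened tiles, row-major."""
    f, h, w, c = voxels.shape
    p = patch_size
    if h % p or w % p:
        raise ValueError(f"spatial size {h}x{w} not divisible by P={p}")
    gh, gw = h // p, w // p
    tiles = voxels.reshape(f, gh, p, gw, p, c).transpose(0, 1, 3, 2, 4, 5)
    return tiles.reshape(f, gh * gw, p * p * c)


def tokenize_volume(voxels: np.ndarray, params: EncoderParams) -> TokenGrid:
    """Embed a (F, S, S, 3) volume: z0(p,t) = E x(p,t) + e_pos(p,t), cls prepended."""
    cfg = params.config
    voxels = np.asarray(voxels, dtype=float)
    if voxels.ndim != 4 or voxels.shape[-1] != 3:
        raise ValueError("expected an (F, S, S, 3) volume")
    if voxels.shape[0] != cfg.depth:
        raise ValueError(
            f"volume depth {voxels.shape[0]} != configured depth {cfg.depth}"
        )
    flat = patchify(voxels, cfg.patch_size)  # (F, N, 3P^2)
    x = Tensor(flat.reshape(-1, flat.shape[-1]))  # (F*N, 3P^2), t-major
    emb = x @ params.embed
    cls_row = params.cls.reshape(1, cfg.embed_dim)
    tokens = concat([cls_row, emb], axis=0) + params.pos
    return TokenGrid(tokens=tokens, n_spatial=cfg.n_spatial, depth=cfg.depth)


def _heads(x: Tensor, a: int, dh: int) -> Tensor:
    """(M, D) -> (A, M, Dh)."""
    m = x.shape[0]
    return x.reshape(m, a, dh).transpose(1, 0, 2)


def divided_attention_block(
    grid: TokenGrid, block: BlockParams, cfg: EncoderConfig
) -> tuple[TokenGrid, AttentionRecord]:
    """One temporal-then-spatial attention block with MLP."""
    n, f = grid.n_spatial, grid.depth
    a, dh, d = cfg.n_heads, cfg.head_dim, cfg.embed_dim
    scale = 1.0 / np.sqrt(dh)
    z = grid.tokens  # (1 + N*F, D)

    # ---- temporal stage ---------------------------------------------------
    y = layer_norm(z, block.ln_t_g, block.ln_t_b)
    q = _heads(y @ block.wq_t, a, dh)  # (A, M, Dh)
    k = _heads(y @ block.wk_t, a, dh)
    v = _heads(y @ block.wv_t, a, dh)

    def tgroup(x: Tensor) -> Tensor:
        # (A, M, Dh) patch rows -> (A, N, F, Dh): group by spatial position
        return x[:, 1:, :].reshape(a, f, n, dh).transpose(0, 2, 1, 3)

    qp, kp, vp = tgroup(q), tgroup(k), tgroup(v)
    k_cls = k[:, 0:1, :].reshape(a, 1, 1, dh)
    v_cls = v[:, 0:1, :].reshape(a, 1, 1, dh)
    scores = concat(
        [
            (qp * k_cls).sum(axis=-1, keepdims=True) * scale,  # (A,N,F,1)
            (qp @ kp.swapaxes(-1, -2)) * scale,  # (A,N,F,F)
        ],
        axis=-1,
    )
    alpha_t = softmax(scores, axis=-1)  # (A, N, F, F+1)
    out = alpha_t[..., 0:1] * v_cls + alpha_t[..., 1:] @ vp  # (A,N,F,Dh)
    out = out.transpose(2, 1, 0, 3).reshape(f * n, d)  # back to t-major rows
    update = out @ block.wo_t
    zero_cls = Tensor(np.zeros((1, d)))
    z_time = z + concat([zero_cls, update], axis=0)  # cls passes unchanged

    # ---- spatial stage ----------------------------------------------------
    y2 = layer_norm(z_time, block.ln_s_g, block.ln_s_b)
    q2 = _heads(y2 @ block.wq_s, a, dh)
    k2 = _heads(y2 @ block.wk_s, a, dh)
    v2 = _heads(y2 @ block.wv_s, a, dh)

    def sgroup(x: Tensor) -> Tensor:
        # (A, M, Dh) patch rows -> (A, F, N, Dh): group by section
        return x[:, 1:, :].reshape(a, f, n, dh)

    q2p, k2p, v2p = sgroup(q2), sgroup(k2), sgroup(v2)
    k2_cls = k2[:, 0:1, :].reshape(a, 1, 1, dh)
    v2_cls = v2[:, 0:1, :].reshape(a, 1, 1, dh)
    scores2 = concat(
        [
            (q2p * k2_cls).sum(axis=-1, keepdims=True) * scale,  # (A,F,N,1)
            (q2p @ k2p.swapaxes(-1, -2)) * scale,  # (A,F,N,N)
        ],
        axis=-1,
    )
    alpha_s = softmax(scores2, axis=-1)  # (A, F, N, N+1)
    out_p = alpha_s[..., 0:1] * v2_cls + alpha_s[..., 1:] @ v2p  # (A,F,N,Dh)
    out_p = out_p.transpose(1, 2, 0, 3).reshape(f * n, d)

    # cls query attends jointly over every token (itself included)
    q_cls = q2[:, 0:1, :]  # (A, 1, Dh)
    cls_scores = (q_cls @ k2.swapaxes(-1, -2)) * scale  # (A, 1, M)
    alpha_c = softmax(cls_scores, axis=-1)
    out_c = (alpha_c @ v2).transpose(1, 0, 2).reshape(1, d)

    update2 = concat([out_c, out_p], axis=0) @ block.wo_s
    z_space = z_time + update2

    # ---- MLP --------------------------------------------------------------
    h = layer_norm(z_space, block.ln_m_g, block.ln_m_b)
    h = (h @ block.w1 + block.b1).gelu() @ block.w2 + block.b2
    z_out = z_space + h

    record = AttentionRecord(
        alpha_time=alpha_t.data.copy(),
        alpha_space=alpha_s.data.copy(),
        alpha_cls=alpha_c.data.reshape(a, -1).copy(),
        n_spatial=n,
        depth=f,
    )
    return TokenGrid(tokens=z_out, n_spatial=n, depth=f), record


def encoder_forward(
    voxels: np.ndarray, params: EncoderParams
) -> tuple[Tensor, list[AttentionRecord]]:
    """Full forward pass: returns the final cls feature and all attention
    records. The feature is a Tensor so the same path serves training; call
    ``.numpy()`` for evaluation."""
    cfg = params.config
    grid = tokenize_volume(voxels, params)
    records: list[AttentionRecord] = []
    for block in params.blocks:
        grid, rec = divided_attention_block(grid, block, cfg)
        records.append(rec)
    final = layer_norm(grid.tokens, params.ln_f_g, params.ln_f_b)
    return final[0], records


def encode(voxels: np.ndarray, params: EncoderParams) -> np.ndarray:
    """Evaluation-mode feature extraction (plain numpy output)."""
    feat, _ = encoder_forward(voxels, params)
    return feat.numpy().copy()


# ---------------------------------------------------------------------------
# naive oracle


def _ln_np(x: np.ndarray, g: np.ndarray, b: np.ndarray, eps: float = 1e-6
           ) -> np.ndarray:
    mu = x.mean()
    var = ((x - mu) ** 2).mean()
    return (x - mu) / np.sqrt(var + eps) * g + b


def _softmax_np(s: np.ndarray) -> np.ndarray:
    e = np.exp(s - s.max())
    return e / e.sum()


def encoder_forward_naive(
    voxels: np.ndarray, params: EncoderParams
) -> np.ndarray:
    """Token-by-token, head-by-head reference implementation.

    Every query token's attention is evaluated with explicit python loops —
    slow on purpose, structured directly after the per-token equations — and
    used as the independent oracle for the vectorized forward.
    """
    cfg = params.config
    n, f, a, dh, d = (cfg.n_spatial, cfg.depth, cfg.n_heads, cfg.head_dim,
                      cfg.embed_dim)
    flat = patchify(np.asarray(voxels, float), cfg.patch_size)
    m = n * f + 1
    z = np.zeros((m, d))
    z[0] = params.cls.data
    for t in range(f):
        for p in range(n):
            z[1 + t * n + p] = params.embed.data.T @ flat[t, p]
    z = z + params.pos.data

    def idx(p: int, t: int) -> int:
        return 1 + t * n + p

    for block in params.blocks:
        # temporal
        y = np.stack([_ln_np(z[i], block.ln_t_g.data, block.ln_t_b.data)
                      for i in range(m)])
        z_time = z.copy()
        for t in range(f):
            for p in range(n):
                row = np.zeros(d)
                for h in range(a):
                    sl = slice(h * dh, (h + 1) * dh)
                    wq = block.wq_t.data[:, sl]
                    wk = block.wk_t.data[:, sl]
                    wv = block.wv_t.data[:, sl]
                    qv = y[idx(p, t)] @ wq
                    keys = [y[0] @ wk] + [y[idx(p, tp)] @ wk for tp in range(f)]
                    vals = [y[0] @ wv] + [y[idx(p, tp)] @ wv for tp in range(f)]
                    alpha = _softmax_np(
                        np.array([qv @ kk for kk in keys]) / np.sqrt(dh)
                    )
                    row[sl] = sum(w * vv for w, vv in zip(alpha, vals))
                z_time[idx(p, t)] = z[idx(p, t)] + block.wo_t.data.T @ row
        # spatial
        y2 = np.stack([_ln_np(z_time[i], block.ln_s_g.data, block.ln_s_b.data)
                       for i in range(m)])
        z_space = z_time.copy()
        for t in range(f):
            for p in range(n):
                row = np.zeros(d)
                for h in range(a):
                    sl = slice(h * dh, (h + 1) * dh)
                    wq = block.wq_s.data[:, sl]
                    wk = block.wk_s.data[:, sl]
                    wv = block.wv_s.data[:, sl]
                    qv = y2[idx(p, t)] @ wq
                    keys = [y2[0] @ wk] + [y2[idx(pp, t)] @ wk
                                           for pp in range(n)]
                    vals = [y2[0] @ wv] + [y2[idx(pp, t)] @ wv
                                           for pp in range(n)]
                    alpha = _softmax_np(
                        np.array([qv @ kk for kk in keys]) / np.sqrt(dh)
                    )
                    row[sl] = sum(w * vv for w, vv in zip(alpha, vals))
                z_space[idx(p, t)] = z_time[idx(p, t)] + block.wo_s.data.T @ row
        row = np.zeros(d)
        for h in range(a):
            sl = slice(h * dh, (h + 1) * dh)
            qv = y2[0] @ block.wq_s.data[:, sl]
            keys = [y2[i] @ block.wk_s.data[:, sl] for i in range(m)]
            vals = [y2[i] @ block.wv_s.data[:, sl] for i in range(m)]
            alpha = _softmax_np(np.array([qv @ kk for kk in keys]) / np.sqrt(dh))
            row[sl] = sum(w * vv for w, vv in zip(alpha, vals))
        z_space[0] = z_time[0] + block.wo_s.data.T @ row
        # mlp
        z_new = z_space.copy()
        for i in range(m):
            hcur = _ln_np(z_space[i], block.ln_m_g.data, block.ln_m_b.data)
            hcur = hcur @ block.w1.data + block.b1.data
            c = np.sqrt(2.0 / np.pi)
            hcur = 0.5 * hcur * (1 + np.tanh(c * (hcur + 0.044715 * hcur**3)))
            z_new[i] = z_space[i] + hcur @ block.w2.data + block.b2.data
        z = z_new

    return _ln_np(z[0], params.ln_f_g.data, params.ln_f_b.data)
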