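"""Self-supervised pretraining of the volumetric encoder (DINO-style).

A student network is trained to match the output distribution of a momentum
("teacher") copy of itself across augmented views of the same volumetric
patch. Global views (standard-resolution spatial crops) feed the teacher;
the student sees global and local (low-resolution) views, so the contrastive
objective enforces local-to-global correspondence. Crops are spatial only:
every view keeps all F depth sections, because depth is the volumetric
signal the encoder exists to capture; photometric jitter is drawn once per
view and applied to all sections consistently.

Teacher updates are exact parameter-wise exponential moving averages; the
teacher output distribution is centered (running mean, to avoid collapse to
a constant) and sharpened with a lower temperature than the student's.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize

from .autodiff import Adam, Parameter, Tensor, log_softmax, softmax
from .encoder import EncoderConfig, EncoderParams, encoder_forward

__all__ = ["DinoConfig", "DinoState", "make_dino_views", "dino_step", "pretrain"]


@dataclass(frozen=True)
class DinoConfig:
    """Desk-scale DINO hyperparameters (all exposed; none are canonical)."""

    n_global: int = 2
    n_local: int = 4
    global_scale: tuple[float, float] = (0.5, 1.0)
    local_scale: tuple[float, float] = (0.15, 0.4)
    head_hidden: int = 128
    head_bottleneck: int = 32
    n_prototypes: int = 256
    teacher_temp: float = 0.04
    student_temp: float = 0.1
    momentum: float = 0.996
    center_momentum: float = 0.9
    lr: float = 2e-3
    jitter_brightness: float = 0.2
    jitter_contrast: float = 0.2


@dataclass
class ProjectionHead:
    """3-layer MLP -> L2 normalize -> weight-normalized prototype layer."""

    w1: Parameter
    b1: Parameter
    w2: Parameter
    b2: Parameter
    w3: Parameter
    b3: Parameter
    prototypes: Parameter  # (bottleneck, K); columns normalized at use

    @classmethod
    def init(cls, in_dim: int, cfg: DinoConfig, rng: np.random.Generator
             ) -> "ProjectionHead":
        h, bt, k = cfg.head_hidden, cfg.head_bottleneck, cfg.n_prototypes

        def lin(n_in, n_out):
            return Parameter(rng.normal(0, 1 / np.sqrt(n_in), (n_in, n_out)))

        return cls(
            w1=lin(in_dim, h), b1=Parameter(np.zeros(h)),
            w2=lin(h, h), b2=Parameter(np.zeros(h)),
            w3=lin(h, bt), b3=Parameter(np.zeros(bt)),
            prototypes=lin(bt, k),
        )

    def params(self) -> list[Parameter]:
        return [self.w1, self.b1, self.w2, self.b2, self.w3, self.b3,
                self.prototypes]

    def forward(self, x: Tensor) -> Tensor:
        h = (x.reshape(1, -1) @ self.w1 + self.b1).gelu()
        h = (h @ self.w2 + self.b2).gelu()
        h = h @ self.w3 + self.b3
        h = h * (((h * h).sum(axis=-1, keepdims=True) + 1e-12) ** -0.5)
        wn = self.prototypes * (
            ((self.prototypes * self.prototypes).sum(axis=0, keepdims=True)
             + 1e-12) ** -0.5
        )
        return (h @ wn).reshape(-1)


@dataclass
class DinoState:
    """Student/teacher parameter sets plus the distillation bookkeeping."""

    student: EncoderParams
    student_head: ProjectionHead
    teacher: EncoderParams
    teacher_head: ProjectionHead
    center: np.ndarray
    config: DinoConfig
    optimizer: Adam
    step_count: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.config.momentum <= 1.0:
            raise ValueError("teacher momentum must lie in [0, 1]")

    @classmethod
    def init(cls, enc_cfg: EncoderConfig, dino_cfg: DinoConfig | None = None,
             seed: int = 0) -> "DinoState":
        dino_cfg = dino_cfg or DinoConfig()
        rng = np.random.default_rng(seed)
        student = EncoderParams.init(enc_cfg, seed=seed)
        student_head = ProjectionHead.init(enc_cfg.embed_dim, dino_cfg, rng)
        teacher = student.copy()
        teacher_head = ProjectionHead.init(enc_cfg.embed_dim, dino_cfg, rng)
        for pt, ps in zip(teacher_head.params(), student_head.params()):
            pt.data = ps.data.copy()
        params = student.params() + student_head.params()
        return cls(
            student=student,
            student_head=student_head,
            teacher=teacher,
            teacher_head=teacher_head,
            center=np.zeros(dino_cfg.n_prototypes),
            config=dino_cfg,
            optimizer=Adam(params, lr=dino_cfg.lr),
        )

    def student_params(self) -> list[Parameter]:
        return self.student.params() + self.student_head.params()

    def teacher_params(self) -> list[Parameter]:
        return self.teacher.params() + self.teacher_head.params()


def _jitter(view: np.ndarray, rng: np.random.Generator, cfg: DinoConfig
            ) -> np.ndarray:
    """Photometric jitter drawn once, applied to every depth section."""
    gain = 1.0 + rng.uniform(-cfg.jitter_contrast, cfg.jitter_contrast)
    bias = rng.uniform(-cfg.jitter_brightness, cfg.jitter_brightness)
    out = (view - 0.5) * gain + 0.5 + bias
    return np.clip(out, 0.0, 1.0)


def make_dino_views(
    patch_voxels: np.ndarray,
    n_global: int = 2,
    n_local: int = 4,
    seed: int = 0,
    config: DinoConfig | None = None,
    out_size: int | None = None,
) -> list[np.ndarray]:
    """Augmented views of one volumetric patch; globals first.

    Each view is a random square spatial crop (scale range depending on
    global/local), resized to ``out_size`` (default: the input side), with
    consistent-over-depth photometric jitter and a possible horizontal flip.
    Depth is never cropped.
    """
    cfg = config or DinoConfig()
    vox = np.asarray(patch_voxels, dtype=float)
    if vox.max() > 1.5:
        vox = vox / 255.0
    f, s = vox.shape[0], vox.shape[1]
    out_size = out_size or s
    rng = np.random.default_rng(seed)
    views = []
    for i in range(n_global + n_local):
        lo, hi = cfg.global_scale if i < n_global else cfg.local_scale
        side = int(round(np.sqrt(rng.uniform(lo, hi)) * s))
        side = max(4, side)
        if side > s:
            raise ValueError(f"crop side {side} exceeds patch side {s}")
        r0 = rng.integers(0, s - side + 1)
        c0 = rng.integers(0, s - side + 1)
        crop = vox[:, r0:r0 + side, c0:c0 + side, :]
        view = resize(crop, (f, out_size, out_size, 3), order=1,
                      anti_aliasing=side > out_size, preserve_range=True)
        if rng.random() < 0.5:
            view = view[:, :, ::-1, :]
        views.append(_jitter(np.ascontiguousarray(view), rng, cfg))
    return views


def _forward_head(voxels: np.ndarray, enc: EncoderParams,
                  head: ProjectionHead) -> Tensor:
    feat, _ = encoder_forward(voxels, enc)
    return head.forward(feat)


def dino_step(
    state: DinoState, batch_views: list[list[np.ndarray]]
) -> tuple[DinoState, float]:
    """One distillation step on a batch of per-patch view lists.

    Teacher processes the global views; the student processes all views;
    the loss is the mean cross-entropy between the centered, sharpened
    teacher distribution and the student distribution over all
    (teacher view, different student view) pairs. The student moves by one
    Adam step, the teacher by an exact parameter-wise EMA, and the center by
    a running mean of teacher outputs.
    """
    cfg = state.config
    m = cfg.momentum
    n_g = cfg.n_global
    if any(len(v) < 1 for v in batch_views):
        raise ValueError("every patch needs at least one global view")

    if state.step_count == 0:
        # initialize the center on the first batch so targets are stable
        # from step one instead of drifting through the running-mean warmup
        first = [
            _forward_head(v, state.teacher, state.teacher_head).numpy()
            for views in batch_views
            for v in views[:n_g]
        ]
        state.center = np.mean(first, axis=0)

    total: Tensor | None = None
    n_terms = 0
    teacher_logits_all = []
    center_t = Tensor(state.center)
    for views in batch_views:
        t_logits = []
        for v in views[:n_g]:
            out = _forward_head(v, state.teacher, state.teacher_head)
            t_logits.append(out.numpy().copy())
            teacher_logits_all.append(t_logits[-1])
        s_out = [
            _forward_head(v, state.student, state.student_head)
            for v in views
        ]
        for ti, tl in enumerate(t_logits):
            t_prob = _softmax_np((tl - state.center) / cfg.teacher_temp)
            for sj, so in enumerate(s_out):
                if sj == ti:
                    continue
                logp = log_softmax(so * (1.0 / cfg.student_temp))
                term = -(Tensor(t_prob) * logp).sum()
                total = term if total is None else total + term
                n_terms += 1
    loss = total * (1.0 / n_terms)
    state.optimizer.zero_grad()
    loss.backward()
    state.optimizer.step()

    for pt, ps in zip(state.teacher_params(), state.student_params()):
        pt.data = m * pt.data + (1.0 - m) * ps.data
    batch_mean = np.mean(np.stack(teacher_logits_all), axis=0)
    state.center = (
        cfg.center_momentum * state.center
        + (1.0 - cfg.center_momentum) * batch_mean
    )
    state.step_count += 1
    return state, float(loss.item())


def _softmax_np(x: np.ndarray) -> np.ndarray:
    e = np.exp(x - x.max())
    return e / e.sum()


def pretrain(
    patches: list[np.ndarray],
    enc_cfg: EncoderConfig,
    dino_cfg: DinoConfig | None = None,
    n_steps: int = 100,
    batch_size: int = 4,
    seed: int = 0,
) -> tuple[DinoState, list[float]]:
    """Run the distillation loop over a pool of volumetric patches.

    Returns the final state (the *teacher* encoder is the recommended frozen
    feature extractor) and the per-step loss history.
    """
    dino_cfg = dino_cfg or DinoConfig()
    state = DinoState.init(enc_cfg, dino_cfg, seed=seed)
    rng = np.random.default_rng(seed + 1)
    losses = []
    for step in range(n_steps):
        idx = rng.choice(len(patches), size=min(batch_size, len(patches)),
                         replace=False)
        batch = [
            make_dino_views(
                patches[i], dino_cfg.n_global, dino_cfg.n_local,
                seed=int(rng.integers(2**31 - 1)), config=dino_cfg,
                out_size=enc_cfg.image_size,
            )
            for i in idx
        ]
        state, loss = dino_step(state, batch)
        losses.append(loss)
    return state, losses
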