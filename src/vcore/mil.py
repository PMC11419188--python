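"""Attention-based multiple-instance learning over frozen patch features.

A core is a "bag" of volumetric-patch feature vectors with a single
core-level label (Gleason Grade Group, or the binary clinically-significant
relabeling GGG >= 2). A gated attention module (tanh branch gated by a
sigmoid branch) scores each instance; softmax over instances gives
nonnegative weights summing to one; the attention-weighted feature mean is
classified by a linear layer. Training uses class-frequency-weighted
cross-entropy with Adam and early stopping on validation macro AUC.

Instance aggregation is permutation invariant; the inference path sorts
instances into a canonical order first so the invariance is bitwise exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .autodiff import Adam, Parameter, Tensor, log_softmax, softmax
from .encoder import EncoderParams, encode
from .volumize import VolumetricPatch, fit_depth

__all__ = [
    "Bag",
    "BagPrediction",
    "MILParams",
    "MILTrainConfig",
    "MILResults",
    "encode_bag",
    "encode_bag_2d",
    "abmil_forward",
    "train_mil",
    "binarize_cs",
    "GGG_CLASS_NAMES",
]

#: default label map: indices into {BN, GGG1, GGG2, GGG3, GGG4/5}
GGG_CLASS_NAMES = ("BN", "GGG1", "GGG2", "GGG3", "GGG4/5")
#: classes counted as clinically significant (GGG >= 2)
CS_CLASSES = (2, 3, 4)


@dataclass
class Bag:
    instance_features: np.ndarray  # (n, D)
    instance_origins: list  # patch coordinates or (origin, slice) keys
    core_id: str = ""
    label: int | None = None

    def __post_init__(self) -> None:
        if len(self.instance_features) < 1:
            raise ValueError(f"empty bag for core {self.core_id!r}")


@dataclass
class BagPrediction:
    attention_weights: np.ndarray  # (n,), nonnegative, sums to 1
    class_probabilities: np.ndarray  # (K,), sums to 1
    predicted_label: int

    def __post_init__(self) -> None:
        assert self.predicted_label == int(np.argmax(self.class_probabilities))


@dataclass
class MILParams:
    v: Parameter  # (D, H) tanh branch
    u: Parameter  # (D, H) sigmoid gate
    w: Parameter  # (H, 1) attention score
    wc: Parameter  # (D, K) classifier
    bc: Parameter  # (K,)

    @classmethod
    def init(cls, n_features: int, n_classes: int, hidden: int = 128,
             seed: int = 0) -> "MILParams":
        rng = np.random.default_rng(seed)

        def lin(n_in, n_out):
            return Parameter(rng.normal(0, 1 / np.sqrt(n_in), (n_in, n_out)))

        return cls(
            v=lin(n_features, hidden),
            u=lin(n_features, hidden),
            w=lin(hidden, 1),
            wc=lin(n_features, n_classes),
            bc=Parameter(np.zeros(n_classes)),
        )

    def params(self) -> list[Parameter]:
        return [self.v, self.u, self.w, self.wc, self.bc]

    def copy(self) -> "MILParams":
        new = MILParams(*[Parameter(p.data.copy()) for p in self.params()])
        return new

    @property
    def n_classes(self) -> int:
        return self.wc.shape[1]


def _forward_tensor(features: np.ndarray, model: MILParams
                    ) -> tuple[Tensor, Tensor]:
    """Differentiable forward: returns (logits (1, K), attention (n, 1))."""
    x = Tensor(features)
    gate = (x @ model.v).tanh() * (x @ model.u).sigmoid()
    scores = gate @ model.w  # (n, 1)
    attn = softmax(scores, axis=0)
    pooled = attn.transpose(1, 0) @ x  # (1, D)
    logits = pooled @ model.wc + model.bc
    return logits, attn


def abmil_forward(bag: Bag, model: MILParams) -> BagPrediction:
    """Gated-attention bag classification (inference path).

    Instances are internally sorted into a canonical lexicographic order so
    the output is bitwise identical under any instance permutation.
    """
    feats = np.asarray(bag.instance_features, dtype=float)
    if feats.shape[1] != model.v.shape[0]:
        raise ValueError(
            f"feature dim {feats.shape[1]} != model dim {model.v.shape[0]}"
        )
    order = np.lexsort(feats.T[::-1])  # canonical instance order
    logits, attn = _forward_tensor(feats[order], model)
    probs = softmax(logits, axis=-1).numpy().ravel()
    weights = np.empty(len(feats))
    weights[order] = attn.numpy().ravel()
    return BagPrediction(
        attention_weights=weights,
        class_probabilities=probs,
        predicted_label=int(np.argmax(probs)),
    )


def encode_bag(
    patches: list[VolumetricPatch], encoder: EncoderParams,
    core_id: str = "", label: int | None = None,
) -> Bag:
    """One feature row per volumetric patch from the frozen encoder."""
    if not patches:
        raise ValueError("empty bag: core has no retained patches")
    depth = encoder.config.depth
    feats = []
    for p in patches:
        vox = fit_depth(p.voxels, depth).astype(float)
        if vox.max() > 1.5:
            vox = vox / 255.0
        feats.append(encode(vox, encoder))
    return Bag(
        instance_features=np.stack(feats),
        instance_origins=[p.origin for p in patches],
        core_id=core_id or (patches[0].core_id if patches else ""),
        label=label if label is not None else patches[0].label,
    )


def encode_bag_2d(
    patches: list[VolumetricPatch], encoder_2d: EncoderParams,
    core_id: str = "", label: int | None = None,
) -> Bag:
    """Per-slice baseline: every (patch, section) pair becomes an instance.

    ``encoder_2d`` must be configured with depth 1; this is the
    same-capacity 2D comparison arm for the volumetric encoder.
    """
    if encoder_2d.config.depth != 1:
        raise ValueError("encode_bag_2d requires a depth-1 encoder")
    if not patches:
        raise ValueError("empty bag: core has no retained patches")
    feats, origins = [], []
    for p in patches:
        vox = p.voxels.astype(float)
        if vox.max() > 1.5:
            vox = vox / 255.0
        for t in range(vox.shape[0]):
            feats.append(encode(vox[t:t + 1], encoder_2d))
            origins.append((p.origin, t))
    return Bag(
        instance_features=np.stack(feats),
        instance_origins=origins,
        core_id=core_id or patches[0].core_id,
        label=label if label is not None else patches[0].label,
    )


@dataclass(frozen=True)
class MILTrainConfig:
    lr: float = 1e-4
    weight_decay: float = 1e-5
    patience: int = 10
    max_epochs: int = 100
    hidden: int = 128


@dataclass
class MILResults:
    """Fitted MIL aggregator with its training history."""

    model: MILParams
    history: pd.DataFrame
    best_epoch: int

    def predict(self, bags: list[Bag]) -> list[BagPrediction]:
        return [abmil_forward(b, self.model) for b in bags]

    def predict_proba(self, bags: list[Bag]) -> np.ndarray:
        return np.stack([p.class_probabilities for p in self.predict(bags)])


def _macro_auc(y_true: np.ndarray, probs: np.ndarray) -> float:
    from .evaluate import classification_metrics

    return classification_metrics(y_true, probs)["macro_auc"]


def train_mil(
    train_bags: list[Bag],
    val_bags: list[Bag] | None = None,
    n_classes: int | None = None,
    config: MILTrainConfig | None = None,
    seed: int = 0,
) -> MILResults:
    """Fit the gated-attention aggregator on labeled bags.

    Cross-entropy is weighted by inverse class frequency; when validation
    bags are given, training stops after ``patience`` epochs without a new
    best validation macro AUC and the best checkpoint is returned.
    """
    cfg = config or MILTrainConfig()
    labels = np.array([b.label for b in train_bags])
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("training bags must contain at least 2 classes")
    k = n_classes or int(labels.max()) + 1
    d = train_bags[0].instance_features.shape[1]
    model = MILParams.init(d, k, hidden=cfg.hidden, seed=seed)
    opt = Adam(model.params(), lr=cfg.lr, weight_decay=cfg.weight_decay)

    counts = np.bincount(labels, minlength=k).astype(float)
    class_w = np.where(counts > 0, counts.sum() / np.maximum(counts, 1), 0.0)
    class_w = class_w / class_w[counts > 0].mean()

    rng = np.random.default_rng(seed)
    best_auc, best_epoch, best_model = -np.inf, 0, model.copy()
    rows = []
    wait = 0
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(len(train_bags))
        total_loss, n_correct = 0.0, 0
        for i in order:
            bag = train_bags[i]
            logits, _ = _forward_tensor(
                np.asarray(bag.instance_features, float), model
            )
            logp = log_softmax(logits, axis=-1)
            loss = -logp[0, bag.label] * class_w[bag.label]
            opt.zero_grad()
            loss.backward()
            opt.step()
            total_loss += float(loss.item())
            n_correct += int(np.argmax(logits.numpy()) == bag.label)
        row = {
            "epoch": epoch,
            "train_loss": total_loss / len(train_bags),
            "train_acc": n_correct / len(train_bags),
        }
        if val_bags:
            y_val = np.array([b.label for b in val_bags])
            probs = np.stack(
                [abmil_forward(b, model).class_probabilities for b in val_bags]
            )
            row["val_macro_auc"] = _macro_auc(y_val, probs)
            if row["val_macro_auc"] > best_auc:
                best_auc = row["val_macro_auc"]
                best_epoch = epoch
                best_model = model.copy()
                wait = 0
            else:
                wait += 1
        rows.append(row)
        if val_bags and wait >= cfg.patience:
            break
    if not val_bags:
        best_model, best_epoch = model, rows[-1]["epoch"]
    return MILResults(
        model=best_model, history=pd.DataFrame(rows), best_epoch=best_epoch
    )


def binarize_cs(labels: np.ndarray, cs_classes=CS_CLASSES) -> np.ndarray:
    """Relabel GGG class indices as clinically significant (1) vs not (0)."""
    return np.isin(np.asarray(labels), cs_classes).astype(int)
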