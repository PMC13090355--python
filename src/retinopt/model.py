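"""Dual-stream fundus classifier with lightweight channel-wise attention.

Two convolutional streams consume the same 224x224x3 input: a *structural*
stream tuned to large-scale optic-disc/cup geometry and a *texture* stream
for finer local patterns.  Each stream is globally average-pooled to a
feature vector F, gated by channel attention

    A = sigmoid(W F + b),      F' = A ⊙ F,

and the two modulated vectors are concatenated (structural first) before a
dropout-regularized dense head with a single sigmoid output for the binary
glaucoma decision.  The transfer-learning ratio controls what percentage of
the topmost stream layers stay trainable; at 0 only attention and head
train, which also lets stream features be precomputed once per fit.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np

from . import nn
from .evaluation import binary_cross_entropy


# ---------------------------------------------------------------------------
# Pure attention/fusion algebra (also used standalone)
# ---------------------------------------------------------------------------

def channel_attention(f: np.ndarray, weight: np.ndarray, bias: np.ndarray) -> np.ndarray:
    """Attention weights A = sigmoid(W·F + b); every component in (0, 1)."""
    f = np.asarray(f, dtype=float)
    weight = np.asarray(weight, dtype=float)
    bias = np.asarray(bias, dtype=float)
    if weight.shape != (f.shape[-1], f.shape[-1]) or bias.shape[-1] != f.shape[-1]:
        raise ValueError("attention weight/bias dimensions do not match the feature")
    return nn.sigmoid(f @ weight.T + bias)


def apply_attention(f: np.ndarray, a: np.ndarray) -> np.ndarray:
    """Modulated features F' = A ⊙ F."""
    f = np.asarray(f, dtype=float)
    a = np.asarray(a, dtype=float)
    if f.shape != a.shape:
        raise ValueError("feature/attention length mismatch")
    return a * f


def fuse_features(fs: np.ndarray, ft: np.ndarray) -> np.ndarray:
    """Concatenation fusion, structural stream first."""
    return np.concatenate([np.asarray(fs, dtype=float), np.asarray(ft, dtype=float)], axis=-1)


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------

@dataclass
class AttentionLayerSpec:
    weight: np.ndarray
    bias: np.ndarray


@dataclass
class ModelHyperparams:
    optimizer_name: str = "Adam"
    learning_rate: float = 0.001
    batch_size: int = 32
    tl_learn_ratio: float = 0.0  # percent of top stream layers left trainable

    @classmethod
    def from_values(cls, values: dict[str, Any]) -> "ModelHyperparams":
        return cls(
            optimizer_name=str(values.get("optimizer", "Adam")),
            learning_rate=float(values.get("learning_rate", 0.001)),
            batch_size=int(values.get("batch_size", 32)),
            tl_learn_ratio=float(values.get("tl_learn_ratio", 0.0)),
        )


# backbone id -> (channel widths of the three conv blocks, output dim)
_BACKBONES = {
    "tiny-structural": ((8, 16, 24), 24),
    "tiny-texture": ((8, 16, 32), 32),
}


@dataclass
class DualStreamSpec:
    structural_backbone: str = "tiny-structural"
    texture_backbone: str = "tiny-texture"
    head_units: int = 256
    dropout: float = 0.5
    input_size: tuple[int, int, int] = (224, 224, 3)
    pool_factor: int = 8  # fixed input downsample before the conv blocks


class _AttentionGate(nn.Layer):
    """Trainable channel gate: y = sigmoid(x W + b) ⊙ x."""

    def __init__(self, dim: int, rng: np.random.Generator):
        super().__init__()
        self.params = {
            "W": rng.normal(0.0, 1.0 / np.sqrt(dim), size=(dim, dim)),
            "b": np.zeros(dim),
        }

    def forward(self, x, train=False):
        self._x = x
        self._a = nn.sigmoid(x @ self.params["W"] + self.params["b"])
        return self._a * x

    def backward(self, grad):
        da = grad * self._x
        dz = da * self._a * (1.0 - self._a)
        self.grads["W"] = self._x.T @ dz
        self.grads["b"] = dz.sum(axis=0)
        return grad * self._a + dz @ self.params["W"].T


def _build_stream(backbone: str, pool_factor: int, rng: np.random.Generator) -> tuple[list[nn.Layer], int]:
    if backbone not in _BACKBONES:
        raise ValueError(f"unknown backbone {backbone!r}; options: {sorted(_BACKBONES)}")
    widths, dim = _BACKBONES[backbone]
    layers: list[nn.Layer] = [nn.AvgPool(pool_factor)]
    c_in = 3
    for c_out in widths[:-1]:
        layers += [nn.Conv3x3(c_in, c_out, rng), nn.ReLU(), nn.MaxPool2()]
        c_in = c_out
    layers += [nn.Conv3x3(c_in, widths[-1], rng), nn.ReLU(), nn.GlobalAvgPool()]
    return layers, dim


class DualStreamModel:
    """Assembled dual-stream network; see the module docstring."""

    def __init__(self, spec: DualStreamSpec, hp: ModelHyperparams, seed: int = 0):
        self.spec = spec
        self.hp = hp
        rng = np.random.default_rng(seed)
        self.stream_s, self.d_s = _build_stream(spec.structural_backbone, spec.pool_factor, rng)
        self.stream_t, self.d_t = _build_stream(spec.texture_backbone, spec.pool_factor, rng)
        self.attn_s = _AttentionGate(self.d_s, rng)
        self.attn_t = _AttentionGate(self.d_t, rng)
        # feature standardization (set from the training set at fit time)
        self.feat_mean: tuple[np.ndarray, np.ndarray] | None = None
        self.feat_std: tuple[np.ndarray, np.ndarray] | None = None
        fused = self.d_s + self.d_t
        self.head: list[nn.Layer] = [
            nn.Dense(fused, spec.head_units, rng),
            nn.ReLU(),
            nn.Dropout(spec.dropout, rng),
            nn.Dense(spec.head_units, 1, rng),
        ]
        self._apply_freezing()

    # -- freezing ----------------------------------------------------------
    def _conv_layers(self, stream: list[nn.Layer]) -> list[nn.Layer]:
        return [l for l in stream if isinstance(l, nn.Conv3x3)]

    def _apply_freezing(self) -> None:
        """Unfreeze the top tl_learn_ratio percent of each stream's conv layers."""
        ratio = self.hp.tl_learn_ratio / 100.0
        for stream in (self.stream_s, self.stream_t):
            convs = self._conv_layers(stream)
            n_unfrozen = int(round(ratio * len(convs)))
            for i, layer in enumerate(convs):
                layer.trainable = i >= len(convs) - n_unfrozen

    @property
    def backbone_fully_frozen(self) -> bool:
        return not any(
            l.trainable for s in (self.stream_s, self.stream_t) for l in self._conv_layers(s)
        )

    def trainable_parameter_count(self, backbone_only: bool = False) -> int:
        layers: list[nn.Layer] = []
        for s in (self.stream_s, self.stream_t):
            layers += self._conv_layers(s)
        if not backbone_only:
            layers += [self.attn_s, self.attn_t] + list(self.head)
        return sum(p.size for l in layers if l.trainable for p in l.params.values())

    # -- forward / backward ------------------------------------------------
    @staticmethod
    def _run(layers: Sequence[nn.Layer], x: np.ndarray, train: bool) -> np.ndarray:
        for layer in layers:
            x = layer.forward(x, train)
        return x

    def extract_features(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Pooled stream features (no attention) for a batch of images."""
        x = self._prep(x)
        return self._run(self.stream_s, x, False), self._run(self.stream_t, x, False)

    def _prep(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.ndim == 3:
            x = x[None]
        if x.max() > 1.5:  # stored as 8-bit intensities
            x = x / 255.0
        return x

    def set_feature_norm(self, fs: np.ndarray, ft: np.ndarray) -> None:
        """Freeze per-channel standardization statistics from a feature batch."""
        self.feat_mean = (fs.mean(axis=0), ft.mean(axis=0))
        self.feat_std = (fs.std(axis=0) + 1e-6, ft.std(axis=0) + 1e-6)

    def _normalize(self, fs: np.ndarray, ft: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        if self.feat_mean is None:
            return fs, ft
        return (
            (fs - self.feat_mean[0]) / self.feat_std[0],
            (ft - self.feat_mean[1]) / self.feat_std[1],
        )

    def _head_forward(self, fs: np.ndarray, ft: np.ndarray, train: bool) -> np.ndarray:
        fs, ft = self._normalize(fs, ft)
        gs = self.attn_s.forward(fs, train)
        gt = self.attn_t.forward(ft, train)
        fused = np.concatenate([gs, gt], axis=1)
        logits = self._run(self.head, fused, train)
        return nn.sigmoid(logits[:, 0])

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        fs, ft = self.extract_features(x)
        return self._head_forward(fs, ft, train=False)

    def _forward_train(self, x: np.ndarray) -> np.ndarray:
        x = self._prep(x)
        self._fs_in = self._run(self.stream_s, x, True)
        self._ft_in = self._run(self.stream_t, x, True)
        return self._head_forward(self._fs_in, self._ft_in, True)

    def _backward(self, probs: np.ndarray, y: np.ndarray, through_backbone: bool) -> None:
        dlogit = ((probs - y) / len(y))[:, None]
        grad = dlogit
        for layer in reversed(self.head):
            grad = layer.backward(grad)
        gs, gt = grad[:, : self.d_s], grad[:, self.d_s :]
        gfs = self.attn_s.backward(gs)
        gft = self.attn_t.backward(gt)
        if self.feat_std is not None:
            gfs = gfs / self.feat_std[0]
            gft = gft / self.feat_std[1]
        if through_backbone:
            for stream, g in ((self.stream_s, gfs), (self.stream_t, gft)):
                # stop once the remaining layers are all frozen
                lowest = min(
                    (i for i, l in enumerate(stream) if l.trainable and l.params),
                    default=None,
                )
                if lowest is None:
                    continue
                for layer in reversed(stream[lowest:]):
                    g = layer.backward(g)

    def _trainable_layers(self) -> list[nn.Layer]:
        layers = [l for s in (self.stream_s, self.stream_t) for l in s]
        return layers + [self.attn_s, self.attn_t] + list(self.head)

    def get_weights(self) -> list[dict[str, np.ndarray]]:
        return [copy.deepcopy(l.params) for l in self._trainable_layers()]

    def set_weights(self, weights: list[dict[str, np.ndarray]]) -> None:
        for layer, w in zip(self._trainable_layers(), weights):
            layer.params = copy.deepcopy(w)


def build_model(
    spec: DualStreamSpec | None = None,
    hp: ModelHyperparams | None = None,
    seed: int = 0,
) -> DualStreamModel:
    """Assemble a dual-stream model per the spec and hyperparameters."""
    return DualStreamModel(spec or DualStreamSpec(), hp or ModelHyperparams(), seed)


@dataclass
class TrainingRecord:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    best_epoch: int = -1


def train_model(
    model: DualStreamModel,
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_val: np.ndarray,
    y_val: np.ndarray,
    epochs: int,
    rng: np.random.Generator,
) -> TrainingRecord:
    """Minimize binary cross-entropy; restores the best-validation weights.

    When the streams are fully frozen their pooled features are computed
    once and training iterates only over attention and head, which is what
    makes short hyperparameter-search fits cheap.
    """
    if len(x_train) == 0:
        raise ValueError("empty training set")
    record = TrainingRecord()
    if epochs == 0:
        return record
    hp = model.hp
    opt = nn.make_optimizer(hp.optimizer_name, model._trainable_layers(), hp.learning_rate)
    y_train = np.asarray(y_train, dtype=float)
    y_val = np.asarray(y_val, dtype=float)
    frozen = model.backbone_fully_frozen
    if frozen:
        fs_tr, ft_tr = model.extract_features(x_train)
        fs_va, ft_va = model.extract_features(x_val)
        model.set_feature_norm(fs_tr, ft_tr)
    else:
        fs0, ft0 = model.extract_features(x_train)
        model.set_feature_norm(fs0, ft0)
    best_loss, best_weights = np.inf, None
    n = len(x_train)
    for epoch in range(epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, hp.batch_size):
            idx = order[start : start + hp.batch_size]
            yb = y_train[idx]
            if frozen:
                probs = model._head_forward(fs_tr[idx], ft_tr[idx], train=True)
                model._backward(probs, yb, through_backbone=False)
            else:
                probs = model._forward_train(np.asarray(x_train)[idx])
                model._backward(probs, yb, through_backbone=True)
            opt.step()
            losses.append(binary_cross_entropy(yb, probs))
        if frozen:
            val_probs = model._head_forward(fs_va, ft_va, train=False)
        else:
            val_probs = model.predict_proba(x_val)
        vloss = binary_cross_entropy(y_val, val_probs)
        record.train_loss.append(float(np.mean(losses)))
        record.val_loss.append(vloss)
        record.val_accuracy.append(float(np.mean((val_probs >= 0.5) == (y_val == 1))))
        if vloss < best_loss:
            best_loss, best_weights = vloss, model.get_weights()
            record.best_epoch = epoch
    if best_weights is not None:
        model.set_weights(best_weights)
    return record
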