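"""MIP gating classifier: a lightweight residual 2D network.

Whole-brain sub-blocks are expensive to segment; most contain no somata.
Each sub-block's maximum intensity projection is classified
soma-containing / background, and only positive blocks proceed to 3D
segmentation.  The network is a small residual design: a stem convolution
lifts the single channel, then four stages each apply a 3x3 convolution
followed by a stride-2 3x3 convolution with an additive shortcut (1x1
stride-2 projection on the skip path).  Downsampling is done entirely by
strided convolution — there is no max pooling.  Every convolution except the
output head is followed by batch normalization and ReLU.  Global average
pooling, a fully connected layer and a softmax over the two classes close
the network.

Training uses SGD (default lr 1e-4, batch 8) with per-epoch validation AUC
monitoring and early stopping after 10 epochs without improvement; the
best-AUC weights are returned.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize

from .blocking import MIPImage
from .metrics import UndefinedMetricError, auc
from .nn import SGD, Conv, ConvBNReLU, Linear, Module, Tensor

IMPROVEMENT_EPS = 1e-4  # minimal AUC gain that counts as improvement


@dataclass
class ClassifierConfig:
    in_channels: int = 1
    stem_channels: int = 16
    stage_channels: tuple[int, int, int, int] = (16, 32, 64, 128)
    n_classes: int = 2
    input_size: int = 512  # MIPs are resized/padded to this square resolution
    lr: float = 1e-4
    batch_size: int = 8
    max_epochs: int = 100
    patience: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.patience >= self.max_epochs:
            raise ValueError("patience must be < max_epochs")
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if self.input_size % 16 != 0:
            raise ValueError("input_size must be divisible by 2**4 (four stride-2 stages)")


@dataclass
class ClassificationResult:
    prob_soma: float
    label: int
    source_index: tuple[int, int, int]


class _ResidualStage(Module):
    """conv3x3 -> conv3x3(stride 2), with a 1x1 stride-2 projection shortcut."""

    def __init__(self, in_ch: int, out_ch: int, rng):
        super().__init__()
        self.body1 = ConvBNReLU(in_ch, out_ch, 3, nd=2, padding=1, rng=rng)
        self.body2 = ConvBNReLU(out_ch, out_ch, 3, nd=2, stride=2, padding=1, rng=rng)
        self.proj = ConvBNReLU(in_ch, out_ch, 1, nd=2, stride=2, rng=rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.body2(self.body1(x)) + self.proj(x)


class SomaClassifier(Module):
    def __init__(self, cfg: ClassifierConfig):
        super().__init__()
        rng = np.random.default_rng(cfg.seed)
        self.cfg = cfg
        self.stem = ConvBNReLU(cfg.in_channels, cfg.stem_channels, 3, nd=2,
                               padding=1, rng=rng)
        chans = [cfg.stem_channels, *cfg.stage_channels]
        self.stages = [
            _ResidualStage(chans[i], chans[i + 1], rng) for i in range(4)
        ]
        self.fc = Linear(cfg.stage_channels[-1], cfg.n_classes, rng=rng)

    def __call__(self, x: Tensor) -> Tensor:
        """x: (N, 1, H, W) with H, W divisible by 16 -> softmax probs (N, 2)."""
        if x.shape[2] % 16 or x.shape[3] % 16:
            raise ValueError("classifier input spatial dims must be divisible by 16")
        h = self.stem(x)
        for stage in self.stages:
            h = stage(h)
        pooled = h.mean(axis=(2, 3))  # global average pooling
        return self.fc(pooled).softmax(axis=-1)


def build_classifier(cfg: ClassifierConfig) -> SomaClassifier:
    return SomaClassifier(cfg)


def prepare_mip(img: np.ndarray, size: int) -> np.ndarray:
    """Resize a MIP to the fixed square training resolution (bilinear)."""
    img = np.asarray(img, dtype=np.float32)
    if img.shape == (size, size):
        return img
    return resize(img, (size, size), order=1, preserve_range=True,
                  anti_aliasing=False).astype(np.float32)


def _forward_batch(model: SomaClassifier, images: np.ndarray) -> Tensor:
    x = Tensor(images[:, None, :, :])
    return model(x)


def _cross_entropy(probs: Tensor, labels: np.ndarray) -> Tensor:
    onehot = np.eye(probs.shape[-1], dtype=np.float32)[labels]
    eps = 1e-9
    return -((probs + eps).log() * Tensor(onehot)).sum() * (1.0 / len(labels))


def train_classifier(model: SomaClassifier, train: tuple[np.ndarray, np.ndarray],
                     val: tuple[np.ndarray, np.ndarray],
                     cfg: ClassifierConfig | None = None):
    """SGD training with validation-AUC early stopping.

    `train` / `val` are (images, labels) with images (N, H, W) already at the
    configured input resolution.  Returns ``(model, history)`` where history
    is a list of per-epoch dicts; the model carries the best-AUC weights.
    """
    cfg = cfg or model.cfg
    x_tr, y_tr = train
    x_val, y_val = val
    if len(np.unique(y_val)) < 2:
        raise UndefinedMetricError(
            "validation set must contain both classes for AUC monitoring")
    rng = np.random.default_rng(cfg.seed + 1)
    opt = SGD(model.parameters(), cfg.lr)
    best_auc = -np.inf
    best_state = None
    stale = 0
    history: list[dict] = []
    for epoch in range(1, cfg.max_epochs + 1):
        model.train()
        order = rng.permutation(len(x_tr))
        losses = []
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            model.zero_grad()
            probs = _forward_batch(model, x_tr[idx])
            loss = _cross_entropy(probs, y_tr[idx])
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        model.eval()
        scores = _forward_batch(model, x_val).data[:, 1]
        val_auc = auc(scores, y_val)
        history.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                        "val_auc": val_auc})
        improved = val_auc > best_auc + IMPROVEMENT_EPS
        if val_auc >= best_auc:
            # on AUC ties keep the later weights: same ranking quality,
            # better-calibrated probabilities for the 0.5 decision threshold
            best_auc = max(best_auc, val_auc)
            best_state = [a.copy() for a in model.state_arrays()]
        if improved:
            stale = 0
        else:
            stale += 1
            if stale >= cfg.patience:
                break
    if best_state is not None:
        model.load_state_arrays(best_state)
    model.eval()
    return model, history


def classify(model: SomaClassifier, images: list[MIPImage],
             threshold: float = 0.5) -> list[ClassificationResult]:
    """Deterministic inference on a list of MIPs; results keep source tags."""
    if not images:
        return []
    size = model.cfg.input_size
    batch = np.stack([prepare_mip(m.data, size) for m in images])
    model.eval()
    probs = _forward_batch(model, batch).data[:, 1]
    return [
        ClassificationResult(prob_soma=float(p), label=int(p >= threshold),
                             source_index=m.source_index)
        for p, m in zip(probs, images)
    ]
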