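"""3D soma segmentation network and its training loop.

Architecture: a convolutional encoder downsamples a single-channel sub-block
to 1/8 resolution by three stride-2 convolutions (stages: 1 conv + stride-2;
2 convs + stride-2; 2 convs + stride-2; then 4 convs without downsampling),
keeping a constant channel width K.  At the bottleneck, L shifted-window 3D
self-attention blocks (each a W-MSA sub-layer followed by an SW-MSA
sub-layer, with layer norm, feed-forward expansion and residual connections)
mix global context across the block.  A convolutional decoder restores full
resolution in three 2x upsampling stages, each concatenating the matching
encoder feature over a skip connection.  A 1-channel head with a sigmoid
produces per-voxel soma probabilities; masks are binarized at 0.5.

Training: Dice loss, Adam (default lr 1e-4 decayed by 10% every 10 epochs),
batch size 1, random-crop + left-right/up-down flip augmentation, per-epoch
validation Dice with early stopping (patience 30), best-Dice weights kept.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .metrics import dice as dice_score
from .nn import (
    Adam,
    Conv,
    ConvBNReLU,
    ConvTranspose2x3D,
    LayerNorm,
    Linear,
    Module,
    Tensor,
    concat,
    embedding_lookup,
)

DICE_EPS = 1e-5
IMPROVEMENT_EPS = 1e-4
MASK_NEG = -1e9  # attention logit for masked (wrapped) positions


@dataclass
class SegmenterConfig:
    K: int = 16  # embedding/channel width throughout the network
    window: tuple[int, int, int] = (4, 4, 4)  # attention window at 1/8 scale
    L: int = 1  # number of shifted-window attention blocks
    heads: int = 4
    ffn_ratio: float = 4.0
    rel_pos_bias: bool = True
    lr: float = 1e-4
    decay: tuple[float, int] = (0.9, 10)  # multiply lr by factor every n epochs
    batch_size: int = 1
    max_epochs: int = 200
    iters_per_epoch: int = 80
    patience: int = 30
    crop: int = 128
    flip_prob: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.K % self.heads:
            raise ValueError("heads must divide K")
        if min(self.window) < 1 or self.L < 1:
            raise ValueError("window components and L must be >= 1")
        if self.crop % 8:
            raise ValueError("crop must be divisible by 8 (three stride-2 stages)")


@dataclass
class SegMask:
    """Binary segmentation aligned to its source sub-block."""

    data: np.ndarray
    threshold_used: float = 0.5

    def __post_init__(self):
        if not np.isin(self.data, (0, 1)).all():
            raise ValueError("SegMask data must be binary")


# -- window geometry ----------------------------------------------------------


def window_partition(x: Tensor, window: tuple[int, int, int]) -> Tensor:
    """(N, H, W, D, C) -> (N * n_windows, prod(window), C)."""
    n, h, w, d, c = x.shape
    wh, ww, wd = window
    if h % wh or w % ww or d % wd:
        raise ValueError("feature dims must be divisible by the window")
    x = x.reshape(n, h // wh, wh, w // ww, ww, d // wd, wd, c)
    x = x.transpose(0, 1, 3, 5, 2, 4, 6, 7)
    return x.reshape(-1, wh * ww * wd, c)


def window_reverse(x: Tensor, window: tuple[int, int, int],
                   shape: tuple[int, int, int, int, int]) -> Tensor:
    """Inverse of :func:`window_partition`."""
    n, h, w, d, c = shape
    wh, ww, wd = window
    x = x.reshape(n, h // wh, w // ww, d // wd, wh, ww, wd, c)
    x = x.transpose(0, 1, 4, 2, 5, 3, 6, 7)
    return x.reshape(n, h, w, d, c)


def _relative_position_index(window: tuple[int, int, int]) -> np.ndarray:
    """(T, T) indices into a (2w-1)^3 relative-offset bias table."""
    coords = np.stack(np.meshgrid(*[np.arange(w) for w in window],
                                  indexing="ij")).reshape(3, -1)
    rel = coords[:, :, None] - coords[:, None, :]  # (3, T, T)
    dims = [2 * w - 1 for w in window]
    rel = rel + np.array([w - 1 for w in window])[:, None, None]
    return (rel[0] * dims[1] * dims[2] + rel[1] * dims[2] + rel[2]).astype(np.int64)


def shift_window_mask(shape: tuple[int, int, int], window: tuple[int, int, int],
                      shift: tuple[int, int, int]) -> np.ndarray:
    """Attention mask (n_windows, T, T) forbidding attention across the wrap.

    After a cyclic shift, a window near the volume edge contains voxels from
    opposite faces; those must not attend to each other.
    """
    region = np.zeros(shape, dtype=np.int64)
    cnt = 0
    slabs = []
    for w, s in zip(window, shift):
        slabs.append([slice(0, -w), slice(-w, -s if s else None)] +
                     ([slice(-s, None)] if s else []))
    for sx in slabs[0]:
        for sy in slabs[1]:
            for sz in slabs[2]:
                region[sx, sy, sz] = cnt
                cnt += 1
    region_w = window_partition(Tensor(region[None, :, :, :, None]), window)
    ids = region_w.data.reshape(-1, int(np.prod(window)))
    mask = np.where(ids[:, :, None] == ids[:, None, :], 0.0, MASK_NEG)
    return mask.astype(np.float32)


# -- attention ----------------------------------------------------------------


class WindowAttention(Module):
    """Multi-head self-attention within 3D windows, optional relative bias."""

    def __init__(self, dim: int, window: tuple[int, int, int], heads: int,
                 rel_pos_bias: bool, rng):
        super().__init__()
        self.dim = dim
        self.window = window
        self.heads = heads
        self.scale = (dim // heads) ** -0.5
        self.q = Linear(dim, dim, rng)
        self.k = Linear(dim, dim, rng)
        self.v = Linear(dim, dim, rng)
        self.proj = Linear(dim, dim, rng)
        self.rel_index = _relative_position_index(window)
        if rel_pos_bias:
            n_offsets = int(np.prod([2 * w - 1 for w in window]))
            self.bias_table = Tensor(
                (rng.standard_normal((n_offsets, heads)) * 0.02).astype(np.float32),
                requires_grad=True,
            )
        else:
            self.bias_table = None

    def __call__(self, x: Tensor, mask: np.ndarray | None = None) -> Tensor:
        b, t, c = x.shape
        h = self.heads
        dk = c // h

        def split_heads(z: Tensor) -> Tensor:
            return z.reshape(b, t, h, dk).transpose(0, 2, 1, 3)

        q = split_heads(self.q(x)) * self.scale
        k = split_heads(self.k(x))
        v = split_heads(self.v(x))
        attn = q @ k.transpose(0, 1, 3, 2)  # (b, h, t, t)
        if self.bias_table is not None:
            bias = embedding_lookup(self.bias_table, self.rel_index)  # (t, t, h)
            attn = attn + bias.transpose(2, 0, 1).reshape(1, h, t, t)
        if mask is not None:
            nw = mask.shape[0]
            m = np.broadcast_to(
                mask[None, :, None, :, :],
                (b // nw, nw, 1, t, t),
            ).reshape(b, 1, t, t)
            attn = attn + Tensor(m)
        attn = attn.softmax(axis=-1)
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(b, t, c)
        return self.proj(out)


class SwinSubLayer(Module):
    """LN -> (optionally shifted) window MSA -> residual; LN -> FFN -> residual."""

    def __init__(self, dim: int, window, heads: int, ffn_ratio: float,
                 shifted: bool, rel_pos_bias: bool, rng):
        super().__init__()
        self.window = tuple(window)
        self.shift = tuple(w // 2 for w in window) if shifted else (0, 0, 0)
        self.norm1 = LayerNorm(dim)
        self.attn = WindowAttention(dim, self.window, heads, rel_pos_bias, rng)
        self.norm2 = LayerNorm(dim)
        hidden = int(dim * ffn_ratio)
        self.ffn1 = Linear(dim, hidden, rng)
        self.ffn2 = Linear(hidden, dim, rng)

    def __call__(self, x: Tensor) -> Tensor:
        n, h, w, d, c = x.shape
        if any(s % ww for s, ww in zip((h, w, d), self.window)):
            raise ValueError("feature dims must be divisible by the window size")
        # shifting is a no-op along an axis whose window spans the full
        # feature extent (full attention is permutation-equivariant there)
        shift = tuple(s if ww < dim else 0
                      for s, ww, dim in zip(self.shift, self.window, (h, w, d)))
        shifted = any(s > 0 for s in shift)
        y = self.norm1(x)
        if shifted:
            y = y.roll(tuple(-s for s in shift), axis=(1, 2, 3))
            mask = shift_window_mask((h, w, d), self.window, shift)
        else:
            mask = None
        windows = window_partition(y, self.window)
        windows = self.attn(windows, mask)
        y = window_reverse(windows, self.window, (n, h, w, d, c))
        if shifted:
            y = y.roll(shift, axis=(1, 2, 3))
        x = x + y
        z = self.ffn2(self.ffn1(self.norm2(x)).relu())
        return x + z


class VideoSwinBlock(Module):
    """Two consecutive attention sub-layers: plain windows, then shifted."""

    def __init__(self, dim: int, window, heads: int, ffn_ratio: float,
                 rel_pos_bias: bool, rng):
        super().__init__()
        self.sub1 = SwinSubLayer(dim, window, heads, ffn_ratio, False,
                                 rel_pos_bias, rng)
        self.sub2 = SwinSubLayer(dim, window, heads, ffn_ratio, True,
                                 rel_pos_bias, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.sub2(self.sub1(x))


# -- network ------------------------------------------------------------------


class SomaSegmenter(Module):
    def __init__(self, cfg: SegmenterConfig):
        super().__init__()
        rng = np.random.default_rng(cfg.seed)
        self.cfg = cfg
        K = cfg.K

        def conv(i=K, o=K, stride=1):
            return ConvBNReLU(i, o, 3, nd=3, stride=stride, padding=1, rng=rng)

        self.stem = conv(1, K)
        self.enc1 = [conv()]
        self.down1 = conv(stride=2)
        self.enc2 = [conv(), conv()]
        self.down2 = conv(stride=2)
        self.enc3 = [conv(), conv()]
        self.down3 = conv(stride=2)
        self.enc4 = [conv(), conv(), conv(), conv()]
        self.swin = [
            VideoSwinBlock(K, cfg.window, cfg.heads, cfg.ffn_ratio,
                           cfg.rel_pos_bias, rng)
            for _ in range(cfg.L)
        ]
        self.pre_dec = [conv(), conv()]
        self.up3 = ConvTranspose2x3D(K, K, rng)
        self.dec3 = conv(2 * K, K)
        self.up2 = ConvTranspose2x3D(K, K, rng)
        self.dec2 = conv(2 * K, K)
        self.up1 = ConvTranspose2x3D(K, K, rng)
        self.dec1 = conv(2 * K, K)
        self.head = Conv(K, 1, 1, nd=3, rng=rng)

    def __call__(self, x: Tensor) -> Tensor:
        """x: (N, 1, H, W, D), dims divisible by 8 and by window at 1/8 scale."""
        spatial = x.shape[2:]
        if any(s % 8 for s in spatial):
            raise ValueError("input spatial dims must be divisible by 8")
        feat8 = tuple(s // 8 for s in spatial)
        if any(f % w for f, w in zip(feat8, self.cfg.window)):
            raise ValueError(
                f"1/8-scale feature {feat8} not divisible by window {self.cfg.window}")

        h = self.stem(x)
        for m in self.enc1:
            h = m(h)
        skip1 = h  # full resolution
        h = self.down1(h)
        for m in self.enc2:
            h = m(h)
        skip2 = h  # 1/2
        h = self.down2(h)
        for m in self.enc3:
            h = m(h)
        skip3 = h  # 1/4
        h = self.down3(h)
        for m in self.enc4:
            h = m(h)

        # shifted-window attention at 1/8 scale: channels-last tokens
        t = h.transpose(0, 2, 3, 4, 1)
        for blk in self.swin:
            t = blk(t)
        h = t.transpose(0, 4, 1, 2, 3)

        for m in self.pre_dec:
            h = m(h)
        h = self.dec3(concat([self.up3(h), skip3], axis=1))
        h = self.dec2(concat([self.up2(h), skip2], axis=1))
        h = self.dec1(concat([self.up1(h), skip1], axis=1))
        return self.head(h).sigmoid()

    def predict_mask(self, volume: np.ndarray, threshold: float = 0.5) -> SegMask:
        self.eval()
        probs = self(Tensor(volume[None, None])).data[0, 0]
        return SegMask((probs >= threshold).astype(np.uint8), threshold)


def build_segmenter(cfg: SegmenterConfig) -> SomaSegmenter:
    return SomaSegmenter(cfg)


# -- loss & augmentation ------------------------------------------------------


def dice_loss(pred: Tensor, target: np.ndarray, eps: float = DICE_EPS) -> Tensor:
    """1 - (2 Σ p·t + ε) / (Σ p + Σ t + ε); soft Dice on probabilities."""
    target_t = Tensor(np.asarray(target, dtype=np.float32))
    if pred.shape != target_t.shape:
        raise ValueError("pred and target must share a shape")
    inter = (pred * target_t).sum()
    denom = pred.sum() + target_t.sum()
    return 1.0 - (2.0 * inter + eps) / (denom + eps)


def augment(image: np.ndarray, label: np.ndarray, crop: int, flip_prob: float,
            rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Random crop + left-right / up-down flips, identical on image and label."""
    if image.shape != label.shape:
        raise ValueError("image and label must share a shape")
    if any(crop > s for s in image.shape):
        raise ValueError("crop larger than the volume")
    starts = [int(rng.integers(0, s - crop + 1)) for s in image.shape]
    sl = tuple(slice(st, st + crop) for st in starts)
    image, label = image[sl], label[sl]
    if rng.random() < flip_prob:  # left-right
        image, label = image[::-1], label[::-1]
    if rng.random() < flip_prob:  # up-down
        image, label = image[:, ::-1], label[:, ::-1]
    return np.ascontiguousarray(image), np.ascontiguousarray(label)


def lr_at_epoch(base_lr: float, epoch: int, decay: tuple[float, int]) -> float:
    """Step-decay schedule: lr * factor ** floor((epoch - 1) / every)."""
    factor, every = decay
    return base_lr * factor ** ((epoch - 1) // every)


def train_segmenter(model: SomaSegmenter,
                    train: list[tuple[np.ndarray, np.ndarray]],
                    val: list[tuple[np.ndarray, np.ndarray]],
                    cfg: SegmenterConfig | None = None):
    """Adam + Dice-loss training with validation-Dice early stopping.

    `train` / `val` are lists of (volume, mask) pairs.  Training samples a
    random volume per iteration and applies the crop/flip augmentation;
    validation runs the full volumes.  Returns ``(model, history)``.
    """
    cfg = cfg or model.cfg
    if not train or not val:
        raise ValueError("train and val sets must be non-empty")
    rng = np.random.default_rng(cfg.seed + 1)
    opt = Adam(model.parameters(), cfg.lr)
    best_dice = -np.inf
    best_state = None
    stale = 0
    history: list[dict] = []
    for epoch in range(1, cfg.max_epochs + 1):
        opt.lr = lr_at_epoch(cfg.lr, epoch, cfg.decay)
        model.train()
        losses = []
        for _ in range(cfg.iters_per_epoch):
            vol, lab = train[int(rng.integers(0, len(train)))]
            crop = min(cfg.crop, *vol.shape)
            vi, li = augment(vol, lab, crop, cfg.flip_prob, rng)
            model.zero_grad()
            pred = model(Tensor(vi[None, None]))
            loss = dice_loss(pred, li[None, None].astype(np.float32))
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        model.eval()
        val_dices = []
        for vol, lab in val:
            pred = model(Tensor(vol[None, None])).data[0, 0]
            val_dices.append(dice_score(pred >= 0.5, lab))
        val_dice = float(np.mean(val_dices))
        history.append({"epoch": epoch, "lr": opt.lr,
                        "train_loss": float(np.mean(losses)),
                        "val_dice": val_dice})
        if val_dice > best_dice + IMPROVEMENT_EPS:
            best_dice = val_dice
            best_state = [a.copy() for a in model.state_arrays()]
            stale = 0
        else:
            stale += 1
            if stale >= cfg.patience:
                break
    if best_state is not None:
        model.load_state_arrays(best_state)
    model.eval()
    return model, history
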