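"""Test-time pipeline: resampling, pad-to-stride, overlapping sliding-window
patching, model application, and overlap-averaged stitching.

Large volumes cannot be pushed through the segmentation network whole; they
are zero-padded so every dimension tiles under the stride, cut into
overlapping patches, segmented patch-by-patch, and the per-voxel
probabilities are averaged where patches overlap before cropping back to the
original extent and binarizing at 0.5.  Averaging makes the stitched result
independent of patch enumeration order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .blocking import Volume3D
from .segmenter import SegMask


@dataclass
class PatchPlan:
    patch_size: tuple[int, int, int]
    stride: tuple[int, int, int]
    pad: tuple[tuple[int, int], tuple[int, int], tuple[int, int]]
    positions: list[tuple[int, int, int]]
    padded_shape: tuple[int, int, int]


def plan_patches(shape: tuple[int, int, int], patch: tuple[int, int, int],
                 stride: tuple[int, int, int]) -> PatchPlan:
    """Plan an overlapping sliding-window tiling of `shape`.

    Trailing zero padding grows each dimension to ``patch + k * stride`` for
    the smallest integer k >= 0 covering it, so patch origins at every stride
    multiple tile the padded volume completely.
    """
    patch = tuple(int(p) for p in patch)
    stride = tuple(int(s) for s in stride)
    if min(patch) <= 0 or min(stride) <= 0:
        raise ValueError("patch and stride must be positive")
    if any(s > p for s, p in zip(stride, patch)):
        raise ValueError("stride must not exceed patch (coverage requires overlap)")
    padded = []
    for d, p, s in zip(shape, patch, stride):
        if d <= p:
            padded.append(p)
        else:
            k = -(-(d - p) // s)  # ceil
            padded.append(p + k * s)
    pad = tuple((0, pd - d) for pd, d in zip(padded, shape))
    axes = [list(range(0, pd - p + 1, s)) for pd, p, s in zip(padded, patch, stride)]
    positions = [(i, j, k) for i in axes[0] for j in axes[1] for k in axes[2]]
    return PatchPlan(patch, stride, pad, positions, tuple(padded))


def segment_volume(model, v: Volume3D, plan: PatchPlan,
                   threshold: float = 0.5) -> SegMask:
    """Apply `model` patch-wise and stitch by overlap averaging.

    `model` maps a (H, W, D) array to a same-shape probability array (a
    trained segmenter's ``predict_probs``, or any callable with that
    contract).  The result is cropped to the original extent and binarized.
    """
    data = np.pad(v.data.astype(np.float32), plan.pad)
    acc = np.zeros(plan.padded_shape, dtype=np.float64)
    cnt = np.zeros(plan.padded_shape, dtype=np.int32)
    p = plan.patch_size
    for pos in plan.positions:
        sl = tuple(slice(o, o + s) for o, s in zip(pos, p))
        probs = np.asarray(model(data[sl]), dtype=np.float64)
        if probs.shape != tuple(p):
            raise ValueError("model output shape differs from the patch size")
        acc[sl] += probs
        cnt[sl] += 1
    if (cnt == 0).any():
        raise RuntimeError("patch plan does not cover the padded volume")
    mean = acc / cnt
    orig = tuple(slice(0, s) for s in v.shape)
    return SegMask((mean[orig] >= threshold).astype(np.uint8), threshold)


def stitch_probabilities(model, v: Volume3D, plan: PatchPlan) -> np.ndarray:
    """As :func:`segment_volume` but returning the stitched probability map."""
    data = np.pad(v.data.astype(np.float32), plan.pad)
    acc = np.zeros(plan.padded_shape, dtype=np.float64)
    cnt = np.zeros(plan.padded_shape, dtype=np.int32)
    for pos in plan.positions:
        sl = tuple(slice(o, o + s) for o, s in zip(pos, plan.patch_size))
        acc[sl] += np.asarray(model(data[sl]), dtype=np.float64)
        cnt[sl] += 1
    mean = acc / np.maximum(cnt, 1)
    return mean[tuple(slice(0, s) for s in v.shape)]


def resample_for_inference(v: Volume3D, factors: tuple[float, float, float]
                           ) -> Volume3D:
    """Scale each dimension by its factor (cubic interpolation).

    The returned volume's voxel_size is updated by the inverse factors so
    detections in the resampled frame map back to original coordinates via
    ``p_original = p_resampled / factor``.
    """
    if min(factors) <= 0:
        raise ValueError("factors must be positive")
    out_shape = tuple(max(int(round(d * f)), 1) for d, f in zip(v.shape, factors))
    if min(out_shape) < 2:
        raise ValueError("resampling would collapse a dimension")
    zoom = [o / i for o, i in zip(out_shape, v.shape)]
    out = ndimage.zoom(v.data.astype(np.float32), zoom, order=3, grid_mode=True,
                       mode="nearest")
    out = np.clip(out, float(v.data.min()), float(v.data.max()))
    new_voxel = tuple(s / z for s, z in zip(v.voxel_size, zoom))
    return Volume3D(out, new_voxel, v.origin)


def map_points_back(points, factors: tuple[float, float, float]):
    """Map detections from the resampled frame to original voxel coordinates."""
    return [tuple(c / f for c, f in zip(p, factors)) for p in points]
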