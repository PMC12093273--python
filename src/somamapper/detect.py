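"""Centroid detection from segmentation masks and point-set matching.

Each connected foreground component of a binary mask is taken to be one
soma; its geometric center (mean of member voxel coordinates) is the
detected location.  Detections are compared with ground-truth centroids by
distance-thresholded one-to-one matching (maximum pairs, then minimum total
distance).  The default threshold of 10 pixels corresponds to the average
soma radius in sub-micron-resolution whole-brain data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.optimize import linear_sum_assignment
from skimage import measure

MATCH_THRESHOLD_PX = 10.0

_STRUCTS = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass
class DetectionSet:
    """Per-component centroids (block-local voxel coordinates) and sizes."""

    points: list[tuple[float, float, float]]
    component_sizes: list[int]
    source_index: tuple[int, int, int] = (0, 0, 0)

    def to_global(self, origin: tuple[int, int, int]) -> "DetectionSet":
        shifted = [tuple(p[i] + origin[i] for i in range(3)) for p in self.points]
        return DetectionSet(shifted, list(self.component_sizes), self.source_index)


@dataclass
class MatchResult:
    """One-to-one matching between ground-truth and predicted centroids."""

    pairs: list[tuple[int, int, float]]  # (gt_idx, pred_idx, distance)
    unmatched_gt: list[int]
    unmatched_pred: list[int]
    threshold: float

    @property
    def n_tp(self) -> int:
        return len(self.pairs)

    @property
    def distances(self) -> list[float]:
        return [d for _, _, d in self.pairs]


def connected_components(mask: np.ndarray, connectivity: int = 26):
    """Label maximal connected foreground regions.

    Parameters
    ----------
    mask : binary 3D array
    connectivity : {6, 18, 26}
        Voxel neighborhood; 26 merges diagonal touches (default, since
        touching somata are the known failure mode and should not split).

    Returns
    -------
    (labeled, count) : int array of labels 1..count, and the count.
    """
    mask = np.asarray(mask)
    if not np.isin(mask, (0, 1)).all():
        raise ValueError("connected_components requires a binary mask")
    if connectivity not in _STRUCTS:
        raise ValueError("connectivity must be 6, 18 or 26")
    # skimage connectivity: 1 (faces), 2 (+edges), 3 (+corners)
    conn = {6: 1, 18: 2, 26: 3}[connectivity]
    labeled, count = measure.label(mask, connectivity=conn, return_num=True)
    return labeled, count


def centroids(labeled: np.ndarray, source_index: tuple[int, int, int] = (0, 0, 0)
              ) -> DetectionSet:
    """Geometric centers of labeled components, one detection per component."""
    count = int(labeled.max())
    if count == 0:
        return DetectionSet([], [], source_index)
    coms = ndimage.center_of_mass(np.ones_like(labeled, dtype=np.uint8),
                                  labeled, range(1, count + 1))
    sizes = ndimage.sum_labels(np.ones_like(labeled, dtype=np.int64),
                               labeled, range(1, count + 1))
    return DetectionSet(
        points=[tuple(float(c) for c in com) for com in coms],
        component_sizes=[int(s) for s in sizes],
        source_index=source_index,
    )


def detect(mask: np.ndarray, connectivity: int = 26,
           source_index: tuple[int, int, int] = (0, 0, 0)) -> DetectionSet:
    """Convenience: connected components then centroids."""
    labeled, _ = connected_components(mask, connectivity)
    return centroids(labeled, source_index)


def match(gt, pred, threshold: float = MATCH_THRESHOLD_PX) -> MatchResult:
    """Distance-thresholded one-to-one matching of centroids.

    Candidate pairs are all (ground truth, prediction) pairs with Euclidean
    distance <= threshold ("below the threshold" read inclusively, so a pair
    at exactly the threshold counts).  Among matchings using only candidate
    pairs, the result maximizes the number of matched pairs and, among
    those, minimizes the total distance (solved as a rectangular assignment
    problem).  On conflict-free instances — each point having at most one
    candidate partner, the typical case for well-separated somata — this
    reduces to per-point nearest matching.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    gt = np.asarray(list(gt), dtype=float).reshape(-1, 3)
    pred = np.asarray(list(pred), dtype=float).reshape(-1, 3)
    if len(gt) == 0 or len(pred) == 0:
        return MatchResult([], list(range(len(gt))), list(range(len(pred))), threshold)
    d = np.sqrt(((gt[:, None, :] - pred[None, :, :]) ** 2).sum(-1))
    feasible = d <= threshold
    # forbidden edges get a cost exceeding any feasible total, so the solver
    # first maximizes the number of feasible pairs, then their total distance
    big = threshold * (d.size + 1.0)
    cost = np.where(feasible, d, big)
    rows, cols = linear_sum_assignment(cost)
    pairs = [
        (int(g), int(p), float(d[g, p]))
        for g, p in zip(rows, cols)
        if feasible[g, p]
    ]
    used_g = {g for g, _, _ in pairs}
    used_p = {p for _, p, _ in pairs}
    return MatchResult(
        pairs=pairs,
        unmatched_gt=[i for i in range(len(gt)) if i not in used_g],
        unmatched_pred=[i for i in range(len(pred)) if i not in used_p],
        threshold=threshold,
    )


def consolidate_blocks(masks: dict[tuple[int, int, int], np.ndarray],
                       block_shape: tuple[int, int, int],
                       full_shape: tuple[int, int, int],
                       connectivity: int = 26) -> DetectionSet:
    """Merge per-block masks into the global frame before centroiding.

    A soma straddling a block face would otherwise yield one detection per
    block; stitching the masks first lets connected-component analysis merge
    it into a single component.
    """
    full = np.zeros(full_shape, dtype=np.uint8)
    for gidx, m in masks.items():
        origin = tuple(g * b for g, b in zip(gidx, block_shape))
        stop = tuple(min(o + b, d) for o, b, d in zip(origin, block_shape, full_shape))
        size = tuple(s - o for s, o in zip(stop, origin))
        full[origin[0]:stop[0], origin[1]:stop[1], origin[2]:stop[2]] |= \
            np.asarray(m, dtype=np.uint8)[: size[0], : size[1], : size[2]]
    return detect(full, connectivity)
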