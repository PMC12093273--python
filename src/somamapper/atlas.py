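"""Atlas-space mapping: transform detections, assign brain regions, count.

Detected soma coordinates (global voxel positions in the sample frame) are
carried into an annotated reference atlas frame by a precomputed affine
transform (optionally refined by a dense displacement field), assigned to
the region labeled at their containing voxel, counted per region, and
normalized by the whole-brain total.  Estimating the registration itself is
an external concern; this module consumes its exported parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class PointTransform:
    """Sample-to-atlas point transform: 4x4 affine (+ optional field).

    ``affine`` acts on homogeneous (x, y, z, 1) columns.  When a
    displacement field (3-vector per atlas voxel, same frame as the atlas
    grid) is present, it is sampled at the affinely mapped position and
    added.
    """

    affine: np.ndarray
    displacement: np.ndarray | None = None  # (X, Y, Z, 3) in atlas voxels

    def __post_init__(self):
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be a 4x4 matrix")
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine must be invertible")

    @classmethod
    def identity(cls) -> "PointTransform":
        return cls(np.eye(4))

    def inverse(self) -> "PointTransform":
        if self.displacement is not None:
            raise ValueError("displacement-field transforms are not invertible here")
        return PointTransform(np.linalg.inv(self.affine))


@dataclass
class AtlasLabelVolume:
    """Integer region labels per voxel; 0 = outside the brain."""

    labels: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    region_names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3D integer grid")
        present = set(np.unique(self.labels).tolist()) - {0}
        missing = present - set(self.region_names)
        if missing:
            raise ValueError(f"labels without a name entry: {sorted(missing)}")


@dataclass
class RegionTable:
    """Per-region counts and whole-brain-normalized fractions."""

    table: pd.DataFrame  # columns: region_id, region_name, count, fraction
    n_unassigned: int
    n_total: int

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def transform_points(points, t: PointTransform) -> np.ndarray:
    """Apply the affine (then displacement, if any) to an (N, 3) point set."""
    pts = np.asarray(list(points), dtype=float).reshape(-1, 3)
    if len(pts) == 0:
        return pts
    homo = np.hstack([pts, np.ones((len(pts), 1))])
    out = (t.affine @ homo.T).T[:, :3]
    if t.displacement is not None:
        idx = np.clip(
            np.floor(out).astype(int), 0,
            np.array(t.displacement.shape[:3]) - 1,
        )
        out = out + t.displacement[idx[:, 0], idx[:, 1], idx[:, 2]]
    return out


def assign_regions(points, atlas: AtlasLabelVolume) -> np.ndarray:
    """Region id per point (containing-voxel lookup); -1 = unassigned.

    Points are in atlas physical coordinates; the voxel index is the floor
    of coordinate / voxel_size.  Points outside the grid, or landing on
    label 0 (outside the brain), are unassigned.
    """
    pts = np.asarray(list(points), dtype=float).reshape(-1, 3)
    out = np.full(len(pts), -1, dtype=np.int64)
    if len(pts) == 0:
        return out
    idx = np.floor(pts / np.asarray(atlas.voxel_size)).astype(np.int64)
    inside = np.all((idx >= 0) & (idx < np.array(atlas.labels.shape)), axis=1)
    ii = idx[inside]
    labels = atlas.labels[ii[:, 0], ii[:, 1], ii[:, 2]].astype(np.int64)
    vals = np.where(labels == 0, -1, labels)
    out[inside] = vals
    return out


def region_fractions(assignments, atlas: AtlasLabelVolume | None = None
                     ) -> RegionTable:
    """Count points per region and normalize by the total assigned.

    Unassigned points (id -1) are excluded from the fractions' denominator
    and reported separately, so counts + unassigned always conserve the
    input size.
    """
    assignments = np.asarray(list(assignments), dtype=np.int64)
    n_total = len(assignments)
    assigned = assignments[assignments >= 0]
    n_unassigned = n_total - len(assigned)
    ids, counts = np.unique(assigned, return_counts=True)
    total = counts.sum()
    names = atlas.region_names if atlas is not None else {}
    df = pd.DataFrame({
        "region_id": ids,
        "region_name": [names.get(int(i), str(int(i))) for i in ids],
        "count": counts,
        "fraction": counts / total if total > 0 else counts.astype(float),
    })
    return RegionTable(df, n_unassigned=int(n_unassigned), n_total=int(n_total))


def hemisphere_flags(points, midline_axis: int = 0,
                     midline_coord: float = 0.0) -> np.ndarray:
    """Left/right split: True where the coordinate exceeds the midline plane.

    Supports ipsi/contralateral comparisons of per-hemisphere counts.
    """
    pts = np.asarray(list(points), dtype=float).reshape(-1, 3)
    return pts[:, midline_axis] > midline_coord
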