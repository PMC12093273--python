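"""Readers and writers for the pipeline's on-disk formats.

Volumes travel as multi-page TIFF (pages along z) or HDF5 (dataset
"/volume"); centroid lists as CSV ``id,x,y,z,radius``; detections as CSV
with global coordinates and source-block indices; transforms as JSON
holding the 4x4 affine; region tables as CSV.

Arrays in memory are indexed (x, y, z); TIFF pages are written as (z, y, x)
so standard viewers show xy slices stacked along depth.
"""

from __future__ import annotations

import json

import h5py
import numpy as np
import pandas as pd
import tifffile

from .atlas import AtlasLabelVolume, PointTransform
from .blocking import Volume3D
from .detect import DetectionSet


def write_volume_tiff(path, v: Volume3D) -> None:
    tifffile.imwrite(path, np.ascontiguousarray(v.data.transpose(2, 1, 0)),
                     photometric="minisblack")


def read_volume_tiff(path, voxel_size=(1.0, 1.0, 1.0)) -> Volume3D:
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    return Volume3D(np.ascontiguousarray(data.transpose(2, 1, 0)), voxel_size)


def write_volume_h5(path, v: Volume3D) -> None:
    with h5py.File(path, "w") as fh:
        ds = fh.create_dataset("/volume", data=v.data)
        ds.attrs["voxel_size"] = v.voxel_size
        ds.attrs["origin"] = v.origin


def read_volume_h5(path) -> Volume3D:
    with h5py.File(path, "r") as fh:
        ds = fh["/volume"]
        voxel = tuple(ds.attrs.get("voxel_size", (1.0, 1.0, 1.0)))
        origin = tuple(int(o) for o in ds.attrs.get("origin", (0, 0, 0)))
        return Volume3D(ds[()], voxel, origin)


def write_centroids_csv(path, centroids, radii=None, labels=None) -> None:
    centroids = list(centroids)
    n = len(centroids)
    df = pd.DataFrame({
        "id": labels if labels is not None else list(range(1, n + 1)),
        "x": [c[0] for c in centroids],
        "y": [c[1] for c in centroids],
        "z": [c[2] for c in centroids],
        "radius": radii if radii is not None else [float("nan")] * n,
    })
    df.to_csv(path, index=False)


def read_centroids_csv(path) -> list[tuple[float, float, float]]:
    df = pd.read_csv(path)
    return [tuple(r) for r in df[["x", "y", "z"]].to_numpy(dtype=float)]


def write_detections_csv(path, detections: DetectionSet,
                         origin=(0, 0, 0)) -> None:
    glob = detections.to_global(origin)
    df = pd.DataFrame({
        "x": [p[0] for p in glob.points],
        "y": [p[1] for p in glob.points],
        "z": [p[2] for p in glob.points],
        "component_voxels": glob.component_sizes,
        "block_i": detections.source_index[0],
        "block_j": detections.source_index[1],
        "block_k": detections.source_index[2],
    })
    df.to_csv(path, index=False)


def write_block_manifest(path, blocks) -> None:
    manifest = {
        ",".join(map(str, b.grid_index)): {
            "origin": list(b.volume.origin),
            "shape": list(b.block_shape),
            "pad": list(b.pad),
        }
        for b in blocks
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2)


def read_transform_json(path) -> PointTransform:
    with open(path) as fh:
        payload = json.load(fh)
    affine = np.asarray(payload["affine"], dtype=float)
    disp = None
    if payload.get("displacement_h5"):
        with h5py.File(payload["displacement_h5"], "r") as fh:
            disp = fh["/displacement"][()]
    return PointTransform(affine, disp)


def write_transform_json(path, t: PointTransform) -> None:
    with open(path, "w") as fh:
        json.dump({"affine": t.affine.tolist()}, fh, indent=2)


def read_atlas_h5(path) -> AtlasLabelVolume:
    with h5py.File(path, "r") as fh:
        labels = fh["/labels"][()]
        voxel = tuple(fh["/labels"].attrs.get("voxel_size", (1.0, 1.0, 1.0)))
        names = json.loads(fh.attrs.get("region_names", "{}"))
    return AtlasLabelVolume(labels, voxel, {int(k): v for k, v in names.items()})


def write_atlas_h5(path, atlas: AtlasLabelVolume) -> None:
    with h5py.File(path, "w") as fh:
        ds = fh.create_dataset("/labels", data=atlas.labels)
        ds.attrs["voxel_size"] = atlas.voxel_size
        fh.attrs["region_names"] = json.dumps(
            {str(k): v for k, v in atlas.region_names.items()})
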