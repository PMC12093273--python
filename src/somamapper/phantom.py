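"""Seeded synthetic phantoms emulating whole-brain fluorescence soma imaging.

Real whole-brain volumes of retrogradely labeled neurons show densely packed
sphere-like somata of varying radius and brightness, soma-mimicking background
speckles, uneven illumination, and sensor noise.  The generator reproduces
those regimes with exact ground truth (binary mask + centroid list), so every
pipeline stage — MIP gating, 3D segmentation, centroid detection, matching,
atlas counting — is testable without the original microscope data.

Somata are rendered as hard balls (mask support ``||p - c|| <= r``) with a
1-voxel cosine intensity rolloff at the rim, which keeps the ground-truth
mask binary while giving sub-voxel-stable centroids.  A configurable fraction
of somata is placed as touching pairs (center distance ``1.2 * (r1 + r2) / 2``)
to exercise the known hard case of closely adjacent somata.

All randomness flows from a single ``numpy.random.default_rng(spec.seed)``
stream with a documented draw order (soma radii/intensities/positions first,
then noise blobs, then the additive noise field), so equal seeds give
bit-identical samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .blocking import Volume3D

_PLACEMENT_TRIES = 2000


class PlacementError(RuntimeError):
    """Raised when a spec is too crowded to place all requested somata."""


@dataclass
class PhantomSpec:
    """Parameters of one synthetic volume.

    ``overlap_fraction`` is the fraction of somata placed as touching pairs;
    ``n_noise_blobs`` are soma-mimicking speckles (radius below
    ``radius_range[0]``) that appear in the image but never in the mask;
    ``illumination_gradient`` is the amplitude of a multiplicative ramp along
    x (1 at the bright face, ``1 - amplitude`` at the dim face);
    ``noise_sigma`` is the std of additive Gaussian noise.
    """

    shape: tuple[int, int, int] = (64, 64, 64)
    n_somata: int = 12
    radius_range: tuple[float, float] = (3.0, 6.0)
    intensity_range: tuple[float, float] = (0.4, 1.0)
    overlap_fraction: float = 0.0
    n_noise_blobs: int = 0
    illumination_gradient: float = 0.0
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.radius_range[0] < 2:
            raise ValueError("minimum soma radius must be >= 2 voxels")
        if self.radius_range[1] >= min(self.shape) / 4:
            raise ValueError("maximum soma radius must be < min(shape)/4")
        if not (0 <= self.overlap_fraction <= 1):
            raise ValueError("overlap_fraction must lie in [0, 1]")
        if not (0 <= self.illumination_gradient <= 1):
            raise ValueError("illumination_gradient must lie in [0, 1]")
        if self.n_somata < 0 or self.n_noise_blobs < 0 or self.noise_sigma < 0:
            raise ValueError("counts and noise_sigma must be non-negative")


@dataclass
class PhantomSample:
    """A rendered phantom with its ground truth."""

    volume: Volume3D
    mask: np.ndarray  # uint8, 1 = soma voxel
    centroids: list[tuple[float, float, float]]
    labels: list[int]  # per-soma IDs, 1..n_somata
    radii: list[float] = field(default_factory=list)


def _ball_patch(center: np.ndarray, r: float, shape: tuple[int, int, int]):
    """Voxel coordinates within distance r of center, clipped to the grid."""
    lo = np.maximum(np.floor(center - r).astype(int), 0)
    hi = np.minimum(np.ceil(center + r).astype(int) + 1, shape)
    grids = np.meshgrid(*[np.arange(a, b) for a, b in zip(lo, hi)], indexing="ij")
    d = np.sqrt(sum((g - c) ** 2 for g, c in zip(grids, center)))
    region = tuple(slice(a, b) for a, b in zip(lo, hi))
    return region, d


def _render_ball(img: np.ndarray, center: np.ndarray, r: float, peak: float,
                 mask: np.ndarray | None) -> None:
    region, d = _ball_patch(center, r, img.shape)
    inside = d <= r
    rim = (d > r - 1.0) & inside
    intensity = np.where(inside, peak, 0.0)
    # cosine rolloff from full peak at r-1 to half peak at r
    intensity[rim] = peak * (0.75 + 0.25 * np.cos(np.pi * (d[rim] - (r - 1.0))))
    np.maximum(img[region], intensity, out=img[region])
    if mask is not None:
        mask[region][inside] = 1


def _sample_center(rng: np.random.Generator, shape, r: float) -> np.ndarray:
    """Integer voxel center uniformly inside the volume with margin r."""
    lo = int(np.ceil(r)) + 1
    return np.array([float(rng.integers(lo, s - lo)) for s in shape])


def generate_phantom(spec: PhantomSpec) -> PhantomSample:
    """Render a phantom volume with ground truth from `spec`.

    Raises
    ------
    PlacementError
        If somata cannot be placed without exceeding the retry budget —
        the spec is overcrowded for its volume.
    """
    rng = np.random.default_rng(spec.seed)
    shape = tuple(int(s) for s in spec.shape)
    img = np.zeros(shape, dtype=np.float32)
    mask = np.zeros(shape, dtype=np.uint8)

    n_pairs = int(round(spec.overlap_fraction * spec.n_somata / 2.0))
    n_single = spec.n_somata - 2 * n_pairs

    centers: list[np.ndarray] = []
    radii: list[float] = []
    peaks: list[float] = []

    def clear_of_others(c: np.ndarray, r: float, skip: set[int] = frozenset()) -> bool:
        for i, (oc, orad) in enumerate(zip(centers, radii)):
            if i in skip:
                continue
            # gap > 2 keeps masks disconnected even at 26-connectivity
            if np.linalg.norm(c - oc) <= r + orad + 2.0:
                return False
        return True

    def draw_soma():
        r = float(rng.uniform(*spec.radius_range))
        peak = float(rng.uniform(*spec.intensity_range))
        return r, peak

    for _ in range(n_pairs):
        r1, p1 = draw_soma()
        r2, p2 = draw_soma()
        sep = 1.2 * (r1 + r2) / 2.0  # touching/merging masks by construction
        for attempt in range(_PLACEMENT_TRIES):
            c1 = _sample_center(rng, shape, max(r1, r2) + sep)
            direction = rng.standard_normal(3)
            direction /= np.linalg.norm(direction)
            c2 = c1 + direction * sep
            if clear_of_others(c1, r1) and clear_of_others(c2, r2):
                break
        else:
            raise PlacementError("could not place a touching soma pair; spec too dense")
        centers += [c1, c2]
        radii += [r1, r2]
        peaks += [p1, p2]

    for _ in range(n_single):
        r, peak = draw_soma()
        for attempt in range(_PLACEMENT_TRIES):
            c = _sample_center(rng, shape, r)
            if clear_of_others(c, r):
                break
        else:
            raise PlacementError("could not place a soma; spec too dense")
        centers.append(c)
        radii.append(r)
        peaks.append(peak)

    for c, r, peak in zip(centers, radii, peaks):
        _render_ball(img, c, r, peak, mask)

    # soma-mimicking background speckles: smaller than any true soma,
    # present in the image but absent from the mask
    max_noise_r = max(spec.radius_range[0] - 1.0, 1.0)
    for _ in range(spec.n_noise_blobs):
        r = float(rng.uniform(1.0, max_noise_r))
        peak = float(rng.uniform(*spec.intensity_range))
        c = _sample_center(rng, shape, r)
        _render_ball(img, c, r, peak, mask=None)

    if spec.illumination_gradient > 0:
        ramp = 1.0 - spec.illumination_gradient * (
            np.arange(shape[0], dtype=np.float32) / max(shape[0] - 1, 1)
        )
        img *= ramp[:, None, None]

    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, size=shape).astype(np.float32)

    img = np.clip(img, 0.0, 1.0).astype(np.float32)

    return PhantomSample(
        volume=Volume3D(img, voxel_size=(1.0, 1.0, 1.0)),
        mask=mask,
        centroids=[tuple(float(x) for x in c) for c in centers],
        labels=list(range(1, len(centers) + 1)),
        radii=radii,
    )


def generate_classification_set(
    spec: PhantomSpec, n_pos: int, n_neg: int
) -> tuple[np.ndarray, np.ndarray]:
    """Labeled 2D MIP dataset for the gating classifier.

    Positives are z-MIPs of phantoms containing somata; negatives are MIPs of
    soma-free phantoms that keep the background regime (noise blobs, uneven
    illumination, sensor noise).  Returns ``(images, labels)`` with images
    stacked along axis 0 and labels ``1`` for the first ``n_pos`` entries.
    """
    if n_pos < 0 or n_neg < 0:
        raise ValueError("n_pos and n_neg must be non-negative")
    rng = np.random.default_rng(spec.seed)
    images = []
    labels = []
    for i in range(n_pos + n_neg):
        positive = i < n_pos
        sub_seed = int(rng.integers(0, 2**31 - 1))
        sub = PhantomSpec(
            shape=spec.shape,
            n_somata=max(spec.n_somata, 1) if positive else 0,
            radius_range=spec.radius_range,
            intensity_range=spec.intensity_range,
            overlap_fraction=spec.overlap_fraction if positive else 0.0,
            n_noise_blobs=spec.n_noise_blobs,
            illumination_gradient=spec.illumination_gradient,
            noise_sigma=spec.noise_sigma,
            seed=sub_seed,
        )
        sample = generate_phantom(sub)
        images.append(sample.volume.data.max(axis=2))
        labels.append(1 if positive else 0)
    if images:
        return np.stack(images), np.array(labels, dtype=np.int64)
    return np.zeros((0,) + tuple(spec.shape[:2]), dtype=np.float32), np.zeros(0, dtype=np.int64)
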