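"""Intensity rescaling, template cropping, trilinear resampling and the
quality-grade → quality-label rule, plus the train/test split bookkeeping.

Bias-field correction, affine registration and skull stripping are external
to this package: inputs are assumed grid-aligned (true for phantom data, or
for clinical data already passed through a linear-registration pipeline).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .types import ImagePair, QualityGrades, Volume3D

QUALITY_LABELS = ("good", "medium", "low")


@dataclass(frozen=True)
class PreprocessConfig:
    crop_shape: tuple[int, int, int] = (169, 208, 179)
    model_shape: tuple[int, int, int] = (128, 128, 128)
    rescale_eps: float = 1e-8


def rescale_minmax(vol: Volume3D, eps: float = 1e-8) -> Volume3D:
    """Affinely map intensities to span exactly [0, 1].

    Raises on (near-)constant images, where the map is undefined.
    """
    lo = float(vol.values.min())
    hi = float(vol.values.max())
    if hi - lo < eps:
        raise ValueError(f"constant image: intensity range {hi - lo:g} < {eps:g}")
    out = (vol.values - lo) / (hi - lo)
    return Volume3D(out, vol.voxel_size_mm, (0.0, 1.0))


def crop_center(vol: Volume3D, crop_shape: tuple[int, int, int]) -> Volume3D:
    """Centered sub-block of the requested shape.

    When a margin is odd the extra voxel is dropped from the far side, i.e.
    the crop window is shifted toward the origin.
    """
    shape = vol.shape
    if any(c > s for c, s in zip(crop_shape, shape)):
        raise ValueError(f"crop shape {crop_shape} exceeds input shape {shape}")
    starts = [(s - c) // 2 for s, c in zip(shape, crop_shape)]
    sl = tuple(slice(st, st + c) for st, c in zip(starts, crop_shape))
    return vol.with_values(vol.values[sl].copy())


def resample_trilinear(vol: Volume3D, target_shape: tuple[int, int, int]) -> Volume3D:
    """Trilinear resampling on a corner-aligned grid.

    Output sample i along an axis of input length n and output length m sits
    at input coordinate i*(n-1)/(m-1), so the first and last samples of the
    two grids coincide.  Constant volumes map to the same constant and
    outputs never exceed the input range (linear interpolation is a convex
    combination).
    """
    if any(t <= 0 for t in target_shape):
        raise ValueError("target_shape must be positive")
    in_shape = vol.shape
    axes = [
        np.linspace(0.0, n - 1.0, m) if m > 1 else np.array([(n - 1.0) / 2.0])
        for n, m in zip(in_shape, target_shape)
    ]
    coords = np.meshgrid(*axes, indexing="ij")
    out = ndimage.map_coordinates(vol.values.astype(np.float64), coords, order=1,
                                  mode="nearest")
    scale = float(np.prod([n / m for n, m in zip(in_shape, target_shape)]) ** (1.0 / 3.0))
    return Volume3D(out, vol.voxel_size_mm * scale, vol.intensity_range)


def quality_label(grades: QualityGrades | tuple[int, int, int]) -> str:
    """Map 0/1/2 contrast/motion/noise grades to good/medium/low.

    Any grade of 2 → low; otherwise any grade of 1 → medium; all 0 → good.
    """
    if not isinstance(grades, QualityGrades):
        grades = QualityGrades(*grades)  # validates entries
    worst = max(grades.as_tuple())
    return {0: "good", 1: "medium", 2: "low"}[worst]


def split_dataset(pairs: list[ImagePair], test_fraction: float,
                  seed: int) -> tuple[list[ImagePair], list[ImagePair], list[ImagePair]]:
    """Partition pairs into (train, test_good, test_low).

    Pairs with a low-quality T1ce go entirely to test_low; of the remaining
    medium/good pairs, round(test_fraction * n) are held out as test_good
    and the rest train.  The partition is exhaustive, disjoint and
    deterministic given the seed.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must be in (0, 1)")
    for p in pairs:
        if quality_label(p.grades_t1nce) == "low":
            raise ValueError(
                f"{p.subject_id}: low-quality T1nce pairs are excluded upstream"
            )
    low = [p for p in pairs if quality_label(p.grades_t1ce) == "low"]
    rest = [p for p in pairs if quality_label(p.grades_t1ce) != "low"]
    n_test = int(np.floor(test_fraction * len(rest) + 0.5))
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(rest))
    test_good = [rest[i] for i in sorted(order[:n_test])]
    train = [rest[i] for i in sorted(order[n_test:])]
    for p, name in ((train, "train"), (test_good, "test_good"), (low, "test_low")):
        for pair in p:
            pair.split = name
    return train, test_good, low
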