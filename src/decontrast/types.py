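"""Shared domain containers.

Intensities follow the convention of min-max rescaled T1-weighted MRI:
values in [0, 1], isotropic voxels whose edge length is carried in mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

TISSUES = ("GM", "WM", "CSF")  # fixed order; also the arg-max tie-break order


@dataclass
class Volume3D:
    """Scalar intensities on a 3D grid with isotropic voxel spacing."""

    values: np.ndarray
    voxel_size_mm: float = 1.0
    intensity_range: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.values.ndim}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume contains non-finite values")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def with_values(self, values: np.ndarray) -> "Volume3D":
        return Volume3D(values, self.voxel_size_mm, self.intensity_range)


@dataclass(frozen=True)
class QualityGrades:
    """0/1/2 ratings of contrast, motion and noise for one image.

    Grade 0: good contrast / no motion / no noise; grade 1: medium / some;
    grade 2: bad / severe.
    """

    contrast: int
    motion: int
    noise: int

    def __post_init__(self):
        for name in ("contrast", "motion", "noise"):
            g = getattr(self, name)
            if g not in (0, 1, 2):
                raise ValueError(f"{name} grade must be in {{0,1,2}}, got {g!r}")

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.contrast, self.motion, self.noise)


@dataclass
class TissueMaps:
    """Per-voxel probability maps for GM/WM/CSF (background implicit)."""

    probabilities: dict[str, np.ndarray]
    voxel_size_mm: float = 1.0
    degenerate: bool = False   # set by fitters whose class structure collapsed

    def __post_init__(self):
        missing = set(TISSUES) - set(self.probabilities)
        if missing:
            raise ValueError(f"missing tissue maps: {sorted(missing)}")
        shapes = {t: self.probabilities[t].shape for t in TISSUES}
        if len(set(shapes.values())) != 1:
            raise ValueError(f"tissue maps on different grids: {shapes}")
        stack = self.stack()
        if stack.min() < -1e-6 or stack.max() > 1 + 1e-6:
            raise ValueError("tissue probabilities must lie in [0, 1]")
        if stack.sum(axis=0).max() > 1 + 1e-6:
            raise ValueError("per-voxel tissue probabilities sum to more than 1")

    def stack(self) -> np.ndarray:
        """(3, D, H, W) array in the fixed GM, WM, CSF order."""
        return np.stack([self.probabilities[t] for t in TISSUES])

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.probabilities[TISSUES[0]].shape


@dataclass
class ImagePair:
    """Co-registered T1ce + T1nce acquisitions for one subject/session."""

    subject_id: str
    session_id: str
    t1ce: Volume3D
    t1nce: Volume3D
    grades_t1ce: QualityGrades
    grades_t1nce: QualityGrades
    split: str | None = None
    extra: dict = field(default_factory=dict)
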