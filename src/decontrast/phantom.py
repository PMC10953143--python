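"""Seeded paired T1nce/T1ce brain phantoms with ground-truth tissue maps.

The generator emulates the statistical structure of a paired clinical
T1-weighted data set: for each synthetic subject it builds nested ellipsoidal
tissue compartments (WM core, GM ribbon, CSF shell plus ventricles), renders
a non-contrast-enhanced volume from per-tissue mean intensities plus Gaussian
noise, derives the contrast-enhanced counterpart by brightening an
"enhancing" compartment (meningeal/vascular shell patches and random tubes)
and shifting the GM mean, and finally records 0/1/2 quality grades for
contrast, motion and noise whose realisation is a separate, explicit
degradation operator.

Default geometry: a 32-voxel cube with 6 mm voxels, giving an intracranial
volume around 1.4 L — the order of magnitude of an adult head — so that
tissue-volume statistics downstream are on a familiar scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .types import TISSUES, QualityGrades, TissueMaps, Volume3D

DEFAULT_TISSUE_MEANS = {"WM": 0.75, "GM": 0.55, "CSF": 0.20, "background": 0.0}

# per-axis grade probabilities emulating the warehouse mix: T1nce images are
# never severe (the pairing rule keeps only medium/good T1nce), while ~17% of
# T1ce images end up with at least one grade-2 axis
GRADE_PROBS_T1CE = (0.62, 0.32, 0.06)
GRADE_PROBS_T1NCE = (0.60, 0.40, 0.0)


@dataclass(frozen=True)
class PhantomParams:
    grid_shape: tuple[int, int, int] = (32, 32, 32)
    voxel_size_mm: float = 6.0
    tissue_means: dict = field(default_factory=lambda: dict(DEFAULT_TISSUE_MEANS))
    noise_sigma: float = 0.01
    enhancement_strength: float = 0.25
    contrast_shift: float = 0.10
    seed: int = 0

    def __post_init__(self):
        if any(s < 8 for s in self.grid_shape):
            raise ValueError("grid_shape entries must be >= 8")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be positive")
        for t, m in self.tissue_means.items():
            if not 0.0 <= m <= 1.0:
                raise ValueError(f"tissue mean for {t} outside [0, 1]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")
        if self.enhancement_strength < 0:
            raise ValueError("enhancement_strength must be nonnegative")


@dataclass(frozen=True)
class DegradeParams:
    """Numerical realisation of the semantic 0/1/2 quality grades.

    contrast grade g compresses intensities toward the foreground mean by
    c_g; motion applies a 1D Gaussian blur of width w_g voxels along a
    random axis; noise adds Gaussian noise of sd n_g.
    """

    contrast_factors: tuple[float, float, float] = (0.0, 0.25, 0.5)
    motion_sigmas: tuple[float, float, float] = (0.0, 0.7, 1.5)
    noise_sigmas: tuple[float, float, float] = (0.0, 0.01, 0.03)


@dataclass
class PhantomSample:
    t1nce: Volume3D
    t1ce: Volume3D
    brain_mask: np.ndarray
    tissue_truth: TissueMaps
    enhancing_mask: np.ndarray
    grades_t1ce: QualityGrades
    grades_t1nce: QualityGrades
    subject_id: str = "sub-000"


def _ellipsoid_radius(shape, center, semi_axes) -> np.ndarray:
    """Normalised ellipsoid radius field: r<=1 inside."""
    grids = np.meshgrid(*[np.arange(s, dtype=np.float64) for s in shape], indexing="ij")
    r2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi_axes))
    return np.sqrt(r2)


def _draw_grades(rng: np.random.Generator, probs) -> QualityGrades:
    g = rng.choice(3, size=3, p=probs)
    return QualityGrades(int(g[0]), int(g[1]), int(g[2]))


def make_phantom(params: PhantomParams, subject_id: str = "sub-000") -> PhantomSample:
    """Generate one paired phantom subject, deterministically from params.seed."""
    rng = np.random.default_rng(params.seed)
    shape = tuple(params.grid_shape)
    half = np.array(shape, dtype=np.float64) / 2.0

    # per-subject anatomy: jittered ellipsoid axes and centre
    semi = half * rng.uniform(0.78, 0.88, size=3)
    center = half + rng.uniform(-0.03, 0.03, size=3) * np.array(shape)
    r = _ellipsoid_radius(shape, center, semi)

    brain_mask = r <= 1.0
    labels = np.zeros(shape, dtype=np.uint8)  # 0 bg, 1 CSF, 2 GM, 3 WM
    labels[brain_mask] = 1
    labels[r <= 0.92] = 2
    labels[r <= 0.70] = 3

    # ventricles: two small CSF ellipsoids inside the WM core
    for sign in (-1.0, 1.0):
        vc = center + np.array([0.0, sign * 0.12 * shape[1], 0.0])
        vr = _ellipsoid_radius(shape, vc, np.array(shape) * np.array([0.06, 0.10, 0.06]))
        labels[(vr <= 1.0) & (labels == 3)] = 1

    if not np.any(labels == 3) or not np.any(labels == 2) or not np.any(labels == 1):
        raise ValueError("grid too small to fit nested tissue compartments")

    # enhancing compartment: meningeal shell patches + random vessel tubes
    enhancing = np.zeros(shape, dtype=bool)
    with np.errstate(invalid="ignore"):
        grids = np.meshgrid(*[np.arange(s, dtype=np.float64) for s in shape], indexing="ij")
        vec = np.stack([g - c for g, c in zip(grids, center)])
        norm = np.sqrt((vec ** 2).sum(axis=0))
        norm[norm == 0] = 1.0
        unit = vec / norm
    shell = (r > 0.88) & (r <= 1.0)
    for _ in range(6):
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        cap = (unit[0] * d[0] + unit[1] * d[1] + unit[2] * d[2]) > 0.92
        enhancing |= shell & cap
    tubes = np.zeros(shape, dtype=bool)
    for _ in range(4):
        start = center + (rng.uniform(-0.35, 0.35, size=3)) * np.array(shape)
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        length = 0.5 * min(shape)
        ts = np.linspace(0.0, length, int(4 * length))
        pts = np.round(start[None, :] + ts[:, None] * d[None, :]).astype(int)
        ok = np.all((pts >= 0) & (pts < np.array(shape)), axis=1)
        pts = pts[ok]
        tubes[pts[:, 0], pts[:, 1], pts[:, 2]] = True
    tubes = ndimage.binary_dilation(tubes)
    enhancing |= tubes
    enhancing &= brain_mask

    # one-hot tissue truth (hard compartments; no partial-volume mixing)
    probs = {
        "GM": (labels == 2).astype(np.float64),
        "WM": (labels == 3).astype(np.float64),
        "CSF": (labels == 1).astype(np.float64),
    }
    tissue_truth = TissueMaps(probs, voxel_size_mm=params.voxel_size_mm)

    means = params.tissue_means
    clean = np.full(shape, means.get("background", 0.0), dtype=np.float64)
    for t in TISSUES:
        clean[probs[t] > 0] = means[t]
    noise = rng.normal(0.0, params.noise_sigma, size=shape) if params.noise_sigma > 0 else 0.0
    t1nce_vals = np.clip(clean + noise, 0.0, 1.0)
    t1nce = Volume3D(t1nce_vals, params.voxel_size_mm)

    grades_t1ce = _draw_grades(rng, GRADE_PROBS_T1CE)
    grades_t1nce = _draw_grades(rng, GRADE_PROBS_T1NCE)

    sample = PhantomSample(
        t1nce=t1nce,
        t1ce=t1nce,  # placeholder, replaced below
        brain_mask=brain_mask,
        tissue_truth=tissue_truth,
        enhancing_mask=enhancing,
        grades_t1ce=grades_t1ce,
        grades_t1nce=grades_t1nce,
        subject_id=subject_id,
    )
    sample.t1ce = apply_enhancement(sample, params.enhancement_strength, params.contrast_shift)
    return sample


def apply_enhancement(sample: PhantomSample, delta: float, contrast_shift: float) -> Volume3D:
    """Render the contrast-enhanced volume from the sample's T1nce.

    t1ce = t1nce + delta * 1[enhancing] + contrast_shift * 1[GM], clipped to
    [0, 1].  Voxels outside the enhancing and GM compartments are untouched.
    """
    gm = sample.tissue_truth.probabilities["GM"]
    vals = sample.t1nce.values + delta * sample.enhancing_mask + contrast_shift * gm
    return sample.t1nce.with_values(np.clip(vals, 0.0, 1.0))


def degrade_quality(vol: Volume3D, grades: QualityGrades, seed: int,
                    params: DegradeParams | None = None,
                    mask: np.ndarray | None = None) -> Volume3D:
    """Realise 0/1/2 contrast/motion/noise grades as image degradation.

    Grade (0,0,0) returns the input bit-identically.  The foreground used
    for the contrast compression is `mask` if given, else voxels > 0.
    """
    params = params or DegradeParams()
    if grades.as_tuple() == (0, 0, 0):
        return vol
    rng = np.random.default_rng(seed)
    vals = vol.values.astype(np.float64, copy=True)
    fg = mask if mask is not None else vals > 0
    c = params.contrast_factors[grades.contrast]
    if c > 0:
        m = vals[fg].mean() if np.any(fg) else vals.mean()
        vals[fg] = m + (1.0 - c) * (vals[fg] - m)
    w = params.motion_sigmas[grades.motion]
    if w > 0:
        axis = int(rng.integers(0, 3))
        vals = ndimage.gaussian_filter1d(vals, sigma=w, axis=axis)
    s = params.noise_sigmas[grades.noise]
    if s > 0:
        vals = vals + rng.normal(0.0, s, size=vals.shape)
    return vol.with_values(np.clip(vals, 0.0, 1.0))


def degraded_pair(sample: PhantomSample, seed: int,
                  params: DegradeParams | None = None,
                  acquisition_noise_sigma: float = 0.02) -> tuple[Volume3D, Volume3D]:
    """Materialise the pair as acquired: per-image grade degradation plus
    independent per-acquisition thermal noise.

    The phantom's own noise_sigma models tissue texture and is shared by the
    two images of a subject (it is anatomy); each acquisition additionally
    carries its own independent Gaussian thermal noise, as two separate
    scans of one head would.  Returns (t1ce, t1nce).
    """
    t1ce = degrade_quality(sample.t1ce, sample.grades_t1ce, seed=seed * 2 + 1,
                           params=params, mask=sample.brain_mask)
    t1nce = degrade_quality(sample.t1nce, sample.grades_t1nce, seed=seed * 2 + 2,
                            params=params, mask=sample.brain_mask)
    if acquisition_noise_sigma > 0:
        rng = np.random.default_rng(seed * 2 + 3)
        out = []
        for vol in (t1ce, t1nce):
            vals = vol.values + rng.normal(0.0, acquisition_noise_sigma, vol.shape)
            out.append(vol.with_values(np.clip(vals, 0.0, 1.0)))
        t1ce, t1nce = out
    return t1ce, t1nce


def make_cohort(n_subjects: int, params: PhantomParams | None = None,
                seed: int = 0) -> list[PhantomSample]:
    """Generate a cohort of independent subjects with derived seeds."""
    base = params or PhantomParams()
    out = []
    for i in range(n_subjects):
        p = replace(base, seed=(seed * 100003 + i) % (2 ** 31))
        out.append(make_phantom(p, subject_id=f"sub-{i + 1:03d}"))
    return out
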