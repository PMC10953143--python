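"""Brain-masked image-similarity metrics (MAE, PSNR, SSIM) and paired
t-tests with Bonferroni correction.

All metrics are restricted to a brain mask: MAE and PSNR average only over
mask voxels; SSIM computes the usual sliding-window map over the whole grid
and then averages the map inside the mask.  MAE is reported in percent of
the [0, 1] intensity range; PSNR uses data_range = 1.0 by default and
returns +inf when the two images agree exactly on the mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

from .types import Volume3D


@dataclass
class SimilarityReport:
    pair_id: str
    comparison: str               # t1nce_vs_t1ce | t1nce_vs_synthetic
    mae_percent: float
    psnr_db: float
    ssim: float
    mask_voxels: int


@dataclass
class PairedTestResult:
    t: float
    p_raw: float
    p_corrected: float
    n: int
    degenerate: bool = False


def _values(x) -> np.ndarray:
    return x.values if isinstance(x, Volume3D) else np.asarray(x)


def _check_mask(mask: np.ndarray, shape) -> np.ndarray:
    mask = np.asarray(mask).astype(bool)
    if mask.shape != tuple(shape):
        raise ValueError(f"mask shape {mask.shape} does not match volume {shape}")
    if not mask.any():
        raise ValueError("empty mask")
    return mask


def mask_union(mask_a: np.ndarray, mask_b: np.ndarray) -> np.ndarray:
    """Voxelwise OR of two binary masks on the same grid."""
    a = np.asarray(mask_a).astype(bool)
    b = np.asarray(mask_b).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    return a | b


def mae(x, y, mask) -> float:
    """Mean absolute error over mask voxels, in percent of the [0,1] range."""
    xv, yv = _values(x), _values(y)
    m = _check_mask(mask, xv.shape)
    return float(100.0 * np.abs(xv[m] - yv[m]).mean())


def psnr(x, y, mask, data_range: float = 1.0) -> float:
    """10·log10(data_range² / masked MSE) in dB; +inf for identical inputs."""
    if data_range <= 0:
        raise ValueError("data_range must be positive")
    xv, yv = _values(x), _values(y)
    m = _check_mask(mask, xv.shape)
    mse = float(((xv[m] - yv[m]) ** 2).mean())
    if mse == 0.0:
        return float("inf")
    return float(10.0 * np.log10(data_range ** 2 / mse))


def ssim(x, y, mask, window: int = 7, k1: float = 0.01, k2: float = 0.03,
         data_range: float = 1.0) -> float:
    """Single-scale SSIM with a uniform cubic window, averaged inside the mask.

    Local first and second moments come from a `window`³ uniform filter with
    reflective boundaries; population (uncorrected) variances are used.
    Intensities outside the mask are zeroed first, so the score depends only
    on in-mask values.
    """
    xv = _values(x).astype(np.float64)
    yv = _values(y).astype(np.float64)
    m = _check_mask(mask, xv.shape)
    xv = xv * m
    yv = yv * m
    if any(window > s for s in xv.shape):
        raise ValueError(f"window {window} larger than volume {xv.shape}")
    c1 = (k1 * data_range) ** 2
    c2 = (k2 * data_range) ** 2
    uf = lambda a: ndimage.uniform_filter(a, size=window, mode="reflect")
    mu_x, mu_y = uf(xv), uf(yv)
    sxx = uf(xv * xv) - mu_x * mu_x
    syy = uf(yv * yv) - mu_y * mu_y
    sxy = uf(xv * yv) - mu_x * mu_y
    num = (2 * mu_x * mu_y + c1) * (2 * sxy + c2)
    den = (mu_x ** 2 + mu_y ** 2 + c1) * (sxx + syy + c2)
    return float((num / den)[m].mean())


def similarity_report(pair_id: str, comparison: str, x, y, mask) -> SimilarityReport:
    m = np.asarray(mask).astype(bool)
    return SimilarityReport(
        pair_id=pair_id,
        comparison=comparison,
        mae_percent=mae(x, y, m),
        psnr_db=psnr(x, y, m),
        ssim=ssim(x, y, m),
        mask_voxels=int(m.sum()),
    )


def paired_ttest_bonferroni(metric_vectors: dict[str, tuple[np.ndarray, np.ndarray]],
                            m: int | None = None) -> dict[str, PairedTestResult]:
    """Two-sided paired t-tests with Bonferroni correction.

    `metric_vectors` maps a comparison name to a pair of equally long
    paired sample vectors.  `m` (the number of comparisons) defaults to
    len(metric_vectors).  Zero-variance differences are flagged degenerate
    rather than assigned a p-value, except the all-zero-difference case
    where t = 0 and p = 1 are well defined.
    """
    if m is None:
        m = len(metric_vectors)
    out: dict[str, PairedTestResult] = {}
    for name, (a, b) in metric_vectors.items():
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        if a.shape != b.shape or a.ndim != 1 or a.size < 2:
            raise ValueError(f"{name}: paired vectors must be 1D, equal length >= 2")
        d = a - b
        if np.std(d, ddof=1) == 0:
            if np.allclose(d, 0):
                out[name] = PairedTestResult(t=0.0, p_raw=1.0, p_corrected=1.0,
                                             n=a.size, degenerate=False)
            else:
                out[name] = PairedTestResult(t=float("nan"), p_raw=float("nan"),
                                             p_corrected=float("nan"),
                                             n=a.size, degenerate=True)
            continue
        res = stats.ttest_rel(a, b)
        p_corr = min(1.0, m * float(res.pvalue))
        out[name] = PairedTestResult(t=float(res.statistic), p_raw=float(res.pvalue),
                                     p_corrected=p_corr, n=a.size)
    return out
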