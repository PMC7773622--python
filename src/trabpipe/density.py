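"""Apparent bone volume fraction and first-order gray-value statistics of a VOI.

On uncalibrated clinical CT the bone volume fraction is "apparent": the VOI is
split into bone and non-bone voxels by Otsu's histogram threshold and BV/TV is
the bone-voxel count over the total voxel count.  The gray-value (GV) histogram
statistics (mean, SD, variance, skewness, kurtosis) act as indirect density
descriptors.

Conventions: voxels with gray value >= threshold count as bone, where the
threshold returned by :func:`otsu_threshold` is the first bone level (last
background level + 1); ties in the between-class variance break to the lowest
level.  SD and variance use the n-1 denominator; skewness and kurtosis use
central moments with the n denominator, and kurtosis is non-excess (normal=3).
Variance is stored raw; the paper-style report layer prints it in units of 1e3.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .voi import VOIGrid

__all__ = [
    "DensityFeatures",
    "otsu_threshold",
    "bvtv",
    "gv_stats",
    "density_features",
    "DENSITY_FEATURE_NAMES",
]

DENSITY_FEATURE_NAMES = [
    "bvtv",
    "gv_mean",
    "gv_sd",
    "gv_variance",
    "gv_skewness",
    "gv_kurtosis",
]


@dataclass
class DensityFeatures:
    bvtv: float
    gv_mean: float
    gv_sd: float
    gv_variance: float
    gv_skewness: float
    gv_kurtosis: float

    def as_series(self) -> pd.Series:
        return pd.Series(
            [self.bvtv, self.gv_mean, self.gv_sd, self.gv_variance, self.gv_skewness, self.gv_kurtosis],
            index=DENSITY_FEATURE_NAMES,
        )


def otsu_threshold(gray_histogram: np.ndarray) -> int:
    """Otsu's threshold on a 256-bin gray histogram.

    Returns the first foreground (bone) level t in 1..255 such that the split
    {v < t} / {v >= t} maximizes the between-class variance
    w0*w1*(mu0 - mu1)^2; ties break to the lowest t.
    """
    hist = np.asarray(gray_histogram, dtype=float)
    if hist.ndim != 1 or hist.size != 256:
        raise ValueError("expected a 256-bin histogram")
    if (hist > 0).sum() < 2:
        raise ValueError("degenerate histogram: fewer than two occupied gray levels")
    levels = np.arange(256, dtype=float)
    total = hist.sum()
    w0 = np.cumsum(hist) / total              # mass of {v < t} indexed by t-1
    m0 = np.cumsum(hist * levels) / total     # unnormalized first moment
    mu_total = m0[-1]
    w1 = 1.0 - w0
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = m0 / w0
        mu1 = (mu_total - m0) / w1
        bcv = w0 * w1 * (mu0 - mu1) ** 2
    bcv = np.nan_to_num(bcv[:-1], nan=-1.0)   # cut after level t-1 -> threshold t = index+1
    return int(np.argmax(bcv)) + 1


def bvtv(voi: VOIGrid | np.ndarray) -> float:
    """Apparent bone volume fraction: Otsu-segmented bone voxels / total voxels."""
    values = voi.values if isinstance(voi, VOIGrid) else np.asarray(voi)
    hist = np.bincount(values.ravel().astype(np.int64), minlength=256)
    t = otsu_threshold(hist)
    return float((values >= t).mean())


def gv_stats(voi: VOIGrid | np.ndarray) -> tuple[float, float, float, float, float]:
    """Gray-value mean, SD, variance, skewness and kurtosis of all voxels.

    A constant VOI yields SD 0, variance 0 and undefined (NaN) skewness and
    kurtosis.
    """
    values = (voi.values if isinstance(voi, VOIGrid) else np.asarray(voi)).ravel().astype(float)
    mean = float(values.mean())
    if np.ptp(values) == 0:
        return mean, 0.0, 0.0, float("nan"), float("nan")
    sd = float(values.std(ddof=1))
    variance = sd**2
    skew = float(stats.skew(values, bias=True))
    kurt = float(stats.kurtosis(values, fisher=False, bias=True))
    return mean, sd, variance, skew, kurt


def density_features(voi: VOIGrid | np.ndarray) -> DensityFeatures:
    """BV/TV plus the five GV histogram statistics of a VOI."""
    mean, sd, var, skew, kurt = gv_stats(voi)
    return DensityFeatures(bvtv(voi), mean, sd, var, skew, kurt)
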