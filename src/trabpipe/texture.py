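"""3D gray-level co-occurrence matrix (GLCM) texture features of a VOI.

The VOI is quantized to 16 gray levels on fixed equal-width bins over [0, 255]
(global bins, so features are comparable across VOIs).  Co-occurrences are
counted at distance 1 along the 13 unique displacement directions of the 3D
neighborhood — the 26 nonzero offsets with components in {-1, 0, 1}, reduced
by antipodal symmetry.  Each direction's count matrix is symmetrized by adding
its transpose and then normalized to a probability matrix, giving a GLCM of
shape (16, 16, 13).  Nine Haralick descriptors are computed per direction and
averaged over the 13 directions for rotational invariance: contrast,
correlation, entropy, difference entropy, difference variance, homogeneity,
maximum probability, sum variance and the (first) information measure of
correlation.  Entropies use the natural logarithm with 0*log(0) = 0.

Dialect flags expose two common variants: ``homogeneity_dialect='matlab'``
uses 1/(1+|i-j|) instead of the inverse difference moment 1/(1+(i-j)^2), and
``sum_variance_dialect='haralick'`` centers the sum distribution on the sum
entropy (the 1973 typo-afflicted form) instead of its mean.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd

from .voi import VOIGrid

__all__ = [
    "QuantizedVOI",
    "TextureFeatures",
    "quantize",
    "unique_offsets_3d",
    "build_glcm",
    "haralick_features",
    "texture_features",
    "TEXTURE_FEATURE_NAMES",
    "N_GRAY_LEVELS",
]

N_GRAY_LEVELS = 16

TEXTURE_FEATURE_NAMES = [
    "contrast",
    "correlation",
    "entropy",
    "difference_entropy",
    "difference_variance",
    "homogeneity",
    "maximum_probability",
    "sum_variance",
    "imc",
]


@dataclass
class QuantizedVOI:
    levels: np.ndarray  # integers in 1..n_levels
    n_levels: int = N_GRAY_LEVELS


@dataclass
class TextureFeatures:
    contrast: float
    correlation: float
    entropy: float
    difference_entropy: float
    difference_variance: float
    homogeneity: float
    maximum_probability: float
    sum_variance: float
    imc: float

    def as_series(self) -> pd.Series:
        return pd.Series(
            [getattr(self, name) for name in TEXTURE_FEATURE_NAMES],
            index=TEXTURE_FEATURE_NAMES,
        )


def quantize(voi: VOIGrid | np.ndarray, n_levels: int = N_GRAY_LEVELS) -> QuantizedVOI:
    """Quantize 8-bit gray values to ``n_levels`` equal-width global bins.

    level = floor(value * n_levels / 256) + 1, so 0 -> 1 and 255 -> n_levels.
    """
    values = voi.values if isinstance(voi, VOIGrid) else np.asarray(voi)
    if values.min() < 0 or values.max() > 255:
        raise ValueError("gray values must lie in [0, 255]")
    levels = (values.astype(np.int64) * n_levels) // 256 + 1
    return QuantizedVOI(levels.astype(np.int64), n_levels)


def unique_offsets_3d() -> list[tuple[int, int, int]]:
    """The 13 unique unit displacement directions of the 26-neighborhood.

    All nonzero (row, col, slice) vectors with components in {-1, 0, 1} are
    enumerated and one of each antipodal pair is kept: the lexicographically
    positive one (first nonzero component +1).
    """
    offsets = []
    for v in product((-1, 0, 1), repeat=3):
        if v == (0, 0, 0):
            continue
        if v > tuple(-c for c in v):  # lexicographic antipodal dedup
            offsets.append(v)
    assert len(offsets) == 13
    return offsets


def build_glcm(
    q: QuantizedVOI,
    offsets: list[tuple[int, int, int]] | None = None,
    distance: int = 1,
) -> np.ndarray:
    """Per-direction symmetric co-occurrence probability matrices, (L, L, 13).

    For each direction, level pairs at the given voxel displacement are counted
    (pairs with either voxel outside the volume are skipped), the count matrix
    is symmetrized by adding its transpose, and the result is normalized so
    each direction's matrix sums to 1.
    """
    if offsets is None:
        offsets = unique_offsets_3d()
    levels = q.levels
    L = q.n_levels
    p = np.zeros((L, L, len(offsets)))
    for d, off in enumerate(offsets):
        dr, dc, ds = (distance * o for o in off)
        src = [slice(max(-dr, 0), levels.shape[0] - max(dr, 0)),
               slice(max(-dc, 0), levels.shape[1] - max(dc, 0)),
               slice(max(-ds, 0), levels.shape[2] - max(ds, 0))]
        dst = [slice(max(dr, 0), levels.shape[0] + min(dr, 0)),
               slice(max(dc, 0), levels.shape[1] + min(dc, 0)),
               slice(max(ds, 0), levels.shape[2] + min(ds, 0))]
        a = levels[tuple(src)].ravel() - 1
        b = levels[tuple(dst)].ravel() - 1
        if a.size == 0:
            raise ValueError(f"direction {off} at distance {distance} has no valid voxel pairs")
        counts = np.bincount(a * L + b, minlength=L * L).reshape(L, L).astype(float)
        counts = counts + counts.T
        p[:, :, d] = counts / counts.sum()
    return p


def _direction_features(
    p: np.ndarray,
    homogeneity_dialect: str,
    sum_variance_dialect: str,
) -> dict[str, float]:
    L = p.shape[0]
    i = np.arange(1, L + 1, dtype=float)[:, None]
    j = np.arange(1, L + 1, dtype=float)[None, :]
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    lv = np.arange(1, L + 1, dtype=float)
    mu_x = float(lv @ px)
    mu_y = float(lv @ py)
    var_x = float(((lv - mu_x) ** 2) @ px)
    var_y = float(((lv - mu_y) ** 2) @ py)

    contrast = float(((i - j) ** 2 * p).sum())
    if var_x > 0 and var_y > 0:
        correlation = float(((i - mu_x) * (j - mu_y) * p).sum() / np.sqrt(var_x * var_y))
    else:
        correlation = float("nan")
    nz = p > 0
    entropy = float(-(p[nz] * np.log(p[nz])).sum())
    if homogeneity_dialect == "matlab":
        homogeneity = float((p / (1.0 + np.abs(i - j))).sum())
    else:
        homogeneity = float((p / (1.0 + (i - j) ** 2)).sum())
    maximum_probability = float(p.max())

    # difference distribution p_{x-y}(k), k = 0..L-1
    k_diff = np.abs(np.arange(L)[:, None] - np.arange(L)[None, :])
    p_diff = np.bincount(k_diff.ravel(), weights=p.ravel(), minlength=L)
    nzd = p_diff > 0
    difference_entropy = float(-(p_diff[nzd] * np.log(p_diff[nzd])).sum())
    kd = np.arange(L, dtype=float)
    mu_d = float(kd @ p_diff)
    difference_variance = float(((kd - mu_d) ** 2) @ p_diff)

    # sum distribution p_{x+y}(k), k = 2..2L
    k_sum = (np.arange(L)[:, None] + np.arange(L)[None, :] + 2).ravel()
    p_sum = np.bincount(k_sum, weights=p.ravel(), minlength=2 * L + 1)
    ks = np.arange(p_sum.size, dtype=float)
    if sum_variance_dialect == "haralick":
        nzs = p_sum > 0
        center = float(-(p_sum[nzs] * np.log(p_sum[nzs])).sum())  # sum entropy
    else:
        center = float(ks @ p_sum)
    sum_variance = float(((ks - center) ** 2) @ p_sum)

    # information measure of correlation (IMC1)
    nzx = px > 0
    nzy = py > 0
    hx = float(-(px[nzx] * np.log(px[nzx])).sum())
    hy = float(-(py[nzy] * np.log(py[nzy])).sum())
    denom = max(hx, hy)
    if denom > 0:
        log_pxy = np.log(np.outer(px, py)[nz])
        hxy1 = float(-(p[nz] * log_pxy).sum())
        imc = (entropy - hxy1) / denom
    else:
        imc = float("nan")

    return {
        "contrast": contrast,
        "correlation": correlation,
        "entropy": entropy,
        "difference_entropy": difference_entropy,
        "difference_variance": difference_variance,
        "homogeneity": homogeneity,
        "maximum_probability": maximum_probability,
        "sum_variance": sum_variance,
        "imc": imc,
    }


def haralick_features(
    glcm: np.ndarray,
    homogeneity_dialect: str = "idm",
    sum_variance_dialect: str = "mean",
) -> TextureFeatures:
    """Nine Haralick descriptors, each averaged over the GLCM's directions.

    For a constant VOI (zero marginal variance) correlation and IMC are
    undefined and returned as NaN; the remaining descriptors are computed.
    """
    if glcm.ndim != 3:
        raise ValueError("expected a (levels, levels, n_directions) GLCM")
    if not np.allclose(glcm.sum(axis=(0, 1)), 1.0, atol=1e-8):
        raise ValueError("each direction's matrix must be normalized to sum 1")
    per_dir = [
        _direction_features(glcm[:, :, d], homogeneity_dialect, sum_variance_dialect)
        for d in range(glcm.shape[2])
    ]
    means = {name: float(np.mean([f[name] for f in per_dir])) for name in TEXTURE_FEATURE_NAMES}
    return TextureFeatures(**means)


def texture_features(
    voi: VOIGrid | np.ndarray,
    n_levels: int = N_GRAY_LEVELS,
    distance: int = 1,
    **dialects,
) -> TextureFeatures:
    """Quantize, build the 13-direction GLCM and average the nine descriptors."""
    q = quantize(voi, n_levels)
    glcm = build_glcm(q, distance=distance)
    return haralick_features(glcm, **dialects)
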