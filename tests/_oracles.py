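"""Independent brute-force oracles used across the test suite.

These are deliberately literal (nested loops, exhaustive enumeration) and
share no code with the implementation they check.
"""

from __future__ import annotations

import math

import numpy as np


def otsu_exhaustive(hist: np.ndarray) -> int:
    """Best threshold by direct enumeration of all 255 cuts."""
    hist = np.asarray(hist, dtype=float)
    total = hist.sum()
    best_t, best_v = None, -1.0
    for t in range(1, 256):
        w0 = hist[:t].sum() / total
        w1 = 1.0 - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (hist[:t] * np.arange(t)).sum() / (w0 * total)
        mu1 = (hist[t:] * np.arange(t, 256)).sum() / (w1 * total)
        v = w0 * w1 * (mu0 - mu1) ** 2
        if v > best_v + 1e-12:
            best_v, best_t = v, t
    return best_t


def glcm_bruteforce(levels: np.ndarray, offset: tuple[int, int, int], n_levels: int) -> np.ndarray:
    """Symmetrized, normalized co-occurrence matrix by a double loop over all
    voxel pairs at one displacement."""
    counts = np.zeros((n_levels, n_levels))
    nr, nc, ns = levels.shape
    dr, dc, ds = offset
    for r in range(nr):
        for c in range(nc):
            for s in range(ns):
                r2, c2, s2 = r + dr, c + dc, s + ds
                if 0 <= r2 < nr and 0 <= c2 < nc and 0 <= s2 < ns:
                    counts[levels[r, c, s] - 1, levels[r2, c2, s2] - 1] += 1
    counts = counts + counts.T
    return counts / counts.sum()


def haralick_transcription(p: np.ndarray) -> dict[str, float]:
    """Literal transcription of the nine descriptor formulas with explicit
    loops (natural log, 0*log 0 = 0)."""
    L = p.shape[0]
    px = [sum(p[i][j] for j in range(L)) for i in range(L)]
    py = [sum(p[i][j] for i in range(L)) for j in range(L)]
    mu_x = sum((i + 1) * px[i] for i in range(L))
    mu_y = sum((j + 1) * py[j] for j in range(L))
    sig_x = math.sqrt(sum((i + 1 - mu_x) ** 2 * px[i] for i in range(L)))
    sig_y = math.sqrt(sum((j + 1 - mu_y) ** 2 * py[j] for j in range(L)))

    contrast = corr = ent = homog = 0.0
    maxprob = 0.0
    hxy1 = 0.0
    for i in range(L):
        for j in range(L):
            v = p[i][j]
            contrast += (i - j) ** 2 * v
            homog += v / (1.0 + (i - j) ** 2)
            maxprob = max(maxprob, v)
            if v > 0:
                ent -= v * math.log(v)
                corr += (i + 1 - mu_x) * (j + 1 - mu_y) * v
                hxy1 -= v * math.log(px[i] * py[j])
    corr = corr / (sig_x * sig_y) if sig_x > 0 and sig_y > 0 else float("nan")

    p_diff = [0.0] * L
    for i in range(L):
        for j in range(L):
            p_diff[abs(i - j)] += p[i][j]
    diff_ent = -sum(v * math.log(v) for v in p_diff if v > 0)
    mu_d = sum(k * p_diff[k] for k in range(L))
    diff_var = sum((k - mu_d) ** 2 * p_diff[k] for k in range(L))

    p_sum = [0.0] * (2 * L + 1)
    for i in range(L):
        for j in range(L):
            p_sum[i + j + 2] += p[i][j]
    mu_s = sum(k * p_sum[k] for k in range(len(p_sum)))
    sum_var = sum((k - mu_s) ** 2 * p_sum[k] for k in range(len(p_sum)))

    hx = -sum(v * math.log(v) for v in px if v > 0)
    hy = -sum(v * math.log(v) for v in py if v > 0)
    imc = (ent - hxy1) / max(hx, hy) if max(hx, hy) > 0 else float("nan")

    return {
        "contrast": contrast,
        "correlation": corr,
        "entropy": ent,
        "difference_entropy": diff_ent,
        "difference_variance": diff_var,
        "homogeneity": homog,
        "maximum_probability": maxprob,
        "sum_variance": sum_var,
        "imc": imc,
    }


def auc_pairwise(scores, labels) -> float:
    """AUC by exhaustive pairwise concordance, ties counted 1/2."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (len(pos) * len(neg))
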