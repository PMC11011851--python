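"""Independent oracles used across the test suite.

These deliberately re-derive texture statistics, colour conversions and
rank tests from first principles (double loops, exhaustive enumeration,
textbook formulas) so the package implementations are checked against a
second, independent route.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

# offsets matching the package's angle convention (skimage's graycomatrix):
# angle -> (row step, col step) for distance 1
GLCM_OFFSETS = {0: (0, 1), 45: (1, 1), 90: (1, 0), 135: (1, -1)}

GLRLM_STEPS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def glcm_bruteforce(levels: np.ndarray, n_levels: int, angle: int, symmetric: bool = True):
    """Pair-count co-occurrence matrix by explicit pixel enumeration."""
    dr, dc = GLCM_OFFSETS[angle]
    H, W = levels.shape
    P = np.zeros((n_levels, n_levels))
    for r in range(H):
        for c in range(W):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < H and 0 <= c2 < W:
                P[levels[r, c], levels[r2, c2]] += 1
    if symmetric:
        P = P + P.T
    return P / P.sum()


def glcm_features_bruteforce(P: np.ndarray) -> dict[str, float]:
    """Double-loop evaluation of the seven co-occurrence features."""
    G = P.shape[0]
    feats = dict.fromkeys(
        ["contrast", "dissimilarity", "homogeneity", "angular_second_moment", "entropy"], 0.0
    )
    mu_i = sum(i * P[i, j] for i in range(G) for j in range(G))
    mu_j = sum(j * P[i, j] for i in range(G) for j in range(G))
    var_i = sum((i - mu_i) ** 2 * P[i, j] for i in range(G) for j in range(G))
    var_j = sum((j - mu_j) ** 2 * P[i, j] for i in range(G) for j in range(G))
    cov = 0.0
    for i in range(G):
        for j in range(G):
            p = P[i, j]
            feats["contrast"] += p * (i - j) ** 2
            feats["dissimilarity"] += p * abs(i - j)
            feats["homogeneity"] += p / (1 + (i - j) ** 2)
            feats["angular_second_moment"] += p * p
            if p > 0:
                feats["entropy"] -= p * math.log2(p)
            cov += p * (i - mu_i) * (j - mu_j)
    feats["energy"] = math.sqrt(feats["angular_second_moment"])
    denom = math.sqrt(var_i * var_j)
    feats["correlation"] = 1.0 if denom == 0 else cov / denom
    return feats


def glrlm_bruteforce(levels: np.ndarray, n_levels: int, direction: int):
    """Run counts by walking every scan line pixel by pixel."""
    H, W = levels.shape
    dr, dc = GLRLM_STEPS[direction]
    R = np.zeros((n_levels, max(H, W)), dtype=int)
    # starting points: cells with no predecessor along (dr, dc)
    starts = [
        (r, c)
        for r in range(H)
        for c in range(W)
        if not (0 <= r - dr < H and 0 <= c - dc < W)
    ]
    for r0, c0 in starts:
        r, c = r0, c0
        run_val, run_len = levels[r, c], 0
        while 0 <= r < H and 0 <= c < W:
            if levels[r, c] == run_val:
                run_len += 1
            else:
                R[run_val, run_len - 1] += 1
                run_val, run_len = levels[r, c], 1
            r, c = r + dr, c + dc
        R[run_val, run_len - 1] += 1
    return R


def glrlm_features_bruteforce(R: np.ndarray, n_pixels: int) -> dict[str, float]:
    nr = R.sum()
    sre = sum(R[g, l] / (l + 1) ** 2 for g in range(R.shape[0]) for l in range(R.shape[1])) / nr
    lre = sum(R[g, l] * (l + 1) ** 2 for g in range(R.shape[0]) for l in range(R.shape[1])) / nr
    gln = sum(R[g, :].sum() ** 2 for g in range(R.shape[0])) / nr
    rln = sum(R[:, l].sum() ** 2 for l in range(R.shape[1])) / nr
    return {
        "short_run_emphasis": sre,
        "long_run_emphasis": lre,
        "gray_level_nonuniformity": gln,
        "run_length_nonuniformity": rln,
        "run_percentage": nr / n_pixels,
    }


def srgb_to_lab_reference(rgb8: tuple[int, int, int]) -> tuple[float, float, float]:
    """Textbook sRGB -> XYZ (D65) -> CIELAB chain for one pixel."""

    def inv_gamma(u):
        u = u / 255.0
        return u / 12.92 if u <= 0.04045 else ((u + 0.055) / 1.055) ** 2.4

    r, g, b = (inv_gamma(v) for v in rgb8)
    M = [
        (0.412456439089692, 0.357576077643909, 0.180437483266399),
        (0.212672851405623, 0.715152155287818, 0.072174993306560),
        (0.019333895582329, 0.119192025881303, 0.950304078536368),
    ]
    X, Y, Z = (m[0] * r + m[1] * g + m[2] * b for m in M)
    Xn, Yn, Zn = 0.95047, 1.0, 1.08883

    def f(t):
        return t ** (1 / 3) if t > (6 / 29) ** 3 else t / (3 * (6 / 29) ** 2) + 4 / 29

    fx, fy, fz = f(X / Xn), f(Y / Yn), f(Z / Zn)
    return 116 * fy - 16, 500 * (fx - fy), 200 * (fy - fz)


def mann_whitney_exact_oracle(x, y) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney p by enumerating all label splits."""
    x, y = list(x), list(y)
    pooled = x + y
    n1, n2 = len(x), len(y)

    def u_stat(sample_x, sample_y):
        return sum(
            1.0 if a > b else (0.5 if a == b else 0.0) for a in sample_x for b in sample_y
        )

    u_obs = u_stat(x, y)
    mu = n1 * n2 / 2.0
    count = total = 0
    for combo in itertools.combinations(range(n1 + n2), n1):
        xs = [pooled[i] for i in combo]
        ys = [pooled[i] for i in range(n1 + n2) if i not in combo]
        u = u_stat(xs, ys)
        total += 1
        if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
            count += 1
    return u_obs, count / total
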