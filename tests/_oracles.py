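"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's implementation paths: GLCM
statistics are computed from an explicitly enumerated co-occurrence
matrix with plain numpy formulas, Laws responses from a dense 3D kernel
correlation, AUC from explicit concordant-pair counting, and the
rank-sum p-value from exhaustive enumeration of group assignments.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy import ndimage

from octradiomics.texture_bank import LAWS_KERNELS, OFFSETS_3D


def glcm_matrix(codes, valid, center, half, offsets, n_levels):
    """Pooled symmetric co-occurrence matrix at one voxel, by nested loops."""
    Z, Y, X = codes.shape
    cz, cy, cx = center
    P = np.zeros((n_levels, n_levels))
    for dz in range(-half, half + 1):
        for dy in range(-half, half + 1):
            for dx in range(-half, half + 1):
                uz, uy, ux = cz + dz, cy + dy, cx + dx
                if not (0 <= uz < Z and 0 <= uy < Y and 0 <= ux < X):
                    continue
                if not valid[uz, uy, ux]:
                    continue
                for oz, oy, ox in offsets:
                    vz, vy, vx = uz + oz, uy + oy, ux + ox
                    if not (0 <= vz < Z and 0 <= vy < Y and 0 <= vx < X):
                        continue
                    if abs(vz - cz) > half or abs(vy - cy) > half or abs(vx - cx) > half:
                        continue
                    if not valid[vz, vy, vx]:
                        continue
                    i, j = codes[uz, uy, ux], codes[vz, vy, vx]
                    P[i, j] += 1
                    P[j, i] += 1
    total = P.sum()
    return P / total if total else P


def haralick_from_glcm(P):
    """The 13 classical statistics from a normalized symmetric GLCM."""
    L = P.shape[0]
    i, j = np.indices((L, L))
    px = P.sum(axis=1)
    idx = np.arange(L)
    mu = (idx * px).sum()
    var = ((idx - mu) ** 2 * px).sum()

    def ent(p):
        p = p[p > 0]
        return -(p * np.log(p)).sum()

    p_sum = np.zeros(2 * L - 1)
    p_diff = np.zeros(L)
    for a in range(L):
        for b in range(L):
            p_sum[a + b] += P[a, b]
            p_diff[abs(a - b)] += P[a, b]
    sa = (np.arange(2 * L - 1) * p_sum).sum()
    da = (np.arange(L) * p_diff).sum()
    hxy = ent(P.ravel())
    hx = ent(px)
    pxpy = np.outer(px, px)
    mask = pxpy > 0
    hxy1 = -(P[mask] * np.log(pxpy[mask])).sum()
    hxy2 = ent(pxpy.ravel())
    corr = ((i * j * P).sum() - mu * mu) / var if var > 0 else 0.0
    arg = 1 - np.exp(-2 * (hxy2 - hxy))
    return {
        "energy": (P**2).sum(),
        "contrast": ((i - j) ** 2 * P).sum(),
        "correlation": corr,
        "variance": var,
        "homogeneity": (P / (1 + (i - j) ** 2)).sum(),
        "sum_average": sa,
        "sum_variance": ((np.arange(2 * L - 1) - sa) ** 2 * p_sum).sum(),
        "sum_entropy": ent(p_sum),
        "entropy": hxy,
        "difference_variance": ((np.arange(L) - da) ** 2 * p_diff).sum(),
        "difference_entropy": ent(p_diff),
        "imc1": (hxy - hxy1) / hx if hx > 0 else 0.0,
        "imc2": np.sqrt(arg) if arg > 0 else 0.0,
    }


def haralick_oracle(codes, valid, half, n_levels, offsets=OFFSETS_3D):
    """All 13 stat maps by per-voxel nested-loop GLCM enumeration."""
    from octradiomics.texture_bank import HARALICK_STATS

    out = {name: np.full(codes.shape, np.nan) for name in HARALICK_STATS}
    for center in itertools.product(*(range(s) for s in codes.shape)):
        if not valid[center]:
            continue
        P = glcm_matrix(codes, valid, center, half, offsets, n_levels)
        if P.sum() == 0:
            continue
        stats = haralick_from_glcm(P)
        for name in HARALICK_STATS:
            out[name][center] = stats[name]
    return out


def laws_dense_response(volume, triplet):
    """Dense 3D correlation with the outer-product kernel (axes: slice, depth, ascan)."""
    kd = LAWS_KERNELS[triplet[0:2]]
    ka = LAWS_KERNELS[triplet[2:4]]
    ks = LAWS_KERNELS[triplet[4:6]]
    kernel = np.einsum("d,a,s->sda", kd, ka, ks)
    return ndimage.correlate(np.asarray(volume, dtype=float), kernel, mode="reflect")


def auc_pairs(scores, labels):
    """AUC by explicit concordant-pair counting with ties worth 1/2."""
    scores = np.asarray(scores, dtype=float)
    pos = np.asarray(labels).astype(bool)
    num = 0.0
    n = 0
    for sp in scores[pos]:
        for sn in scores[~pos]:
            num += 1.0 if sp > sn else (0.5 if sp == sn else 0.0)
            n += 1
    return num / n


def ranksum_exact_p(x, y):
    """Two-sided exact rank-sum p-value by enumerating all group assignments."""
    pooled = np.concatenate([x, y])
    n = len(x)
    ranks = {v: r for r, v in enumerate(sorted(pooled), start=1)}
    observed = sum(ranks[v] for v in x)
    mean = n * (len(pooled) + 1) / 2
    stats = []
    for combo in itertools.combinations(range(len(pooled)), n):
        stats.append(sum(ranks[pooled[i]] for i in combo))
    stats = np.array(stats, dtype=float)
    return np.mean(np.abs(stats - mean) >= abs(observed - mean) - 1e-12)
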