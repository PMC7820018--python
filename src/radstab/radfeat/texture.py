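"""Gray-level texture matrices and their feature sets.

Conventions (the common 3D defaults of the radiomics literature):

* GLCM and GLRLM are built at distance 1 along each of the 13 unique 3D
  direction vectors; a feature is computed per direction and the values
  averaged over directions ("3D average" aggregation).  GLCM matrices are
  symmetric and normalized per direction.
* GLSZM zones and GLDM/NGTDM neighborhoods use 26-connectivity.
* Degenerate inputs take their analytic limits instead of crashing: a
  single-gray-level ROI gives JointEnergy 1, JointEntropy 0, Contrast 0,
  Correlation 1, and every "non-uniformity normalized" equal to 1; each
  division is guarded with the documented limit value.

The feature rosters and formulas follow the public reference definitions
(22 GLCM, 16 GLRLM, 16 GLSZM, 5 NGTDM, 14 GLDM features).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .preprocess import DiscretizedRoi

__all__ = [
    "DIRECTIONS_13",
    "GLCM_NAMES",
    "GLRLM_NAMES",
    "GLSZM_NAMES",
    "NGTDM_NAMES",
    "GLDM_NAMES",
    "glcm_features",
    "glrlm_features",
    "glszm_features",
    "ngtdm_features",
    "gldm_features",
]

#: The 13 unique 3D direction vectors in (z, y, x) offset order — one
#: representative per antipodal pair (first nonzero component positive).
DIRECTIONS_13: list[tuple[int, int, int]] = [
    (dz, dy, dx)
    for dz in (0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if (dz > 0) or (dz == 0 and dy > 0) or (dz == 0 and dy == 0 and dx > 0)
]
assert len(DIRECTIONS_13) == 13

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)

_OFFSETS_26 = [
    (dz, dy, dx)
    for dz in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if (dz, dy, dx) != (0, 0, 0)
]


def _bounded_labels(droi: DiscretizedRoi) -> np.ndarray:
    """Crop the level grid to the mask bounding box (0 = outside ROI)."""
    zs, ys, xs = np.nonzero(droi.mask)
    sl = tuple(slice(a.min(), a.max() + 1) for a in (zs, ys, xs))
    return droi.labels[sl]


def _shift(a: np.ndarray, d: tuple[int, int, int]) -> np.ndarray:
    """shifted[p] = a[p - d], zero outside the grid."""
    out = np.zeros_like(a)
    dst, src = [], []
    for o, n in zip(d, a.shape):
        if abs(o) >= n:
            return out
        if o >= 0:
            dst.append(slice(o, n))
            src.append(slice(0, n - o))
        else:
            dst.append(slice(0, n + o))
            src.append(slice(-o, n))
    out[tuple(dst)] = a[tuple(src)]
    return out


def _plog2(p: np.ndarray) -> np.ndarray:
    """p * log2(p) with the 0 log 0 = 0 convention."""
    out = np.zeros_like(p, dtype=float)
    pos = p > 0
    out[pos] = p[pos] * np.log2(p[pos])
    return out


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

GLCM_NAMES = [
    "Autocorrelation",
    "ClusterProminence",
    "ClusterShade",
    "ClusterTendency",
    "Contrast",
    "Correlation",
    "DifferenceAverage",
    "DifferenceEntropy",
    "DifferenceVariance",
    "Id",
    "Idm",
    "Idmn",
    "Idn",
    "Imc1",
    "Imc2",
    "InverseVariance",
    "JointAverage",
    "JointEnergy",
    "JointEntropy",
    "MaximumProbability",
    "SumEntropy",
    "SumSquares",
]


def _glcm_matrix(L: np.ndarray, d: tuple[int, int, int], ng: int) -> np.ndarray | None:
    """Symmetric normalized co-occurrence matrix for one direction."""
    b = _shift(L, d)
    valid = (L > 0) & (b > 0)
    if not valid.any():
        return None
    a = L[valid] - 1
    c = b[valid] - 1
    counts = np.bincount(a * ng + c, minlength=ng * ng).reshape(ng, ng).astype(float)
    counts = counts + counts.T
    return counts / counts.sum()


def _glcm_features_one(p: np.ndarray, ng: int) -> dict[str, float]:
    i = np.arange(1, ng + 1, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    ux = float(np.sum(i * px))
    uy = float(np.sum(i * py))
    sx = float(np.sqrt(np.sum((i - ux) ** 2 * px)))
    sy = float(np.sqrt(np.sum((i - uy) ** 2 * py)))

    # diagonal (difference) and cross-diagonal (sum) probabilities
    diff_idx = np.abs(ii - jj).astype(int)
    sum_idx = (ii + jj).astype(int)
    p_diff = np.bincount(diff_idx.ravel(), weights=p.ravel(), minlength=ng)
    p_sum = np.bincount(sum_idx.ravel(), weights=p.ravel(), minlength=2 * ng + 1)[2:]
    kd = np.arange(ng, dtype=float)
    ks = np.arange(2, 2 * ng + 1, dtype=float)

    hxy = float(-np.sum(_plog2(p)))
    hx = float(-np.sum(_plog2(px)))
    hy = float(-np.sum(_plog2(py)))
    pxpy = np.outer(px, py)
    with np.errstate(divide="ignore"):
        log_pxpy = np.where(pxpy > 0, np.log2(np.where(pxpy > 0, pxpy, 1.0)), 0.0)
    hxy1 = float(-np.sum(p * log_pxpy))
    hxy2 = float(-np.sum(_plog2(pxpy)))

    da = float(np.sum(kd * p_diff))
    corr_den = sx * sy
    corr_num = float(np.sum(p * ii * jj)) - ux * uy
    imc2_inner = max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))
    off = ii != jj

    return {
        "Autocorrelation": float(np.sum(p * ii * jj)),
        "ClusterProminence": float(np.sum(p * (ii + jj - ux - uy) ** 4)),
        "ClusterShade": float(np.sum(p * (ii + jj - ux - uy) ** 3)),
        "ClusterTendency": float(np.sum(p * (ii + jj - ux - uy) ** 2)),
        "Contrast": float(np.sum(p * (ii - jj) ** 2)),
        "Correlation": float(corr_num / corr_den) if corr_den > 0 else 1.0,
        "DifferenceAverage": da,
        "DifferenceEntropy": float(-np.sum(_plog2(p_diff))),
        "DifferenceVariance": float(np.sum((kd - da) ** 2 * p_diff)),
        "Id": float(np.sum(p / (1.0 + np.abs(ii - jj)))),
        "Idm": float(np.sum(p / (1.0 + (ii - jj) ** 2))),
        "Idmn": float(np.sum(p / (1.0 + ((ii - jj) / ng) ** 2))),
        "Idn": float(np.sum(p / (1.0 + np.abs(ii - jj) / ng))),
        "Imc1": float((hxy - hxy1) / max(hx, hy)) if max(hx, hy) > 0 else 0.0,
        "Imc2": float(np.sqrt(imc2_inner)),
        "InverseVariance": float(np.sum(p[off] / (ii[off] - jj[off]) ** 2)),
        "JointAverage": ux,
        "JointEnergy": float(np.sum(p**2)),
        "JointEntropy": hxy,
        "MaximumProbability": float(p.max()),
        "SumEntropy": float(-np.sum(_plog2(p_sum))),
        "SumSquares": float(np.sum(p * (ii - ux) ** 2)),
    }


def _glcm_degenerate() -> dict[str, float]:
    """Analytic limits for an ROI with no valid voxel pairs."""
    vals = dict.fromkeys(GLCM_NAMES, 0.0)
    vals.update(
        JointEnergy=1.0,
        MaximumProbability=1.0,
        Correlation=1.0,
        Id=1.0,
        Idm=1.0,
        Idmn=1.0,
        Idn=1.0,
        JointAverage=1.0,
        Autocorrelation=1.0,
    )
    return vals


def glcm_features(droi: DiscretizedRoi) -> dict[str, float]:
    """The 22 co-occurrence features, averaged over the 13 directions."""
    L = _bounded_labels(droi)
    ng = droi.n_levels
    per_dir = []
    for d in DIRECTIONS_13:
        p = _glcm_matrix(L, d, ng)
        if p is not None:
            per_dir.append(_glcm_features_one(p, ng))
    if not per_dir:
        return _glcm_degenerate()
    return {k: float(np.mean([f[k] for f in per_dir])) for k in GLCM_NAMES}


# ---------------------------------------------------------------------------
# GLRLM
# ---------------------------------------------------------------------------

GLRLM_NAMES = [
    "ShortRunEmphasis",
    "LongRunEmphasis",
    "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized",
    "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized",
    "RunPercentage",
    "GrayLevelVariance",
    "RunVariance",
    "RunEntropy",
    "LowGrayLevelRunEmphasis",
    "HighGrayLevelRunEmphasis",
    "ShortRunLowGrayLevelEmphasis",
    "ShortRunHighGrayLevelEmphasis",
    "LongRunLowGrayLevelEmphasis",
    "LongRunHighGrayLevelEmphasis",
]


def _runs_along(L: np.ndarray, d: tuple[int, int, int]) -> tuple[np.ndarray, np.ndarray]:
    """(levels, lengths) of all maximal same-level runs along direction d.

    Run starts/ends are voxels whose predecessor/successor along d breaks
    the run; matching uses the line invariant p x d (constant along a
    line) with the in-line coordinate t = p . d.
    """
    prev = _shift(L, d)
    nxt = _shift(L, tuple(-c for c in d))
    inm = L > 0
    start = inm & (prev != L)
    end = inm & (nxt != L)
    zs, ys, xs = np.nonzero(start)
    ze, ye, xe = np.nonzero(end)
    dz, dy, dx = d

    def line_key(z, y, x):
        return (y * dx - x * dy, x * dz - z * dx, z * dy - y * dz)

    t_s = zs * dz + ys * dy + xs * dx
    t_e = ze * dz + ye * dy + xe * dx
    cs = line_key(zs, ys, xs)
    ce = line_key(ze, ye, xe)
    ks = np.lexsort((t_s, cs[2], cs[1], cs[0]))
    ke = np.lexsort((t_e, ce[2], ce[1], ce[0]))
    levels = L[zs, ys, xs][ks]
    step = dz * dz + dy * dy + dx * dx
    lengths = (t_e[ke] - t_s[ks]) // step + 1
    return levels, lengths


def _rl_matrix(L: np.ndarray, d: tuple[int, int, int], ng: int) -> np.ndarray:
    levels, lengths = _runs_along(L, d)
    nr_max = int(lengths.max()) if lengths.size else 1
    counts = np.bincount(
        (levels - 1) * nr_max + (lengths - 1), minlength=ng * nr_max
    ).astype(float)
    return counts.reshape(ng, nr_max)


def _rl_features_one(R: np.ndarray, n_voxels: int) -> dict[str, float]:
    ng, nr_len = R.shape
    i = np.arange(1, ng + 1, dtype=float)
    j = np.arange(1, nr_len + 1, dtype=float)
    nr = R.sum()
    p = R / nr
    r_i = R.sum(axis=1)
    r_j = R.sum(axis=0)
    mu_i = float(np.sum(p.sum(axis=1) * i))
    mu_j = float(np.sum(p.sum(axis=0) * j))
    return {
        "ShortRunEmphasis": float(np.sum(r_j / j**2) / nr),
        "LongRunEmphasis": float(np.sum(r_j * j**2) / nr),
        "GrayLevelNonUniformity": float(np.sum(r_i**2) / nr),
        "GrayLevelNonUniformityNormalized": float(np.sum(r_i**2) / nr**2),
        "RunLengthNonUniformity": float(np.sum(r_j**2) / nr),
        "RunLengthNonUniformityNormalized": float(np.sum(r_j**2) / nr**2),
        "RunPercentage": float(nr / n_voxels),
        "GrayLevelVariance": float(np.sum(p.sum(axis=1) * (i - mu_i) ** 2)),
        "RunVariance": float(np.sum(p.sum(axis=0) * (j - mu_j) ** 2)),
        "RunEntropy": float(-np.sum(_plog2(p))),
        "LowGrayLevelRunEmphasis": float(np.sum(r_i / i**2) / nr),
        "HighGrayLevelRunEmphasis": float(np.sum(r_i * i**2) / nr),
        "ShortRunLowGrayLevelEmphasis": float(np.sum(R / np.outer(i**2, j**2)) / nr),
        "ShortRunHighGrayLevelEmphasis": float(np.sum(R * np.outer(i**2, 1.0 / j**2)) / nr),
        "LongRunLowGrayLevelEmphasis": float(np.sum(R * np.outer(1.0 / i**2, j**2)) / nr),
        "LongRunHighGrayLevelEmphasis": float(np.sum(R * np.outer(i**2, j**2)) / nr),
    }


def glrlm_features(droi: DiscretizedRoi) -> dict[str, float]:
    """The 16 run-length features, averaged over the 13 directions."""
    L = _bounded_labels(droi)
    per_dir = [
        _rl_features_one(_rl_matrix(L, d, droi.n_levels), droi.n_voxels)
        for d in DIRECTIONS_13
    ]
    return {k: float(np.mean([f[k] for f in per_dir])) for k in GLRLM_NAMES}


# ---------------------------------------------------------------------------
# GLSZM
# ---------------------------------------------------------------------------

GLSZM_NAMES = [
    "SmallAreaEmphasis",
    "LargeAreaEmphasis",
    "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized",
    "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized",
    "ZonePercentage",
    "GrayLevelVariance",
    "ZoneVariance",
    "ZoneEntropy",
    "LowGrayLevelZoneEmphasis",
    "HighGrayLevelZoneEmphasis",
    "SmallAreaLowGrayLevelEmphasis",
    "SmallAreaHighGrayLevelEmphasis",
    "LargeAreaLowGrayLevelEmphasis",
    "LargeAreaHighGrayLevelEmphasis",
]


def _szm(L: np.ndarray, ng: int) -> np.ndarray:
    """Size-zone matrix: 26-connected zones per gray level."""
    zones: list[tuple[int, int]] = []
    max_size = 1
    for lvl in range(1, ng + 1):
        sel = L == lvl
        if not sel.any():
            continue
        lab, n = ndimage.label(sel, structure=_STRUCT_26)
        sizes = np.bincount(lab.ravel())[1:]
        for s in sizes:
            zones.append((lvl, int(s)))
            max_size = max(max_size, int(s))
    S = np.zeros((ng, max_size))
    for lvl, s in zones:
        S[lvl - 1, s - 1] += 1
    return S


def glszm_features(droi: DiscretizedRoi) -> dict[str, float]:
    """The 16 size-zone features (single matrix, 26-connectivity)."""
    L = _bounded_labels(droi)
    S = _szm(L, droi.n_levels)
    ng, ns = S.shape
    i = np.arange(1, ng + 1, dtype=float)
    j = np.arange(1, ns + 1, dtype=float)
    nz = S.sum()
    p = S / nz
    s_i = S.sum(axis=1)
    s_j = S.sum(axis=0)
    mu_i = float(np.sum(p.sum(axis=1) * i))
    mu_j = float(np.sum(p.sum(axis=0) * j))
    return {
        "SmallAreaEmphasis": float(np.sum(s_j / j**2) / nz),
        "LargeAreaEmphasis": float(np.sum(s_j * j**2) / nz),
        "GrayLevelNonUniformity": float(np.sum(s_i**2) / nz),
        "GrayLevelNonUniformityNormalized": float(np.sum(s_i**2) / nz**2),
        "SizeZoneNonUniformity": float(np.sum(s_j**2) / nz),
        "SizeZoneNonUniformityNormalized": float(np.sum(s_j**2) / nz**2),
        "ZonePercentage": float(nz / droi.n_voxels),
        "GrayLevelVariance": float(np.sum(p.sum(axis=1) * (i - mu_i) ** 2)),
        "ZoneVariance": float(np.sum(p.sum(axis=0) * (j - mu_j) ** 2)),
        "ZoneEntropy": float(-np.sum(_plog2(p))),
        "LowGrayLevelZoneEmphasis": float(np.sum(s_i / i**2) / nz),
        "HighGrayLevelZoneEmphasis": float(np.sum(s_i * i**2) / nz),
        "SmallAreaLowGrayLevelEmphasis": float(np.sum(S / np.outer(i**2, j**2)) / nz),
        "SmallAreaHighGrayLevelEmphasis": float(np.sum(S * np.outer(i**2, 1.0 / j**2)) / nz),
        "LargeAreaLowGrayLevelEmphasis": float(np.sum(S * np.outer(1.0 / i**2, j**2)) / nz),
        "LargeAreaHighGrayLevelEmphasis": float(np.sum(S * np.outer(i**2, j**2)) / nz),
    }


# ---------------------------------------------------------------------------
# NGTDM
# ---------------------------------------------------------------------------

NGTDM_NAMES = ["Coarseness", "Contrast", "Busyness", "Complexity", "Strength"]

#: Documented cap for Coarseness when its denominator vanishes.
COARSENESS_CAP = 1e6


def _ngtdm(L: np.ndarray, ng: int) -> tuple[np.ndarray, np.ndarray, int]:
    """(n_i counts, s_i sums, Nvp) over voxels with >= 1 in-mask neighbor."""
    inm = L > 0
    nbr_sum = np.zeros(L.shape, dtype=float)
    nbr_cnt = np.zeros(L.shape, dtype=float)
    for d in _OFFSETS_26:
        sh = _shift(L, d)
        nbr_sum += sh
        nbr_cnt += _shift(inm.astype(np.int8), d)
    ok = inm & (nbr_cnt > 0)
    mean_nbr = np.zeros(L.shape)
    mean_nbr[ok] = nbr_sum[ok] / nbr_cnt[ok]
    diff = np.abs(L - mean_nbr)
    n_i = np.zeros(ng)
    s_i = np.zeros(ng)
    lv = L[ok]
    np.add.at(n_i, lv - 1, 1.0)
    np.add.at(s_i, lv - 1, diff[ok])
    return n_i, s_i, int(ok.sum())


def ngtdm_features(droi: DiscretizedRoi) -> dict[str, float]:
    """The 5 neighborhood gray-tone difference features."""
    L = _bounded_labels(droi)
    ng = droi.n_levels
    n_i, s_i, nvp = _ngtdm(L, ng)
    if nvp == 0:
        return {
            "Coarseness": COARSENESS_CAP,
            "Contrast": 0.0,
            "Busyness": 0.0,
            "Complexity": 0.0,
            "Strength": 0.0,
        }
    p_i = n_i / nvp
    i = np.arange(1, ng + 1, dtype=float)
    present = p_i > 0
    ngp = int(present.sum())

    coarse_den = float(np.sum(p_i * s_i))
    coarseness = 1.0 / coarse_den if coarse_den > 0 else COARSENESS_CAP

    if ngp > 1:
        pi, pj = np.meshgrid(p_i[present], p_i[present], indexing="ij")
        iv, jv = np.meshgrid(i[present], i[present], indexing="ij")
        contrast = (
            float(np.sum(pi * pj * (iv - jv) ** 2)) / (ngp * (ngp - 1))
        ) * (float(np.sum(s_i)) / nvp)
        busy_den = float(np.sum(np.abs(iv * pi - jv * pj)))
        busyness = coarse_den / busy_den if busy_den > 0 else 0.0
        complexity = float(
            np.sum(
                np.abs(iv - jv)
                * (pi * s_i[present][:, None] + pj * s_i[present][None, :])
                / (pi + pj)
            )
        ) / nvp
        strength_den = float(np.sum(s_i))
        strength = (
            float(np.sum((pi + pj) * (iv - jv) ** 2)) / strength_den
            if strength_den > 0
            else 0.0
        )
    else:
        contrast = 0.0
        busyness = 0.0
        complexity = 0.0
        strength = 0.0
    return {
        "Coarseness": coarseness,
        "Contrast": contrast,
        "Busyness": busyness,
        "Complexity": complexity,
        "Strength": strength,
    }


# ---------------------------------------------------------------------------
# GLDM
# ---------------------------------------------------------------------------

GLDM_NAMES = [
    "SmallDependenceEmphasis",
    "LargeDependenceEmphasis",
    "GrayLevelNonUniformity",
    "DependenceNonUniformity",
    "DependenceNonUniformityNormalized",
    "GrayLevelVariance",
    "DependenceVariance",
    "DependenceEntropy",
    "LowGrayLevelEmphasis",
    "HighGrayLevelEmphasis",
    "SmallDependenceLowGrayLevelEmphasis",
    "SmallDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis",
    "LargeDependenceHighGrayLevelEmphasis",
]


def _gldm(L: np.ndarray, ng: int) -> np.ndarray:
    """Dependence matrix, alpha = 0: a neighbor is dependent iff its level
    equals the center's; dependence size j = 1 + #dependent neighbors."""
    inm = L > 0
    dep = np.zeros(L.shape, dtype=np.int64)
    for d in _OFFSETS_26:
        sh = _shift(L, d)
        dep += (sh == L) & (sh > 0)
    j = dep[inm] + 1
    lv = L[inm]
    nd_max = int(j.max())
    counts = np.bincount((lv - 1) * nd_max + (j - 1), minlength=ng * nd_max).astype(float)
    return counts.reshape(ng, nd_max)


def gldm_features(droi: DiscretizedRoi) -> dict[str, float]:
    """The 14 gray-level dependence features."""
    L = _bounded_labels(droi)
    D = _gldm(L, droi.n_levels)
    ng, nd = D.shape
    i = np.arange(1, ng + 1, dtype=float)
    j = np.arange(1, nd + 1, dtype=float)
    nz = D.sum()  # == number of in-mask voxels
    p = D / nz
    d_i = D.sum(axis=1)
    d_j = D.sum(axis=0)
    mu_i = float(np.sum(p.sum(axis=1) * i))
    mu_j = float(np.sum(p.sum(axis=0) * j))
    return {
        "SmallDependenceEmphasis": float(np.sum(d_j / j**2) / nz),
        "LargeDependenceEmphasis": float(np.sum(d_j * j**2) / nz),
        "GrayLevelNonUniformity": float(np.sum(d_i**2) / nz),
        "DependenceNonUniformity": float(np.sum(d_j**2) / nz),
        "DependenceNonUniformityNormalized": float(np.sum(d_j**2) / nz**2),
        "GrayLevelVariance": float(np.sum(p.sum(axis=1) * (i - mu_i) ** 2)),
        "DependenceVariance": float(np.sum(p.sum(axis=0) * (j - mu_j) ** 2)),
        "DependenceEntropy": float(-np.sum(_plog2(p))),
        "LowGrayLevelEmphasis": float(np.sum(d_i / i**2) / nz),
        "HighGrayLevelEmphasis": float(np.sum(d_i * i**2) / nz),
        "SmallDependenceLowGrayLevelEmphasis": float(np.sum(D / np.outer(i**2, j**2)) / nz),
        "SmallDependenceHighGrayLevelEmphasis": float(
            np.sum(D * np.outer(i**2, 1.0 / j**2)) / nz
        ),
        "LargeDependenceLowGrayLevelEmphasis": float(
            np.sum(D * np.outer(1.0 / i**2, j**2)) / nz
        ),
        "LargeDependenceHighGrayLevelEmphasis": float(np.sum(D * np.outer(i**2, j**2)) / nz),
    }
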