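"""Gray-level texture matrices and their standardized features.

All matrices are built in 3D over the distance-1, 26-connectivity
neighborhood (13 unique directions for the pairwise matrices).  Gray
levels are the integer bins produced by fixed-bin-number discretization;
formulas use the actual level values, never a compacted re-indexing.
Conventions follow the common reference-extractor defaults: symmetric
GLCM with per-direction feature computation averaged over directions,
GLRLM likewise direction-averaged, single 26-connected GLSZM, GLDM with
dependence threshold alpha = 0 (dependence size counts the centre voxel
plus its equal-level in-ROI neighbours), and NGTDM neighbourhood
averages restricted to in-ROI voxels.

Feature class sizes: GLCM 24, GLRLM 16, GLSZM 16, GLDM 14, NGTDM 5.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

__all__ = [
    "DIRECTIONS_13",
    "OFFSETS_26",
    "glcm_features",
    "glrlm_features",
    "glszm_features",
    "gldm_features",
    "ngtdm_features",
    "texture_features",
    "GLCM_NAMES",
    "GLRLM_NAMES",
    "GLSZM_NAMES",
    "GLDM_NAMES",
    "NGTDM_NAMES",
]

_EPS = np.spacing(1.0)

# 13 unique directions of the 26-neighborhood (one per +/- pair)
DIRECTIONS_13 = [
    (dx, dy, dz)
    for dz in (0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if (dz, dy, dx) > (0, 0, 0)
]
# all 26 neighbor offsets
OFFSETS_26 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
]

GLCM_NAMES = [
    "Autocorrelation", "ClusterProminence", "ClusterShade", "ClusterTendency",
    "Contrast", "Correlation", "DifferenceAverage", "DifferenceEntropy",
    "DifferenceVariance", "Dissimilarity", "Id", "Idm", "Idmn", "Idn",
    "Imc1", "Imc2", "InverseVariance", "JointAverage", "JointEnergy",
    "JointEntropy", "MCC", "MaximumProbability", "SumEntropy", "SumSquares",
]
GLRLM_NAMES = [
    "ShortRunEmphasis", "LongRunEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized", "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized", "RunPercentage", "GrayLevelVariance",
    "RunVariance", "RunEntropy", "LowGrayLevelRunEmphasis",
    "HighGrayLevelRunEmphasis", "ShortRunLowGrayLevelEmphasis",
    "ShortRunHighGrayLevelEmphasis", "LongRunLowGrayLevelEmphasis",
    "LongRunHighGrayLevelEmphasis",
]
GLSZM_NAMES = [
    "SmallAreaEmphasis", "LargeAreaEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized", "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized", "ZonePercentage", "GrayLevelVariance",
    "ZoneVariance", "ZoneEntropy", "LowGrayLevelZoneEmphasis",
    "HighGrayLevelZoneEmphasis", "SmallAreaLowGrayLevelEmphasis",
    "SmallAreaHighGrayLevelEmphasis", "LargeAreaLowGrayLevelEmphasis",
    "LargeAreaHighGrayLevelEmphasis",
]
GLDM_NAMES = [
    "SmallDependenceEmphasis", "LargeDependenceEmphasis",
    "GrayLevelNonUniformity", "DependenceNonUniformity",
    "DependenceNonUniformityNormalized", "GrayLevelVariance",
    "DependenceVariance", "DependenceEntropy", "LowGrayLevelEmphasis",
    "HighGrayLevelEmphasis", "SmallDependenceLowGrayLevelEmphasis",
    "SmallDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis",
    "LargeDependenceHighGrayLevelEmphasis",
]
NGTDM_NAMES = ["Coarseness", "Contrast", "Busyness", "Complexity", "Strength"]


def _crop(levels: np.ndarray) -> np.ndarray:
    """Tight bounding-box crop of the nonzero (in-ROI) region."""
    idx = np.nonzero(levels)
    if len(idx[0]) == 0:
        raise ValueError("empty ROI")
    sl = tuple(slice(int(a.min()), int(a.max()) + 1) for a in idx)
    return levels[sl]


def _pair_slices(shape, offset):
    """Slices (sa, sb) so arr[sa] and arr[sb] are offset-shifted pairs."""
    sa, sb = [], []
    for n, d in zip(shape, offset):
        if d >= 0:
            sa.append(slice(0, n - d))
            sb.append(slice(d, n))
        else:
            sa.append(slice(-d, n))
            sb.append(slice(0, n + d))
    return tuple(sa), tuple(sb)


# ---------------------------------------------------------------- GLCM


def glcm_matrices(levels: np.ndarray, n_levels: int) -> list[np.ndarray]:
    """Symmetric, normalized co-occurrence matrix per direction.

    Directions with no valid voxel pair are omitted.
    """
    lv = _crop(levels)
    mats = []
    for off in DIRECTIONS_13:
        sa, sb = _pair_slices(lv.shape, off)
        a, b = lv[sa], lv[sb]
        valid = (a > 0) & (b > 0)
        if not valid.any():
            continue
        idx = (a[valid] - 1) * n_levels + (b[valid] - 1)
        c = np.bincount(idx, minlength=n_levels * n_levels).reshape(n_levels, n_levels)
        c = c + c.T
        mats.append(c / c.sum())
    return mats


_GRID_CACHE: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _index_grids(ng: int) -> tuple[np.ndarray, np.ndarray]:
    if ng not in _GRID_CACHE:
        i = np.arange(1, ng + 1)
        _GRID_CACHE[ng] = np.meshgrid(i, i, indexing="ij")
    return _GRID_CACHE[ng]


def _glcm_mcc(p: np.ndarray, px: np.ndarray, py: np.ndarray) -> float:
    present = px > 0
    if present.sum() < 2:
        return 1.0
    pp = p[np.ix_(present, present)]
    pxp, pyp = px[present], py[present]
    q = pp @ (pp / np.outer(pxp, pyp)).T
    eig = np.sort(np.real(np.linalg.eigvals(q)))
    second = eig[-2]
    return float(np.sqrt(max(0.0, second)))


def _glcm_batch(P: np.ndarray, n_present: int) -> dict[str, float]:
    """Feature means over a stack of per-direction matrices (nd, ng, ng)."""
    nd, ng, _ = P.shape
    i = np.arange(1, ng + 1, dtype=np.float64)
    ii, jj = _index_grids(ng)
    px = P.sum(axis=2)                      # (nd, ng)
    mu = (P * ii).sum(axis=(1, 2))          # (nd,) symmetric: mu_x == mu_y
    sigma2 = ((i[None, :] - mu[:, None]) ** 2 * px).sum(axis=1)

    flat = P.reshape(nd, ng * ng)
    sum_idx = (ii + jj).ravel()
    diff_idx = np.abs(ii - jj).ravel()
    M_sum = np.zeros((ng * ng, 2 * ng - 1))
    M_sum[np.arange(ng * ng), sum_idx - 2] = 1.0
    M_diff = np.zeros((ng * ng, ng))
    M_diff[np.arange(ng * ng), diff_idx] = 1.0
    p_sum = flat @ M_sum                    # (nd, 2ng-1), k = 2..2ng
    p_diff = flat @ M_diff                  # (nd, ng),   k = 0..ng-1
    k_sum = np.arange(2, 2 * ng + 1, dtype=np.float64)
    k_diff = np.arange(0, ng, dtype=np.float64)

    def ent(q, axis=None):
        return -(q * np.log2(q + _EPS) * (q > 0)).sum(axis=axis)

    da = (p_diff * k_diff).sum(axis=1)
    hxy = ent(flat, axis=1)
    hx = ent(px, axis=1)
    pxpy = px[:, :, None] * px[:, None, :]
    mask_p = P > 0
    hxy1 = -(P * np.log2(pxpy + _EPS) * mask_p).sum(axis=(1, 2))
    hxy2 = -(pxpy * np.log2(pxpy + _EPS) * (pxpy > 0)).sum(axis=(1, 2))

    absdiff = np.abs(ii - jj)[None, :, :]
    dev = (ii + jj)[None, :, :] - 2 * mu[:, None, None]
    autoc = (P * (ii * jj)).sum(axis=(1, 2))
    off = absdiff > 0

    out = {}
    out["Autocorrelation"] = autoc
    out["ClusterProminence"] = (dev**4 * P).sum(axis=(1, 2))
    out["ClusterShade"] = (dev**3 * P).sum(axis=(1, 2))
    out["ClusterTendency"] = (dev**2 * P).sum(axis=(1, 2))
    out["Contrast"] = (absdiff**2 * P).sum(axis=(1, 2))
    out["Correlation"] = np.where(sigma2 > 0, (autoc - mu**2) / np.where(sigma2 > 0, sigma2, 1.0), 1.0)
    out["DifferenceAverage"] = da
    out["DifferenceEntropy"] = ent(p_diff, axis=1)
    out["DifferenceVariance"] = ((k_diff[None, :] - da[:, None]) ** 2 * p_diff).sum(axis=1)
    out["Dissimilarity"] = (absdiff * P).sum(axis=(1, 2))
    out["Id"] = (P / (1.0 + absdiff)).sum(axis=(1, 2))
    out["Idm"] = (P / (1.0 + absdiff**2)).sum(axis=(1, 2))
    out["Idmn"] = (P / (1.0 + (absdiff / n_present) ** 2)).sum(axis=(1, 2))
    out["Idn"] = (P / (1.0 + absdiff / n_present)).sum(axis=(1, 2))
    out["Imc1"] = np.where(hx > 0, (hxy - hxy1) / np.where(hx > 0, hx, 1.0), 0.0)
    out["Imc2"] = np.sqrt(np.clip(1.0 - np.exp(-2.0 * (hxy2 - hxy)), 0.0, None))
    inv = np.where(off, absdiff**2, 1.0)
    out["InverseVariance"] = (np.where(off, P, 0.0) / inv).sum(axis=(1, 2))
    out["JointAverage"] = mu
    out["JointEnergy"] = (P**2).sum(axis=(1, 2))
    out["JointEntropy"] = hxy
    out["MCC"] = np.array([_glcm_mcc(P[d], px[d], P[d].sum(axis=0)) for d in range(nd)])
    out["MaximumProbability"] = P.max(axis=(1, 2))
    out["SumEntropy"] = ent(p_sum, axis=1)
    out["SumSquares"] = sigma2
    return {name: float(np.mean(out[name])) for name in GLCM_NAMES}


def glcm_features(levels: np.ndarray, n_levels: int | None = None) -> dict[str, float]:
    """Direction-averaged GLCM features from a discretized ROI volume."""
    if n_levels is None:
        n_levels = int(levels.max())
    n_present = int(len(np.unique(levels[levels > 0])))
    mats = glcm_matrices(levels, n_levels)
    return _glcm_batch(np.stack(mats), n_present)


# ---------------------------------------------------------------- GLRLM


_LINE_CACHE: dict[tuple, np.ndarray] = {}


def _line_indices(shape: tuple[int, int, int], offset) -> np.ndarray:
    """Flat gather indices (n_lines, max_len + 1) for one direction.

    Entry -1 marks positions outside the grid; the trailing -1 column
    separates consecutive lines after flattening.
    """
    key = (shape, offset)
    if key in _LINE_CACHE:
        return _LINE_CACHE[key]
    shp = np.asarray(shape)
    d = np.asarray(offset)
    pts = np.indices(shape).reshape(3, -1).T
    prev = pts - d
    starts = pts[((prev < 0) | (prev >= shp)).any(axis=1)]
    max_len = int(np.ceil(max(
        shp[k] / abs(d[k]) for k in range(3) if d[k] != 0)))
    idx = np.full((len(starts), max_len + 1), -1, dtype=np.int64)
    pos = starts.copy()
    for t in range(max_len):
        inside = ((pos >= 0) & (pos < shp)).all(axis=1)
        p_in = pos[inside]
        idx[inside, t] = np.ravel_multi_index((p_in[:, 0], p_in[:, 1], p_in[:, 2]), shape)
        pos = pos + d
    if len(_LINE_CACHE) > 512:
        _LINE_CACHE.clear()
    _LINE_CACHE[key] = idx
    return idx


def _rlm_one_direction(lv: np.ndarray, offset, n_levels: int) -> np.ndarray:
    """Run-length matrix R[level-1, length-1] for one direction."""
    idx = _line_indices(lv.shape, offset)
    max_len = idx.shape[1] - 1
    vals = np.where(idx >= 0, lv.reshape(-1)[idx.clip(0)], 0)
    flat = vals.reshape(-1)  # trailing zero column separates lines
    change = np.flatnonzero(flat[1:] != flat[:-1]) + 1
    bounds = np.concatenate([[0], change, [len(flat)]])
    run_vals = flat[bounds[:-1]]
    run_lens = np.diff(bounds)
    keep = run_vals > 0
    run_vals, run_lens = run_vals[keep], run_lens[keep]
    R = np.zeros((n_levels, max_len), dtype=np.float64)
    if len(run_vals):
        idx = (run_vals - 1) * max_len + (run_lens - 1)
        R = np.bincount(idx, minlength=n_levels * max_len).reshape(
            n_levels, max_len).astype(np.float64)
    return R


def _rlm_single(R: np.ndarray, n_voxels: int) -> dict[str, float]:
    nr = R.sum()
    i = np.arange(1, R.shape[0] + 1, dtype=np.float64)
    l = np.arange(1, R.shape[1] + 1, dtype=np.float64)
    ii, ll = np.meshgrid(i, l, indexing="ij")
    ri = R.sum(axis=1)
    rl = R.sum(axis=0)
    p = R / nr
    pi, pl = ri / nr, rl / nr
    mu_i = float((i * pi).sum())
    mu_l = float((l * pl).sum())
    out = {
        "ShortRunEmphasis": float((R / ll**2).sum() / nr),
        "LongRunEmphasis": float((R * ll**2).sum() / nr),
        "GrayLevelNonUniformity": float((ri**2).sum() / nr),
        "GrayLevelNonUniformityNormalized": float((ri**2).sum() / nr**2),
        "RunLengthNonUniformity": float((rl**2).sum() / nr),
        "RunLengthNonUniformityNormalized": float((rl**2).sum() / nr**2),
        "RunPercentage": float(nr / n_voxels),
        "GrayLevelVariance": float(((i - mu_i) ** 2 * pi).sum()),
        "RunVariance": float(((l - mu_l) ** 2 * pl).sum()),
        "RunEntropy": float(-(p * np.log2(p + _EPS))[p > 0].sum()),
        "LowGrayLevelRunEmphasis": float((R / ii**2).sum() / nr),
        "HighGrayLevelRunEmphasis": float((R * ii**2).sum() / nr),
        "ShortRunLowGrayLevelEmphasis": float((R / (ii**2 * ll**2)).sum() / nr),
        "ShortRunHighGrayLevelEmphasis": float((R * ii**2 / ll**2).sum() / nr),
        "LongRunLowGrayLevelEmphasis": float((R * ll**2 / ii**2).sum() / nr),
        "LongRunHighGrayLevelEmphasis": float((R * ii**2 * ll**2).sum() / nr),
    }
    return out


def glrlm_features(levels: np.ndarray, n_levels: int | None = None) -> dict[str, float]:
    """Direction-averaged run-length features from a discretized ROI volume."""
    if n_levels is None:
        n_levels = int(levels.max())
    lv = _crop(levels)
    n_voxels = int((lv > 0).sum())
    per_dir = []
    for off in DIRECTIONS_13:
        R = _rlm_one_direction(lv, off, n_levels)
        if R.sum() > 0:
            per_dir.append(_rlm_single(R, n_voxels))
    return {name: float(np.mean([d[name] for d in per_dir])) for name in GLRLM_NAMES}


# ---------------------------------------------------------------- GLSZM


def glszm_matrix(levels: np.ndarray, n_levels: int) -> np.ndarray:
    """Size-zone matrix Z[level-1, size-1], zones 26-connected."""
    lv = _crop(levels)
    structure = np.ones((3, 3, 3), dtype=int)
    max_size = int((lv > 0).sum())
    Z = np.zeros((n_levels, max_size), dtype=np.float64)
    for g in np.unique(lv[lv > 0]):
        lab, n_lab = ndimage.label(lv == g, structure=structure)
        if n_lab == 0:
            continue
        sizes = np.bincount(lab.reshape(-1))[1:]
        for s in sizes:
            Z[g - 1, s - 1] += 1
    last = np.flatnonzero(Z.any(axis=0))
    return Z[:, : last[-1] + 1] if len(last) else Z[:, :1]


def glszm_features(levels: np.ndarray, n_levels: int | None = None) -> dict[str, float]:
    if n_levels is None:
        n_levels = int(levels.max())
    Z = glszm_matrix(levels, n_levels)
    nz = Z.sum()
    n_voxels = int((levels > 0).sum())
    i = np.arange(1, Z.shape[0] + 1, dtype=np.float64)
    s = np.arange(1, Z.shape[1] + 1, dtype=np.float64)
    ii, ss = np.meshgrid(i, s, indexing="ij")
    zi = Z.sum(axis=1)
    zs = Z.sum(axis=0)
    p = Z / nz
    pi, ps = zi / nz, zs / nz
    mu_i = float((i * pi).sum())
    mu_s = float((s * ps).sum())
    return {
        "SmallAreaEmphasis": float((Z / ss**2).sum() / nz),
        "LargeAreaEmphasis": float((Z * ss**2).sum() / nz),
        "GrayLevelNonUniformity": float((zi**2).sum() / nz),
        "GrayLevelNonUniformityNormalized": float((zi**2).sum() / nz**2),
        "SizeZoneNonUniformity": float((zs**2).sum() / nz),
        "SizeZoneNonUniformityNormalized": float((zs**2).sum() / nz**2),
        "ZonePercentage": float(nz / n_voxels),
        "GrayLevelVariance": float(((i - mu_i) ** 2 * pi).sum()),
        "ZoneVariance": float(((s - mu_s) ** 2 * ps).sum()),
        "ZoneEntropy": float(-(p * np.log2(p + _EPS))[p > 0].sum()),
        "LowGrayLevelZoneEmphasis": float((Z / ii**2).sum() / nz),
        "HighGrayLevelZoneEmphasis": float((Z * ii**2).sum() / nz),
        "SmallAreaLowGrayLevelEmphasis": float((Z / (ii**2 * ss**2)).sum() / nz),
        "SmallAreaHighGrayLevelEmphasis": float((Z * ii**2 / ss**2).sum() / nz),
        "LargeAreaLowGrayLevelEmphasis": float((Z * ss**2 / ii**2).sum() / nz),
        "LargeAreaHighGrayLevelEmphasis": float((Z * ii**2 * ss**2).sum() / nz),
    }


# ---------------------------------------------------------------- GLDM


def gldm_matrix(levels: np.ndarray, n_levels: int, alpha: float = 0.0) -> np.ndarray:
    """Dependence matrix D[level-1, size-1].

    Dependence size = 1 + number of 26-neighbours inside the ROI whose
    level differs from the centre by at most ``alpha``.
    """
    lv = _crop(levels)
    dep = np.zeros(lv.shape, dtype=np.int64)
    for off in OFFSETS_26:
        sa, sb = _pair_slices(lv.shape, off)
        a, b = lv[sa], lv[sb]
        hit = (a > 0) & (b > 0) & (np.abs(a - b) <= alpha)
        dep[sa] += hit
    roi = lv > 0
    sizes = dep[roi] + 1
    vals = lv[roi]
    max_dep = 27
    idx = (vals - 1) * max_dep + (sizes - 1)
    return np.bincount(idx, minlength=n_levels * max_dep).reshape(
        n_levels, max_dep).astype(np.float64)


def gldm_features(
    levels: np.ndarray, n_levels: int | None = None, alpha: float = 0.0
) -> dict[str, float]:
    if n_levels is None:
        n_levels = int(levels.max())
    D = gldm_matrix(levels, n_levels, alpha)
    nz = D.sum()
    i = np.arange(1, D.shape[0] + 1, dtype=np.float64)
    j = np.arange(1, D.shape[1] + 1, dtype=np.float64)
    ii, jj = np.meshgrid(i, j, indexing="ij")
    di = D.sum(axis=1)
    dj = D.sum(axis=0)
    p = D / nz
    pi, pj = di / nz, dj / nz
    mu_i = float((i * pi).sum())
    mu_j = float((j * pj).sum())
    return {
        "SmallDependenceEmphasis": float((D / jj**2).sum() / nz),
        "LargeDependenceEmphasis": float((D * jj**2).sum() / nz),
        "GrayLevelNonUniformity": float((di**2).sum() / nz),
        "DependenceNonUniformity": float((dj**2).sum() / nz),
        "DependenceNonUniformityNormalized": float((dj**2).sum() / nz**2),
        "GrayLevelVariance": float(((i - mu_i) ** 2 * pi).sum()),
        "DependenceVariance": float(((j - mu_j) ** 2 * pj).sum()),
        "DependenceEntropy": float(-(p * np.log2(p + _EPS))[p > 0].sum()),
        "LowGrayLevelEmphasis": float((D / ii**2).sum() / nz),
        "HighGrayLevelEmphasis": float((D * ii**2).sum() / nz),
        "SmallDependenceLowGrayLevelEmphasis": float((D / (ii**2 * jj**2)).sum() / nz),
        "SmallDependenceHighGrayLevelEmphasis": float((D * ii**2 / jj**2).sum() / nz),
        "LargeDependenceLowGrayLevelEmphasis": float((D * jj**2 / ii**2).sum() / nz),
        "LargeDependenceHighGrayLevelEmphasis": float((D * ii**2 * jj**2).sum() / nz),
    }


# ---------------------------------------------------------------- NGTDM


def ngtdm_table(levels: np.ndarray, n_levels: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-level occurrence counts n_i and summed deviations s_i.

    s_i sums |i - A_v| over ROI voxels of level i, where A_v is the mean
    level of the voxel's in-ROI 26-neighbours; voxels with no in-ROI
    neighbour contribute zero deviation.
    """
    lv = _crop(levels).astype(np.float64)
    roi = lv > 0
    kernel = np.ones((3, 3, 3))
    kernel[1, 1, 1] = 0
    nb_sum = ndimage.correlate(lv * roi, kernel, mode="constant", cval=0.0)
    nb_cnt = ndimage.correlate(roi.astype(np.float64), kernel,
                               mode="constant", cval=0.0)
    n = np.zeros(n_levels)
    s = np.zeros(n_levels)
    vals = lv[roi].astype(np.int64)
    has_nb = nb_cnt[roi] > 0
    avg = np.zeros(vals.shape)
    avg[has_nb] = nb_sum[roi][has_nb] / nb_cnt[roi][has_nb]
    dev = np.where(has_nb, np.abs(vals - avg), 0.0)
    n = np.bincount(vals - 1, minlength=n_levels).astype(np.float64)
    s = np.bincount(vals - 1, weights=dev, minlength=n_levels)
    return n, s


def ngtdm_features(levels: np.ndarray, n_levels: int | None = None) -> dict[str, float]:
    if n_levels is None:
        n_levels = int(levels.max())
    n, s = ngtdm_table(levels, n_levels)
    n_voxels = n.sum()
    p = n / n_voxels
    i = np.arange(1, n_levels + 1, dtype=np.float64)
    present = p > 0
    ngp = int(present.sum())
    ip, pp, sp = i[present], p[present], s[present]

    coarse_den = float((pp * sp).sum())
    out: dict[str, float] = {}
    out["Coarseness"] = 1e6 if coarse_den == 0 else float(1.0 / coarse_den)
    if ngp <= 1:
        out["Contrast"] = 0.0
    else:
        pij = np.outer(pp, pp)
        dij2 = (ip[:, None] - ip[None, :]) ** 2
        out["Contrast"] = float(
            (pij * dij2).sum() / (ngp * (ngp - 1)) * (sp.sum() / n_voxels))
    bus_den = float(np.abs(ip[:, None] * pp[:, None] - ip[None, :] * pp[None, :]).sum())
    out["Busyness"] = 0.0 if bus_den == 0 else float((pp * sp).sum() / bus_den)
    absd = np.abs(ip[:, None] - ip[None, :])
    psum = pp[:, None] + pp[None, :]
    wsum = pp[:, None] * sp[:, None] + pp[None, :] * sp[None, :]
    out["Complexity"] = float((absd * wsum / psum).sum() / n_voxels)
    s_total = float(sp.sum())
    out["Strength"] = 0.0 if s_total == 0 else float(
        (psum * (ip[:, None] - ip[None, :]) ** 2).sum() / s_total)
    return out


# ---------------------------------------------------------------- bundle


def texture_features(levels: np.ndarray, n_levels: int | None = None) -> dict[str, float]:
    """All 75 texture features keyed as ``"<class>|<name>"``."""
    if n_levels is None:
        n_levels = int(levels.max())
    out: dict[str, float] = {}
    for cls, fn in (
        ("glcm", glcm_features),
        ("glrlm", glrlm_features),
        ("glszm", glszm_features),
        ("gldm", gldm_features),
        ("ngtdm", ngtdm_features),
    ):
        for name, value in fn(levels, n_levels).items():
            out[f"{cls}|{name}"] = value
    return out
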