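"""Independent naive oracles for texture, ICC and AUC checks.

Everything here is deliberately written as explicit enumeration (python
loops, dictionaries), independent of the vectorized package code paths.
Conventions mirror the package's documented choices: actual gray-level
values in formulas, 13 unique directions, per-direction feature
averaging for GLCM/GLRLM, number-of-present-levels for normalized
inverse-difference features.
"""

import math
from collections import defaultdict

import numpy as np
from scipy.stats import f_oneway

DIRS = [
    (dx, dy, dz)
    for dz in (0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if (dz, dy, dx) > (0, 0, 0)
]
ALL26 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
]


def _crop(levels):
    idx = np.nonzero(levels)
    sl = tuple(slice(a.min(), a.max() + 1) for a in idx)
    return levels[sl]


def _inside(shape, p):
    return all(0 <= p[d] < shape[d] for d in range(3))


def _voxels(lv):
    return [tuple(p) for p in np.argwhere(lv > 0)]


# ---------------------------------------------------------------- GLCM


def naive_glcm(levels):
    lv = _crop(levels)
    n_present = len({int(lv[p]) for p in _voxels(lv)})
    shape = lv.shape
    per_dir = []
    for d in DIRS:
        counts = defaultdict(float)
        for p in _voxels(lv):
            q = (p[0] + d[0], p[1] + d[1], p[2] + d[2])
            if _inside(shape, q) and lv[q] > 0:
                i, j = int(lv[p]), int(lv[q])
                counts[(i, j)] += 1
                counts[(j, i)] += 1  # symmetric
        total = sum(counts.values())
        if total == 0:
            continue
        p_ij = {k: v / total for k, v in counts.items()}
        per_dir.append(_glcm_from_matrix(p_ij, n_present))
    return {k: float(np.mean([d[k] for d in per_dir])) for k in per_dir[0]}


def _glcm_from_matrix(p, n_present):
    eps = np.spacing(1.0)
    mu = sum(i * v for (i, j), v in p.items())
    px = defaultdict(float)
    for (i, j), v in p.items():
        px[i] += v
    sigma2 = sum((i - mu) ** 2 * v for i, v in px.items())
    psum = defaultdict(float)
    pdiff = defaultdict(float)
    for (i, j), v in p.items():
        psum[i + j] += v
        pdiff[abs(i - j)] += v
    da = sum(k * v for k, v in pdiff.items())
    hxy = -sum(v * math.log2(v + eps) for v in p.values() if v > 0)
    hx = -sum(v * math.log2(v + eps) for v in px.values() if v > 0)
    hxy1 = -sum(v * math.log2(px[i] * px[j] + eps) for (i, j), v in p.items() if v > 0)
    hxy2 = -sum(px[i] * px[j] * math.log2(px[i] * px[j] + eps)
                for i in px for j in px if px[i] * px[j] > 0)
    out = {}
    out["Autocorrelation"] = sum(i * j * v for (i, j), v in p.items())
    for name, power in (("ClusterProminence", 4), ("ClusterShade", 3),
                        ("ClusterTendency", 2)):
        out[name] = sum((i + j - 2 * mu) ** power * v for (i, j), v in p.items())
    out["Contrast"] = sum((i - j) ** 2 * v for (i, j), v in p.items())
    out["Correlation"] = (1.0 if sigma2 <= 0
                          else (out["Autocorrelation"] - mu * mu) / sigma2)
    out["DifferenceAverage"] = da
    out["DifferenceEntropy"] = -sum(v * math.log2(v + eps)
                                    for v in pdiff.values() if v > 0)
    out["DifferenceVariance"] = sum((k - da) ** 2 * v for k, v in pdiff.items())
    out["Dissimilarity"] = sum(abs(i - j) * v for (i, j), v in p.items())
    out["Id"] = sum(v / (1 + abs(i - j)) for (i, j), v in p.items())
    out["Idm"] = sum(v / (1 + (i - j) ** 2) for (i, j), v in p.items())
    out["Idmn"] = sum(v / (1 + ((i - j) / n_present) ** 2) for (i, j), v in p.items())
    out["Idn"] = sum(v / (1 + abs(i - j) / n_present) for (i, j), v in p.items())
    out["Imc1"] = 0.0 if hx == 0 else (hxy - hxy1) / hx
    out["Imc2"] = math.sqrt(max(0.0, 1 - math.exp(-2 * (hxy2 - hxy))))
    out["InverseVariance"] = sum(v / (i - j) ** 2 for (i, j), v in p.items() if i != j)
    out["JointAverage"] = mu
    out["JointEnergy"] = sum(v * v for v in p.values())
    out["JointEntropy"] = hxy
    out["MCC"] = _naive_mcc(p, px)
    out["MaximumProbability"] = max(p.values())
    out["SumEntropy"] = -sum(v * math.log2(v + eps) for v in psum.values() if v > 0)
    out["SumSquares"] = sigma2
    return out


def _naive_mcc(p, px):
    lv = sorted(px)
    if len(lv) < 2:
        return 1.0
    n = len(lv)
    q = np.zeros((n, n))
    for a, i in enumerate(lv):
        for b, j in enumerate(lv):
            q[a, b] = sum(p.get((i, k), 0.0) * p.get((j, k), 0.0) / (px[i] * px[k])
                          for k in lv)
    eig = sorted(np.real(np.linalg.eigvals(q)))
    return math.sqrt(max(0.0, eig[-2]))


# ---------------------------------------------------------------- GLRLM


def naive_glrlm(levels):
    lv = _crop(levels)
    shape = lv.shape
    n_vox = len(_voxels(lv))
    per_dir = []
    for d in DIRS:
        runs = defaultdict(float)  # (level, length) -> count
        for p in np.ndindex(shape):
            prev = (p[0] - d[0], p[1] - d[1], p[2] - d[2])
            if _inside(shape, prev):
                continue  # not a line start
            # walk the whole line, run-length encoding nonzero stretches
            q = p
            current, length = 0, 0
            while _inside(shape, q):
                v = int(lv[q])
                if v == current:
                    length += 1
                else:
                    if current > 0:
                        runs[(current, length)] += 1
                    current, length = v, 1
                q = (q[0] + d[0], q[1] + d[1], q[2] + d[2])
            if current > 0:
                runs[(current, length)] += 1
        if runs:
            per_dir.append(_srm_features(runs, n_vox, kind="run"))
    return {k: float(np.mean([d[k] for d in per_dir])) for k in per_dir[0]}


def _srm_features(table, n_vox, kind):
    """Shared level/size-indexed features for run and zone tables."""
    eps = np.spacing(1.0)
    total = sum(table.values())
    by_level = defaultdict(float)
    by_size = defaultdict(float)
    for (i, s), v in table.items():
        by_level[i] += v
        by_size[s] += v
    mu_i = sum(i * v / total for i, v in by_level.items())
    mu_s = sum(s * v / total for s, v in by_size.items())
    f = {}
    f["small"] = sum(v / s**2 for (i, s), v in table.items()) / total
    f["large"] = sum(v * s**2 for (i, s), v in table.items()) / total
    f["gln"] = sum(v**2 for v in by_level.values()) / total
    f["glnn"] = sum(v**2 for v in by_level.values()) / total**2
    f["sn"] = sum(v**2 for v in by_size.values()) / total
    f["snn"] = sum(v**2 for v in by_size.values()) / total**2
    f["pct"] = total / n_vox
    f["glvar"] = sum((i - mu_i) ** 2 * v / total for i, v in by_level.items())
    f["svar"] = sum((s - mu_s) ** 2 * v / total for s, v in by_size.items())
    f["ent"] = -sum((v / total) * math.log2(v / total + eps) for v in table.values())
    f["lowgl"] = sum(v / i**2 for (i, s), v in table.items()) / total
    f["highgl"] = sum(v * i**2 for (i, s), v in table.items()) / total
    f["smalllow"] = sum(v / (i**2 * s**2) for (i, s), v in table.items()) / total
    f["smallhigh"] = sum(v * i**2 / s**2 for (i, s), v in table.items()) / total
    f["largelow"] = sum(v * s**2 / i**2 for (i, s), v in table.items()) / total
    f["largehigh"] = sum(v * i**2 * s**2 for (i, s), v in table.items()) / total
    names = {
        "run": ["ShortRunEmphasis", "LongRunEmphasis", "GrayLevelNonUniformity",
                "GrayLevelNonUniformityNormalized", "RunLengthNonUniformity",
                "RunLengthNonUniformityNormalized", "RunPercentage",
                "GrayLevelVariance", "RunVariance", "RunEntropy",
                "LowGrayLevelRunEmphasis", "HighGrayLevelRunEmphasis",
                "ShortRunLowGrayLevelEmphasis", "ShortRunHighGrayLevelEmphasis",
                "LongRunLowGrayLevelEmphasis", "LongRunHighGrayLevelEmphasis"],
        "zone": ["SmallAreaEmphasis", "LargeAreaEmphasis", "GrayLevelNonUniformity",
                 "GrayLevelNonUniformityNormalized", "SizeZoneNonUniformity",
                 "SizeZoneNonUniformityNormalized", "ZonePercentage",
                 "GrayLevelVariance", "ZoneVariance", "ZoneEntropy",
                 "LowGrayLevelZoneEmphasis", "HighGrayLevelZoneEmphasis",
                 "SmallAreaLowGrayLevelEmphasis", "SmallAreaHighGrayLevelEmphasis",
                 "LargeAreaLowGrayLevelEmphasis", "LargeAreaHighGrayLevelEmphasis"],
    }[kind]
    keys = ["small", "large", "gln", "glnn", "sn", "snn", "pct", "glvar",
            "svar", "ent", "lowgl", "highgl", "smalllow", "smallhigh",
            "largelow", "largehigh"]
    return dict(zip(names, (f[k] for k in keys)))


# ---------------------------------------------------------------- GLSZM


def naive_glszm(levels):
    lv = _crop(levels)
    shape = lv.shape
    n_vox = len(_voxels(lv))
    seen = set()
    zones = defaultdict(float)
    for start in _voxels(lv):
        if start in seen:
            continue
        g = int(lv[start])
        stack, zone = [start], {start}
        seen.add(start)
        while stack:
            p = stack.pop()
            for d in ALL26:
                q = (p[0] + d[0], p[1] + d[1], p[2] + d[2])
                if q not in zone and _inside(shape, q) and int(lv[q]) == g:
                    zone.add(q)
                    seen.add(q)
                    stack.append(q)
        zones[(g, len(zone))] += 1
    return _srm_features(zones, n_vox, kind="zone")


# ---------------------------------------------------------------- GLDM


def naive_gldm(levels, alpha=0.0):
    lv = _crop(levels)
    shape = lv.shape
    table = defaultdict(float)
    for p in _voxels(lv):
        g = int(lv[p])
        dep = 1
        for d in ALL26:
            q = (p[0] + d[0], p[1] + d[1], p[2] + d[2])
            if _inside(shape, q) and lv[q] > 0 and abs(int(lv[q]) - g) <= alpha:
                dep += 1
        table[(g, dep)] += 1
    f = _srm_features(table, len(_voxels(lv)), kind="zone")
    rename = {
        "SmallAreaEmphasis": "SmallDependenceEmphasis",
        "LargeAreaEmphasis": "LargeDependenceEmphasis",
        "GrayLevelNonUniformity": "GrayLevelNonUniformity",
        "SizeZoneNonUniformity": "DependenceNonUniformity",
        "SizeZoneNonUniformityNormalized": "DependenceNonUniformityNormalized",
        "GrayLevelVariance": "GrayLevelVariance",
        "ZoneVariance": "DependenceVariance",
        "ZoneEntropy": "DependenceEntropy",
        "LowGrayLevelZoneEmphasis": "LowGrayLevelEmphasis",
        "HighGrayLevelZoneEmphasis": "HighGrayLevelEmphasis",
        "SmallAreaLowGrayLevelEmphasis": "SmallDependenceLowGrayLevelEmphasis",
        "SmallAreaHighGrayLevelEmphasis": "SmallDependenceHighGrayLevelEmphasis",
        "LargeAreaLowGrayLevelEmphasis": "LargeDependenceLowGrayLevelEmphasis",
        "LargeAreaHighGrayLevelEmphasis": "LargeDependenceHighGrayLevelEmphasis",
    }
    return {rename[k]: v for k, v in f.items() if k in rename}


# ---------------------------------------------------------------- NGTDM


def naive_ngtdm(levels):
    lv = _crop(levels)
    shape = lv.shape
    vox = _voxels(lv)
    n_vox = len(vox)
    n = defaultdict(float)
    s = defaultdict(float)
    for p in vox:
        g = int(lv[p])
        nb = [int(lv[q]) for d in ALL26
              for q in [(p[0] + d[0], p[1] + d[1], p[2] + d[2])]
              if _inside(shape, q) and lv[q] > 0]
        n[g] += 1
        if nb:
            s[g] += abs(g - sum(nb) / len(nb))
    p_i = {g: n[g] / n_vox for g in n}
    ngp = len(p_i)
    out = {}
    den = sum(p_i[g] * s[g] for g in p_i)
    out["Coarseness"] = 1e6 if den == 0 else 1.0 / den
    if ngp <= 1:
        out["Contrast"] = 0.0
    else:
        out["Contrast"] = (sum(p_i[i] * p_i[j] * (i - j) ** 2 for i in p_i for j in p_i)
                           / (ngp * (ngp - 1)) * sum(s.values()) / n_vox)
    bus = sum(abs(i * p_i[i] - j * p_i[j]) for i in p_i for j in p_i)
    out["Busyness"] = 0.0 if bus == 0 else den / bus
    out["Complexity"] = sum(abs(i - j) * (p_i[i] * s[i] + p_i[j] * s[j])
                            / (p_i[i] + p_i[j])
                            for i in p_i for j in p_i) / n_vox
    stot = sum(s.values())
    out["Strength"] = 0.0 if stot == 0 else sum(
        (p_i[i] + p_i[j]) * (i - j) ** 2 for i in p_i for j in p_i) / stot
    return out


def naive_texture(levels):
    out = {}
    for cls, fn in (("glcm", naive_glcm), ("glrlm", naive_glrlm),
                    ("glszm", naive_glszm), ("gldm", naive_gldm),
                    ("ngtdm", naive_ngtdm)):
        for k, v in fn(levels).items():
            out[f"{cls}|{k}"] = v
    return out


# ---------------------------------------------------------------- ICC / AUC


def icc1_via_f_oneway(values):
    """ICC(1) from scipy's one-way ANOVA F statistic."""
    groups = [row for row in np.asarray(values)]
    F = f_oneway(*groups).statistic
    k = values.shape[1]
    return (F - 1.0) / (F + k - 1.0)


def auc_by_enumeration(y, s):
    """AUC as the fraction of correctly ordered (pos, neg) pairs."""
    pos = [si for yi, si in zip(y, s) if yi == 1]
    neg = [si for yi, si in zip(y, s) if yi == 0]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(pos) * len(neg))
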