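"""Compact 2D texture-feature engine backing the engineered feature bank.

Implements the classic matrix-based texture families (GLCM, GLRLM,
GLSZM, GLDM, NGTDM) plus first-order statistics and 2D shape
descriptors on a masked image.  Intensities are discretized into a fixed
number of gray levels inside the mask; the four principal directions are
merged by summing their matrices before normalisation.

This is a self-contained engine with the standard formulas of the field;
it targets 2D ROIs and a fixed-bin-count discretization (32 levels).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage import measure

N_BINS = 32
_DIRECTIONS = ((0, 1), (1, 1), (1, 0), (1, -1))  # 0, 45, 90, 135 degrees


def quantize(image: np.ndarray, mask: np.ndarray, n_bins: int = N_BINS) -> np.ndarray:
    """Discretize in-mask intensities to levels 1..n_bins (0 outside)."""
    vals = image[mask]
    lo, hi = vals.min(), vals.max()
    q = np.zeros(image.shape, dtype=np.int32)
    if hi == lo:
        q[mask] = 1
        return q
    levels = np.floor((image[mask] - lo) / (hi - lo) * n_bins).astype(np.int32) + 1
    q[mask] = np.clip(levels, 1, n_bins)
    return q


# ---------------------------------------------------------------- first order

def _moment_ratio(v: np.ndarray, order: int) -> float:
    """Standardized central moment (skewness for 3, kurtosis for 4)."""
    d = v - v.mean()
    m2 = np.mean(d ** 2)
    if m2 < 1e-24:
        return 0.0
    return float(np.mean(d ** order) / m2 ** (order / 2.0))


def firstorder_features(image: np.ndarray, mask: np.ndarray) -> dict[str, float]:
    v = image[mask].astype(float)
    n = v.size
    p10, p25, p50, p75, p90 = np.percentile(v, [10, 25, 50, 75, 90])
    mean = v.mean()
    hist = np.bincount(quantize(image, mask)[mask])[1:]
    p = hist[hist > 0] / n
    mid = v[(v >= p10) & (v <= p90)]
    return {
        "Energy": float(np.sum(v ** 2)),
        "TotalEnergy": float(np.sum(v ** 2)),  # unit pixel area
        "Entropy": float(-(p * np.log2(p)).sum()),
        "Minimum": float(v.min()),
        "Percentile10": float(p10),
        "Percentile90": float(p90),
        "Maximum": float(v.max()),
        "Mean": float(mean),
        "Median": float(p50),
        "InterquartileRange": float(p75 - p25),
        "Range": float(v.max() - v.min()),
        "MeanAbsoluteDeviation": float(np.abs(v - mean).mean()),
        "RobustMeanAbsoluteDeviation": float(np.abs(mid - mid.mean()).mean()) if mid.size else 0.0,
        "RootMeanSquared": float(np.sqrt(np.mean(v ** 2))),
        "Skewness": _moment_ratio(v, 3),
        "Kurtosis": _moment_ratio(v, 4),
        "Variance": float(v.var()),
        "Uniformity": float((p ** 2).sum()),
    }


# ---------------------------------------------------------------------- GLCM

def glcm_matrix(q: np.ndarray, n_bins: int = N_BINS) -> np.ndarray:
    """Symmetric co-occurrence counts summed over the 4 directions."""
    g = np.zeros((n_bins, n_bins))
    rows, cols = q.shape
    for dr, dc in _DIRECTIONS:
        a = q[max(0, -dr):rows - max(0, dr), max(0, -dc):cols - max(0, dc)]
        b = q[max(0, dr):rows - max(0, -dr), max(0, dc):cols - max(0, -dc)]
        ok = (a > 0) & (b > 0)
        np.add.at(g, (a[ok] - 1, b[ok] - 1), 1.0)
    return g + g.T


def glcm_features(q: np.ndarray, n_bins: int = N_BINS) -> dict[str, float]:
    g = glcm_matrix(q, n_bins)
    if g.sum() == 0:  # single-pixel mask: no neighbours
        return {k: 0.0 for k in _GLCM_KEYS}
    p = g / g.sum()
    i = np.arange(1, n_bins + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    mu = float((i * px).sum())
    sigma2 = float(((i - mu) ** 2 * px).sum())

    k_sum = np.arange(2, 2 * n_bins + 1)
    p_sum = np.array([p[(ii + jj) == k].sum() for k in k_sum])
    k_diff = np.arange(0, n_bins)
    p_diff = np.array([p[np.abs(ii - jj) == k].sum() for k in k_diff])

    def ent(x):
        x = x[x > 0]
        return float(-(x * np.log2(x)).sum())

    hx = ent(px)
    hxy = ent(p.ravel())
    pxpy = np.outer(px, px)
    nz = (p > 0) & (pxpy > 0)
    hxy1 = float(-(p[nz] * np.log2(pxpy[nz])).sum())
    nz2 = pxpy > 0
    hxy2 = float(-(pxpy[nz2] * np.log2(pxpy[nz2])).sum())

    da = float((k_diff * p_diff).sum())
    corr = float((((ii - mu) * (jj - mu) * p).sum()) / sigma2) if sigma2 > 1e-12 else 1.0
    imc1 = (hxy - hxy1) / hx if hx > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy))))) if hxy2 >= hxy else 0.0
    off = ii != jj
    return {
        "Autocorrelation": float((ii * jj * p).sum()),
        "ClusterProminence": float(((ii + jj - 2 * mu) ** 4 * p).sum()),
        "ClusterShade": float(((ii + jj - 2 * mu) ** 3 * p).sum()),
        "ClusterTendency": float(((ii + jj - 2 * mu) ** 2 * p).sum()),
        "Contrast": float(((ii - jj) ** 2 * p).sum()),
        "Correlation": corr,
        "DifferenceAverage": da,
        "DifferenceEntropy": ent(p_diff),
        "DifferenceVariance": float(((k_diff - da) ** 2 * p_diff).sum()),
        "Id": float((p / (1.0 + np.abs(ii - jj))).sum()),
        "Idm": float((p / (1.0 + (ii - jj) ** 2)).sum()),
        "Idmn": float((p / (1.0 + (ii - jj) ** 2 / n_bins ** 2)).sum()),
        "Idn": float((p / (1.0 + np.abs(ii - jj) / n_bins)).sum()),
        "Imc1": float(imc1),
        "Imc2": imc2,
        "InverseVariance": float((p[off] / (ii[off] - jj[off]) ** 2).sum()),
        "JointAverage": mu,
        "JointEnergy": float((p ** 2).sum()),
        "JointEntropy": hxy,
        "MaximumProbability": float(p.max()),
        "SumAverage": float((k_sum * p_sum).sum()),
        "SumEntropy": ent(p_sum),
        "SumSquares": float(((ii - mu) ** 2 * p).sum()),
    }


_GLCM_KEYS = (
    "Autocorrelation", "ClusterProminence", "ClusterShade", "ClusterTendency",
    "Contrast", "Correlation", "DifferenceAverage", "DifferenceEntropy",
    "DifferenceVariance", "Id", "Idm", "Idmn", "Idn", "Imc1", "Imc2",
    "InverseVariance", "JointAverage", "JointEnergy", "JointEntropy",
    "MaximumProbability", "SumAverage", "SumEntropy", "SumSquares")


# ------------------------------------------------------- size/length matrices

def _sij_features(mat: np.ndarray, n_pixels: int, prefix_i: str, prefix_j: str) -> dict[str, float]:
    """Shared small/large + low/high gray emphasis machinery.

    ``mat[i-1, j-1]`` counts items of gray level i with size/length/
    dependence j; the 16 standard ratio features plus entropy/variance
    are derived from it.  Names are assembled by the callers.
    """
    ns = mat.sum()
    if ns == 0:
        return {}
    p = mat / ns
    gi = np.arange(1, mat.shape[0] + 1)
    sj = np.arange(1, mat.shape[1] + 1)
    ii, jj = np.meshgrid(gi, sj, indexing="ij")
    pg = p.sum(axis=1)
    ps = p.sum(axis=0)
    mu_i = (gi * pg).sum()
    mu_j = (sj * ps).sum()
    nzp = p[p > 0]
    return {
        "SmallEmphasis": float((p / jj ** 2).sum()),
        "LargeEmphasis": float((p * jj ** 2).sum()),
        "GrayLevelNonUniformity": float((mat.sum(axis=1) ** 2).sum() / ns),
        "GrayLevelNonUniformityNormalized": float((pg ** 2).sum()),
        "SizeNonUniformity": float((mat.sum(axis=0) ** 2).sum() / ns),
        "SizeNonUniformityNormalized": float((ps ** 2).sum()),
        "Percentage": float(ns / n_pixels),
        "GrayLevelVariance": float(((ii - mu_i) ** 2 * p).sum()),
        "SizeVariance": float(((jj - mu_j) ** 2 * p).sum()),
        "Entropy": float(-(nzp * np.log2(nzp)).sum()),
        "LowGrayLevelEmphasis": float((p / ii ** 2).sum()),
        "HighGrayLevelEmphasis": float((p * ii ** 2).sum()),
        "SmallLowGrayLevelEmphasis": float((p / (ii ** 2 * jj ** 2)).sum()),
        "SmallHighGrayLevelEmphasis": float((p * ii ** 2 / jj ** 2).sum()),
        "LargeLowGrayLevelEmphasis": float((p * jj ** 2 / ii ** 2).sum()),
        "LargeHighGrayLevelEmphasis": float((p * ii ** 2 * jj ** 2).sum()),
    }


def glrlm_features(q: np.ndarray, n_bins: int = N_BINS) -> dict[str, float]:
    """Gray-level run-length features, runs merged over 4 directions."""
    n_pixels = int((q > 0).sum())
    max_run = max(q.shape)
    mat = np.zeros((n_bins, max_run))
    for dr, dc in _DIRECTIONS:
        for line in _lines(q, dr, dc):
            for level, length in _runs(line):
                if level > 0:
                    mat[level - 1, length - 1] += 1
    f = _sij_features(mat, n_pixels * 4, "GrayLevel", "Run")
    if not f:
        return {k: 0.0 for k in BASE_GLRLM}
    return {
        "GrayLevelNonUniformity": f["GrayLevelNonUniformity"],
        "GrayLevelNonUniformityNormalized": f["GrayLevelNonUniformityNormalized"],
        "GrayLevelVariance": f["GrayLevelVariance"],
        "HighGrayLevelRunEmphasis": f["HighGrayLevelEmphasis"],
        "LongRunEmphasis": f["LargeEmphasis"],
        "LongRunHighGrayLevelEmphasis": f["LargeHighGrayLevelEmphasis"],
        "LongRunLowGrayLevelEmphasis": f["LargeLowGrayLevelEmphasis"],
        "LowGrayLevelRunEmphasis": f["LowGrayLevelEmphasis"],
        "RunEntropy": f["Entropy"],
        "RunLengthNonUniformity": f["SizeNonUniformity"],
        "RunLengthNonUniformityNormalized": f["SizeNonUniformityNormalized"],
        "RunPercentage": f["Percentage"],
        "RunVariance": f["SizeVariance"],
        "ShortRunEmphasis": f["SmallEmphasis"],
        "ShortRunHighGrayLevelEmphasis": f["SmallHighGrayLevelEmphasis"],
        "ShortRunLowGrayLevelEmphasis": f["SmallLowGrayLevelEmphasis"],
    }


BASE_GLRLM = (
    "GrayLevelNonUniformity", "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance", "HighGrayLevelRunEmphasis", "LongRunEmphasis",
    "LongRunHighGrayLevelEmphasis", "LongRunLowGrayLevelEmphasis",
    "LowGrayLevelRunEmphasis", "RunEntropy", "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized", "RunPercentage", "RunVariance",
    "ShortRunEmphasis", "ShortRunHighGrayLevelEmphasis",
    "ShortRunLowGrayLevelEmphasis")


def _lines(q: np.ndarray, dr: int, dc: int):
    """All scan lines of q along direction (dr, dc)."""
    if (dr, dc) == (0, 1):
        yield from q
    elif (dr, dc) == (1, 0):
        yield from q.T
    elif (dr, dc) == (1, 1):
        for off in range(-q.shape[0] + 1, q.shape[1]):
            yield np.diagonal(q, offset=off)
    else:  # (1, -1): anti-diagonals
        fl = np.fliplr(q)
        for off in range(-q.shape[0] + 1, q.shape[1]):
            yield np.diagonal(fl, offset=off)


def _runs(line: np.ndarray):
    """(value, run length) pairs along one scan line."""
    if line.size == 0:
        return
    change = np.flatnonzero(np.diff(line)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [line.size]])
    for s, e in zip(starts, ends):
        yield int(line[s]), int(e - s)


def glszm_features(q: np.ndarray, n_bins: int = N_BINS) -> dict[str, float]:
    """Gray-level size-zone features (8-connected zones)."""
    n_pixels = int((q > 0).sum())
    if n_pixels == 0:
        return {k: 0.0 for k in BASE_GLSZM}
    zones = []
    structure = np.ones((3, 3))
    for level in np.unique(q[q > 0]):
        lab, nlab = ndimage.label(q == level, structure=structure)
        sizes = np.bincount(lab.ravel())[1:]
        zones.extend((int(level), int(s)) for s in sizes)
    max_zone = max(s for _, s in zones)
    mat = np.zeros((n_bins, max_zone))
    for level, s in zones:
        mat[level - 1, s - 1] += 1
    f = _sij_features(mat, n_pixels, "GrayLevel", "Zone")
    return {
        "GrayLevelNonUniformity": f["GrayLevelNonUniformity"],
        "GrayLevelNonUniformityNormalized": f["GrayLevelNonUniformityNormalized"],
        "GrayLevelVariance": f["GrayLevelVariance"],
        "HighGrayLevelZoneEmphasis": f["HighGrayLevelEmphasis"],
        "LargeAreaEmphasis": f["LargeEmphasis"],
        "LargeAreaHighGrayLevelEmphasis": f["LargeHighGrayLevelEmphasis"],
        "LargeAreaLowGrayLevelEmphasis": f["LargeLowGrayLevelEmphasis"],
        "LowGrayLevelZoneEmphasis": f["LowGrayLevelEmphasis"],
        "SizeZoneNonUniformity": f["SizeNonUniformity"],
        "SizeZoneNonUniformityNormalized": f["SizeNonUniformityNormalized"],
        "SmallAreaEmphasis": f["SmallEmphasis"],
        "SmallAreaHighGrayLevelEmphasis": f["SmallHighGrayLevelEmphasis"],
        "SmallAreaLowGrayLevelEmphasis": f["SmallLowGrayLevelEmphasis"],
        "ZoneEntropy": f["Entropy"],
        "ZonePercentage": f["Percentage"],
        "ZoneVariance": f["SizeVariance"],
    }


BASE_GLSZM = (
    "GrayLevelNonUniformity", "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance", "HighGrayLevelZoneEmphasis", "LargeAreaEmphasis",
    "LargeAreaHighGrayLevelEmphasis", "LargeAreaLowGrayLevelEmphasis",
    "LowGrayLevelZoneEmphasis", "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized", "SmallAreaEmphasis",
    "SmallAreaHighGrayLevelEmphasis", "SmallAreaLowGrayLevelEmphasis",
    "ZoneEntropy", "ZonePercentage", "ZoneVariance")


def gldm_features(q: np.ndarray, n_bins: int = N_BINS, alpha: int = 0) -> dict[str, float]:
    """Gray-level dependence features (8-neighbourhood, tolerance alpha)."""
    mask = q > 0
    n_pixels = int(mask.sum())
    if n_pixels == 0:
        return {k: 0.0 for k in BASE_GLDM}
    pad = np.pad(q, 1)
    deps = np.zeros(q.shape, dtype=int)
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == dc == 0:
                continue
            nb = pad[1 + dr:pad.shape[0] - 1 + dr, 1 + dc:pad.shape[1] - 1 + dc]
            deps += (nb > 0) & (np.abs(nb - q) <= alpha)
    mat = np.zeros((n_bins, 9))  # dependence 0..8 -> column d+1 in 1-based j
    np.add.at(mat, (q[mask] - 1, deps[mask]), 1.0)
    # j index is dependence+1 so the ratio features stay finite at d=0
    f = _sij_features(mat, n_pixels, "GrayLevel", "Dependence")
    return {
        "DependenceEntropy": f["Entropy"],
        "DependenceNonUniformity": f["SizeNonUniformity"],
        "DependenceNonUniformityNormalized": f["SizeNonUniformityNormalized"],
        "DependenceVariance": f["SizeVariance"],
        "GrayLevelNonUniformity": f["GrayLevelNonUniformity"],
        "GrayLevelVariance": f["GrayLevelVariance"],
        "HighGrayLevelEmphasis": f["HighGrayLevelEmphasis"],
        "LargeDependenceEmphasis": f["LargeEmphasis"],
        "LargeDependenceHighGrayLevelEmphasis": f["LargeHighGrayLevelEmphasis"],
        "LargeDependenceLowGrayLevelEmphasis": f["LargeLowGrayLevelEmphasis"],
        "LowGrayLevelEmphasis": f["LowGrayLevelEmphasis"],
        "SmallDependenceEmphasis": f["SmallEmphasis"],
        "SmallDependenceHighGrayLevelEmphasis": f["SmallHighGrayLevelEmphasis"],
        "SmallDependenceLowGrayLevelEmphasis": f["SmallLowGrayLevelEmphasis"],
    }


BASE_GLDM = (
    "DependenceEntropy", "DependenceNonUniformity",
    "DependenceNonUniformityNormalized", "DependenceVariance",
    "GrayLevelNonUniformity", "GrayLevelVariance", "HighGrayLevelEmphasis",
    "LargeDependenceEmphasis", "LargeDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis", "LowGrayLevelEmphasis",
    "SmallDependenceEmphasis", "SmallDependenceHighGrayLevelEmphasis",
    "SmallDependenceLowGrayLevelEmphasis")


def ngtdm_features(q: np.ndarray, n_bins: int = N_BINS) -> dict[str, float]:
    """Neighbouring gray-tone difference features."""
    mask = q > 0
    n = int(mask.sum())
    if n == 0:
        return {k: 0.0 for k in ("Busyness", "Coarseness", "Complexity", "Contrast", "Strength")}
    pad = np.pad(q.astype(float), 1)
    padm = np.pad(mask, 1)
    nb_sum = np.zeros(q.shape)
    nb_cnt = np.zeros(q.shape)
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == dc == 0:
                continue
            nb = pad[1 + dr:pad.shape[0] - 1 + dr, 1 + dc:pad.shape[1] - 1 + dc]
            nbm = padm[1 + dr:padm.shape[0] - 1 + dr, 1 + dc:padm.shape[1] - 1 + dc]
            nb_sum += nb * nbm
            nb_cnt += nbm
    has_nb = mask & (nb_cnt > 0)
    avg = np.zeros(q.shape)
    avg[has_nb] = nb_sum[has_nb] / nb_cnt[has_nb]
    s = np.zeros(n_bins)
    cnt = np.zeros(n_bins)
    lv = q[has_nb] - 1
    np.add.at(s, lv, np.abs(q[has_nb] - avg[has_nb]))
    np.add.at(cnt, lv, 1.0)
    p = cnt / n
    present = p > 0
    ngp = int(present.sum())
    i = np.arange(1, n_bins + 1, dtype=float)

    coarse_den = float((p * s).sum())
    coarseness = min(1.0 / coarse_den, 1e6) if coarse_den > 0 else 1e6
    if ngp > 1:
        pi, pj = np.meshgrid(p[present], p[present], indexing="ij")
        li, lj = np.meshgrid(i[present], i[present], indexing="ij")
        contrast = float((pi * pj * (li - lj) ** 2).sum()) / (ngp * (ngp - 1)) * s.sum() / n
        busy_den = float(np.abs(li * pi - lj * pj).sum())
        busyness = coarse_den / busy_den if busy_den > 0 else 0.0
        si, sj = np.meshgrid(s[present], s[present], indexing="ij")
        complexity = float((np.abs(li - lj) * (pi * si + pj * sj) / (pi + pj)).sum()) / n
        strength = (float(((pi + pj) * (li - lj) ** 2).sum()) / s.sum()) if s.sum() > 0 else 0.0
    else:
        contrast = busyness = complexity = strength = 0.0
    return {"Busyness": busyness, "Coarseness": coarseness,
            "Complexity": complexity, "Contrast": contrast, "Strength": strength}


def shape_features(mask: np.ndarray) -> dict[str, float]:
    """2D shape descriptors of the (largest connected) mask region."""
    lab = measure.label(mask, connectivity=2)
    props = measure.regionprops(lab)
    r = max(props, key=lambda p: p.area)
    perim = max(r.perimeter, 1e-9)
    return {
        "Area": float(r.area),
        "Perimeter": float(r.perimeter),
        "PerimeterAreaRatio": float(perim / r.area),
        "MajorAxisLength": float(r.axis_major_length),
        "MinorAxisLength": float(r.axis_minor_length),
        "Elongation": float(r.axis_minor_length / r.axis_major_length)
        if r.axis_major_length > 0 else 1.0,
        "Eccentricity": float(r.eccentricity),
        "Sphericity": float(2.0 * np.sqrt(np.pi * r.area) / perim),
        "MaximumDiameter": float(r.feret_diameter_max),
        "Extent": float(r.extent),
        "Solidity": float(r.solidity),
        "EquivalentDiameter": float(r.equivalent_diameter_area),
    }


CLASS_FUNCS = {
    "firstorder": None,  # operates on continuous values, handled by caller
    "glcm": glcm_features,
    "gldm": gldm_features,
    "glrlm": glrlm_features,
    "glszm": glszm_features,
    "ngtdm": ngtdm_features,
}
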