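"""Gray-level texture-matrix features (GLCM, GLRLM, GLSZM, GLDM, NGTDM).

All functions operate on a discretized label volume ``L`` (int array on the
ROI bounding box; 0 = outside the ROI, 1..Ng = gray level). GLCM and GLRLM
are computed per direction over the 13 unique 3D directions at distance 1 and
averaged; GLSZM zones and GLDM/NGTDM neighborhoods use 26-connectivity.

Degenerate single-gray-level ROIs return the documented fallbacks (entropies
0, correlation-type features 1 or 0) instead of NaN.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy import ndimage

GLCM_FEATURE_NAMES = (
    "Autocorrelation", "ClusterProminence", "ClusterShade", "ClusterTendency",
    "Contrast", "Correlation", "DifferenceAverage", "DifferenceEntropy",
    "DifferenceVariance", "Id", "Idm", "Idmn", "Idn", "Imc1", "Imc2",
    "InverseVariance", "JointAverage", "JointEnergy", "JointEntropy", "MCC",
    "MaximumProbability", "SumAverage", "SumEntropy", "SumSquares",
)
GLRLM_FEATURE_NAMES = (
    "GrayLevelNonUniformity", "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance", "HighGrayLevelRunEmphasis", "LongRunEmphasis",
    "LongRunHighGrayLevelEmphasis", "LongRunLowGrayLevelEmphasis",
    "LowGrayLevelRunEmphasis", "RunEntropy", "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized", "RunPercentage", "RunVariance",
    "ShortRunEmphasis", "ShortRunHighGrayLevelEmphasis",
    "ShortRunLowGrayLevelEmphasis",
)
GLSZM_FEATURE_NAMES = (
    "GrayLevelNonUniformity", "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance", "HighGrayLevelZoneEmphasis", "LargeAreaEmphasis",
    "LargeAreaHighGrayLevelEmphasis", "LargeAreaLowGrayLevelEmphasis",
    "LowGrayLevelZoneEmphasis", "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized", "SmallAreaEmphasis",
    "SmallAreaHighGrayLevelEmphasis", "SmallAreaLowGrayLevelEmphasis",
    "ZoneEntropy", "ZonePercentage", "ZoneVariance",
)
GLDM_FEATURE_NAMES = (
    "DependenceEntropy", "DependenceNonUniformity",
    "DependenceNonUniformityNormalized", "DependenceVariance",
    "GrayLevelNonUniformity", "GrayLevelVariance", "HighGrayLevelEmphasis",
    "LargeDependenceEmphasis", "LargeDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis", "LowGrayLevelEmphasis",
    "SmallDependenceEmphasis", "SmallDependenceHighGrayLevelEmphasis",
    "SmallDependenceLowGrayLevelEmphasis",
)
NGTDM_FEATURE_NAMES = ("Busyness", "Coarseness", "Complexity", "Contrast", "Strength")

#: The 13 unique 3D direction vectors at Chebyshev distance 1.
DIRECTIONS_3D = tuple(
    d
    for d in itertools.product((-1, 0, 1), repeat=3)
    if d > (0, 0, 0)
)

_EPS = np.finfo(np.float64).eps


def _shift(arr: np.ndarray, d: tuple[int, int, int], fill=0) -> np.ndarray:
    """result[v] = arr[v + d], with out-of-bounds filled."""
    out = np.full_like(arr, fill)
    src = []
    dst = []
    for n, di in zip(arr.shape, d):
        if di >= 0:
            src.append(slice(di, n))
            dst.append(slice(0, n - di))
        else:
            src.append(slice(0, n + di))
            dst.append(slice(-di, n))
    out[tuple(dst)] = arr[tuple(src)]
    return out


def _compact_levels(L: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Map labels to 1..Ngp and return the original gray values per row."""
    grays = np.unique(L[L > 0])
    lut = np.zeros(int(L.max()) + 1, dtype=np.int64)
    lut[grays] = np.arange(1, len(grays) + 1)
    return lut[L], grays.astype(np.float64)


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

def glcm_matrix(L: np.ndarray, n_levels: int, d: tuple[int, int, int]) -> np.ndarray:
    """Symmetric, normalized co-occurrence matrix for one direction."""
    Ln = _shift(L, d)
    valid = (L > 0) & (Ln > 0)
    pairs = L[valid] * (n_levels + 1) + Ln[valid]
    counts = np.bincount(pairs, minlength=(n_levels + 1) ** 2).reshape(
        n_levels + 1, n_levels + 1
    )[1:, 1:]
    P = counts + counts.T
    total = P.sum()
    return P / total if total > 0 else P.astype(np.float64)


def _entropy_over_groups(weights: np.ndarray, groups: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Aggregate flat probability weights by group value; returns (values, probs)."""
    vals, inv = np.unique(groups, return_inverse=True)
    probs = np.bincount(inv, weights=weights)
    return vals, probs


def _glcm_features_single(P: np.ndarray, lv: np.ndarray) -> dict[str, float]:
    ng = len(lv)
    i = lv[:, None]
    j = lv[None, :]
    D = np.abs(i - j)
    S = i + j
    px = P.sum(axis=1)
    mu = float((px * lv).sum())
    sigma2 = float((px * (lv - mu) ** 2).sum())

    d_vals, d_p = _entropy_over_groups(P.ravel(), D.ravel())
    s_vals, s_p = _entropy_over_groups(P.ravel(), S.ravel())
    da = float((d_vals * d_p).sum())

    hxy = float(-(P[P > 0] * np.log2(P[P > 0])).sum())
    px_pos = px[px > 0]
    hx = float(-(px_pos * np.log2(px_pos)).sum())
    pxpy = np.outer(px, px)
    nz = (P > 0) & (pxpy > 0)
    hxy1 = float(-(P[nz] * np.log2(pxpy[nz])).sum())
    nz2 = pxpy > 0
    hxy2 = float(-(pxpy[nz2] * np.log2(pxpy[nz2])).sum())

    if ng > 1 and sigma2 > 0:
        correlation = float(((P * i * j).sum() - mu * mu) / sigma2)
    else:
        correlation = 1.0
    imc1 = (hxy - hxy1) / hx if hx > 0 else 0.0
    imc2 = float(np.sqrt(1 - np.exp(-2.0 * (hxy2 - hxy)))) if hxy2 >= hxy else 0.0

    if ng > 1:
        with np.errstate(divide="ignore", invalid="ignore"):
            Q = P / np.where(px > 0, px, 1.0)[:, None]
            Q = Q @ (P / np.where(px > 0, px, 1.0)[:, None]).T
        eig = np.sort(np.linalg.eigvals(Q).real)
        mcc = float(np.sqrt(max(eig[-2], 0.0))) if len(eig) > 1 else 1.0
    else:
        mcc = 1.0

    off = D > 0
    return {
        "Autocorrelation": float((P * i * j).sum()),
        "ClusterProminence": float((P * (S - 2 * mu) ** 4).sum()),
        "ClusterShade": float((P * (S - 2 * mu) ** 3).sum()),
        "ClusterTendency": float((P * (S - 2 * mu) ** 2).sum()),
        "Contrast": float((P * D**2).sum()),
        "Correlation": correlation,
        "DifferenceAverage": da,
        "DifferenceEntropy": float(-(d_p[d_p > 0] * np.log2(d_p[d_p > 0])).sum()),
        "DifferenceVariance": float((d_p * (d_vals - da) ** 2).sum()),
        "Id": float((P / (1.0 + D)).sum()),
        "Idm": float((P / (1.0 + D**2)).sum()),
        "Idmn": float((P / (1.0 + D**2 / ng**2)).sum()),
        "Idn": float((P / (1.0 + D / ng)).sum()),
        "Imc1": float(imc1),
        "Imc2": imc2,
        "InverseVariance": float((P[off] / D[off] ** 2).sum()) if off.any() else 0.0,
        "JointAverage": mu,
        "JointEnergy": float((P**2).sum()),
        "JointEntropy": hxy,
        "MCC": mcc,
        "MaximumProbability": float(P.max()),
        "SumAverage": float((s_vals * s_p).sum()),
        "SumEntropy": float(-(s_p[s_p > 0] * np.log2(s_p[s_p > 0])).sum()),
        "SumSquares": sigma2,
    }


def glcm_features(L: np.ndarray) -> dict[str, float]:
    """GLCM features averaged over the 13 unique 3D directions."""
    Lc, lv = _compact_levels(L)
    per_dir = []
    for d in DIRECTIONS_3D:
        P = glcm_matrix(Lc, len(lv), d)
        if P.sum() == 0:
            continue
        per_dir.append(_glcm_features_single(P, lv))
    if not per_dir:
        raise ValueError("no co-occurring voxel pairs in ROI")
    return {k: float(np.mean([f[k] for f in per_dir])) for k in GLCM_FEATURE_NAMES}


# ---------------------------------------------------------------------------
# GLRLM
# ---------------------------------------------------------------------------

def run_length_matrix(L: np.ndarray, n_levels: int, d: tuple[int, int, int]) -> np.ndarray:
    """Run-length counts P[i-1, l-1] along one direction (vectorized scan)."""
    in_roi = L > 0
    Ln = _shift(L, d)
    same = in_roi & (Ln == L) & (Ln > 0)

    # Suffix run length: s[v] = 1 + s[v+d] when the next voxel continues the run.
    s = in_roi.astype(np.int64)
    max_iter = int(np.ceil(np.linalg.norm(L.shape)) + 2)
    for _ in range(max_iter):
        s_new = np.where(same, 1 + _shift(s, d), in_roi.astype(np.int64))
        if np.array_equal(s_new, s):
            break
        s = s_new

    pred_same = _shift(same, tuple(-x for x in d))
    starts = in_roi & ~pred_same
    grays = L[starts]
    lengths = s[starts]
    max_len = int(lengths.max()) if lengths.size else 1
    P = np.zeros((n_levels, max_len), dtype=np.float64)
    np.add.at(P, (grays - 1, lengths - 1), 1.0)
    return P


def _weighted_matrix_features(
    P: np.ndarray, iv: np.ndarray, jv: np.ndarray, n_p: int,
    names: dict[str, str],
) -> dict[str, float]:
    """Shared size/gray-weighted statistics for run/zone/dependence matrices.

    ``names`` maps the generic keys to the family's feature names; generic
    keys: small, large, gln, glnn, sn, snn, perc, glv, sv, ent, lgl, hgl,
    s_lgl, s_hgl, l_lgl, l_hgl.
    """
    ns = P.sum()
    if ns == 0:
        raise ValueError("empty texture matrix")
    i2 = iv[:, None] ** 2
    j2 = jv[None, :] ** 2
    pg = P.sum(axis=1)  # per gray level
    ps = P.sum(axis=0)  # per size
    p = P / ns
    mu_i = (p.sum(axis=1) * iv).sum()
    mu_j = (p.sum(axis=0) * jv).sum()
    out = {
        "small": float((P / j2).sum() / ns),
        "large": float((P * j2).sum() / ns),
        "gln": float((pg**2).sum() / ns),
        "glnn": float((pg**2).sum() / ns**2),
        "sn": float((ps**2).sum() / ns),
        "snn": float((ps**2).sum() / ns**2),
        "perc": float(ns / n_p),
        "glv": float((p.sum(axis=1) * (iv - mu_i) ** 2).sum()),
        "sv": float((p.sum(axis=0) * (jv - mu_j) ** 2).sum()),
        "ent": float(-(p[p > 0] * np.log2(p[p > 0])).sum()),
        "lgl": float((P / i2).sum() / ns),
        "hgl": float((P * i2).sum() / ns),
        "s_lgl": float((P / (i2 * j2)).sum() / ns),
        "s_hgl": float((P * i2 / j2).sum() / ns),
        "l_lgl": float((P * j2 / i2).sum() / ns),
        "l_hgl": float((P * i2 * j2).sum() / ns),
    }
    return {full: out[key] for key, full in names.items() if full is not None}


_GLRLM_MAP = {
    "small": "ShortRunEmphasis", "large": "LongRunEmphasis",
    "gln": "GrayLevelNonUniformity", "glnn": "GrayLevelNonUniformityNormalized",
    "sn": "RunLengthNonUniformity", "snn": "RunLengthNonUniformityNormalized",
    "perc": "RunPercentage", "glv": "GrayLevelVariance", "sv": "RunVariance",
    "ent": "RunEntropy", "lgl": "LowGrayLevelRunEmphasis",
    "hgl": "HighGrayLevelRunEmphasis", "s_lgl": "ShortRunLowGrayLevelEmphasis",
    "s_hgl": "ShortRunHighGrayLevelEmphasis", "l_lgl": "LongRunLowGrayLevelEmphasis",
    "l_hgl": "LongRunHighGrayLevelEmphasis",
}

_GLSZM_MAP = {
    "small": "SmallAreaEmphasis", "large": "LargeAreaEmphasis",
    "gln": "GrayLevelNonUniformity", "glnn": "GrayLevelNonUniformityNormalized",
    "sn": "SizeZoneNonUniformity", "snn": "SizeZoneNonUniformityNormalized",
    "perc": "ZonePercentage", "glv": "GrayLevelVariance", "sv": "ZoneVariance",
    "ent": "ZoneEntropy", "lgl": "LowGrayLevelZoneEmphasis",
    "hgl": "HighGrayLevelZoneEmphasis", "s_lgl": "SmallAreaLowGrayLevelEmphasis",
    "s_hgl": "SmallAreaHighGrayLevelEmphasis", "l_lgl": "LargeAreaLowGrayLevelEmphasis",
    "l_hgl": "LargeAreaHighGrayLevelEmphasis",
}


def glrlm_features(L: np.ndarray) -> dict[str, float]:
    """Run-length features averaged over the 13 unique 3D directions."""
    Lc, lv = _compact_levels(L)
    n_p = int((L > 0).sum())
    per_dir = []
    for d in DIRECTIONS_3D:
        P = run_length_matrix(Lc, len(lv), d)
        jv = np.arange(1, P.shape[1] + 1, dtype=np.float64)
        per_dir.append(_weighted_matrix_features(P, lv, jv, n_p, _GLRLM_MAP))
    return {k: float(np.mean([f[k] for f in per_dir])) for k in GLRLM_FEATURE_NAMES}


# ---------------------------------------------------------------------------
# GLSZM
# ---------------------------------------------------------------------------

def size_zone_matrix(L: np.ndarray, n_levels: int) -> np.ndarray:
    """Zone-size counts P[i-1, s-1]; zones are 26-connected same-level components."""
    structure = np.ones((3, 3, 3), dtype=int)
    rows, sizes = [], []
    for g in range(1, n_levels + 1):
        lab, n_zone = ndimage.label(L == g, structure=structure)
        if n_zone == 0:
            continue
        zone_sizes = np.bincount(lab.ravel())[1:]
        rows.extend([g] * n_zone)
        sizes.extend(zone_sizes.tolist())
    sizes = np.asarray(sizes, dtype=np.int64)
    P = np.zeros((n_levels, int(sizes.max())), dtype=np.float64)
    np.add.at(P, (np.asarray(rows) - 1, sizes - 1), 1.0)
    return P


def glszm_features(L: np.ndarray) -> dict[str, float]:
    Lc, lv = _compact_levels(L)
    n_p = int((L > 0).sum())
    P = size_zone_matrix(Lc, len(lv))
    jv = np.arange(1, P.shape[1] + 1, dtype=np.float64)
    return {
        k: v
        for k, v in _weighted_matrix_features(P, lv, jv, n_p, _GLSZM_MAP).items()
        if k in GLSZM_FEATURE_NAMES
    }


# ---------------------------------------------------------------------------
# GLDM
# ---------------------------------------------------------------------------

_GLDM_MAP = {
    "small": "SmallDependenceEmphasis", "large": "LargeDependenceEmphasis",
    "gln": "GrayLevelNonUniformity", "glnn": None,
    "sn": "DependenceNonUniformity", "snn": "DependenceNonUniformityNormalized",
    "perc": None, "glv": "GrayLevelVariance", "sv": "DependenceVariance",
    "ent": "DependenceEntropy", "lgl": "LowGrayLevelEmphasis",
    "hgl": "HighGrayLevelEmphasis", "s_lgl": "SmallDependenceLowGrayLevelEmphasis",
    "s_hgl": "SmallDependenceHighGrayLevelEmphasis",
    "l_lgl": "LargeDependenceLowGrayLevelEmphasis",
    "l_hgl": "LargeDependenceHighGrayLevelEmphasis",
}


def dependence_matrix(L: np.ndarray, n_levels: int) -> np.ndarray:
    """Dependence counts P[i-1, j-1]; j = 1 + number of 26-neighbors with the
    same gray level (the center voxel always depends on itself)."""
    in_roi = L > 0
    dep = np.zeros(L.shape, dtype=np.int64)
    for d in DIRECTIONS_3D:
        for dd in (d, tuple(-x for x in d)):
            Ln = _shift(L, dd)
            dep += (in_roi & (Ln == L) & (Ln > 0)).astype(np.int64)
    j = dep[in_roi] + 1
    g = L[in_roi]
    P = np.zeros((n_levels, int(j.max())), dtype=np.float64)
    np.add.at(P, (g - 1, j - 1), 1.0)
    return P


def gldm_features(L: np.ndarray) -> dict[str, float]:
    Lc, lv = _compact_levels(L)
    n_p = int((L > 0).sum())
    P = dependence_matrix(Lc, len(lv))
    jv = np.arange(1, P.shape[1] + 1, dtype=np.float64)
    return _weighted_matrix_features(P, lv, jv, n_p, _GLDM_MAP)


# ---------------------------------------------------------------------------
# NGTDM
# ---------------------------------------------------------------------------

def ngtdm_features(L: np.ndarray) -> dict[str, float]:
    """Neighborhood gray-tone difference features (26-neighborhood means)."""
    Lc, lv = _compact_levels(L)
    in_roi = Lc > 0
    kernel = np.ones((3, 3, 3))
    kernel[1, 1, 1] = 0.0
    # neighbor sums of actual gray values and counts of in-ROI neighbors
    gray_vol = np.zeros(Lc.shape, dtype=np.float64)
    gray_vol[in_roi] = lv[Lc[in_roi] - 1]
    nb_sum = ndimage.convolve(gray_vol, kernel, mode="constant", cval=0.0)
    nb_cnt = ndimage.convolve(in_roi.astype(np.float64), kernel, mode="constant", cval=0.0)

    valid = in_roi & (nb_cnt > 0)
    diffs = np.abs(gray_vol[valid] - nb_sum[valid] / nb_cnt[valid])
    labels = Lc[valid]

    ngp_all = len(lv)
    n_i = np.bincount(labels - 1, minlength=ngp_all).astype(np.float64)
    s_i = np.bincount(labels - 1, weights=diffs, minlength=ngp_all)
    nvp = n_i.sum()
    p_i = n_i / nvp

    present = p_i > 0
    iv = lv[present]
    p = p_i[present]
    s = s_i[present]
    ngp = int(present.sum())

    ps = float((p * s).sum())
    coarseness = 1.0 / ps if ps > 0 else 1e6

    if ngp > 1:
        di = iv[:, None] - iv[None, :]
        contrast = float(
            (np.outer(p, p) * di**2).sum() / (ngp * (ngp - 1)) * (s.sum() / nvp)
        )
        ipi = iv * p
        busy_den = float(np.abs(ipi[:, None] - ipi[None, :]).sum())
        busyness = ps / busy_den if busy_den > 0 else 0.0
        pis = p * s
        complexity = float(
            (np.abs(di) * (pis[:, None] + pis[None, :]) / (p[:, None] + p[None, :])).sum()
            / nvp
        )
        s_sum = float(s.sum())
        strength = (
            float(((p[:, None] + p[None, :]) * di**2).sum()) / s_sum if s_sum > 0 else 0.0
        )
    else:
        contrast = busyness = complexity = strength = 0.0

    return {
        "Busyness": busyness,
        "Coarseness": coarseness,
        "Complexity": complexity,
        "Contrast": contrast,
        "Strength": strength,
    }
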