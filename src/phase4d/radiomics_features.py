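"""IBSI-aligned first-order and texture feature computation on 3-D ROIs.

Implements the 93 first-order and texture features used throughout the
package: 18 first-order, 24 grey level co-occurrence matrix (GLCM), 16 grey
level run length matrix (GLRLM), 16 grey level size zone matrix (GLSZM), 5
neighbouring grey tone difference matrix (NGTDM) and 14 grey level dependence
matrix (GLDM) features.

Conventions
-----------
* Intensities are discretised with a fixed bin width anchored at the ROI
  minimum: ``level = floor((x - min) / width) + 1``; levels run 1..Ng.  This
  makes texture features invariant to adding a constant to the ROI.
* GLCM and GLRLM are computed per 3-D direction (13 unique angles, distance 1)
  and feature values are averaged over directions; the GLCM is symmetrised.
* GLSZM zones and GLDM/NGTDM neighbourhoods use 26-connectivity.
* GLDM dependence size is 1 + the number of 26-neighbours (inside the ROI)
  whose level differs from the centre by at most ``alpha`` (default 0).

Matrix computations are performed on the bounding box of the mask.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

EPS = np.finfo(float).eps

#: 13 unique direction offsets covering all 26 neighbours up to sign.
ANGLES: tuple[tuple[int, int, int], ...] = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0) or (dx, dy, dz) < (0, 0, 0)
)[13:]  # second half: the 13 strictly-positive lexicographic offsets

OFFSETS_26 = [(dx, dy, dz)
              for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
              if (dx, dy, dz) != (0, 0, 0)]


def discretise(values: np.ndarray, bin_width: float) -> np.ndarray:
    """Fixed-bin-width discretisation anchored at the ROI minimum (levels >= 1)."""
    values = np.asarray(values, dtype=float)
    return np.floor((values - values.min()) / bin_width).astype(int) + 1


def _crop(image: np.ndarray, mask: np.ndarray):
    sl = ndimage.find_objects(mask.astype(int))[0]
    return image[sl], mask[sl]


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


# ---------------------------------------------------------------- first order

def first_order(values: np.ndarray, bin_width: float,
                voxel_volume: float) -> dict[str, float]:
    x = np.asarray(values, dtype=float)
    n = x.size
    mean = x.mean()
    var = x.var()  # population variance
    p10, p25, p75, p90 = np.percentile(x, [10, 25, 75, 90])
    robust = x[(x >= p10) & (x <= p90)]
    m2 = var
    m3 = ((x - mean) ** 3).mean()
    m4 = ((x - mean) ** 4).mean()
    lv = discretise(x, bin_width)
    p = np.bincount(lv)[1:] / n
    return {
        "Energy": float((x ** 2).sum()),
        "TotalEnergy": float(voxel_volume * (x ** 2).sum()),
        "Entropy": _entropy(p),
        "Minimum": float(x.min()),
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Maximum": float(x.max()),
        "Mean": float(mean),
        "Median": float(np.median(x)),
        "InterquartileRange": float(p75 - p25),
        "Range": float(x.max() - x.min()),
        "MeanAbsoluteDeviation": float(np.abs(x - mean).mean()),
        "RobustMeanAbsoluteDeviation":
            float(np.abs(robust - robust.mean()).mean()) if robust.size else 0.0,
        "RootMeanSquared": float(np.sqrt((x ** 2).mean())),
        "Skewness": float(m3 / m2 ** 1.5) if m2 > 0 else 0.0,
        "Kurtosis": float(m4 / m2 ** 2) if m2 > 0 else 0.0,
        "Variance": float(var),
        "Uniformity": float((p ** 2).sum()),
    }


# ----------------------------------------------------------------------- GLCM

def _glcm_matrix(levels: np.ndarray, mask: np.ndarray, ng: int,
                 offset) -> np.ndarray:
    """Symmetric co-occurrence counts for one offset (distance 1)."""
    sl_a, sl_b = [], []
    for d in offset:
        if d == 0:
            sl_a.append(slice(None)); sl_b.append(slice(None))
        elif d > 0:
            sl_a.append(slice(None, -d)); sl_b.append(slice(d, None))
        else:
            sl_a.append(slice(-d, None)); sl_b.append(slice(None, d))
    a, b = levels[tuple(sl_a)], levels[tuple(sl_b)]
    valid = mask[tuple(sl_a)] & mask[tuple(sl_b)]
    i, j = a[valid] - 1, b[valid] - 1
    m = np.zeros((ng, ng))
    np.add.at(m, (i, j), 1.0)
    return m + m.T


def _glcm_features(P: np.ndarray) -> dict[str, float]:
    ng = P.shape[0]
    s = P.sum()
    if s == 0:
        return {k: np.nan for k in GLCM_NAMES}
    P = P / s
    i = np.arange(1, ng + 1)
    I, J = np.meshgrid(i, i, indexing="ij")
    px = P.sum(axis=1)
    mu = float((i * px).sum())
    sig2 = float(((i - mu) ** 2 * px).sum())
    # sum and difference distributions
    ksum = np.arange(2, 2 * ng + 1)
    psum = np.array([P[I + J == k].sum() for k in ksum])
    kdiff = np.arange(0, ng)
    pdiff = np.array([P[np.abs(I - J) == k].sum() for k in kdiff])
    da = float((kdiff * pdiff).sum())
    HXY = _entropy(P.ravel())
    HX = _entropy(px)
    pxpy = np.outer(px, px)
    nz = pxpy > 0
    HXY1 = float(-(P[nz] * np.log2(pxpy[nz] + EPS)).sum())
    HXY2 = float(-(pxpy[nz] * np.log2(pxpy[nz])).sum())
    if sig2 > 0:
        corr = float(((I * J * P).sum() - mu * mu) / sig2)
    else:
        corr = 1.0
    imc1 = (HXY - HXY1) / HX if HX > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (HXY2 - HXY)))))
    offdiag = I != J
    inv_var = float((P[offdiag] / (I - J)[offdiag] ** 2).sum()) if offdiag.any() else 0.0
    # maximal correlation coefficient
    if ng == 1 or sig2 == 0:
        mcc = 1.0
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            W = P / np.where(px[None, :] > 0, px[None, :], np.nan)
        W = np.nan_to_num(W)
        Q = (P / np.where(px[:, None] > 0, px[:, None], np.inf)) @ W
        ev = np.sort(np.abs(np.linalg.eigvals(Q)))
        mcc = float(np.sqrt(max(0.0, ev[-2].real))) if ev.size > 1 else 1.0
    return {
        "Autocorrelation": float((I * J * P).sum()),
        "JointAverage": mu,
        "ClusterProminence": float(((I + J - 2 * mu) ** 4 * P).sum()),
        "ClusterShade": float(((I + J - 2 * mu) ** 3 * P).sum()),
        "ClusterTendency": float(((I + J - 2 * mu) ** 2 * P).sum()),
        "Contrast": float(((I - J) ** 2 * P).sum()),
        "Correlation": corr,
        "DifferenceAverage": da,
        "DifferenceEntropy": _entropy(pdiff),
        "DifferenceVariance": float(((kdiff - da) ** 2 * pdiff).sum()),
        "Id": float((P / (1.0 + np.abs(I - J))).sum()),
        "Idm": float((P / (1.0 + (I - J) ** 2)).sum()),
        "Idmn": float((P / (1.0 + (I - J) ** 2 / ng ** 2)).sum()),
        "Idn": float((P / (1.0 + np.abs(I - J) / ng)).sum()),
        "Imc1": float(imc1),
        "Imc2": imc2,
        "InverseVariance": inv_var,
        "JointEnergy": float((P ** 2).sum()),
        "JointEntropy": HXY,
        "MCC": mcc,
        "MaximumProbability": float(P.max()),
        "SumAverage": float((ksum * psum).sum()),
        "SumEntropy": _entropy(psum),
        "SumSquares": sig2,
    }


GLCM_NAMES = (
    "Autocorrelation", "JointAverage", "ClusterProminence", "ClusterShade",
    "ClusterTendency", "Contrast", "Correlation", "DifferenceAverage",
    "DifferenceEntropy", "DifferenceVariance", "Id", "Idm", "Idmn", "Idn",
    "Imc1", "Imc2", "InverseVariance", "JointEnergy", "JointEntropy", "MCC",
    "MaximumProbability", "SumAverage", "SumEntropy", "SumSquares")


def glcm(levels: np.ndarray, mask: np.ndarray) -> dict[str, float]:
    ng = int(levels[mask].max())
    per_angle = [_glcm_features(_glcm_matrix(levels, mask, ng, off))
                 for off in ANGLES]
    return {k: float(np.nanmean([f[k] for f in per_angle])) for k in GLCM_NAMES}


# ---------------------------------------------------------------------- GLRLM

def _runs_for_direction(levels: np.ndarray, mask: np.ndarray, ng: int,
                        offset) -> np.ndarray:
    """Run-length counts R[i, l] for one direction (pure line walk)."""
    shape = levels.shape
    off = np.asarray(offset)
    starts = []
    grid = np.indices(shape).reshape(3, -1).T
    prev = grid - off
    inb = ((prev >= 0) & (prev < np.array(shape))).all(axis=1)
    starts = grid[~inb]
    max_len = int(levels.size)
    counts: dict[tuple[int, int], int] = {}
    for s in starts:
        pos = s.copy()
        run_level, run_len = 0, 0
        while ((pos >= 0) & (pos < np.array(shape))).all():
            p = tuple(pos)
            if mask[p]:
                lv = levels[p]
                if lv == run_level:
                    run_len += 1
                else:
                    if run_len:
                        counts[(run_level, run_len)] = counts.get(
                            (run_level, run_len), 0) + 1
                    run_level, run_len = lv, 1
            else:
                if run_len:
                    counts[(run_level, run_len)] = counts.get(
                        (run_level, run_len), 0) + 1
                run_level, run_len = 0, 0
            pos += off
        if run_len:
            counts[(run_level, run_len)] = counts.get((run_level, run_len), 0) + 1
    if not counts:
        return np.zeros((ng, 1))
    lmax = max(l for _, l in counts)
    R = np.zeros((ng, lmax))
    for (lv, l), c in counts.items():
        R[lv - 1, l - 1] = c
    return R


def _rlm_type_features(R: np.ndarray, n_vox: int, kind: str) -> dict[str, float]:
    """Shared formulas for run-length (kind='Run') and size-zone (kind='Zone')."""
    nr = R.sum()
    if nr == 0:
        return {}
    ng, nl = R.shape
    i = np.arange(1, ng + 1)[:, None]
    l = np.arange(1, nl + 1)[None, :]
    p = R / nr
    mu_i = (p * i).sum()
    mu_l = (p * l).sum()
    gsum = R.sum(axis=1)
    lsum = R.sum(axis=0)
    out = {
        "GrayLevelNonUniformity": float((gsum ** 2).sum() / nr),
        "GrayLevelNonUniformityNormalized": float((gsum ** 2).sum() / nr ** 2),
        "GrayLevelVariance": float((p * (i - mu_i) ** 2).sum()),
    }
    if kind == "Run":
        out.update({
            "ShortRunEmphasis": float((R / l ** 2).sum() / nr),
            "LongRunEmphasis": float((R * l ** 2).sum() / nr),
            "RunLengthNonUniformity": float((lsum ** 2).sum() / nr),
            "RunLengthNonUniformityNormalized": float((lsum ** 2).sum() / nr ** 2),
            "RunPercentage": float(nr / n_vox),
            "RunVariance": float((p * (l - mu_l) ** 2).sum()),
            "RunEntropy": _entropy(p.ravel()),
            "LowGrayLevelRunEmphasis": float((R / i ** 2).sum() / nr),
            "HighGrayLevelRunEmphasis": float((R * i ** 2).sum() / nr),
            "ShortRunLowGrayLevelEmphasis": float((R / (i ** 2 * l ** 2)).sum() / nr),
            "ShortRunHighGrayLevelEmphasis": float((R * i ** 2 / l ** 2).sum() / nr),
            "LongRunLowGrayLevelEmphasis": float((R * l ** 2 / i ** 2).sum() / nr),
            "LongRunHighGrayLevelEmphasis": float((R * i ** 2 * l ** 2).sum() / nr),
        })
    else:
        out.update({
            "SmallAreaEmphasis": float((R / l ** 2).sum() / nr),
            "LargeAreaEmphasis": float((R * l ** 2).sum() / nr),
            "SizeZoneNonUniformity": float((lsum ** 2).sum() / nr),
            "SizeZoneNonUniformityNormalized": float((lsum ** 2).sum() / nr ** 2),
            "ZonePercentage": float(nr / n_vox),
            "ZoneVariance": float((p * (l - mu_l) ** 2).sum()),
            "ZoneEntropy": _entropy(p.ravel()),
            "LowGrayLevelZoneEmphasis": float((R / i ** 2).sum() / nr),
            "HighGrayLevelZoneEmphasis": float((R * i ** 2).sum() / nr),
            "SmallAreaLowGrayLevelEmphasis": float((R / (i ** 2 * l ** 2)).sum() / nr),
            "SmallAreaHighGrayLevelEmphasis": float((R * i ** 2 / l ** 2).sum() / nr),
            "LargeAreaLowGrayLevelEmphasis": float((R * l ** 2 / i ** 2).sum() / nr),
            "LargeAreaHighGrayLevelEmphasis": float((R * i ** 2 * l ** 2).sum() / nr),
        })
    return out


GLRLM_NAMES = tuple(sorted(
    ["GrayLevelNonUniformity", "GrayLevelNonUniformityNormalized",
     "GrayLevelVariance", "ShortRunEmphasis", "LongRunEmphasis",
     "RunLengthNonUniformity", "RunLengthNonUniformityNormalized",
     "RunPercentage", "RunVariance", "RunEntropy", "LowGrayLevelRunEmphasis",
     "HighGrayLevelRunEmphasis", "ShortRunLowGrayLevelEmphasis",
     "ShortRunHighGrayLevelEmphasis", "LongRunLowGrayLevelEmphasis",
     "LongRunHighGrayLevelEmphasis"]))

GLSZM_NAMES = tuple(sorted(
    ["GrayLevelNonUniformity", "GrayLevelNonUniformityNormalized",
     "GrayLevelVariance", "SmallAreaEmphasis", "LargeAreaEmphasis",
     "SizeZoneNonUniformity", "SizeZoneNonUniformityNormalized",
     "ZonePercentage", "ZoneVariance", "ZoneEntropy",
     "LowGrayLevelZoneEmphasis", "HighGrayLevelZoneEmphasis",
     "SmallAreaLowGrayLevelEmphasis", "SmallAreaHighGrayLevelEmphasis",
     "LargeAreaLowGrayLevelEmphasis", "LargeAreaHighGrayLevelEmphasis"]))


def glrlm(levels: np.ndarray, mask: np.ndarray) -> dict[str, float]:
    ng = int(levels[mask].max())
    n_vox = int(mask.sum())
    per_dir = [_rlm_type_features(_runs_for_direction(levels, mask, ng, off),
                                  n_vox, "Run") for off in ANGLES]
    return {k: float(np.mean([f[k] for f in per_dir])) for k in GLRLM_NAMES}


def glszm(levels: np.ndarray, mask: np.ndarray) -> dict[str, float]:
    ng = int(levels[mask].max())
    n_vox = int(mask.sum())
    struct = np.ones((3, 3, 3), dtype=bool)
    counts: dict[tuple[int, int], int] = {}
    for g in np.unique(levels[mask]):
        lab, n = ndimage.label(mask & (levels == g), structure=struct)
        if n:
            sizes = np.bincount(lab.ravel())[1:]
            for s in sizes:
                counts[(int(g), int(s))] = counts.get((int(g), int(s)), 0) + 1
    smax = max(s for _, s in counts)
    Z = np.zeros((ng, smax))
    for (g, s), c in counts.items():
        Z[g - 1, s - 1] = c
    return _rlm_type_features(Z, n_vox, "Zone")


# ------------------------------------------------------- neighbourhood shifts

def _neighbour_sums(levels: np.ndarray, mask: np.ndarray):
    """Per-voxel sum and count of in-ROI 26-neighbour levels (vectorised)."""
    lv = np.where(mask, levels, 0).astype(float)
    m = mask.astype(float)
    nsum = np.zeros_like(lv)
    ncount = np.zeros_like(lv)
    for off in OFFSETS_26:
        nsum += _shifted(lv, off)
        ncount += _shifted(m, off)
    return nsum, ncount


def _shifted(arr: np.ndarray, off) -> np.ndarray:
    out = np.zeros_like(arr)
    sl_dst, sl_src = [], []
    for d in off:
        if d == 0:
            sl_dst.append(slice(None)); sl_src.append(slice(None))
        elif d > 0:
            sl_dst.append(slice(None, -d)); sl_src.append(slice(d, None))
        else:
            sl_dst.append(slice(-d, None)); sl_src.append(slice(None, d))
    out[tuple(sl_dst)] = arr[tuple(sl_src)]
    return out


def ngtdm(levels: np.ndarray, mask: np.ndarray) -> dict[str, float]:
    ng = int(levels[mask].max())
    nsum, ncount = _neighbour_sums(levels, mask)
    has_nb = mask & (ncount > 0)
    nv = int(has_nb.sum())
    lv = levels[has_nb]
    avg = nsum[has_nb] / ncount[has_nb]
    diff = np.abs(lv - avg)
    n_i = np.bincount(lv, minlength=ng + 1)[1:].astype(float)
    s_i = np.bincount(lv, weights=diff, minlength=ng + 1)[1:]
    p_i = n_i / nv
    act = p_i > 0
    ivals = np.arange(1, ng + 1, dtype=float)
    ngp = int(act.sum())
    sum_ps = float((p_i * s_i).sum())
    coarseness = 1.0 / sum_ps if sum_ps > 0 else 1e6
    if ngp > 1:
        pi, pj = np.meshgrid(p_i[act], p_i[act], indexing="ij")
        ii, jj = np.meshgrid(ivals[act], ivals[act], indexing="ij")
        contrast = float((pi * pj * (ii - jj) ** 2).sum()) \
            / (ngp * (ngp - 1)) * float(s_i.sum()) / nv
        denom = float(np.abs(ii * pi - jj * pj).sum())
        busyness = sum_ps / denom if denom > 0 else 0.0
        si, sj = np.meshgrid(s_i[act], s_i[act], indexing="ij")
        complexity = float((np.abs(ii - jj) * (pi * si + pj * sj)
                            / (pi + pj)).sum()) / nv
        ssum = float(s_i.sum())
        strength = float(((pi + pj) * (ii - jj) ** 2).sum()) / ssum \
            if ssum > 0 else 0.0
    else:
        contrast = busyness = complexity = strength = 0.0
    return {"Busyness": busyness, "Coarseness": coarseness,
            "Complexity": complexity, "Contrast": contrast,
            "Strength": strength}


def gldm(levels: np.ndarray, mask: np.ndarray, alpha: int = 0) -> dict[str, float]:
    ng = int(levels[mask].max())
    lv_arr = np.where(mask, levels, -10 ** 9)
    dep = np.zeros(levels.shape)
    for off in OFFSETS_26:
        nb = _shifted(lv_arr.astype(float), off)
        dep += (np.abs(nb - lv_arr) <= alpha) & mask & _shifted(
            mask.astype(float), off).astype(bool)
    d = (dep[mask] + 1).astype(int)   # dependence size incl. centre voxel
    g = levels[mask]
    nd = int(d.max())
    D = np.zeros((ng, nd))
    np.add.at(D, (g - 1, d - 1), 1.0)
    nz = D.sum()
    i = np.arange(1, ng + 1)[:, None]
    j = np.arange(1, nd + 1)[None, :]
    p = D / nz
    mu_i = (p * i).sum()
    mu_j = (p * j).sum()
    gsum = D.sum(axis=1)
    dsum = D.sum(axis=0)
    return {
        "DependenceEntropy": _entropy(p.ravel()),
        "DependenceNonUniformity": float((dsum ** 2).sum() / nz),
        "DependenceNonUniformityNormalized": float((dsum ** 2).sum() / nz ** 2),
        "DependenceVariance": float((p * (j - mu_j) ** 2).sum()),
        "GrayLevelNonUniformity": float((gsum ** 2).sum() / nz),
        "GrayLevelVariance": float((p * (i - mu_i) ** 2).sum()),
        "HighGrayLevelEmphasis": float((D * i ** 2).sum() / nz),
        "LargeDependenceEmphasis": float((D * j ** 2).sum() / nz),
        "LargeDependenceHighGrayLevelEmphasis":
            float((D * i ** 2 * j ** 2).sum() / nz),
        "LargeDependenceLowGrayLevelEmphasis":
            float((D * j ** 2 / i ** 2).sum() / nz),
        "LowGrayLevelEmphasis": float((D / i ** 2).sum() / nz),
        "SmallDependenceEmphasis": float((D / j ** 2).sum() / nz),
        "SmallDependenceHighGrayLevelEmphasis":
            float((D * i ** 2 / j ** 2).sum() / nz),
        "SmallDependenceLowGrayLevelEmphasis":
            float((D / (i ** 2 * j ** 2)).sum() / nz),
    }


# ------------------------------------------------------------------ dispatch

FEATURE_CLASSES = ("firstorder", "glcm", "glszm", "glrlm", "ngtdm", "gldm")


def all_features(image: np.ndarray, mask: np.ndarray, spacing,
                 bin_width: float = 25.0) -> dict[str, float]:
    """All 93 features for one image/mask pair.

    Keys are ``<class>_<Name>`` (e.g. ``glcm_Correlation``).  The image and
    mask are cropped to the mask bounding box before matrix construction.
    """
    if not mask.any():
        raise ValueError("empty mask")
    img_c, msk_c = _crop(np.asarray(image, dtype=float), np.asarray(mask, bool))
    vals = img_c[msk_c]
    levels = np.floor((img_c - vals.min()) / bin_width).astype(int) + 1
    levels = np.where(msk_c, levels, 0)
    voxel_volume = float(np.prod(spacing))
    out: dict[str, float] = {}
    for name, v in first_order(vals, bin_width, voxel_volume).items():
        out[f"firstorder_{name}"] = v
    for cls, fn in (("glcm", glcm), ("glszm", glszm), ("glrlm", glrlm),
                    ("ngtdm", ngtdm), ("gldm", gldm)):
        for name, v in fn(levels, msk_c).items():
            out[f"{cls}_{name}"] = v
    return out


N_FEATURES = 18 + 24 + 16 + 16 + 5 + 14   # = 93
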