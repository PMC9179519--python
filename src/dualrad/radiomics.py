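"""Conventional radiomics: 354 named features per lesion ROI.

Nine feature categories are computed inside the lesion mask only:

* on the original image: first-order statistics (18), 2-D shape (9),
  GLCM (24), GLDM (14), GLRLM (16), GLSZM (16), NGTDM (5) — 102 features;
* first-order statistics (18) on each of 14 derived images: Laplacian-of-
  Gaussian responses at two sigmas, and the 12 sub-bands (LL/LH/HL/HH at
  three levels) of an undecimated stationary wavelet transform — 252
  features.

Total: 354.  Gray-level texture matrices use fixed-bin-count discretization
(32 bins inside the ROI), which makes them invariant to affine rescaling of
the input intensities.  Matrix and feature definitions follow the common
radiomics (IBSI-style) conventions; degenerate ROIs (a constant region, a
single pixel) map entropy-type features to 0 and ratio-type features to
their limiting values rather than NaN.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import pywt
from scipy import ndimage
from skimage.measure import find_contours, perimeter_crofton, regionprops

from .phantom import UltrasoundSample

_EPS = 2.2e-16


class RadiomicsError(ValueError):
    """Raised for empty masks or malformed inputs."""


@dataclass(frozen=True)
class RadiomicsConfig:
    n_gray_levels: int = 32
    log_sigmas: Tuple[float, ...] = (1.0, 3.0)
    wavelet: str = "db2"
    wavelet_levels: int = 3

    def __post_init__(self) -> None:
        if self.n_gray_levels < 2:
            raise RadiomicsError("n_gray_levels must be >= 2")
        if self.wavelet_levels < 1:
            raise RadiomicsError("wavelet_levels must be >= 1")


@dataclass
class RadiomicVector:
    """Ordered, named feature vector for one case."""

    case_id: str
    names: List[str]
    values: np.ndarray

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.names, name=self.case_id)


# 4 two-dimensional offsets at distance 1 (0, 45, 90, 135 degrees)
_OFFSETS = ((0, 1), (1, 1), (1, 0), (1, -1))

FIRSTORDER_NAMES = [
    "Energy", "TotalEnergy", "Entropy", "Minimum", "Percentile10",
    "Percentile90", "Maximum", "Mean", "Median", "InterquartileRange",
    "Range", "MeanAbsoluteDeviation", "RobustMeanAbsoluteDeviation",
    "RootMeanSquared", "Skewness", "Kurtosis", "Variance", "Uniformity",
]
SHAPE2D_NAMES = [
    "PixelArea", "MeshSurface", "Perimeter", "PerimeterSurfaceRatio",
    "Sphericity", "MajorAxisLength", "MinorAxisLength", "Elongation",
    "MaximumDiameter",
]
GLCM_NAMES = [
    "Autocorrelation", "ClusterProminence", "ClusterShade", "ClusterTendency",
    "Contrast", "Correlation", "DifferenceAverage", "DifferenceEntropy",
    "DifferenceVariance", "Id", "Idm", "Idmn", "Idn", "Imc1", "Imc2",
    "InverseVariance", "JointAverage", "JointEnergy", "JointEntropy",
    "MaximumProbability", "MCC", "SumAverage", "SumEntropy", "SumSquares",
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
NGTDM_NAMES = ["Coarseness", "Contrast", "Busyness", "Complexity", "Strength"]


def derived_image_names(cfg: RadiomicsConfig = RadiomicsConfig()) -> List[str]:
    names = [f"log-sigma-{s:g}" for s in cfg.log_sigmas]
    for lvl in range(1, cfg.wavelet_levels + 1):
        for band in ("LL", "LH", "HL", "HH"):
            names.append(f"wavelet-L{lvl}-{band}")
    return names


def feature_names(cfg: RadiomicsConfig = RadiomicsConfig()) -> List[str]:
    """The frozen, ordered list of all feature names."""
    names = [f"original_firstorder_{n}" for n in FIRSTORDER_NAMES]
    names += [f"original_shape2D_{n}" for n in SHAPE2D_NAMES]
    names += [f"original_glcm_{n}" for n in GLCM_NAMES]
    names += [f"original_gldm_{n}" for n in GLDM_NAMES]
    names += [f"original_glrlm_{n}" for n in GLRLM_NAMES]
    names += [f"original_glszm_{n}" for n in GLSZM_NAMES]
    names += [f"original_ngtdm_{n}" for n in NGTDM_NAMES]
    for img_name in derived_image_names(cfg):
        names += [f"{img_name}_firstorder_{n}" for n in FIRSTORDER_NAMES]
    return names


# ---------------------------------------------------------------------------
# Discretization and first-order statistics
# ---------------------------------------------------------------------------

def quantize(values: np.ndarray, n_levels: int) -> np.ndarray:
    """Fixed-bin-count discretization to integer levels 1..n_levels."""
    v = np.asarray(values, dtype=np.float64)
    lo, hi = v.min(), v.max()
    if hi <= lo:
        return np.ones(v.shape, dtype=np.int64)
    q = np.floor((v - lo) / (hi - lo) * n_levels).astype(np.int64) + 1
    return np.clip(q, 1, n_levels)


def first_order_features(values: np.ndarray, n_bins: int = 32) -> Dict[str, float]:
    """The 18 intensity statistics of a 1-D array of ROI values."""
    v = np.asarray(values, dtype=np.float64).ravel()
    if v.size == 0:
        raise RadiomicsError("empty ROI")
    mean = v.mean()
    var = v.var()
    p10, p25, p50, p75, p90 = np.percentile(v, [10, 25, 50, 75, 90])
    # histogram probabilities for entropy/uniformity
    q = quantize(v, n_bins)
    p = np.bincount(q)[1:].astype(np.float64)
    p = p[p > 0] / v.size
    if var > 0 and v.max() > v.min():
        sd = np.sqrt(var)
        skew = np.mean((v - mean) ** 3) / sd ** 3
        kurt = np.mean((v - mean) ** 4) / var ** 2
    else:
        skew = 0.0
        kurt = 0.0
    robust = v[(v >= p10) & (v <= p90)]
    rmad = np.abs(robust - robust.mean()).mean() if robust.size else 0.0
    return {
        "Energy": float((v ** 2).sum()),
        "TotalEnergy": float((v ** 2).sum()),  # unit pixel spacing
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
        "RobustMeanAbsoluteDeviation": float(rmad),
        "RootMeanSquared": float(np.sqrt((v ** 2).mean())),
        "Skewness": float(skew),
        "Kurtosis": float(kurt),
        "Variance": float(var),
        "Uniformity": float((p ** 2).sum()),
    }


# ---------------------------------------------------------------------------
# Shape
# ---------------------------------------------------------------------------

def shape_features_2d(mask: np.ndarray) -> Dict[str, float]:
    """Nine 2-D shape descriptors of a connected binary mask."""
    m = np.asarray(mask)
    if not m.any():
        raise RadiomicsError("shape features of an empty mask are undefined")
    area = float(m.sum())
    padded = np.pad(m.astype(np.float64), 1)
    contours = find_contours(padded, 0.5)
    # take the longest contour (outer boundary)
    contour = max(contours, key=lambda c: len(c))
    # Crofton estimator (4 directions) is far less staircase-biased than the
    # polygon length of the marching-squares contour
    perimeter = float(perimeter_crofton(m, directions=4))
    # shoelace polygon area of the marching-squares boundary
    ys, xs = contour[:, 0], contour[:, 1]
    mesh = float(0.5 * np.abs(np.dot(ys, np.roll(xs, -1)) - np.dot(xs, np.roll(ys, -1))))
    props = regionprops(m.astype(np.uint8))[0]
    major = float(props.axis_major_length)
    minor = float(props.axis_minor_length)
    pts = contour
    hull_d = _max_diameter(pts)
    return {
        "PixelArea": area,
        "MeshSurface": mesh,
        "Perimeter": perimeter,
        "PerimeterSurfaceRatio": perimeter / mesh if mesh > 0 else 0.0,
        "Sphericity": (2.0 * np.sqrt(np.pi * mesh) / perimeter) if perimeter > 0 else 1.0,
        "MajorAxisLength": major,
        "MinorAxisLength": minor,
        "Elongation": (np.sqrt(minor / major) if major > 0 else 1.0),
        "MaximumDiameter": hull_d,
    }


def _max_diameter(points: np.ndarray) -> float:
    from scipy.spatial import ConvexHull

    if len(points) < 3:
        d = points[:, None, :] - points[None, :, :]
        return float(np.sqrt((d ** 2).sum(-1)).max())
    try:
        hull = points[ConvexHull(points).vertices]
    except Exception:  # collinear degenerate boundary
        hull = points
    d = hull[:, None, :] - hull[None, :, :]
    return float(np.sqrt((d ** 2).sum(-1)).max())


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

def glcm_matrix(quant: np.ndarray, mask: np.ndarray,
                offset: Tuple[int, int]) -> np.ndarray:
    """Symmetric, normalized gray-level co-occurrence matrix for one offset.

    Pairs are counted only where both pixels lie inside the mask; the offset
    and its negation are pooled (symmetry).  Returns an Ng x Ng matrix
    summing to 1, where Ng is the largest level present; the all-pairs-absent
    case returns a zero matrix.
    """
    dr, dc = offset
    ng = int(quant.max())
    h, w = quant.shape
    r0 = max(0, -dr)
    r1 = min(h, h - dr)
    c0 = max(0, -dc)
    c1 = min(w, w - dc)
    a = quant[r0:r1, c0:c1]
    b = quant[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
    ma = mask[r0:r1, c0:c1].astype(bool) & mask[r0 + dr:r1 + dr, c0 + dc:c1 + dc].astype(bool)
    if not ma.any():
        return np.zeros((ng, ng))
    av = a[ma] - 1
    bv = b[ma] - 1
    counts = np.bincount(av * ng + bv, minlength=ng * ng).reshape(ng, ng).astype(np.float64)
    counts = counts + counts.T  # pool the negated offset
    return counts / counts.sum()


def glcm_features(quant: np.ndarray, mask: np.ndarray,
                  offsets: Sequence[Tuple[int, int]] = _OFFSETS) -> Dict[str, float]:
    """The 24 GLCM scalars, averaged over the four distance-1 offsets."""
    per_offset = []
    for off in offsets:
        P = glcm_matrix(quant, mask, off)
        if P.sum() == 0:
            continue
        per_offset.append(_glcm_scalars(P))
    if not per_offset:
        # single isolated pixel: constant-ROI conventions
        per_offset = [_glcm_scalars(np.array([[1.0]]))]
    return {k: float(np.mean([d[k] for d in per_offset])) for k in GLCM_NAMES}


def _glcm_scalars(P: np.ndarray) -> Dict[str, float]:
    ng = P.shape[0]
    i = np.arange(1, ng + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    mux = float((i * px).sum())
    muy = float((i * py).sum())
    sigx = np.sqrt(float(((i - mux) ** 2 * px).sum()))
    sigy = np.sqrt(float(((i - muy) ** 2 * py).sum()))
    # diagonal and cross-diagonal distributions
    k_sum = np.arange(2, 2 * ng + 1)
    p_sum = np.array([P[ii + jj == k].sum() for k in k_sum])
    k_diff = np.arange(0, ng)
    p_diff = np.array([P[np.abs(ii - jj) == k].sum() for k in k_diff])

    def ent(p):
        p = p[p > 0]
        return float(-(p * np.log2(p)).sum())

    hxy = ent(P.ravel())
    hx, hy = ent(px), ent(py)
    outer = np.outer(px, py)
    with np.errstate(divide="ignore", invalid="ignore"):
        hxy1 = float(-np.nansum(np.where(P > 0, P * np.log2(outer + _EPS), 0.0)))
        hxy2 = float(-np.nansum(np.where(outer > 0, outer * np.log2(outer), 0.0)))
    da = float((k_diff * p_diff).sum())
    corr_den = sigx * sigy
    corr = (float((ii * jj * P).sum()) - mux * muy) / corr_den if corr_den > 0 else 1.0
    imc1 = (hxy - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))
    offdiag = ii != jj
    inv_var = float((P[offdiag] / (ii - jj)[offdiag] ** 2).sum()) if offdiag.any() else 0.0
    mcc = _glcm_mcc(P, px, py)
    return {
        "Autocorrelation": float((ii * jj * P).sum()),
        "ClusterProminence": float(((ii + jj - mux - muy) ** 4 * P).sum()),
        "ClusterShade": float(((ii + jj - mux - muy) ** 3 * P).sum()),
        "ClusterTendency": float(((ii + jj - mux - muy) ** 2 * P).sum()),
        "Contrast": float(((ii - jj) ** 2 * P).sum()),
        "Correlation": float(corr),
        "DifferenceAverage": da,
        "DifferenceEntropy": ent(p_diff),
        "DifferenceVariance": float(((k_diff - da) ** 2 * p_diff).sum()),
        "Id": float((P / (1.0 + np.abs(ii - jj))).sum()),
        "Idm": float((P / (1.0 + (ii - jj) ** 2)).sum()),
        "Idmn": float((P / (1.0 + (ii - jj) ** 2 / ng ** 2)).sum()),
        "Idn": float((P / (1.0 + np.abs(ii - jj) / ng)).sum()),
        "Imc1": float(imc1),
        "Imc2": imc2,
        "InverseVariance": inv_var,
        "JointAverage": mux,
        "JointEnergy": float((P ** 2).sum()),
        "JointEntropy": hxy,
        "MaximumProbability": float(P.max()),
        "MCC": mcc,
        "SumAverage": float((k_sum * p_sum).sum()),
        "SumEntropy": ent(p_sum),
        "SumSquares": float(((ii - mux) ** 2 * P).sum()),
    }


def _glcm_mcc(P: np.ndarray, px: np.ndarray, py: np.ndarray) -> float:
    present = px > 0
    if present.sum() <= 1:
        return 1.0
    Pp = P[np.ix_(present, present)]
    pxp = px[present]
    pyp = py[present]
    Q = (Pp / pxp[:, None]) @ (Pp / pyp[:, None]).T
    ev = np.sort(np.abs(np.linalg.eigvals(Q)))
    return float(np.sqrt(max(0.0, min(1.0, ev[-2])))) if len(ev) > 1 else 1.0


# ---------------------------------------------------------------------------
# GLRLM
# ---------------------------------------------------------------------------

def _line_runs(line: np.ndarray) -> List[Tuple[int, int]]:
    """Maximal runs of equal nonzero values in a 1-D array -> (level, length)."""
    runs = []
    prev = 0
    length = 0
    for v in line:
        if v == prev and v != 0:
            length += 1
        else:
            if prev != 0:
                runs.append((int(prev), length))
            prev = int(v)
            length = 1 if v != 0 else 0
    if prev != 0:
        runs.append((prev, length))
    return runs


def _directional_lines(arr: np.ndarray, direction: Tuple[int, int]):
    h, w = arr.shape
    if direction == (0, 1):
        for r in range(h):
            yield arr[r]
    elif direction == (1, 0):
        for c in range(w):
            yield arr[:, c]
    elif direction == (1, 1):
        for off in range(-h + 1, w):
            yield np.diagonal(arr, offset=off)
    else:  # (1, -1) anti-diagonal
        fl = arr[:, ::-1]
        for off in range(-h + 1, w):
            yield np.diagonal(fl, offset=off)


def glrlm_features(quant: np.ndarray, mask: np.ndarray) -> Dict[str, float]:
    """16 run-length features averaged over the four directions."""
    masked = np.where(mask.astype(bool), quant, 0)
    ng = int(quant.max())
    n_pix = int(mask.sum())
    per_dir = []
    for d in _OFFSETS:
        counts: Dict[Tuple[int, int], int] = {}
        max_len = 1
        for line in _directional_lines(masked, d):
            for lvl, ln in _line_runs(line):
                counts[(lvl, ln)] = counts.get((lvl, ln), 0) + 1
                max_len = max(max_len, ln)
        if not counts:
            continue
        R = np.zeros((ng, max_len))
        for (lvl, ln), c in counts.items():
            R[lvl - 1, ln - 1] = c
        per_dir.append(_rl_scalars(R, n_pix))
    if not per_dir:
        raise RadiomicsError("empty ROI for run-length features")
    return {k: float(np.mean([d[k] for d in per_dir])) for k in GLRLM_NAMES}


def _rl_scalars(R: np.ndarray, n_pix: int) -> Dict[str, float]:
    nr = R.sum()
    i = np.arange(1, R.shape[0] + 1)[:, None]
    r = np.arange(1, R.shape[1] + 1)[None, :]
    p = R / nr
    mu_i = (p * i).sum()
    mu_r = (p * r).sum()
    pv = p[p > 0]
    return {
        "ShortRunEmphasis": float((R / r ** 2).sum() / nr),
        "LongRunEmphasis": float((R * r ** 2).sum() / nr),
        "GrayLevelNonUniformity": float((R.sum(axis=1) ** 2).sum() / nr),
        "GrayLevelNonUniformityNormalized": float((R.sum(axis=1) ** 2).sum() / nr ** 2),
        "RunLengthNonUniformity": float((R.sum(axis=0) ** 2).sum() / nr),
        "RunLengthNonUniformityNormalized": float((R.sum(axis=0) ** 2).sum() / nr ** 2),
        "RunPercentage": float(nr / n_pix),
        "GrayLevelVariance": float((p * (i - mu_i) ** 2).sum()),
        "RunVariance": float((p * (r - mu_r) ** 2).sum()),
        "RunEntropy": float(-(pv * np.log2(pv)).sum()),
        "LowGrayLevelRunEmphasis": float((R / i ** 2).sum() / nr),
        "HighGrayLevelRunEmphasis": float((R * i ** 2).sum() / nr),
        "ShortRunLowGrayLevelEmphasis": float((R / (i ** 2 * r ** 2)).sum() / nr),
        "ShortRunHighGrayLevelEmphasis": float((R * i ** 2 / r ** 2).sum() / nr),
        "LongRunLowGrayLevelEmphasis": float((R * r ** 2 / i ** 2).sum() / nr),
        "LongRunHighGrayLevelEmphasis": float((R * i ** 2 * r ** 2).sum() / nr),
    }


# ---------------------------------------------------------------------------
# GLSZM
# ---------------------------------------------------------------------------

def glszm_features(quant: np.ndarray, mask: np.ndarray) -> Dict[str, float]:
    """16 size-zone features; zones are 8-connected equal-level regions."""
    ng = int(quant.max())
    n_pix = int(mask.sum())
    if n_pix == 0:
        raise RadiomicsError("empty ROI for size-zone features")
    structure = np.ones((3, 3), dtype=int)
    zones: Dict[Tuple[int, int], int] = {}
    max_size = 1
    mb = mask.astype(bool)
    for lvl in np.unique(quant[mb]):
        lab, n = ndimage.label((quant == lvl) & mb, structure=structure)
        if n == 0:
            continue
        sizes = np.bincount(lab.ravel())[1:]
        for sz in sizes:
            zones[(int(lvl), int(sz))] = zones.get((int(lvl), int(sz)), 0) + 1
            max_size = max(max_size, int(sz))
    Z = np.zeros((ng, max_size))
    for (lvl, sz), c in zones.items():
        Z[lvl - 1, sz - 1] = c
    nz = Z.sum()
    i = np.arange(1, ng + 1)[:, None]
    s = np.arange(1, max_size + 1)[None, :]
    p = Z / nz
    mu_i = (p * i).sum()
    mu_s = (p * s).sum()
    pv = p[p > 0]
    return {
        "SmallAreaEmphasis": float((Z / s ** 2).sum() / nz),
        "LargeAreaEmphasis": float((Z * s ** 2).sum() / nz),
        "GrayLevelNonUniformity": float((Z.sum(axis=1) ** 2).sum() / nz),
        "GrayLevelNonUniformityNormalized": float((Z.sum(axis=1) ** 2).sum() / nz ** 2),
        "SizeZoneNonUniformity": float((Z.sum(axis=0) ** 2).sum() / nz),
        "SizeZoneNonUniformityNormalized": float((Z.sum(axis=0) ** 2).sum() / nz ** 2),
        "ZonePercentage": float(nz / n_pix),
        "GrayLevelVariance": float((p * (i - mu_i) ** 2).sum()),
        "ZoneVariance": float((p * (s - mu_s) ** 2).sum()),
        "ZoneEntropy": float(-(pv * np.log2(pv)).sum()),
        "LowGrayLevelZoneEmphasis": float((Z / i ** 2).sum() / nz),
        "HighGrayLevelZoneEmphasis": float((Z * i ** 2).sum() / nz),
        "SmallAreaLowGrayLevelEmphasis": float((Z / (i ** 2 * s ** 2)).sum() / nz),
        "SmallAreaHighGrayLevelEmphasis": float((Z * i ** 2 / s ** 2).sum() / nz),
        "LargeAreaLowGrayLevelEmphasis": float((Z * s ** 2 / i ** 2).sum() / nz),
        "LargeAreaHighGrayLevelEmphasis": float((Z * i ** 2 * s ** 2).sum() / nz),
    }


# ---------------------------------------------------------------------------
# GLDM
# ---------------------------------------------------------------------------

_NEIGHBOR_OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, -1),
                     (0, 1), (1, -1), (1, 0), (1, 1)]


def gldm_features(quant: np.ndarray, mask: np.ndarray, alpha: int = 0
                  ) -> Dict[str, float]:
    """14 dependence features.  A neighbor is "dependent" when its gray level
    differs by at most ``alpha``; each masked pixel contributes one count at
    (its level, 1 + number of dependent neighbors)."""
    mb = mask.astype(bool)
    n_pix = int(mb.sum())
    if n_pix == 0:
        raise RadiomicsError("empty ROI for dependence features")
    ng = int(quant.max())
    dep = np.zeros_like(quant)
    h, w = quant.shape
    for dr, dc in _NEIGHBOR_OFFSETS:
        r0, r1 = max(0, -dr), min(h, h - dr)
        c0, c1 = max(0, -dc), min(w, w - dc)
        a = quant[r0:r1, c0:c1]
        b = quant[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
        ok = (mb[r0:r1, c0:c1] & mb[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
              & (np.abs(a - b) <= alpha))
        dep[r0:r1, c0:c1] += ok
    levels = quant[mb] - 1
    deps = dep[mb]  # 0..8 dependent neighbors -> columns 1..9
    nd = int(deps.max()) + 1
    D = np.zeros((ng, nd))
    np.add.at(D, (levels, deps), 1.0)
    nz = D.sum()
    i = np.arange(1, ng + 1)[:, None]
    j = np.arange(1, nd + 1)[None, :]
    p = D / nz
    mu_i = (p * i).sum()
    mu_j = (p * j).sum()
    pv = p[p > 0]
    return {
        "SmallDependenceEmphasis": float((D / j ** 2).sum() / nz),
        "LargeDependenceEmphasis": float((D * j ** 2).sum() / nz),
        "GrayLevelNonUniformity": float((D.sum(axis=1) ** 2).sum() / nz),
        "DependenceNonUniformity": float((D.sum(axis=0) ** 2).sum() / nz),
        "DependenceNonUniformityNormalized": float((D.sum(axis=0) ** 2).sum() / nz ** 2),
        "GrayLevelVariance": float((p * (i - mu_i) ** 2).sum()),
        "DependenceVariance": float((p * (j - mu_j) ** 2).sum()),
        "DependenceEntropy": float(-(pv * np.log2(pv)).sum()),
        "LowGrayLevelEmphasis": float((D / i ** 2).sum() / nz),
        "HighGrayLevelEmphasis": float((D * i ** 2).sum() / nz),
        "SmallDependenceLowGrayLevelEmphasis": float((D / (i ** 2 * j ** 2)).sum() / nz),
        "SmallDependenceHighGrayLevelEmphasis": float((D * i ** 2 / j ** 2).sum() / nz),
        "LargeDependenceLowGrayLevelEmphasis": float((D * j ** 2 / i ** 2).sum() / nz),
        "LargeDependenceHighGrayLevelEmphasis": float((D * i ** 2 * j ** 2).sum() / nz),
    }


# ---------------------------------------------------------------------------
# NGTDM
# ---------------------------------------------------------------------------

def ngtdm_features(quant: np.ndarray, mask: np.ndarray) -> Dict[str, float]:
    """The five neighboring gray-tone difference features."""
    mb = mask.astype(bool)
    n_pix = int(mb.sum())
    if n_pix == 0:
        raise RadiomicsError("empty ROI for NGTDM features")
    ng = int(quant.max())
    kernel = np.ones((3, 3))
    kernel[1, 1] = 0
    masked_vals = np.where(mb, quant.astype(np.float64), 0.0)
    nb_sum = ndimage.convolve(masked_vals, kernel, mode="constant", cval=0.0)
    nb_cnt = ndimage.convolve(mb.astype(np.float64), kernel, mode="constant", cval=0.0)
    valid = mb & (nb_cnt > 0)
    nvalid = int(valid.sum())
    s = np.zeros(ng)
    n_i = np.zeros(ng)
    if nvalid:
        mean_nb = nb_sum[valid] / nb_cnt[valid]
        lv = quant[valid]
        np.add.at(s, lv - 1, np.abs(lv - mean_nb))
        np.add.at(n_i, lv - 1, 1.0)
    p_i = n_i / nvalid if nvalid else n_i
    present = p_i > 0
    idx = np.arange(1, ng + 1).astype(np.float64)
    ngp = int(present.sum())
    sum_ps = float((p_i * s).sum())
    coarseness = 1.0 / sum_ps if sum_ps > 0 else 1e6
    if ngp > 1 and nvalid:
        pi_p = p_i[present]
        i_p = idx[present]
        s_p = s[present]
        diff2 = (i_p[:, None] - i_p[None, :]) ** 2
        contrast = float((pi_p[:, None] * pi_p[None, :] * diff2).sum()
                         / (ngp * (ngp - 1)) * s.sum() / nvalid)
        busy_den = float(np.abs(i_p[:, None] * pi_p[:, None]
                                - i_p[None, :] * pi_p[None, :]).sum())
        busyness = sum_ps / busy_den if busy_den > 0 else 0.0
        pij_sum = pi_p[:, None] + pi_p[None, :]
        complexity = float((np.abs(i_p[:, None] - i_p[None, :])
                            * (pi_p[:, None] * s_p[:, None] + pi_p[None, :] * s_p[None, :])
                            / pij_sum).sum() / nvalid)
        strength_num = float((pij_sum * diff2).sum())
        strength = strength_num / s.sum() if s.sum() > 0 else 0.0
    else:
        contrast = busyness = complexity = strength = 0.0
    return {
        "Coarseness": float(coarseness),
        "Contrast": contrast,
        "Busyness": float(busyness),
        "Complexity": complexity,
        "Strength": float(strength),
    }


# ---------------------------------------------------------------------------
# Derived images
# ---------------------------------------------------------------------------

def log_kernel(sigma: float) -> np.ndarray:
    """Analytic Laplacian-of-Gaussian kernel sampled on an integer grid.

    Radius 5 sigma; the (tiny) truncation residue is removed by subtracting
    the kernel mean so a constant image maps to an exactly zero response."""
    radius = int(np.ceil(5.0 * sigma))
    ax = np.arange(-radius, radius + 1, dtype=np.float64)
    xx, yy = np.meshgrid(ax, ax, indexing="ij")
    r2 = xx ** 2 + yy ** 2
    k = (r2 - 2.0 * sigma ** 2) / (2.0 * np.pi * sigma ** 6) * np.exp(
        -r2 / (2.0 * sigma ** 2))
    return k - k.mean()


def derive_images(image: np.ndarray, cfg: RadiomicsConfig = RadiomicsConfig()
                  ) -> Dict[str, np.ndarray]:
    """The 14 derived rasters, each with the shape of the input.

    LoG responses come from convolution with the analytic kernel; wavelet
    sub-bands from an undecimated (stationary) 2-D transform, so the original
    mask applies to every derived image directly.  Band naming: LL approx,
    LH horizontal detail, HL vertical detail, HH diagonal.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2:
        raise RadiomicsError("derive_images expects a 2-D raster")
    out: Dict[str, np.ndarray] = {}
    for s in cfg.log_sigmas:
        out[f"log-sigma-{s:g}"] = ndimage.convolve(img, log_kernel(s), mode="reflect")
    # pad to a multiple of 2^levels for the stationary transform, then crop
    mult = 2 ** cfg.wavelet_levels
    h, w = img.shape
    ph = (-h) % mult
    pw = (-w) % mult
    padded = np.pad(img, ((0, ph), (0, pw)), mode="reflect") if (ph or pw) else img
    coeffs = pywt.swt2(padded, cfg.wavelet, level=cfg.wavelet_levels,
                       trim_approx=False, norm=False)
    # pywt returns coarsest level first; re-order to L1 = first filtering level
    coeffs = list(reversed(coeffs))
    for lvl, (ca, (ch, cv, cd)) in enumerate(coeffs, start=1):
        out[f"wavelet-L{lvl}-LL"] = ca[:h, :w]
        out[f"wavelet-L{lvl}-LH"] = ch[:h, :w]
        out[f"wavelet-L{lvl}-HL"] = cv[:h, :w]
        out[f"wavelet-L{lvl}-HH"] = cd[:h, :w]
    return out


# ---------------------------------------------------------------------------
# Top level
# ---------------------------------------------------------------------------

def extract_features(sample_or_image, mask: Optional[np.ndarray] = None,
                     cfg: RadiomicsConfig = RadiomicsConfig(),
                     case_id: Optional[str] = None) -> RadiomicVector:
    """Compute the full 354-feature vector for one lesion ROI.

    Accepts either an :class:`UltrasoundSample` or an (image, mask) pair.
    The mask must contain at least one positive pixel.
    """
    if isinstance(sample_or_image, UltrasoundSample):
        image = sample_or_image.image
        mask = sample_or_image.mask if mask is None else mask
        case_id = case_id or sample_or_image.id
    else:
        image = sample_or_image
        if mask is None:
            raise RadiomicsError("mask is required when passing a raw image")
        case_id = case_id or "case"
    image = np.asarray(image, dtype=np.float64)
    mask = np.asarray(mask)
    if mask.shape != image.shape:
        raise RadiomicsError("mask shape does not match image")
    if not mask.any():
        raise RadiomicsError(f"{case_id}: empty mask, no ROI to extract")
    mb = mask.astype(bool)
    roi_values = image[mb]
    # discretize over the ROI intensity range only; outside-mask pixels are
    # irrelevant (all matrix builders ignore them) but kept at level 1
    quant = np.ones_like(mask, dtype=np.int64)
    quant[mb] = quantize(roi_values, cfg.n_gray_levels)

    values: List[float] = []
    fo = first_order_features(roi_values, cfg.n_gray_levels)
    values += [fo[n] for n in FIRSTORDER_NAMES]
    sh = shape_features_2d(mask)
    values += [sh[n] for n in SHAPE2D_NAMES]
    glcm = glcm_features(quant, mask)
    values += [glcm[n] for n in GLCM_NAMES]
    gldm = gldm_features(quant, mask)
    values += [gldm[n] for n in GLDM_NAMES]
    glrlm = glrlm_features(quant, mask)
    values += [glrlm[n] for n in GLRLM_NAMES]
    glszm = glszm_features(quant, mask)
    values += [glszm[n] for n in GLSZM_NAMES]
    ngtdm = ngtdm_features(quant, mask)
    values += [ngtdm[n] for n in NGTDM_NAMES]
    for name, derived in derive_images(image, cfg).items():
        dfo = first_order_features(derived[mb], cfg.n_gray_levels)
        values += [dfo[n] for n in FIRSTORDER_NAMES]
    vec = np.asarray(values, dtype=np.float64)
    return RadiomicVector(case_id=case_id, names=feature_names(cfg), values=vec)


def extract_cohort_features(samples: Sequence[UltrasoundSample],
                            cfg: RadiomicsConfig = RadiomicsConfig(),
                            masks: Optional[Sequence[np.ndarray]] = None,
                            ) -> pd.DataFrame:
    """Feature table for a cohort: one row per case, id and label included.

    ``masks`` overrides the ground-truth masks (e.g., with model-predicted
    segmentations).  Lesion-free (normal) cases are skipped.
    """
    rows = []
    for i, s in enumerate(samples):
        m = masks[i] if masks is not None else s.mask
        if not np.any(m):
            continue
        rv = extract_features(s.image, mask=m, cfg=cfg, case_id=s.id)
        row = {"id": s.id, "label": s.label}
        row.update(dict(zip(rv.names, rv.values)))
        rows.append(row)
    return pd.DataFrame(rows)
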