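"""Region-level radiomic features and the inter-observer ICC filter.

Features are computed over a whole region of interest (the intratumoral
mask or one habitat subregion) from the standardized peak-enhancement
volume.  The bank follows the public radiomics feature definitions:

* first-order intensity statistics,
* 3-D shape descriptors (intratumor-scale regions),
* gray-level co-occurrence matrix (GLCM) features, pooled symmetrically
  over the 13 unique distance-1 directions,
* gray-level run-length matrix (GLRLM) features, pooled over directions,
* gray-level size-zone matrix (GLSZM) features (26-connected zones).

An optional filter bank (Laplacian-of-Gaussian at configurable sigmas,
single-level stationary wavelet decompositions) multiplies the intensity
families; the default configuration uses the original image only.
Regions smaller than ``min_region_voxels`` yield an all-NaN flagged row
rather than an error — downstream selection imputes or drops them.

The reproducibility filter computes the two-way random-effects,
absolute-agreement, single-measure intraclass correlation ICC(2,1) per
feature between two raters' extractions and retains features above the
threshold (0.75 by default).
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .image import VolumeImage

logger = logging.getLogger(__name__)

__all__ = [
    "ExtractionConfig",
    "extract_region_features",
    "region_feature_table",
    "icc_single_absolute",
    "icc_filter",
    "perturb_mask",
]

_ALL_FAMILIES = ("firstorder", "shape", "glcm", "glrlm", "glszm")


@dataclass(frozen=True)
class ExtractionConfig:
    """Feature families, filter bank and quantization for region extraction."""

    families: tuple[str, ...] = _ALL_FAMILIES
    log_sigmas_mm: tuple[float, ...] = ()
    wavelet: bool = False
    n_bins: int = 32
    bin_width: float | None = None
    min_region_voxels: int = 8

    def __post_init__(self) -> None:
        if not self.families:
            raise ValueError("at least one feature family must be enabled")
        unknown = set(self.families) - set(_ALL_FAMILIES)
        if unknown:
            raise ValueError(f"unknown families: {sorted(unknown)}")
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")

    @property
    def filter_names(self) -> tuple[str, ...]:
        names = ["original"]
        names += [f"log_sigma_{s:g}mm" for s in self.log_sigmas_mm]
        if self.wavelet:
            names += [f"wavelet_{''.join(c)}" for c in
                      itertools.product("LH", repeat=3)]
        return tuple(names)

    def hash(self) -> str:
        payload = json.dumps({
            "families": self.families, "log_sigmas_mm": self.log_sigmas_mm,
            "wavelet": self.wavelet, "n_bins": self.n_bins,
            "bin_width": self.bin_width,
            "min_region_voxels": self.min_region_voxels,
        }, sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


# --------------------------------------------------------------------------
# filters
# --------------------------------------------------------------------------

def _filtered_images(volume: VolumeImage, config: ExtractionConfig
                     ) -> dict[str, np.ndarray]:
    out = {"original": volume.values.astype(np.float64)}
    for s in config.log_sigmas_mm:
        sigma_vox = [s / sp for sp in volume.spacing_mm]
        out[f"log_sigma_{s:g}mm"] = ndimage.gaussian_laplace(
            volume.values.astype(np.float64), sigma=sigma_vox)
    if config.wavelet:
        import pywt
        w = pywt.Wavelet("coif1")
        lo = np.asarray(w.dec_lo)
        hi = np.asarray(w.dec_hi)
        for combo in itertools.product("LH", repeat=3):
            img = volume.values.astype(np.float64)
            for axis, c in enumerate(combo):
                img = ndimage.convolve1d(img, lo if c == "L" else hi,
                                         axis=axis, mode="reflect")
            out[f"wavelet_{''.join(combo)}"] = img
    return out


# --------------------------------------------------------------------------
# quantization and texture matrices
# --------------------------------------------------------------------------

def _quantize_region(values: np.ndarray, region: np.ndarray,
                     config: ExtractionConfig) -> tuple[np.ndarray, int]:
    """Discretize in-region intensities to gray levels 1..n (0 outside)."""
    v = values[region]
    lo = v.min()
    if config.bin_width is not None:
        q = np.floor((values - lo) / config.bin_width).astype(np.int64) + 1
        n_levels = int(q[region].max())
    else:
        hi = v.max()
        span = hi - lo
        if span == 0:
            q = np.ones_like(values, dtype=np.int64)
            n_levels = 1
        else:
            q = np.clip(np.floor((values - lo) / span * config.n_bins),
                        0, config.n_bins - 1).astype(np.int64) + 1
            n_levels = config.n_bins
    q = np.where(region, q, 0)
    return q, n_levels


_DIRECTIONS = [d for d in itertools.product((-1, 0, 1), repeat=3) if d > (0, 0, 0)]


def _shift(arr: np.ndarray, d: tuple[int, int, int], fill=0) -> np.ndarray:
    """Shift with zero (fill) boundary: out[v] = arr[v + d]."""
    out = np.full_like(arr, fill)
    src = [slice(max(di, 0), arr.shape[i] + min(di, 0)) for i, di in enumerate(d)]
    dst = [slice(max(-di, 0), arr.shape[i] - max(di, 0)) for i, di in enumerate(d)]
    out[tuple(dst)] = arr[tuple(src)]
    return out


def _glcm_matrix(q: np.ndarray, n_levels: int) -> np.ndarray:
    """Symmetric co-occurrence counts pooled over the 13 directions."""
    P = np.zeros((n_levels, n_levels))
    for d in _DIRECTIONS:
        b = _shift(q, d)
        sel = (q > 0) & (b > 0)
        if not sel.any():
            continue
        i, j = q[sel] - 1, b[sel] - 1
        np.add.at(P, (i, j), 1.0)
        np.add.at(P, (j, i), 1.0)
    return P


def _glrlm_matrix(q: np.ndarray, n_levels: int) -> np.ndarray:
    """Run-length counts pooled over the 13 directions."""
    max_len = max(q.shape)
    R = np.zeros((n_levels, max_len))
    region = q > 0
    for d in _DIRECTIONS:
        nxt = _shift(q, d)
        same = region & (nxt == q) & (nxt > 0)
        # DP: L[v] = 1 + L[v+d] where the run continues
        L = region.astype(np.int64)
        for _ in range(max_len - 1):
            Ln = np.where(same, 1 + _shift(L, d), L)
            if np.array_equal(Ln, L):
                break
            L = Ln
        prev = _shift(q, tuple(-x for x in d))
        start = region & ~((prev == q) & (prev > 0))
        g = q[start] - 1
        lengths = L[start] - 1  # 0-based column
        np.add.at(R, (g, lengths), 1.0)
    return R


def _glszm_matrix(q: np.ndarray, n_levels: int) -> np.ndarray:
    """Zone-size counts (26-connected zones per gray level)."""
    structure = np.ones((3, 3, 3), dtype=bool)
    n_region = int((q > 0).sum())
    Z = np.zeros((n_levels, n_region))
    for g in range(1, n_levels + 1):
        binary = q == g
        if not binary.any():
            continue
        lab, n = ndimage.label(binary, structure=structure)
        sizes = np.bincount(lab.ravel())[1:]
        for s in sizes:
            Z[g - 1, s - 1] += 1.0
    return Z


# --------------------------------------------------------------------------
# feature families
# --------------------------------------------------------------------------

def _firstorder_features(v: np.ndarray, config: ExtractionConfig) -> dict[str, float]:
    v = np.asarray(v, dtype=np.float64)
    n = v.size
    mean = v.mean()
    p10, p25, p75, p90 = np.percentile(v, [10, 25, 75, 90])
    mid = v[(v >= p10) & (v <= p90)]
    nb = config.n_bins
    lo, hi = v.min(), v.max()
    if hi > lo:
        hist = np.bincount(
            np.clip(((v - lo) / (hi - lo) * nb).astype(int), 0, nb - 1),
            minlength=nb)
    else:
        hist = np.array([n])
    p = hist[hist > 0] / n
    var = v.var()
    sd = np.sqrt(var)
    m3 = np.mean((v - mean) ** 3)
    m4 = np.mean((v - mean) ** 4)
    return {
        "mean": mean, "median": float(np.median(v)), "minimum": lo,
        "maximum": hi, "range": hi - lo, "variance": var,
        "skewness": m3 / sd**3 if sd > 0 else 0.0,
        "kurtosis": m4 / var**2 if var > 0 else 0.0,
        "energy": float(np.sum(v ** 2)), "rms": float(np.sqrt(np.mean(v ** 2))),
        "mad": float(np.mean(np.abs(v - mean))),
        "rmad": float(np.mean(np.abs(mid - mid.mean()))) if mid.size else 0.0,
        "p10": p10, "p90": p90, "iqr": p75 - p25,
        "entropy": float(-np.sum(p * np.log2(p))),
        "uniformity": float(np.sum(p ** 2)),
    }


def _shape_features(region: np.ndarray, spacing: tuple[float, float, float]
                    ) -> dict[str, float]:
    from skimage.measure import marching_cubes
    n = int(region.sum())
    voxel_vol = float(np.prod(spacing))
    volume = n * voxel_vol
    padded = np.pad(region.astype(np.float64), 1)
    try:
        verts, faces, *_ = marching_cubes(padded, level=0.5, spacing=spacing)
        tri = verts[faces]
        cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        surface = float(np.linalg.norm(cross, axis=1).sum() / 2.0)
    except (ValueError, RuntimeError):
        surface = float("nan")
    sphericity = (np.pi ** (1 / 3) * (6 * volume) ** (2 / 3)) / surface \
        if surface and surface > 0 else float("nan")
    coords = np.argwhere(region) * np.asarray(spacing)
    if n > 3:
        centered = coords - coords.mean(axis=0)
        eig = np.sort(np.linalg.eigvalsh(np.cov(centered.T)))[::-1]
        eig = np.maximum(eig, 0.0)
        elongation = float(np.sqrt(eig[1] / eig[0])) if eig[0] > 0 else 0.0
        flatness = float(np.sqrt(eig[2] / eig[0])) if eig[0] > 0 else 0.0
    else:
        elongation = flatness = 0.0
    try:
        from scipy.spatial import ConvexHull
        hull_pts = coords[ConvexHull(coords).vertices]
        d = np.linalg.norm(hull_pts[:, None] - hull_pts[None, :], axis=2)
        max_diam = float(d.max())
    except Exception:
        max_diam = float(np.linalg.norm(coords.max(0) - coords.min(0)))
    return {
        "voxel_count": float(n), "volume_mm3": volume,
        "surface_area_mm2": surface, "sphericity": sphericity,
        "max_3d_diameter_mm": max_diam, "elongation": elongation,
        "flatness": flatness,
    }


def _glcm_features(P: np.ndarray) -> dict[str, float]:
    total = P.sum()
    if total == 0:
        return {k: 0.0 for k in _GLCM_NAMES} | {"joint_energy": 1.0,
                                                "correlation": 1.0,
                                                "maximum_probability": 1.0}
    p = P / total
    n = p.shape[0]
    i = np.arange(1, n + 1, dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    mu = float((px * i).sum())
    sigma2 = float((px * (i - mu) ** 2).sum())
    diff = np.abs(ii - jj)
    pos = p > 0
    joint_entropy = float(-np.sum(p[pos] * np.log2(p[pos])))
    # difference distribution p_{x-y}
    k_diff = np.arange(n)
    p_diff = np.array([p[diff == k].sum() for k in k_diff])
    pdpos = p_diff > 0
    # sum distribution p_{x+y}
    k_sum = np.arange(2, 2 * n + 1)
    s = ii + jj
    p_sum = np.array([p[s == k].sum() for k in k_sum])
    pspos = p_sum > 0
    corr = float(np.sum(p * (ii - mu) * (jj - mu)) / sigma2) if sigma2 > 0 else 1.0
    da = float((p_diff * k_diff).sum())
    return {
        "autocorrelation": float(np.sum(p * ii * jj)),
        "cluster_prominence": float(np.sum(p * (ii + jj - 2 * mu) ** 4)),
        "cluster_shade": float(np.sum(p * (ii + jj - 2 * mu) ** 3)),
        "cluster_tendency": float(np.sum(p * (ii + jj - 2 * mu) ** 2)),
        "contrast": float(np.sum(p * (ii - jj) ** 2)),
        "correlation": corr,
        "difference_average": da,
        "difference_entropy": float(-np.sum(p_diff[pdpos] * np.log2(p_diff[pdpos]))),
        "difference_variance": float((p_diff * (k_diff - da) ** 2).sum()),
        "joint_energy": float(np.sum(p ** 2)),
        "joint_entropy": joint_entropy,
        "idm": float(np.sum(p / (1.0 + (ii - jj) ** 2))),
        "id": float(np.sum(p / (1.0 + diff))),
        "inverse_variance": float(np.sum(p[diff > 0] / diff[diff > 0] ** 2)),
        "maximum_probability": float(p.max()),
        "sum_average": float((p_sum * k_sum).sum()),
        "sum_entropy": float(-np.sum(p_sum[pspos] * np.log2(p_sum[pspos]))),
        "sum_squares": sigma2,
    }


_GLCM_NAMES = (
    "autocorrelation", "cluster_prominence", "cluster_shade",
    "cluster_tendency", "contrast", "correlation", "difference_average",
    "difference_entropy", "difference_variance", "joint_energy",
    "joint_entropy", "idm", "id", "inverse_variance", "maximum_probability",
    "sum_average", "sum_entropy", "sum_squares",
)


def _sized_matrix_features(M: np.ndarray, n_voxels: int, prefix_small: str,
                           prefix_large: str) -> dict[str, float]:
    """Shared GLRLM/GLSZM feature formulas over a (gray level, size) matrix."""
    total = M.sum()
    if total == 0:
        return {}
    p = M / total
    g = np.arange(1, M.shape[0] + 1, dtype=np.float64)[:, None]
    s = np.arange(1, M.shape[1] + 1, dtype=np.float64)[None, :]
    pg = p.sum(axis=1)
    ps = p.sum(axis=0)
    mug = float((p * g).sum())
    mus = float((p * s).sum())
    pos = p > 0
    return {
        prefix_small: float((p / s**2).sum()),
        prefix_large: float((p * s**2).sum()),
        "gl_nonuniformity": float((M.sum(axis=1) ** 2).sum() / total),
        "gl_nonuniformity_norm": float((pg ** 2).sum()),
        "size_nonuniformity": float((M.sum(axis=0) ** 2).sum() / total),
        "size_nonuniformity_norm": float((ps ** 2).sum()),
        "fraction": float(total / n_voxels),
        "gl_variance": float((p * (g - mug) ** 2).sum()),
        "size_variance": float((p * (s - mus) ** 2).sum()),
        "entropy": float(-np.sum(p[pos] * np.log2(p[pos]))),
        "low_gl_emphasis": float((p / g**2).sum()),
        "high_gl_emphasis": float((p * g**2).sum()),
        "small_low_gl": float((p / (g**2 * s**2)).sum()),
        "small_high_gl": float((p * g**2 / s**2).sum()),
        "large_low_gl": float((p * s**2 / g**2).sum()),
        "large_high_gl": float((p * g**2 * s**2).sum()),
    }


# --------------------------------------------------------------------------
# extraction
# --------------------------------------------------------------------------

def extract_region_features(image: VolumeImage, region_mask: np.ndarray,
                            config: ExtractionConfig | None = None
                            ) -> pd.Series:
    """Named feature vector for one region of one patient.

    Regions below ``min_region_voxels`` return an all-NaN series with the
    full column set (flagged missing, not an error).
    """
    config = config or ExtractionConfig()
    region = np.asarray(region_mask).astype(bool)
    n_vox = int(region.sum())
    names = feature_names(config)
    if n_vox < config.min_region_voxels:
        logger.warning("region has %d voxels < minimum %d; emitting missing row",
                       n_vox, config.min_region_voxels)
        return pd.Series(np.nan, index=names)

    out: dict[str, float] = {}
    if "shape" in config.families:
        for k, v in _shape_features(region, image.spacing_mm).items():
            out[f"shape_{k}"] = v
    filtered = _filtered_images(image, config)
    # texture matrices only need the region bounding box (padded by 1)
    lo = np.maximum(np.argwhere(region).min(axis=0) - 1, 0)
    hi = np.argwhere(region).max(axis=0) + 2
    bbox = tuple(slice(a, b) for a, b in zip(lo, hi))
    for fname in config.filter_names:
        img = filtered[fname]
        vals = img[region]
        if "firstorder" in config.families:
            for k, v in _firstorder_features(vals, config).items():
                out[f"{fname}_firstorder_{k}"] = v
        if {"glcm", "glrlm", "glszm"} & set(config.families):
            q, n_levels = _quantize_region(img[bbox], region[bbox], config)
            if "glcm" in config.families:
                for k, v in _glcm_features(_glcm_matrix(q, n_levels)).items():
                    out[f"{fname}_glcm_{k}"] = v
            if "glrlm" in config.families:
                feats = _sized_matrix_features(
                    _glrlm_matrix(q, n_levels), n_vox,
                    "short_run_emphasis", "long_run_emphasis")
                for k, v in feats.items():
                    out[f"{fname}_glrlm_{k}"] = v
            if "glszm" in config.families:
                feats = _sized_matrix_features(
                    _glszm_matrix(q, n_levels), n_vox,
                    "small_area_emphasis", "large_area_emphasis")
                for k, v in feats.items():
                    out[f"{fname}_glszm_{k}"] = v
    ser = pd.Series(out).reindex(names)
    return ser


def feature_names(config: ExtractionConfig | None = None) -> list[str]:
    """Stable ordered column list for a configuration."""
    config = config or ExtractionConfig()
    names: list[str] = []
    if "shape" in config.families:
        names += [f"shape_{k}" for k in ("voxel_count", "volume_mm3",
                                         "surface_area_mm2", "sphericity",
                                         "max_3d_diameter_mm", "elongation",
                                         "flatness")]
    fo = list(_firstorder_features(np.array([0.0, 1.0, 2.0]),
                                   config or ExtractionConfig()).keys())
    szkeys = list(_sized_matrix_features(np.ones((2, 2)), 4, "a", "b").keys())
    for fname in config.filter_names:
        if "firstorder" in config.families:
            names += [f"{fname}_firstorder_{k}" for k in fo]
        if "glcm" in config.families:
            names += [f"{fname}_glcm_{k}" for k in _GLCM_NAMES]
        if "glrlm" in config.families:
            keys = ["short_run_emphasis", "long_run_emphasis"] + szkeys[2:]
            names += [f"{fname}_glrlm_{k}" for k in keys]
        if "glszm" in config.families:
            keys = ["small_area_emphasis", "large_area_emphasis"] + szkeys[2:]
            names += [f"{fname}_glszm_{k}" for k in keys]
    return names


def region_feature_table(patients, masks: dict[str, np.ndarray] | None,
                         region_tag: str,
                         config: ExtractionConfig | None = None) -> pd.DataFrame:
    """Feature table (rows = patients) for one region tag.

    ``masks`` maps patient_id -> boolean region mask; when None the
    patient's own tumor mask is used (region_tag "intratumor").  Columns
    are prefixed with the region tag.
    """
    config = config or ExtractionConfig()
    rows = {}
    for p in patients:
        mask = (p.tumor_mask.values.astype(bool) if masks is None
                else masks[p.patient_id])
        rows[p.patient_id] = extract_region_features(p.peak_std, mask, config)
    df = pd.DataFrame(rows).T
    df.columns = [f"{region_tag}__{c}" for c in df.columns]
    df.index.name = "patient_id"
    return df


# --------------------------------------------------------------------------
# ICC filter
# --------------------------------------------------------------------------

def icc_single_absolute(x1: np.ndarray, x2: np.ndarray) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    Computed from the two-way ANOVA table of an n-subjects x 2-raters
    layout.  Zero between-subject variance is defined as ICC = 0.
    """
    x1 = np.asarray(x1, dtype=np.float64)
    x2 = np.asarray(x2, dtype=np.float64)
    if x1.shape != x2.shape or x1.ndim != 1:
        raise ValueError("x1 and x2 must be 1-D and of equal length")
    n = x1.size
    k = 2
    data = np.column_stack([x1, x2])
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / 1
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if msr == 0 or denom <= 0:
        logger.warning("zero between-subject variance; ICC defined as 0")
        return 0.0
    return float((msr - mse) / denom)


def icc_filter(table_rater1: pd.DataFrame, table_rater2: pd.DataFrame,
               threshold: float = 0.75) -> tuple[list[str], pd.Series]:
    """Retain features whose inter-rater ICC(2,1) exceeds *threshold*."""
    if not table_rater1.index.equals(table_rater2.index):
        raise ValueError("rater tables must share patients (index)")
    if list(table_rater1.columns) != list(table_rater2.columns):
        raise ValueError("rater tables must share columns")
    iccs = {}
    for col in table_rater1.columns:
        a = table_rater1[col].to_numpy(dtype=float)
        b = table_rater2[col].to_numpy(dtype=float)
        ok = np.isfinite(a) & np.isfinite(b)
        iccs[col] = icc_single_absolute(a[ok], b[ok]) if ok.sum() >= 3 else 0.0
    icc_series = pd.Series(iccs)
    retained = [c for c in table_rater1.columns if icc_series[c] > threshold]
    return retained, icc_series


def perturb_mask(mask: np.ndarray, rng: np.random.Generator,
                 flip_prob: float = 0.15) -> np.ndarray:
    """Morphological perturbation emulating a second rater's delineation.

    Each voxel in the one-voxel boundary layer (just inside or just
    outside the contour) is flipped independently with ``flip_prob`` —
    a boundary disagreement comparable to typical inter-observer Dice in
    tumor segmentation.  Never returns an empty mask.
    """
    m = np.asarray(mask).astype(bool)
    boundary = ndimage.binary_dilation(m) & ~ndimage.binary_erosion(m)
    flip = boundary & (rng.random(m.shape) < flip_prob)
    out = m ^ flip
    if not out.any():
        out = m.copy()
    return out
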