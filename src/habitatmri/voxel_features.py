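"""Voxel-level radiomic feature maps: 22 local features per tumor voxel.

Each in-mask voxel is described by a 22-vector computed from its local
3x3x3 neighbourhood (clipped to the tumor mask) and its time-intensity
curve:

* 8 gray-level statistics of the window — mean, median, standard
  deviation, minimum, maximum, skewness, kurtosis (excess, Fisher) and
  histogram entropy of the min-max-quantized window;
* 10 co-occurrence texture descriptors of the quantized window, pooled
  symmetrically over the 13 unique distance-1 3-D directions — contrast,
  correlation, joint energy, homogeneity (inverse difference),
  dissimilarity, joint entropy, cluster shade, cluster prominence,
  maximum probability, inverse difference moment;
* 4 dynamic-enhancement parameters of the voxel curve — peak relative
  enhancement, time-to-peak phase index, wash-in rate, wash-out rate.

Degenerate windows follow fixed conventions (single-voxel window: sd =
skewness = kurtosis = 0; single gray level: correlation = 1, joint energy
= 1, contrast = 0).  All computations are vectorized over voxels.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .image import DynamicSeries, VolumeImage

logger = logging.getLogger(__name__)

__all__ = [
    "VoxelFeatureConfig",
    "VoxelFeatureTable",
    "STAT_FEATURES",
    "TEXTURE_FEATURES",
    "ENHANCEMENT_FEATURES",
    "FEATURE_NAMES",
    "compute_local_statistics",
    "compute_local_texture",
    "compute_enhancement_params",
    "assemble_voxel_features",
]

STAT_FEATURES = (
    "stat_mean", "stat_median", "stat_sd", "stat_min",
    "stat_max", "stat_skewness", "stat_kurtosis", "stat_entropy",
)
TEXTURE_FEATURES = (
    "glcm_contrast", "glcm_correlation", "glcm_joint_energy",
    "glcm_homogeneity", "glcm_dissimilarity", "glcm_joint_entropy",
    "glcm_cluster_shade", "glcm_cluster_prominence",
    "glcm_max_probability", "glcm_idm",
)
ENHANCEMENT_FEATURES = (
    "enh_peak_enhancement", "enh_time_to_peak",
    "enh_washin_rate", "enh_washout_rate",
)
FEATURE_NAMES = STAT_FEATURES + TEXTURE_FEATURES + ENHANCEMENT_FEATURES


@dataclass(frozen=True)
class VoxelFeatureConfig:
    """Window radius (voxels), texture quantization and division guard.

    ``quantization`` controls the gray-level discretization used by the
    histogram-entropy and co-occurrence features: ``"window"`` (default)
    rescales each window to its own min-max before binning, making the
    texture features invariant to monotone intensity scaling and purely
    structural; ``"global"`` derives one set of equal-width bins from the
    whole in-mask intensity range, making them amplitude-sensitive.
    """

    radius: int = 1
    n_bins: int = 16
    quantization: str = "window"
    epsilon: float = 1e-6

    def __post_init__(self) -> None:
        if self.radius < 1:
            raise ValueError("radius must be >= 1")
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if self.quantization not in ("global", "window"):
            raise ValueError("quantization must be 'global' or 'window'")


@dataclass
class VoxelFeatureTable:
    """Per-voxel feature matrix for one patient.

    ``coords`` are the grid indices of in-mask voxels (row order of
    ``matrix``); ``matrix`` is n_voxels x 22 in the order of
    :data:`FEATURE_NAMES`.
    """

    patient_id: str
    coords: np.ndarray
    matrix: np.ndarray
    feature_names: tuple[str, ...] = FEATURE_NAMES

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords)
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.shape != (self.coords.shape[0], len(self.feature_names)):
            raise ValueError("matrix shape inconsistent with coords/feature names")
        if not np.all(np.isfinite(self.matrix)):
            bad = np.argwhere(~np.isfinite(self.matrix))
            r, c = bad[0]
            raise ValueError(
                f"non-finite feature value at voxel {tuple(self.coords[r])}, "
                f"feature {self.feature_names[c]}"
            )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.matrix, columns=list(self.feature_names))
        df.insert(0, "patient_id", self.patient_id)
        for i, ax in enumerate("xyz"):
            df.insert(1 + i, f"voxel_{ax}", self.coords[:, i])
        return df


# --------------------------------------------------------------------------
# window gathering
# --------------------------------------------------------------------------

def _gather_windows(values: np.ndarray, mask: np.ndarray, radius: int
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Neighbourhood values/validity per in-mask voxel.

    Returns (coords (N,3), win (N, w)), valid (N, w)) where w = (2r+1)^3.
    Validity marks window cells inside the grid AND inside the mask; the
    centre cell is always valid.
    """
    mask = mask.astype(bool)
    coords = np.argwhere(mask)
    r = radius
    pad_vals = np.pad(values.astype(np.float64), r, mode="constant")
    pad_mask = np.pad(mask, r, mode="constant")
    offsets = np.array(list(itertools.product(range(-r, r + 1), repeat=3)))
    pts = coords[:, None, :] + offsets[None, :, :] + r  # padded-space indices
    win = pad_vals[pts[..., 0], pts[..., 1], pts[..., 2]]
    valid = pad_mask[pts[..., 0], pts[..., 1], pts[..., 2]]
    return coords, win, valid


def _quantize_windows(win: np.ndarray, valid: np.ndarray,
                      config: VoxelFeatureConfig) -> np.ndarray:
    """Quantize window cells to gray levels 0..n_bins-1.

    Global mode uses one set of equal-width bins spanning the patient's
    in-mask range; window mode rescales each window to its own min-max.
    """
    n_bins = config.n_bins
    if config.quantization == "global":
        flat = win[valid]
        lo, hi = flat.min(), flat.max()
        span = hi - lo
        if span == 0:
            q = np.zeros_like(win, dtype=np.int64)
        else:
            q = np.clip(np.floor((win - lo) / span * n_bins),
                        0, n_bins - 1).astype(np.int64)
    else:
        big = np.where(valid, win, np.nan)
        lo = np.nanmin(big, axis=1, keepdims=True)
        hi = np.nanmax(big, axis=1, keepdims=True)
        span = hi - lo
        with np.errstate(invalid="ignore", divide="ignore"):
            q = np.floor((win - lo) / np.where(span > 0, span, 1.0) * n_bins)
        q = np.clip(np.nan_to_num(q, nan=0.0), 0, n_bins - 1).astype(np.int64)
    q[~valid] = 0
    return q


# --------------------------------------------------------------------------
# 8 gray-level statistics
# --------------------------------------------------------------------------

def compute_local_statistics(peak_phase: VolumeImage, mask: np.ndarray,
                             config: VoxelFeatureConfig | None = None
                             ) -> tuple[np.ndarray, np.ndarray]:
    """The 8 windowed gray-level statistics.  Returns (coords, N x 8)."""
    config = config or VoxelFeatureConfig()
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("mask is empty")
    coords, win, valid = _gather_windows(peak_phase.values, mask, config.radius)
    n = valid.sum(axis=1).astype(np.float64)
    nanwin = np.where(valid, win, np.nan)

    mean = np.nanmean(nanwin, axis=1)
    median = np.nanmedian(nanwin, axis=1)
    dev = np.where(valid, win - mean[:, None], 0.0)
    m2 = (dev ** 2).sum(axis=1) / n
    sd = np.sqrt(m2)
    vmin = np.nanmin(nanwin, axis=1)
    vmax = np.nanmax(nanwin, axis=1)
    m3 = (dev ** 3).sum(axis=1) / n
    m4 = (dev ** 4).sum(axis=1) / n
    safe_m2 = np.where(m2 > 0, m2, 1.0)
    skew = np.where(m2 > 0, m3 / safe_m2 ** 1.5, 0.0)
    kurt = np.where(m2 > 0, m4 / safe_m2 ** 2 - 3.0, 0.0)

    q = _quantize_windows(win, valid, config)
    # histogram entropy per window over valid cells
    rows = np.repeat(np.arange(q.shape[0]), q.shape[1])
    codes = q.ravel()
    w = valid.ravel().astype(np.float64)
    counts = np.zeros((q.shape[0], config.n_bins))
    np.add.at(counts, (rows, codes), w)
    p = counts / n[:, None]
    logp = np.log2(np.where(p > 0, p, 1.0))
    ent = -np.sum(p * logp, axis=1)

    feats = np.column_stack([mean, median, sd, vmin, vmax, skew, kurt, ent])
    return coords, feats


# --------------------------------------------------------------------------
# 10 co-occurrence texture features
# --------------------------------------------------------------------------

def _window_pairs(radius: int) -> np.ndarray:
    """Ordered (a, b) window-slot index pairs for all 26 distance-1 offsets.

    Including both orientations of the 13 unique directions symmetrizes the
    co-occurrence distribution.
    """
    r = radius
    side = 2 * r + 1
    slots = np.array(list(itertools.product(range(side), repeat=3)))
    index = {tuple(s): i for i, s in enumerate(slots)}
    pairs = []
    for d in itertools.product((-1, 0, 1), repeat=3):
        if d == (0, 0, 0):
            continue
        for s in slots:
            t = tuple(s + np.array(d))
            if t in index:
                pairs.append((index[tuple(s)], index[t]))
    return np.asarray(pairs)


def compute_local_texture(peak_phase: VolumeImage, mask: np.ndarray,
                          config: VoxelFeatureConfig | None = None
                          ) -> tuple[np.ndarray, np.ndarray]:
    """The 10 windowed GLCM texture features.  Returns (coords, N x 10)."""
    config = config or VoxelFeatureConfig()
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("mask is empty")
    coords, win, valid = _gather_windows(peak_phase.values, mask, config.radius)
    q = _quantize_windows(win, valid, config)
    pairs = _window_pairs(config.radius)
    a, b = pairs[:, 0], pairs[:, 1]

    i = q[:, a].astype(np.float64)
    j = q[:, b].astype(np.float64)
    w = (valid[:, a] & valid[:, b]).astype(np.float64)
    total = w.sum(axis=1)
    # isolated voxels (no valid pair): neutral conventions below
    safe_total = np.where(total > 0, total, 1.0)

    def pooled(x):
        return (w * x).sum(axis=1) / safe_total

    diff = i - j
    contrast = pooled(diff ** 2)
    dissim = pooled(np.abs(diff))
    homog = pooled(1.0 / (1.0 + np.abs(diff)))
    idm = pooled(1.0 / (1.0 + diff ** 2))
    mu = pooled(i)  # symmetric: mu_x == mu_y
    var = pooled((i - mu[:, None]) ** 2)
    cov = pooled((i - mu[:, None]) * (j - mu[:, None]))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(var > 0, cov / var, 1.0)
    spread = i + j - 2 * mu[:, None]
    shade = pooled(spread ** 3)
    prominence = pooled(spread ** 4)

    # distributional features need the (i, j) cell counts
    nb = config.n_bins
    code = (q[:, a] * nb + q[:, b]).astype(np.int64)
    rows = np.repeat(np.arange(q.shape[0]), pairs.shape[0])
    cells = np.zeros((q.shape[0], nb * nb))
    np.add.at(cells, (rows, code.ravel()), w.ravel())
    p = cells / safe_total[:, None]
    energy = (p ** 2).sum(axis=1)
    entropy = -np.sum(p * np.log2(np.where(p > 0, p, 1.0)), axis=1)
    maxp = p.max(axis=1)

    # single-cell / no-pair windows: fixed conventions
    degenerate = total == 0
    if degenerate.any():
        logger.debug("%d voxels have no valid co-occurrence pair", degenerate.sum())
        for arr, fill in ((contrast, 0.0), (dissim, 0.0), (homog, 1.0),
                          (idm, 1.0), (corr, 1.0), (shade, 0.0),
                          (prominence, 0.0), (energy, 1.0), (entropy, 0.0),
                          (maxp, 1.0)):
            arr[degenerate] = fill

    feats = np.column_stack([contrast, corr, energy, homog, dissim,
                             entropy, shade, prominence, maxp, idm])
    return coords, feats


# --------------------------------------------------------------------------
# 4 dynamic-enhancement parameters
# --------------------------------------------------------------------------

def compute_enhancement_params(series: DynamicSeries, mask: np.ndarray,
                               config: VoxelFeatureConfig | None = None
                               ) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel kinetic parameters from the time-intensity curve.

    PE = (S_peak - S0) / max(S0, eps); TTP = phase index of the post-
    contrast maximum; wash-in = (S_peak - S0) / t_peak; wash-out =
    (S_last - S_peak) / (t_last - t_peak), 0 when the peak is last.
    """
    config = config or VoxelFeatureConfig()
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("mask is empty")
    if series.n_phases < 3:
        raise ValueError("enhancement parameters need at least 3 phases")
    coords = np.argwhere(mask)
    stack = series.stack()[:, mask]            # (n_phases, N)
    times = np.asarray(series.times_s)
    s0 = stack[0]
    post = stack[1:]
    peak_rel = np.argmax(post, axis=0)         # 0-based within post phases
    ttp = peak_rel + 1                         # phase index
    s_peak = post[peak_rel, np.arange(post.shape[1])]
    s_last = stack[-1]
    t_peak = times[ttp]
    eps = config.epsilon
    n_zero = int(np.sum(s0 <= eps))
    if n_zero:
        logger.warning("%d voxels have near-zero baseline; PE guarded by eps", n_zero)
    pe = (s_peak - s0) / np.maximum(s0, eps)
    washin = (s_peak - s0) / t_peak
    dt = times[-1] - t_peak
    washout = np.where(dt > 0, (s_last - s_peak) / np.where(dt > 0, dt, 1.0), 0.0)
    feats = np.column_stack([pe, ttp.astype(np.float64), washin, washout])
    return coords, feats


# --------------------------------------------------------------------------
# assembly
# --------------------------------------------------------------------------

def assemble_voxel_features(patient, config: VoxelFeatureConfig | None = None
                            ) -> VoxelFeatureTable:
    """All 22 features for one preprocessed patient.

    Gray-level statistics and texture come from the standardized
    peak-enhancement volume; kinetic parameters from the corrected series.
    """
    config = config or VoxelFeatureConfig()
    mask = patient.tumor_mask.values.astype(bool)
    if not mask.any():
        raise ValueError(f"patient {patient.patient_id}: empty mask")
    peak_vol = getattr(patient, "peak_std", None)
    if peak_vol is None:  # raw patient: use peak phase directly
        peak_vol = patient.series.phases[patient.series.peak_phase_index(mask)]
    coords, stats = compute_local_statistics(peak_vol, mask, config)
    _, texture = compute_local_texture(peak_vol, mask, config)
    _, kinetics = compute_enhancement_params(patient.series, mask, config)
    matrix = np.column_stack([stats, texture, kinetics])
    return VoxelFeatureTable(patient_id=patient.patient_id, coords=coords,
                             matrix=matrix)
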