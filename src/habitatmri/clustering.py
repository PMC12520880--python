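"""Habitat clustering: pooled voxel k-means with Calinski-Harabasz model
selection.

Voxel feature vectors from all training patients are pooled, z-scored with
the pooled statistics, and clustered with k-means (k-means++ seeding, up
to 1,000 iterations).  For each candidate cluster count k in 2..5 the
clustering is restarted R times and the *mean* Calinski-Harabasz score
over restarts is recorded; the selected k maximizes that mean (ties go to
the smaller k).  Habitat labels are the centroid indices of the
best-inertia run at the selected k, renumbered by decreasing training
cluster size so that "habitat 1" is the largest subregion and label ids
are stable across patients.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans
from sklearn.utils.validation import check_is_fitted

from .image import VolumeImage
from .voxel_features import FEATURE_NAMES, VoxelFeatureTable

logger = logging.getLogger(__name__)

__all__ = ["calinski_harabasz", "HabitatKMeans", "assign_habitats"]


def calinski_harabasz(points: np.ndarray, labels: np.ndarray) -> float:
    """Calinski-Harabasz score: (B/(k-1)) / (W/(n-k)).

    B is the between-cluster dispersion (size-weighted squared distances of
    centroids to the grand mean), W the pooled within-cluster dispersion.
    Perfectly tight clusters (W = 0) return ``inf``.
    """
    X = np.asarray(points, dtype=np.float64)
    if X.ndim == 1:
        X = X[:, None]
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    n, k = X.shape[0], uniq.size
    if k < 2:
        raise ValueError("need at least 2 clusters")
    if n <= k:
        raise ValueError(f"need n > k, got n={n}, k={k}")
    grand = X.mean(axis=0)
    between = 0.0
    within = 0.0
    for c in uniq:
        pts = X[labels == c]
        centroid = pts.mean(axis=0)
        between += pts.shape[0] * float(np.sum((centroid - grand) ** 2))
        within += float(np.sum((pts - centroid) ** 2))
    if within == 0.0:
        logger.warning("zero within-cluster dispersion; CH score is infinite")
        return float("inf")
    return (between / (k - 1)) / (within / (n - k))


class HabitatKMeans(BaseEstimator, ClusterMixin):
    """Pooled-voxel habitat model with CH-based selection of k.

    Parameters
    ----------
    candidate_k : tuple (lo, hi)
        Inclusive candidate range for the cluster count.
    n_restarts : int
        k-means restarts per candidate k; the per-k score is the mean CH
        over restarts and the final centroids come from the best-inertia
        restart at the selected k.
    max_iter : int
        Lloyd-iteration cap per run.
    random_state : int
        Seeds the restart sequence.

    Attributes
    ----------
    scale_mean_, scale_sd_ : per-feature pooled z-scoring statistics.
    kept_features_ : indices of non-constant features used for clustering.
    ch_scores_ : dict k -> mean CH over restarts.
    selected_k_ : argmax of the mean CH (ties toward smaller k).
    cluster_centers_ : (selected_k, n_features) centroids in standardized
        space, ordered by decreasing training cluster size.
    cluster_sizes_ : training voxel count per habitat.
    """

    def __init__(self, candidate_k: tuple[int, int] = (2, 5), n_restarts: int = 10,
                 max_iter: int = 1000, random_state: int = 0):
        self.candidate_k = candidate_k
        self.n_restarts = n_restarts
        self.max_iter = max_iter
        self.random_state = random_state

    # -- helpers -----------------------------------------------------------
    def _pool(self, tables) -> np.ndarray:
        if isinstance(tables, np.ndarray):
            return np.asarray(tables, dtype=np.float64)
        if isinstance(tables, VoxelFeatureTable):
            tables = [tables]
        mats = []
        for t in tables:
            if tuple(t.feature_names) != tuple(FEATURE_NAMES):
                raise ValueError(f"feature-name mismatch for patient {t.patient_id}")
            mats.append(t.matrix)
        return np.vstack(mats)

    def _standardize(self, X: np.ndarray) -> np.ndarray:
        Z = (X[:, self.kept_features_] - self.scale_mean_[self.kept_features_]) \
            / self.scale_sd_[self.kept_features_]
        return Z

    # -- estimator API -----------------------------------------------------
    def fit(self, X, y=None):
        """Fit on pooled training voxels (array or VoxelFeatureTable list)."""
        X = self._pool(X)
        lo, hi = self.candidate_k
        if not (2 <= lo <= hi):
            raise ValueError("candidate_k must satisfy 2 <= lo <= hi")
        if X.shape[0] < 10 * hi:
            raise ValueError(
                f"pooled training voxels ({X.shape[0]}) < 10 x max candidate k ({hi})"
            )
        self.scale_mean_ = X.mean(axis=0)
        self.scale_sd_ = X.std(axis=0)
        kept = np.flatnonzero(self.scale_sd_ > 0)
        if kept.size < X.shape[1]:
            dropped = np.setdiff1d(np.arange(X.shape[1]), kept)
            warnings.warn(f"dropping constant features {dropped.tolist()} "
                          "from the clustering space")
        self.kept_features_ = kept
        self.scale_sd_ = np.where(self.scale_sd_ > 0, self.scale_sd_, 1.0)
        Z = self._standardize(X)

        rng = np.random.default_rng(self.random_state)
        restart_seeds = rng.integers(0, 2**31 - 1, size=(hi - lo + 1, self.n_restarts))
        self.restart_seeds_ = restart_seeds
        self.ch_scores_ = {}
        best_runs = {}
        for ki, k in enumerate(range(lo, hi + 1)):
            scores = []
            best = None
            for r in range(self.n_restarts):
                km = KMeans(n_clusters=k, init="k-means++", n_init=1,
                            max_iter=self.max_iter,
                            random_state=int(restart_seeds[ki, r]))
                labels = km.fit_predict(Z)
                scores.append(calinski_harabasz(Z, labels))
                if best is None or km.inertia_ < best.inertia_:
                    best = km
            self.ch_scores_[k] = float(np.mean(scores))
            best_runs[k] = best
        # argmax with ties toward smaller k
        self.selected_k_ = max(
            self.ch_scores_, key=lambda k: (self.ch_scores_[k], -k))
        if len({round(v, 12) for v in self.ch_scores_.values()}) < len(self.ch_scores_):
            logger.info("CH ties present; selected smaller k=%d", self.selected_k_)
        km = best_runs[self.selected_k_]
        sizes = np.bincount(km.labels_, minlength=self.selected_k_)
        order = np.argsort(-sizes, kind="stable")
        self.cluster_centers_ = km.cluster_centers_[order]
        self.cluster_sizes_ = sizes[order]
        self.labels_ = np.argsort(order)[km.labels_] + 1  # habitat ids 1..k
        return self

    def predict(self, X) -> np.ndarray:
        """Habitat id (1..selected_k) per voxel; nearest centroid, ties to
        the lowest habitat id."""
        check_is_fitted(self, "cluster_centers_")
        X = self._pool(X)
        Z = self._standardize(X)
        d2 = ((Z[:, None, :] - self.cluster_centers_[None, :, :]) ** 2).sum(axis=2)
        return np.argmin(d2, axis=1) + 1  # argmin takes the first minimum

    # -- persistence -------------------------------------------------------
    def to_json(self, path: str | Path) -> Path:
        check_is_fitted(self, "cluster_centers_")
        payload = {
            "candidate_k": list(self.candidate_k),
            "n_restarts": self.n_restarts,
            "max_iter": self.max_iter,
            "random_state": self.random_state,
            "scale_mean": self.scale_mean_.tolist(),
            "scale_sd": self.scale_sd_.tolist(),
            "kept_features": self.kept_features_.tolist(),
            "ch_scores": {str(k): v for k, v in self.ch_scores_.items()},
            "selected_k": int(self.selected_k_),
            "cluster_centers": self.cluster_centers_.tolist(),
            "cluster_sizes": self.cluster_sizes_.tolist(),
        }
        path = Path(path)
        path.write_text(json.dumps(payload, indent=2))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "HabitatKMeans":
        payload = json.loads(Path(path).read_text())
        model = cls(candidate_k=tuple(payload["candidate_k"]),
                    n_restarts=payload["n_restarts"],
                    max_iter=payload["max_iter"],
                    random_state=payload["random_state"])
        model.scale_mean_ = np.asarray(payload["scale_mean"])
        model.scale_sd_ = np.asarray(payload["scale_sd"])
        model.kept_features_ = np.asarray(payload["kept_features"])
        model.ch_scores_ = {int(k): v for k, v in payload["ch_scores"].items()}
        model.selected_k_ = payload["selected_k"]
        model.cluster_centers_ = np.asarray(payload["cluster_centers"])
        model.cluster_sizes_ = np.asarray(payload["cluster_sizes"])
        return model


def assign_habitats(model: HabitatKMeans, table: VoxelFeatureTable,
                    mask: VolumeImage) -> VolumeImage:
    """Habitat label map for one patient: 0 outside the tumor, habitat id
    (1..selected_k) inside."""
    labels = model.predict(table)
    vol = np.zeros(mask.values.shape, dtype=np.int16)
    vol[tuple(table.coords.T)] = labels
    if not np.array_equal(vol > 0, mask.values.astype(bool)):
        raise ValueError("voxel table does not cover the tumor mask")
    return VolumeImage(vol, spacing_mm=mask.spacing_mm, origin=mask.origin)
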