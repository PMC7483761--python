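"""Classical per-pixel baselines: intensity k-means and texture classifiers.

The unsupervised baseline clusters voxel intensities with k-means (k = 3:
background, non-nuclei foreground, bright nuclei) and takes the cluster
with the brightest centroid as the nuclei mask. Convergence is declared
when no centroid moves by more than ``eps`` intensity units (default 0.2).

The supervised baselines classify each pixel of each 2D slice from its
texture descriptor (Haralick or LBP) with an SVM, random forest or
gradient boosting classifier, using inverse-class-frequency weighting
against the extreme foreground:background imbalance. Training draws a
fixed number of randomly selected pixels per slice (default 5,000);
evaluation always uses every pixel. Classifier hyperparameters default to
tuned values: SVM C=0.7 with an RBF kernel; RF with 35 trees, max depth
17, min split 9, min leaf 24, Gini criterion; GBC with 100 depth-1 trees,
min leaf fraction 0.2, min split fraction 0.3, Friedman-MSE criterion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.svm import SVC

from .core_io import VoxelVolume

__all__ = [
    "PixelClassifierConfig",
    "TrainingSubset",
    "KMeansResult",
    "kmeans_segment",
    "subsample_pixel_features",
    "train_pixel_classifier",
    "predict_volume_slicewise",
    "hyperparameter_search",
]


@dataclass
class PixelClassifierConfig:
    """Per-model hyperparameters (tuned defaults)."""

    model: str = "rf"
    svm_c: float = 0.7
    svm_kernel: str = "rbf"
    rf_trees: int = 35
    rf_max_depth: int = 17
    rf_min_split: int = 9
    rf_min_leaf: int = 24
    rf_criterion: str = "gini"
    gbc_trees: int = 100
    gbc_max_depth: int = 1
    gbc_min_leaf_fraction: float = 0.2
    gbc_min_split_fraction: float = 0.3
    gbc_criterion: str = "friedman_mse"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in ("svm", "rf", "gbc"):
            raise ValueError(f"unknown model {self.model!r}")
        if not (0 < self.gbc_min_leaf_fraction < 1 and 0 < self.gbc_min_split_fraction < 1):
            raise ValueError("GBC fractions must lie in (0, 1)")
        for name in ("svm_c", "rf_trees", "rf_max_depth", "rf_min_split", "rf_min_leaf", "gbc_trees", "gbc_max_depth"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class TrainingSubset:
    """Aligned per-pixel feature rows, binary labels and provenance."""

    features: np.ndarray
    labels: np.ndarray
    provenance: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if len(self.features) != len(self.labels):
            raise ValueError("features and labels must align")


@dataclass
class KMeansResult:
    labels: np.ndarray          # per-voxel cluster index
    nuclei_mask: np.ndarray     # voxels of the brightest-centroid cluster
    centroids: np.ndarray       # cluster centroid intensities, ascending index
    counts: np.ndarray          # per-cluster voxel counts
    n_iter: int


def kmeans_segment(
    volume: VoxelVolume | np.ndarray,
    k: int = 3,
    eps: float = 0.2,
    seed: int = 0,
    max_iter: int = 300,
) -> KMeansResult:
    """Intensity-only k-means over all voxels; nuclei = brightest cluster.

    Centroids start from evenly spaced intensity quantiles (deterministic
    up to the data) and iterate until the largest centroid shift falls
    below ``eps`` intensity units. Empty clusters keep their previous
    centroid (with a degenerate-cluster warning when k exceeds the number
    of distinct intensities).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    data = volume.data if isinstance(volume, VoxelVolume) else np.asarray(volume)
    flat = data.reshape(-1).astype(np.float64)
    distinct = np.unique(flat)
    if k > len(distinct):
        import warnings

        warnings.warn(f"k={k} exceeds {len(distinct)} distinct intensities; clusters may be empty")
    qs = np.linspace(0, 1, k + 2)[1:-1]
    centroids = np.quantile(flat, qs)
    # seeded jitter resolves coincident quantiles on low-diversity data
    rng = np.random.default_rng(seed)
    centroids = np.sort(centroids + rng.normal(0, 1e-9, size=k))
    labels = np.zeros(flat.shape, dtype=np.int32)
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        labels = np.abs(flat[:, None] - centroids[None, :]).argmin(axis=1).astype(np.int32)
        new = centroids.copy()
        for j in range(k):
            members = flat[labels == j]
            if len(members):
                new[j] = members.mean()
        shift = np.abs(new - centroids).max()
        centroids = new
        if shift < eps:
            break
    counts = np.bincount(labels, minlength=k)
    nuclei_cluster = int(np.argmax(centroids))
    mask = (labels == nuclei_cluster).reshape(data.shape)
    return KMeansResult(labels.reshape(data.shape), mask, centroids, counts, n_iter)


def subsample_pixel_features(
    features_by_slice: list[np.ndarray],
    labels_by_slice: list[np.ndarray],
    n_per_slice: int = 5000,
    seed: int = 0,
    provenance: list[dict] | None = None,
) -> TrainingSubset:
    """Uniform without-replacement draw of ``n_per_slice`` pixels per slice.

    ``features_by_slice[i]`` is an (n_pixels, n_features) matrix for slice
    i with aligned binary labels. Slices with fewer pixels keep them all.
    Evaluation paths never subsample.
    """
    if n_per_slice < 1:
        raise ValueError("n_per_slice must be >= 1")
    rng = np.random.default_rng(seed)
    rows, labs, prov = [], [], []
    for i, (feats, labels) in enumerate(zip(features_by_slice, labels_by_slice)):
        feats = np.asarray(feats)
        labels = np.asarray(labels).reshape(-1)
        if len(feats) != len(labels):
            raise ValueError(f"slice {i}: features and labels misaligned")
        take = min(n_per_slice, len(feats))
        idx = rng.choice(len(feats), size=take, replace=False)
        rows.append(feats[idx])
        labs.append(labels[idx])
        meta = provenance[i] if provenance else {}
        prov.append(pd.DataFrame({"slice": i, "pixel": idx, **meta}))
    return TrainingSubset(
        features=np.concatenate(rows) if rows else np.empty((0, 0)),
        labels=np.concatenate(labs) if labs else np.empty(0),
        provenance=pd.concat(prov, ignore_index=True) if prov else pd.DataFrame(),
    )


def _inverse_frequency_weights(labels: np.ndarray) -> dict[int, float]:
    classes, counts = np.unique(labels, return_counts=True)
    n = len(labels)
    return {int(c): n / (len(classes) * cnt) for c, cnt in zip(classes, counts)}


def train_pixel_classifier(subset: TrainingSubset, config: PixelClassifierConfig | None = None):
    """Fit the configured classifier with inverse-frequency class weights."""
    config = config or PixelClassifierConfig()
    y = subset.labels.astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("training subset contains a single class; cannot fit a classifier")
    weights = _inverse_frequency_weights(y)
    if config.model == "svm":
        clf = SVC(C=config.svm_c, kernel=config.svm_kernel, class_weight=weights, random_state=config.seed)
        clf.fit(subset.features, y)
    elif config.model == "rf":
        clf = RandomForestClassifier(
            n_estimators=config.rf_trees,
            max_depth=config.rf_max_depth,
            min_samples_split=config.rf_min_split,
            min_samples_leaf=config.rf_min_leaf,
            criterion=config.rf_criterion,
            class_weight=weights,
            random_state=config.seed,
            n_jobs=1,
        )
        clf.fit(subset.features, y)
    else:  # gbc: no class_weight parameter; weight samples instead
        clf = GradientBoostingClassifier(
            n_estimators=config.gbc_trees,
            max_depth=config.gbc_max_depth,
            min_samples_leaf=config.gbc_min_leaf_fraction,
            min_samples_split=config.gbc_min_split_fraction,
            criterion=config.gbc_criterion,
            random_state=config.seed,
        )
        clf.fit(subset.features, y, sample_weight=np.vectorize(weights.get)(y))
    return clf


def predict_volume_slicewise(classifier, feature_volume: np.ndarray) -> np.ndarray:
    """Per-slice per-pixel prediction stacked back into a binary volume.

    ``feature_volume`` has shape (n_features, z, y, x); each z-slice is
    classified independently from its own pixels only.
    """
    feats = np.asarray(feature_volume)
    if feats.ndim != 4:
        raise ValueError("feature volume must be (n_features, z, y, x)")
    n_expected = getattr(classifier, "n_features_in_", feats.shape[0])
    if feats.shape[0] != n_expected:
        raise ValueError(f"classifier expects {n_expected} feature channels; got {feats.shape[0]}")
    _, nz, ny, nx = feats.shape
    out = np.empty((nz, ny, nx), dtype=np.uint8)
    for z in range(nz):
        rows = feats[:, z].reshape(feats.shape[0], -1).T
        out[z] = classifier.predict(rows).reshape(ny, nx).astype(np.uint8)
    return out


def hyperparameter_search(subset: TrainingSubset, param_grid: dict, model: str = "rf", n_iter: int = 10, seed: int = 0):
    """Thin optional randomized-search hook over a user-supplied grid."""
    from sklearn.model_selection import RandomizedSearchCV

    estimator = {
        "svm": SVC(),
        "rf": RandomForestClassifier(random_state=seed),
        "gbc": GradientBoostingClassifier(random_state=seed),
    }[model]
    search = RandomizedSearchCV(estimator, param_grid, n_iter=n_iter, cv=3, random_state=seed)
    search.fit(subset.features, subset.labels.astype(int))
    return search
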