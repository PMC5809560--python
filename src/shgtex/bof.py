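"""Bag-of-features classification: codebook, term vectors, evaluation.

Patch descriptors are quantized to their nearest codebook centroid ("visual
word"), each image becomes a normalized word-occurrence histogram ("term
vector"), and a linear support-vector classifier (one-vs-one for three or
more classes) predicts the image category.  ``evaluate_runs`` performs the
consecutive-run protocol: stratified folds, one fold tested per run,
per-run row-normalized confusion matrices averaged elementwise.

Determinism: all stochastic steps (fold shuffling, k-means initialisation)
derive from the caller's seed; ties in word assignment go to the lowest
word index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans
from sklearn.svm import SVC

from .config import BoFConfig, FeatureConfig
from .errors import (
    DegenerateTrainingError,
    FoldError,
    InsufficientDataError,
    NoSignalError,
)
from .features import image_feature_matrix
from .io import LabeledImageSet

__all__ = [
    "Codebook",
    "TermVector",
    "ConfusionMatrix",
    "build_codebook",
    "assign_words",
    "term_vector_from_features",
    "term_vector",
    "train_classifier",
    "predict",
    "evaluate_runs",
    "evaluate_runs_from_features",
    "parameter_sweep",
    "sweep_table",
    "extract_dataset_features",
]


@dataclass(frozen=True)
class Codebook:
    """k visual words (k-means centroids) in descriptor space."""

    words: np.ndarray  # (k, dim)
    seed: int

    @property
    def k(self) -> int:
        return self.words.shape[0]


@dataclass(frozen=True)
class TermVector:
    """Normalized visual-word occurrence histogram of one image."""

    t: np.ndarray
    image_id: str | None = None


@dataclass(frozen=True)
class ConfusionMatrix:
    """Row-stochastic true-by-predicted class probabilities."""

    classes: tuple[str, ...]
    p: np.ndarray
    n_runs: int
    run_log: tuple[dict, ...] = field(default=(), compare=False)

    @property
    def accuracy(self) -> float:
        """Mean of the diagonal (macro per-class accuracy)."""
        return float(np.mean(np.diag(self.p)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.p, index=list(self.classes), columns=list(self.classes))


def build_codebook(features: np.ndarray, k: int, seed: int = 0, n_restarts: int = 10) -> Codebook:
    """Cluster patch descriptors into k visual words with seeded k-means."""
    features = np.asarray(features, dtype=float)
    if features.ndim != 2:
        features = features.reshape(len(features), -1)
    if features.shape[0] < k:
        raise InsufficientDataError(
            f"need at least k={k} feature vectors, got {features.shape[0]}"
        )
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    km.fit(features)
    return Codebook(words=km.cluster_centers_.copy(), seed=seed)


def assign_words(features: np.ndarray, codebook: Codebook) -> np.ndarray:
    """Nearest-centroid (Euclidean) word index per descriptor; ties -> lowest index."""
    dist = cdist(np.asarray(features, dtype=float), codebook.words)
    return np.argmin(dist, axis=1)  # argmin returns the first (lowest) index on ties


def term_vector_from_features(
    features: np.ndarray, codebook: Codebook, image_id: str | None = None
) -> TermVector:
    if len(features) == 0:
        raise NoSignalError(f"image {image_id!r} has no signal patches")
    words = assign_words(features, codebook)
    counts = np.bincount(words, minlength=codebook.k).astype(float)
    return TermVector(t=counts / counts.sum(), image_id=image_id)


def term_vector(
    image, codebook: Codebook, feature_cfg: FeatureConfig | None = None
) -> TermVector:
    """Patch extraction -> descriptor -> word assignment -> normalized histogram."""
    feats, _ = image_feature_matrix(image, feature_cfg)
    return term_vector_from_features(feats, codebook, getattr(image, "image_id", None))


def train_classifier(term_vectors: np.ndarray, labels, svm_c: float = 1.0) -> SVC:
    """Fit a soft-margin linear SVM (one-vs-one for more than two classes)."""
    x = np.asarray([tv.t if isinstance(tv, TermVector) else tv for tv in term_vectors])
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise DegenerateTrainingError("training data must contain at least two classes")
    clf = SVC(kernel="linear", C=svm_c, decision_function_shape="ovo")
    clf.fit(x, y)
    return clf


def predict(
    image, codebook: Codebook, classifier: SVC, feature_cfg: FeatureConfig | None = None
) -> str:
    """Predicted category of one image (raises NoSignalError if empty)."""
    tv = term_vector(image, codebook, feature_cfg)
    return str(classifier.predict(tv.t[None])[0])


def _stratified_folds(labels: np.ndarray, n_folds: int, rng: np.random.Generator):
    """Per-class shuffled split into n_folds near-equal folds."""
    folds = [[] for _ in range(n_folds)]
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if len(idx) < n_folds:
            raise FoldError(
                f"class {cls!r} has {len(idx)} members, fewer than {n_folds} folds"
            )
        idx = rng.permutation(idx)
        for f, chunk in enumerate(np.array_split(idx, n_folds)):
            folds[f].extend(chunk.tolist())
    return [np.sort(np.array(f)) for f in folds]


def extract_dataset_features(
    dataset: LabeledImageSet, feature_cfg: FeatureConfig | None = None
) -> list[np.ndarray]:
    """Per-image descriptor matrices, aligned with ``dataset.images``."""
    return [image_feature_matrix(im, feature_cfg)[0] for im in dataset.images]


def evaluate_runs_from_features(
    features_per_image: list[np.ndarray],
    labels,
    k: int = 20,
    n_runs: int = 4,
    seed: int = 0,
    vocabulary_mode: str = "strict",
    svm_c: float = 1.0,
    kmeans_restarts: int = 10,
) -> ConfusionMatrix:
    """Consecutive-run evaluation on precomputed per-image descriptors.

    Images with zero signal patches are excluded up front (and recorded in
    the run log).  In ``strict`` mode each run's codebook is built from the
    training folds only; in ``paper`` mode from all images.
    """
    labels = np.asarray([str(l) for l in labels])
    usable = np.array([len(f) > 0 for f in features_per_image])
    excluded = np.flatnonzero(~usable).tolist()
    feats = [f for f, u in zip(features_per_image, usable) if u]
    labels = labels[usable]
    classes = tuple(sorted(np.unique(labels)))
    rng = np.random.default_rng(seed)
    folds = _stratified_folds(labels, n_runs, rng)

    matrices = []
    log = []
    for run, test_idx in enumerate(folds):
        train_idx = np.sort(np.setdiff1d(np.arange(len(labels)), test_idx))
        vocab_idx = np.arange(len(labels)) if vocabulary_mode == "paper" else train_idx
        vocab_feats = np.vstack([feats[i] for i in vocab_idx])
        codebook = build_codebook(vocab_feats, k, seed=seed + run, n_restarts=kmeans_restarts)
        train_tv = np.stack(
            [term_vector_from_features(feats[i], codebook).t for i in train_idx]
        )
        clf = train_classifier(train_tv, labels[train_idx], svm_c=svm_c)
        test_tv = np.stack(
            [term_vector_from_features(feats[i], codebook).t for i in test_idx]
        )
        pred = clf.predict(test_tv)
        cm = np.zeros((len(classes), len(classes)))
        for true, hat in zip(labels[test_idx], pred):
            cm[classes.index(true), classes.index(hat)] += 1
        cm /= cm.sum(axis=1, keepdims=True)
        matrices.append(cm)
        log.append(
            dict(
                run=run,
                train_idx=train_idx.tolist(),
                test_idx=test_idx.tolist(),
                vocab_idx=vocab_idx.tolist(),
                excluded=excluded,
            )
        )
    return ConfusionMatrix(
        classes=classes,
        p=np.mean(matrices, axis=0),
        n_runs=n_runs,
        run_log=tuple(log),
    )


def evaluate_runs(
    dataset: LabeledImageSet,
    k: int = 20,
    n_runs: int = 4,
    seed: int = 0,
    vocabulary_mode: str = "strict",
    feature_cfg: FeatureConfig | None = None,
    bof_cfg: BoFConfig | None = None,
) -> ConfusionMatrix:
    """End-to-end consecutive-run evaluation of a labeled image set."""
    bof_cfg = bof_cfg or BoFConfig(k=k, n_runs=n_runs, vocabulary_mode=vocabulary_mode)
    feats = extract_dataset_features(dataset, feature_cfg)
    return evaluate_runs_from_features(
        feats,
        dataset.labels,
        k=k,
        n_runs=n_runs,
        seed=seed,
        vocabulary_mode=vocabulary_mode,
        svm_c=bof_cfg.svm_c,
        kmeans_restarts=bof_cfg.kmeans_restarts,
    )


def parameter_sweep(
    dataset: LabeledImageSet,
    k_values=(5, 10, 20, 50, 100),
    g_values=(32, 64),
    n_runs: int = 4,
    seed: int = 0,
    vocabulary_mode: str = "strict",
    feature_cfg: FeatureConfig | None = None,
) -> dict[tuple[int, int], ConfusionMatrix]:
    """One averaged confusion matrix per (k, grid_step) combination.

    Descriptors are extracted once per grid step and reused for all k.
    """
    base_cfg = feature_cfg or FeatureConfig()
    results: dict[tuple[int, int], ConfusionMatrix] = {}
    from dataclasses import replace

    for g in g_values:
        cfg = replace(base_cfg, grid_step=g)
        feats = extract_dataset_features(dataset, cfg)
        for k in k_values:
            results[(k, g)] = evaluate_runs_from_features(
                feats, dataset.labels, k=k, n_runs=n_runs, seed=seed,
                vocabulary_mode=vocabulary_mode,
            )
    return results


def sweep_table(results: dict[tuple[int, int], ConfusionMatrix]) -> pd.DataFrame:
    """Long-form table of sweep results (one row per k, g, true, predicted)."""
    rows = []
    for (k, g), cm in sorted(results.items()):
        for i, true in enumerate(cm.classes):
            for j, pred in enumerate(cm.classes):
                rows.append(
                    dict(k=k, g=g, true=true, predicted=pred, probability=cm.p[i, j])
                )
    return pd.DataFrame(rows)
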