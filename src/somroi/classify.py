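"""Fold-safe SVM classification of ROI relevance features, with baselines.

The evaluation protocol is stratified k-fold cross-validation (k = 10 by
default).  Inside every fold, *everything* learned from data — class means
and variances, the FDR image, the difference image, the brain mask, the SOM,
the ROI map, the feature scaler and the SVM hyperparameters — is fitted on
the training portion only; held-out subjects are merely projected and
scored.  Metrics are reported as mean +/- sd across folds, and the pooled
decision scores feed a Mann-Whitney rank AUC and ROC curve.

Three feature extraction methods are supported:

``somroi``
    Per-subject ROI relevance vectors from the trained GM and WM models
    (the method under study), concatenated to 2M features.
``vaf``
    Voxels-as-features: all in-mask voxel intensities, optionally
    block-averaged for tractability; no selection or weighting.
``pca``
    VAF features standardized per voxel and projected onto the leading
    principal components of the training covariance.

Positive class = disease (label 1) for sensitivity/specificity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.metrics import roc_curve
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from somroi.featurespace import tissue_mask
from somroi.pipeline import TissueModel, fit_tissue_model, project_subjects
from somroi.som3d import SomConfig
from somroi.voxelstats import DEFAULT_FDR_EPS, VolumeStack

__all__ = [
    "CvConfig",
    "FoldResult",
    "EvalReport",
    "extract_features",
    "cross_validate",
    "svm_rbf_fit",
    "pca_baseline",
    "vaf_baseline",
    "block_average",
    "metrics_from_confusion",
    "roc_auc",
]

METHODS = ("somroi", "pca", "vaf")


def child_seed(*keys: int) -> int:
    """Deterministic sub-seed (< 2^31) derived from integer keys."""
    return int(np.random.SeedSequence(list(keys)).generate_state(1)[0] % (2**31))


@dataclass(frozen=True)
class CvConfig:
    """Cross-validation settings for :func:`cross_validate`.

    The SOM default uses a per-epoch subsample of 1024 training vectors,
    keeping per-fold training cost independent of grid size.
    """

    n_folds: int = 10
    seed: int = 0
    method: str = "somroi"
    p_min: float = 0.05
    fdr_eps: float = DEFAULT_FDR_EPS
    d_weight: float = 1.0
    absolute_difference: bool = False
    normalize_relevance: bool = True
    som: SomConfig = field(default_factory=lambda: SomConfig(subsample=1024))
    vaf_downsample: int = 1
    pca_variance: float = 0.95
    svm_c_grid: tuple[float, ...] = (0.1, 1.0, 10.0, 100.0)
    svm_gamma_rel_grid: tuple[float, ...] = (0.1, 1.0, 10.0)
    inner_folds: int = 5

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}, got {self.method!r}")
        if self.n_folds < 2:
            raise ValueError(f"n_folds must be >= 2, got {self.n_folds}")
        if self.vaf_downsample < 1:
            raise ValueError("vaf_downsample must be >= 1")


@dataclass
class FoldResult:
    """Held-out scores, predictions and confusion counts for one CV fold.

    ``artifacts`` carries the training-fold objects (FDR images, SOM
    prototypes, relevance vectors, scaler statistics) for isolation checks
    and inspection.
    """

    fold_id: int
    test_index: np.ndarray
    scores: np.ndarray
    predictions: np.ndarray
    labels: np.ndarray
    tp: int
    fp: int
    tn: int
    fn: int
    artifacts: dict = field(default_factory=dict)

    @property
    def n_test(self) -> int:
        return len(self.test_index)

    def metrics(self) -> dict[str, float]:
        return metrics_from_confusion(self.tp, self.fp, self.tn, self.fn)


@dataclass
class EvalReport:
    """Cross-validated evaluation: per-metric mean +/- sd across folds,
    pooled-score ROC points and Mann-Whitney AUC."""

    method: str
    n_folds: int
    accuracy: tuple[float, float]
    sensitivity: tuple[float, float]
    specificity: tuple[float, float]
    auc: float
    roc_points: np.ndarray          # (n_thresholds, 2) of (FPR, TPR)
    folds: list[FoldResult] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "n_folds": self.n_folds,
            "accuracy_mean": self.accuracy[0],
            "accuracy_sd": self.accuracy[1],
            "sensitivity_mean": self.sensitivity[0],
            "sensitivity_sd": self.sensitivity[1],
            "specificity_mean": self.specificity[0],
            "specificity_sd": self.specificity[1],
            "auc": self.auc,
            "fold_metrics": [
                {"fold_id": f.fold_id, **f.metrics(),
                 "tp": f.tp, "fp": f.fp, "tn": f.tn, "fn": f.fn}
                for f in self.folds
            ],
        }


def metrics_from_confusion(tp: int, fp: int, tn: int, fn: int) -> dict[str, float]:
    """Accuracy, sensitivity (TP rate for the disease class) and specificity."""
    n = tp + fp + tn + fn
    if n == 0:
        raise ValueError("empty confusion")
    return {
        "accuracy": (tp + tn) / n,
        "sensitivity": tp / (tp + fn) if (tp + fn) else float("nan"),
        "specificity": tn / (tn + fp) if (tn + fp) else float("nan"),
    }


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve by the Mann-Whitney rank statistic.

    Equals the probability that a random positive outranks a random
    negative, ties counted 1/2 — identical to the trapezoidal area under
    the empirical ROC.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    pos = labels == 1
    n_pos = int(pos.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: need at least one positive and one negative")
    ranks = rankdata(scores)
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


class GlobalScaler(BaseEstimator, TransformerMixin):
    """Scale the whole feature matrix by one training statistic (the pooled
    standard deviation of all entries).

    Unlike per-feature standardization this preserves the *relative*
    magnitudes of the ROI relevance features — the FDR weighting baked into
    them is the method's voxel selection, and equalizing feature variances
    would erase it, drowning the few discriminative ROIs among the many
    irrelevant ones.  A single global factor merely conditions the RBF
    kernel's length scale.
    """

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=np.float64)
        self.mean_ = X.mean(axis=0)
        sd = float(X.std())
        self.scale_ = sd if sd > 0 else 1.0
        return self

    def transform(self, X):
        return np.asarray(X, dtype=np.float64) / self.scale_


def svm_rbf_fit(
    features: np.ndarray,
    labels: np.ndarray,
    seed: int = 0,
    c_grid: tuple[float, ...] = (0.1, 1.0, 10.0, 100.0),
    gamma_rel_grid: tuple[float, ...] = (0.1, 1.0, 10.0),
    inner_folds: int = 5,
) -> GridSearchCV:
    """Maximal-margin RBF-kernel SVM with nested hyperparameter selection.

    Features are scaled by the training-set pooled standard deviation (one
    global factor — see :class:`GlobalScaler`) inside the fitted pipeline;
    (C, gamma) are chosen by stratified inner cross-validation on the
    training data only, with gamma on the 1/n_features scale.
    """
    features = np.asarray(features, dtype=np.float64)
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need two classes to fit a classifier")
    if counts.min() < 2:
        raise ValueError("need at least 2 subjects per class")
    d = features.shape[1]
    grid = {
        "svc__C": list(c_grid),
        "svc__gamma": [g / d for g in gamma_rel_grid],
    }
    inner = min(inner_folds, int(counts.min()))
    pipe = Pipeline([("scaler", GlobalScaler()), ("svc", SVC(kernel="rbf"))])
    if inner >= 2:
        cv = StratifiedKFold(n_splits=inner, shuffle=True, random_state=seed)
        search = GridSearchCV(pipe, grid, cv=cv, scoring="accuracy", n_jobs=None)
        search.fit(features, labels)
        return search
    pipe.fit(features, labels)
    return pipe


def extract_features(
    gm_stack: VolumeStack,
    wm_stack: VolumeStack,
    gm_model: TissueModel,
    wm_model: TissueModel,
    normalize: bool = True,
) -> np.ndarray:
    """Concatenated GM and WM per-subject ROI relevance vectors, (N, 2M)."""
    if gm_stack.n_subjects != wm_stack.n_subjects:
        raise ValueError("GM and WM stacks must hold the same subjects")
    gm = project_subjects(gm_model, gm_stack.volumes, normalize=normalize)
    wm = project_subjects(wm_model, wm_stack.volumes, normalize=normalize)
    return np.hstack([gm, wm])


def block_average(volume: np.ndarray, factor: int) -> np.ndarray:
    """Block-average a volume by an integer factor per axis (edge blocks
    average over the voxels actually present)."""
    if factor == 1:
        return np.asarray(volume, dtype=np.float64)
    vol = np.asarray(volume, dtype=np.float64)
    for axis in range(3):
        edges = np.arange(0, vol.shape[axis], factor)
        sums = np.add.reduceat(vol, edges, axis=axis)
        counts = np.diff(np.append(edges, vol.shape[axis]))
        shape = [1, 1, 1]
        shape[axis] = len(counts)
        vol = sums / counts.reshape(shape)
    return vol


def vaf_baseline(
    volumes: np.ndarray, mask: np.ndarray, downsample: int = 1
) -> np.ndarray:
    """Voxels-as-features: in-mask intensities per subject, no selection.

    With ``downsample > 1`` both volumes and mask are block-averaged first
    and a block is kept when any of its voxels was in the mask.
    """
    volumes = np.asarray(volumes, dtype=np.float64)
    if volumes.ndim == 3:
        volumes = volumes[None]
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    if downsample > 1:
        mask_ds = block_average(mask.astype(np.float64), downsample) > 0
        return np.stack([block_average(v, downsample)[mask_ds] for v in volumes])
    return volumes[:, mask]


def pca_baseline(
    train_features: np.ndarray,
    test_features: np.ndarray | None = None,
    variance: float = 0.95,
) -> tuple[np.ndarray, np.ndarray | None, Pipeline]:
    """Standardize per feature and project onto leading principal components.

    Components are the eigenvectors of the training covariance of the
    standardized ("whitened" to zero mean, unit variance) features; the
    smallest count explaining at least ``variance`` of the total variance is
    kept.  Centering, scaling and the basis come from the training rows
    only.  Returns (projected train, projected test or None, fitted
    projector).
    """
    train_features = np.asarray(train_features, dtype=np.float64)
    if train_features.shape[0] < 2:
        raise ValueError("PCA needs at least 2 training subjects")
    max_comp = min(train_features.shape[0] - 1, train_features.shape[1])
    proj = Pipeline(
        [
            ("scaler", StandardScaler()),
            ("pca", PCA(n_components=variance if variance < 1 else max_comp,
                        svd_solver="full")),
        ]
    )
    z_train = proj.fit_transform(train_features)
    z_test = proj.transform(np.asarray(test_features, dtype=np.float64)) if test_features is not None else None
    return z_train, z_test, proj


def _fold_features(
    gm_stack: VolumeStack,
    wm_stack: VolumeStack,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    config: CvConfig,
    fold_seed: int,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Train/test feature matrices for one fold, training-fold-fitted only."""
    if config.method == "somroi":
        models = {}
        for key, stack in (("GM", gm_stack), ("WM", wm_stack)):
            models[key] = fit_tissue_model(
                stack.subset(train_idx),
                som_config=replace(
                    config.som, seed=child_seed(fold_seed, 0 if key == "GM" else 1)
                ),
                p_min=config.p_min,
                fdr_eps=config.fdr_eps,
                d_weight=config.d_weight,
                absolute_difference=config.absolute_difference,
                normalize_relevance=config.normalize_relevance,
            )
        x_train = extract_features(
            gm_stack.subset(train_idx), wm_stack.subset(train_idx),
            models["GM"], models["WM"], normalize=config.normalize_relevance,
        )
        x_test = extract_features(
            gm_stack.subset(test_idx), wm_stack.subset(test_idx),
            models["GM"], models["WM"], normalize=config.normalize_relevance,
        )
        artifacts = {
            "fdr_gm": models["GM"].stats.fdr,
            "fdr_wm": models["WM"].stats.fdr,
            "prototypes_gm": models["GM"].som.prototypes,
            "prototypes_wm": models["WM"].som.prototypes,
            "relevance_gm": models["GM"].roimap.relevance,
            "relevance_wm": models["WM"].roimap.relevance,
        }
        return x_train, x_test, artifacts

    # Voxel-intensity methods: mask from training subjects only.
    blocks_train, blocks_test, masks = [], [], {}
    for key, stack in (("GM", gm_stack), ("WM", wm_stack)):
        mask = tissue_mask(stack.subset(train_idx), p_min=config.p_min)
        masks[key] = mask
        blocks_train.append(vaf_baseline(stack.volumes[train_idx], mask, config.vaf_downsample))
        blocks_test.append(vaf_baseline(stack.volumes[test_idx], mask, config.vaf_downsample))
    x_train = np.hstack(blocks_train)
    x_test = np.hstack(blocks_test)
    artifacts = {"mask_gm": masks["GM"], "mask_wm": masks["WM"]}
    if config.method == "pca":
        x_train, x_test, proj = pca_baseline(x_train, x_test, variance=config.pca_variance)
        artifacts["pca_components"] = proj.named_steps["pca"].components_
        artifacts["pca_mean"] = proj.named_steps["scaler"].mean_
    return x_train, x_test, artifacts


def cross_validate(
    gm_stack: VolumeStack,
    wm_stack: VolumeStack,
    config: CvConfig | None = None,
) -> EvalReport:
    """Stratified k-fold evaluation of a feature extraction method + RBF SVM.

    Fold assignment depends only on the labels and the seed, never on the
    volumes.  Raises when a class has fewer members than folds.
    """
    if config is None:
        config = CvConfig()
    labels = gm_stack.labels
    if not np.array_equal(labels, wm_stack.labels):
        raise ValueError("GM and WM stacks must carry identical labels")
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes, got {list(classes)}")
    if counts.min() < config.n_folds:
        raise ValueError(
            f"class {classes[np.argmin(counts)]} has only {counts.min()} subjects; "
            f"use k <= {counts.min()} folds"
        )

    skf = StratifiedKFold(
        n_splits=config.n_folds, shuffle=True, random_state=config.seed % (2**31)
    )
    folds: list[FoldResult] = []
    for fold_id, (train_idx, test_idx) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        fold_seed = child_seed(config.seed, fold_id)
        x_train, x_test, artifacts = _fold_features(
            gm_stack, wm_stack, train_idx, test_idx, config, fold_seed
        )
        clf = svm_rbf_fit(
            x_train, labels[train_idx],
            seed=child_seed(fold_seed, 2),
            c_grid=config.svm_c_grid,
            gamma_rel_grid=config.svm_gamma_rel_grid,
            inner_folds=config.inner_folds,
        )
        best = clf.best_estimator_ if isinstance(clf, GridSearchCV) else clf
        artifacts["scaler_mean"] = best.named_steps["scaler"].mean_
        artifacts["scaler_scale"] = best.named_steps["scaler"].scale_
        scores = clf.decision_function(x_test)
        preds = clf.predict(x_test)
        y = labels[test_idx]
        folds.append(
            FoldResult(
                fold_id=fold_id,
                test_index=test_idx,
                scores=scores,
                predictions=preds,
                labels=y,
                tp=int(np.sum((preds == 1) & (y == 1))),
                fp=int(np.sum((preds == 1) & (y == 0))),
                tn=int(np.sum((preds == 0) & (y == 0))),
                fn=int(np.sum((preds == 0) & (y == 1))),
                artifacts=artifacts,
            )
        )

    def agg(metric: str) -> tuple[float, float]:
        vals = np.array([f.metrics()[metric] for f in folds])
        return float(np.nanmean(vals)), float(np.nanstd(vals, ddof=1))

    pooled_scores = np.concatenate([f.scores for f in folds])
    pooled_labels = np.concatenate([f.labels for f in folds])
    fpr, tpr, _ = roc_curve(pooled_labels, pooled_scores, pos_label=1)
    return EvalReport(
        method=config.method,
        n_folds=config.n_folds,
        accuracy=agg("accuracy"),
        sensitivity=agg("sensitivity"),
        specificity=agg("specificity"),
        auc=roc_auc(pooled_scores, pooled_labels),
        roc_points=np.column_stack([fpr, tpr]),
        folds=folds,
    )
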