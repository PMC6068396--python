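"""Classifier grids and replicated stratified cross-validation.

Two families are evaluated over fixed parameter grids:

* SVM — penalty C in {0.01, 0.1, 1, 10, 100, 1000} x kernel in
  {linear, polynomial, rbf} = 18 combinations; multiclass via the
  one-vs-one decomposition (n(n-1)/2 binary subproblems, pairwise-coupled
  calibrated probabilities for AUC).
* MLP — one hidden layer whose size is coded t (attributes + classes),
  a (half of t) or i (attributes), activation in {logistic, tanh, relu},
  warm start on/off = 18 combinations, trained by backpropagation.

Every model is scored by replicated stratified 5-fold cross-validation with
macro-averaged recall, F1 and one-vs-rest AUC (metrics averaged over the
classes, unweighted; with balanced classes macro recall equals micro).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import product

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.metrics import f1_score, recall_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .dataset_builder import SampleTable
from .preprocess import PreprocessConfig, apply_preprocess

__all__ = [
    "SVM_C_VALUES", "SVM_KERNELS", "MLP_HIDDEN_CODES", "MLP_ACTIVATIONS",
    "ModelConfig", "FoldSplit", "CVResult",
    "hidden_size", "n_ovo_subproblems", "enumerate_model_grid",
    "stratified_folds", "fit_predict",
    "recall_macro", "f1_macro", "auc_macro", "cross_validate",
]

logger = logging.getLogger(__name__)

SVM_C_VALUES = (0.01, 0.1, 1.0, 10.0, 100.0, 1000.0)
SVM_KERNELS = ("linear", "poly", "rbf")
MLP_HIDDEN_CODES = ("t", "a", "i")
MLP_ACTIVATIONS = ("logistic", "tanh", "relu")


@dataclass(frozen=True)
class ModelConfig:
    """One classifier cell of the grid; only its own family's fields are set."""

    algorithm: str  # "svm" | "mlp"
    svm_C: float | None = None
    svm_kernel: str | None = None
    svm_degree: int = 3  # polynomial kernel degree (convention; exposed)
    mlp_hidden: str | None = None
    mlp_activation: str | None = None
    mlp_warm_start: bool | None = None
    mlp_max_iter: int = 500

    def __post_init__(self) -> None:
        if self.algorithm == "svm":
            if self.svm_C is None or self.svm_kernel is None:
                raise ValueError("svm config requires svm_C and svm_kernel")
            if self.svm_kernel == "polynomial":
                object.__setattr__(self, "svm_kernel", "poly")
            if self.svm_kernel not in SVM_KERNELS:
                raise ValueError(f"unknown svm kernel {self.svm_kernel!r}")
            if any(v is not None for v in
                   (self.mlp_hidden, self.mlp_activation, self.mlp_warm_start)):
                raise ValueError("svm config must not set mlp fields")
        elif self.algorithm == "mlp":
            if None in (self.mlp_hidden, self.mlp_activation, self.mlp_warm_start):
                raise ValueError("mlp config requires mlp_hidden, mlp_activation, mlp_warm_start")
            if self.mlp_hidden not in MLP_HIDDEN_CODES:
                raise ValueError(f"unknown mlp hidden-size code {self.mlp_hidden!r}")
            if self.mlp_activation not in MLP_ACTIVATIONS:
                raise ValueError(f"unknown mlp activation {self.mlp_activation!r}")
            if self.svm_C is not None or self.svm_kernel is not None:
                raise ValueError("mlp config must not set svm fields")
        else:
            raise ValueError(f"algorithm must be 'svm' or 'mlp'; got {self.algorithm!r}")

    def label(self) -> str:
        if self.algorithm == "svm":
            return f"svm(C={self.svm_C:g},kernel={self.svm_kernel})"
        return (f"mlp(hidden={self.mlp_hidden},activation={self.mlp_activation},"
                f"warm={self.mlp_warm_start})")


@dataclass(frozen=True)
class FoldSplit:
    """One fold of one replicate: disjoint train/test sample-id sets."""

    replicate: int
    fold: int
    train_ids: np.ndarray
    test_ids: np.ndarray
    seed: int


@dataclass
class CVResult:
    """Averaged cross-validation performance of one (preprocess, model) cell."""

    model_config: ModelConfig
    preprocess_config: PreprocessConfig | None
    replicate: int
    recall: float
    f1: float
    auc: float
    per_class: dict
    converged: bool = True


def hidden_size(code: str, n_attributes: int, n_classes: int) -> int:
    """Decode a hidden-layer size code: t = attrs + classes, a = t/2, i = attrs."""
    if n_attributes < 1 or n_classes < 1:
        raise ValueError("counts must be >= 1")
    if code == "t":
        return n_attributes + n_classes
    if code == "a":
        return round((n_attributes + n_classes) / 2)
    if code == "i":
        return n_attributes
    raise ValueError(f"unknown hidden-size code {code!r}; expected one of {MLP_HIDDEN_CODES}")


def n_ovo_subproblems(n_classes: int) -> int:
    """Binary subproblems trained by the one-vs-one decomposition: n(n-1)/2."""
    if n_classes < 2:
        raise ValueError("one-vs-one needs at least 2 classes")
    return n_classes * (n_classes - 1) // 2


def enumerate_model_grid(algorithm: str) -> list[ModelConfig]:
    """The 18 parameter combinations of one classifier family, in deterministic order."""
    if algorithm == "svm":
        return [ModelConfig("svm", svm_C=c, svm_kernel=k)
                for c, k in product(SVM_C_VALUES, SVM_KERNELS)]
    if algorithm == "mlp":
        return [ModelConfig("mlp", mlp_hidden=h, mlp_activation=a, mlp_warm_start=w)
                for h, a, w in product(MLP_HIDDEN_CODES, MLP_ACTIVATIONS, (True, False))]
    raise ValueError(f"algorithm must be 'svm' or 'mlp'; got {algorithm!r}")


def stratified_folds(labels: np.ndarray, k: int = 5, seed: int = 0,
                     replicate: int = 1,
                     sample_ids: np.ndarray | None = None) -> list[FoldSplit]:
    """Seeded stratified k-fold split; test folds partition the dataset.

    ``sample_ids`` defaults to positional indices.  Per-fold class counts
    differ by at most one (stratification); a class with fewer than k
    samples cannot be stratified and raises, naming the class.
    """
    labels = np.asarray(labels)
    if sample_ids is None:
        sample_ids = np.arange(len(labels))
    classes, counts = np.unique(labels, return_counts=True)
    small = classes[counts < k]
    if small.size:
        raise ValueError(
            f"class(es) {small.tolist()} have fewer than k={k} samples; cannot stratify"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [
        FoldSplit(replicate=replicate, fold=fold + 1,
                  train_ids=sample_ids[train], test_ids=sample_ids[test], seed=seed)
        for fold, (train, test) in enumerate(skf.split(np.zeros(len(labels)), labels))
    ]


def _build_estimator(config: ModelConfig, n_attributes: int, n_classes: int, seed: int):
    if config.algorithm == "svm":
        return SVC(C=config.svm_C, kernel=config.svm_kernel, degree=config.svm_degree,
                   gamma="scale", probability=True, random_state=seed)
    hidden = hidden_size(config.mlp_hidden, n_attributes, n_classes)
    return MLPClassifier(hidden_layer_sizes=(hidden,), activation=config.mlp_activation,
                         warm_start=config.mlp_warm_start, max_iter=config.mlp_max_iter,
                         random_state=seed)


def fit_predict(config: ModelConfig, train: SampleTable, test: SampleTable,
                seed: int = 0, estimator=None):
    """Fit one configured classifier and predict the test table.

    Returns ``(predicted, probabilities, classes, estimator, converged)``;
    probability rows sum to 1 and columns follow ``classes``.  Passing a
    previously fitted ``estimator`` re-uses it, which with
    ``mlp_warm_start=True`` carries weights across successive fits.
    Non-convergence is logged and flagged, never fatal.
    """
    if estimator is None:
        estimator = _build_estimator(config, train.n_bands, len(train.classes), seed)
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        estimator.fit(train.features, train.variety)
        if any(issubclass(w.category, ConvergenceWarning) for w in caught):
            converged = False
            logger.warning("%s did not converge (result reported, flagged)", config.label())
    predicted = estimator.predict(test.features)
    probabilities = estimator.predict_proba(test.features)
    return predicted, probabilities, estimator.classes_, estimator, converged


def recall_macro(truth: np.ndarray, predicted: np.ndarray) -> float:
    """Per-class recall tp / (tp + fn), unweighted mean over the classes in truth."""
    truth = np.asarray(truth)
    if truth.size == 0:
        raise ValueError("empty input")
    return float(recall_score(truth, predicted, labels=np.unique(truth),
                              average="macro", zero_division=0))


def f1_macro(truth: np.ndarray, predicted: np.ndarray) -> float:
    """Per-class F1 = 2 x precision x recall / (precision + recall), macro-averaged."""
    truth = np.asarray(truth)
    if truth.size == 0:
        raise ValueError("empty input")
    return float(f1_score(truth, predicted, labels=np.unique(truth),
                          average="macro", zero_division=0))


def _per_class_auc(truth, probabilities, classes) -> dict:
    """One-vs-rest AUC per class; classes with no positives or no negatives are skipped."""
    out = {}
    for idx, cls in enumerate(classes):
        positives = truth == cls
        if positives.all() or not positives.any():
            logger.debug("auc: class %r has no positives or no negatives; excluded", cls)
            continue
        out[cls] = float(roc_auc_score(positives, probabilities[:, idx]))
    return out


def auc_macro(truth: np.ndarray, probabilities: np.ndarray,
              classes: np.ndarray) -> float:
    """One-vs-rest AUC per class from its probability column, macro-averaged.

    Ties in the scores are handled by the rank (trapezoidal) convention.
    Classes without both positive and negative test examples are excluded
    from the mean.
    """
    truth = np.asarray(truth)
    probabilities = np.asarray(probabilities, dtype=float)
    if probabilities.shape != (len(truth), len(classes)):
        raise ValueError("probabilities must be (n_samples, n_classes)")
    if not np.allclose(probabilities.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("probability rows must sum to 1")
    per_class = _per_class_auc(truth, probabilities, np.asarray(classes))
    if not per_class:
        raise ValueError("no class had both positive and negative examples")
    return float(np.mean(list(per_class.values())))


def _subset(table: SampleTable, idx: np.ndarray) -> SampleTable:
    return SampleTable(
        features=table.features[idx],
        variety=table.variety[idx],
        day=table.day[idx],
        sample_id=table.sample_id[idx],
        wavelengths=table.wavelengths,
    )


def cross_validate(table: SampleTable, preprocess_config: PreprocessConfig | None,
                   model_config: ModelConfig, k: int = 5,
                   replicate_seed: int = 0, replicate: int = 1) -> CVResult:
    """One replicate of stratified k-fold cross-validation for one grid cell.

    Preprocessing (strictly per-row, so leakage-free) is applied to the
    full table before splitting.  Metrics are averaged over the k folds,
    overall (macro over classes) and per class.  With
    ``mlp_warm_start=True`` the estimator is re-used across the folds of
    the replicate, so previous weights seed each successive fit.
    """
    if preprocess_config is not None:
        table = apply_preprocess(table, preprocess_config)
    folds = stratified_folds(table.variety, k=k, seed=replicate_seed, replicate=replicate)
    classes = table.classes
    recalls, f1s, aucs = [], [], []
    per_class_acc: dict = {c: {"recall": [], "f1": [], "auc": []} for c in classes}
    estimator = None
    converged = True
    reuse = model_config.algorithm == "mlp" and model_config.mlp_warm_start
    for split in folds:
        train = _subset(table, split.train_ids)
        test = _subset(table, split.test_ids)
        pred, proba, est_classes, estimator, ok = fit_predict(
            model_config, train, test, seed=replicate_seed,
            estimator=estimator if reuse else None)
        converged = converged and ok
        truth = test.variety
        recalls.append(recall_macro(truth, pred))
        f1s.append(f1_macro(truth, pred))
        aucs.append(auc_macro(truth, proba, est_classes))
        cls_recall = recall_score(truth, pred, labels=classes, average=None, zero_division=0)
        cls_f1 = f1_score(truth, pred, labels=classes, average=None, zero_division=0)
        cls_auc = _per_class_auc(truth, proba, est_classes)
        for i, c in enumerate(classes):
            per_class_acc[c]["recall"].append(float(cls_recall[i]))
            per_class_acc[c]["f1"].append(float(cls_f1[i]))
            if c in cls_auc:
                per_class_acc[c]["auc"].append(cls_auc[c])
    per_class = {
        str(c): {stat: float(np.mean(vals)) if vals else float("nan")
                 for stat, vals in d.items()}
        for c, d in per_class_acc.items()
    }
    return CVResult(
        model_config=model_config,
        preprocess_config=preprocess_config,
        replicate=replicate,
        recall=float(np.mean(recalls)),
        f1=float(np.mean(f1s)),
        auc=float(np.mean(aucs)),
        per_class=per_class,
        converged=converged,
    )
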