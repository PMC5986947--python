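"""SVM training, probability prediction, kernel selection and persistence.

Models are scikit-learn SVC pipelines (per-column standardization learned on
the training split, then an SVC with Platt-calibrated probabilities). The
four supported kernels and their default parameters mirror the defaults of
the classical SVM ecosystem: cost C = 1, gamma = 1/#features, degree 3,
coef0 = 0.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .encoders import FeatureMatrix

logger = logging.getLogger(__name__)

KERNEL_NAMES = ("radial", "linear", "polynomial", "sigmoid")
# tie-break preference when kernels reach equal CV accuracy
KERNEL_TIE_ORDER = ("radial", "polynomial", "sigmoid", "linear")
_SKLEARN_KERNEL = {
    "radial": "rbf",
    "linear": "linear",
    "polynomial": "poly",
    "sigmoid": "sigmoid",
}

MODEL_FORMAT_VERSION = 1


@dataclass(frozen=True)
class KernelSpec:
    """An SVM kernel with its parameters; unset gamma means 1/#features."""

    name: str = "radial"
    cost: float = 1.0
    gamma: float | None = None
    degree: int = 3
    coef0: float = 0.0

    def __post_init__(self) -> None:
        if self.name not in KERNEL_NAMES:
            raise ValueError(f"unknown kernel {self.name!r}; choose from {KERNEL_NAMES}")
        if self.cost <= 0:
            raise ValueError("cost must be positive")
        if self.gamma is not None and self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.degree < 1:
            raise ValueError("degree must be >= 1")


def _make_svc(kernel: KernelSpec, seed: int, probability: bool = True) -> SVC:
    kwargs = dict(
        C=kernel.cost,
        kernel=_SKLEARN_KERNEL[kernel.name],
        gamma=kernel.gamma if kernel.gamma is not None else "auto",  # auto = 1/#features
        degree=kernel.degree,
        coef0=kernel.coef0,
    )
    if probability:
        kwargs.update(probability=True, random_state=seed)
    return SVC(**kwargs)


@dataclass(frozen=True)
class PredictionScore:
    """Per-class calibrated probabilities for one sequence."""

    sequence_id: str
    class_labels: tuple[str, ...]
    probabilities: np.ndarray
    label: str
    max_prob: float

    def probability_of(self, label: str) -> float:
        return float(self.probabilities[self.class_labels.index(label)])


@dataclass
class TrainedModel:
    """A fitted SVM bound to the feature scheme it expects.

    ``pipeline`` is a scaler+SVC pair fitted on the training data only;
    probabilities come from Platt-style calibration fitted during training.
    """

    stage: str  # "binary" | "multiclass"
    kernel: KernelSpec
    class_labels: tuple[str, ...]
    scheme: str
    params: dict
    n_features: int
    seed: int
    pipeline: Pipeline = field(repr=False)

    def _check_features(self, X: FeatureMatrix) -> None:
        if X.scheme != self.scheme or X.n_features != self.n_features:
            raise ValueError(
                f"feature mismatch: model expects {self.scheme} with "
                f"{self.n_features} columns, got {X.scheme} with {X.n_features}"
            )


def train_svm(
    X: FeatureMatrix, y: Sequence[str], kernel: KernelSpec = KernelSpec(), seed: int = 0
) -> TrainedModel:
    """Fit an SVM with calibrated probabilities on an encoded dataset.

    Column standardization is learned from ``X`` itself; refitting with the
    same inputs and seed reproduces identical predictions.
    """
    y = np.asarray(y, dtype=object)
    if len(y) != len(X):
        raise ValueError(f"{len(X)} rows but {len(y)} labels")
    if not np.all(np.isfinite(X.X)):
        raise ValueError("feature matrix contains non-finite values")
    labels, counts = np.unique(y, return_counts=True)
    if len(labels) < 2:
        raise ValueError("training data must contain at least 2 classes")
    if counts.min() < 2:
        small = labels[counts < 2].tolist()
        raise ValueError(f"each class needs >= 2 samples; too small: {small}")
    pipeline = Pipeline(
        [("scale", StandardScaler()), ("svc", _make_svc(kernel, seed))]
    )
    with warnings.catch_warnings():
        # tiny classes make the internal Platt CV complain; predictions stay
        # valid. FutureWarning: probability=True is the intended Platt path.
        warnings.simplefilter("ignore", UserWarning)
        warnings.simplefilter("ignore", FutureWarning)
        pipeline.fit(X.X, y)
    return TrainedModel(
        stage="binary" if len(labels) == 2 else "multiclass",
        kernel=kernel,
        class_labels=tuple(sorted(labels)),
        scheme=X.scheme,
        params=dict(X.params),
        n_features=X.n_features,
        seed=seed,
        pipeline=pipeline,
    )


def predict_scores(model: TrainedModel, X: FeatureMatrix) -> list[PredictionScore]:
    """Calibrated per-class probabilities, one record per row of ``X``.

    The argmax label breaks ties by ``class_labels`` order.
    """
    model._check_features(X)
    if len(X) == 0:
        return []
    proba = model.pipeline.predict_proba(X.X)
    fitted_order = list(model.pipeline.named_steps["svc"].classes_)
    col = [fitted_order.index(lab) for lab in model.class_labels]
    proba = proba[:, col]
    out = []
    for sid, p in zip(X.ids, proba):
        k = int(np.argmax(p))  # first max wins -> class_labels order breaks ties
        out.append(
            PredictionScore(
                sequence_id=sid,
                class_labels=model.class_labels,
                probabilities=p,
                label=model.class_labels[k],
                max_prob=float(p[k]),
            )
        )
    return out


def select_kernel(
    X: FeatureMatrix,
    y: Sequence[str],
    subset_per_class: int = 100,
    seed: int = 0,
    cv_folds: int = 5,
) -> KernelSpec:
    """Pick the best of the four basic kernels on a per-class subsample.

    Draws ``subset_per_class`` samples per class (all of a class, with a
    warning, when it is smaller), runs stratified ``cv_folds``-fold CV for
    each kernel at default parameters, and returns the kernel with highest
    mean accuracy. Ties break radial > polynomial > sigmoid > linear.
    """
    y = np.asarray(y, dtype=object)
    labels = np.unique(y)
    if len(labels) < 2:
        raise ValueError("kernel selection needs at least 2 classes")
    rng = np.random.default_rng(seed)
    chosen: list[np.ndarray] = []
    for lab in labels:
        idx = np.nonzero(y == lab)[0]
        if len(idx) < subset_per_class:
            warnings.warn(
                f"class {lab!r} has only {len(idx)} samples "
                f"(< subset_per_class={subset_per_class}); using all of them",
                stacklevel=2,
            )
            chosen.append(idx)
        else:
            chosen.append(rng.choice(idx, size=subset_per_class, replace=False))
    sub = np.sort(np.concatenate(chosen))
    Xs, ys = X.X[sub], y[sub]

    accuracies: dict[str, float] = {}
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    for name in KERNEL_TIE_ORDER:
        spec = KernelSpec(name=name)
        accs = []
        for tr, te in skf.split(Xs, ys):
            pipe = Pipeline(
                [("scale", StandardScaler()), ("svc", _make_svc(spec, seed, probability=False))]
            )
            pipe.fit(Xs[tr], ys[tr])
            accs.append(float(np.mean(pipe.predict(Xs[te]) == ys[te])))
        accuracies[name] = float(np.mean(accs))
    best = max(KERNEL_TIE_ORDER, key=lambda n: accuracies[n])  # first max wins ties
    logger.info("kernel selection accuracies: %s -> %s", accuracies, best)
    return KernelSpec(name=best)


def save_model(model, path: str | Path) -> None:
    """Persist a trained model (or a composite of them) with a version tag."""
    joblib.dump({"format_version": MODEL_FORMAT_VERSION, "payload": model}, path)


def load_model(path: str | Path):
    """Load a model archive; refuses files without a matching version tag."""
    blob = joblib.load(path)
    if not isinstance(blob, dict) or "format_version" not in blob:
        raise ValueError(f"{path}: not a nifscan model archive")
    if blob["format_version"] != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"{path}: model format version {blob['format_version']} "
            f"not supported (expected {MODEL_FORMAT_VERSION})"
        )
    return blob["payload"]
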