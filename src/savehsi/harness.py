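"""Reproducible classification experiments on phantom image sets.

The harness compares imaging conditions (white-light versus narrow-band
re-rendered images) with identical patient-level splits, so any metric
difference reflects the imaging transform rather than split luck.  Model
internals are delegated to scikit-learn: random forests (optionally
grid-search tuned with stratified k-fold cross-validation), an RBF support
vector machine, and a multilayer-perceptron neural network ("mlp", with
"cnn" accepted as an alias for configuration compatibility).

Features for the classical models are flattened downscaled pixels plus
per-channel intensity histograms — a documented stand-in, since how image
pixels feed non-convolutional models is an open modelling choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.transform import resize as sk_resize
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .evalmetrics import (
    ConfusionMatrix,
    balanced_accuracy,
    classification_report,
    cohen_kappa,
    macro_f1,
    wilson_ci,
)
from .synthetic import LabeledImage

__all__ = ["ExperimentConfig", "split_dataset", "extract_features", "run_experiment", "manifest_from_items"]

DEFAULT_RF_GRID = {"n_estimators": [100, 200, 500], "min_samples_leaf": [1, 2, 5]}
DEFAULT_SVM_GRID = {"svc__C": [0.1, 1.0, 10.0], "svc__gamma": ["scale", 0.01, 0.001]}

_MODEL_ALIASES = {"cnn": "mlp"}
_KNOWN_MODELS = {"rf", "rf_tuned", "svm", "mlp"}


@dataclass
class ExperimentConfig:
    """One classification run: model family, split fractions and seed."""

    model: str = "rf"
    split: tuple[float, float, float] | None = None
    seed: int = 0
    feature_size: int = 16
    hist_bins: int = 16
    rf_grid: dict = field(default_factory=lambda: dict(DEFAULT_RF_GRID))
    cv_folds: int = 3

    def __post_init__(self) -> None:
        self.model = _MODEL_ALIASES.get(self.model, self.model)
        if self.model not in _KNOWN_MODELS:
            raise ValueError(f"unknown model {self.model!r}; choose from {sorted(_KNOWN_MODELS | set(_MODEL_ALIASES))}")
        if self.split is None:
            # neural nets keep a validation slice; the classical models use 85/15
            self.split = (0.85, 0.05, 0.10) if self.model == "mlp" else (0.85, 0.0, 0.15)
        if abs(sum(self.split) - 1.0) > 1e-9 or any(f < 0 for f in self.split):
            raise ValueError("split fractions must be non-negative and sum to 1")


def manifest_from_items(items: list[LabeledImage]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "index": np.arange(len(items)),
            "label": [it.label for it in items],
            "patient_id": [it.patient_id for it in items],
            "augmented": [it.augmented for it in items],
            "name": [it.name for it in items],
        }
    )


def split_dataset(manifest: pd.DataFrame, config: ExperimentConfig) -> dict[str, np.ndarray]:
    """Patient-level train/val/test split honouring augmentation rules.

    Patients are shuffled (seeded) and assigned to partitions so that
    image-count fractions approximate the configured split.  No patient
    spans two partitions.  Augmented images are kept only when their
    patient landed in the training partition; augmented copies of
    validation or test patients are dropped entirely.
    """
    required = {"index", "label", "patient_id", "augmented"}
    if not required.issubset(manifest.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")
    rng = np.random.default_rng(config.seed)
    originals = manifest[~manifest["augmented"]]
    patients = originals["patient_id"].unique()
    if len(patients) < sum(f > 0 for f in config.split):
        raise ValueError("too few patients to honour the requested split")
    rng.shuffle(patients)
    n_images = len(originals)
    counts = originals.groupby("patient_id").size()

    targets = [f * n_images for f in config.split]
    assignment: dict[str, str] = {}
    filled = [0.0, 0.0, 0.0]
    names = ["train", "val", "test"]
    for pid in patients:
        # put each patient where the shortfall relative to target is largest
        deficits = [t - f for t, f in zip(targets, filled)]
        part = int(np.argmax(deficits))
        assignment[pid] = names[part]
        filled[part] += counts[pid]

    part_of = manifest["patient_id"].map(assignment)
    out = {}
    for name in names:
        mask = part_of == name
        if name != "train":
            mask &= ~manifest["augmented"]
        out[name] = manifest.loc[mask, "index"].to_numpy()
    return out


def extract_features(images: list[np.ndarray], config: ExperimentConfig) -> np.ndarray:
    """Downscaled flattened pixels plus per-channel histograms."""
    feats = []
    s = config.feature_size
    for img in images:
        arr = np.asarray(img, dtype=float) / 255.0
        small = sk_resize(arr, (s, s, 3), anti_aliasing=True)
        hists = [
            np.histogram(arr[..., c], bins=config.hist_bins, range=(0, 1), density=True)[0]
            for c in range(3)
        ]
        feats.append(np.concatenate([small.ravel(), *hists]))
    return np.asarray(feats)


def _build_model(config: ExperimentConfig):
    seed = config.seed
    if config.model == "rf":
        return RandomForestClassifier(n_estimators=200, random_state=seed, n_jobs=1)
    if config.model == "rf_tuned":
        cv = StratifiedKFold(n_splits=config.cv_folds, shuffle=True, random_state=seed)
        return GridSearchCV(
            RandomForestClassifier(random_state=seed, n_jobs=1),
            config.rf_grid,
            cv=cv,
            scoring="accuracy",
            n_jobs=1,
        )
    if config.model == "svm":
        return make_pipeline(StandardScaler(), SVC(kernel="rbf", C=1.0, gamma="scale", random_state=seed))
    if config.model == "mlp":
        return make_pipeline(
            StandardScaler(),
            MLPClassifier(hidden_layer_sizes=(64, 32), max_iter=500, random_state=seed),
        )
    raise AssertionError(config.model)


def run_experiment(items: list[LabeledImage], config: ExperimentConfig) -> dict:
    """Train the configured model and evaluate once on the held-out test set.

    Returns a dict with the confusion matrix, per-class report, accuracy
    with its Wilson 95% interval, macro-F1, balanced accuracy, kappa, the
    split sizes, and (for tuned models) the selected hyperparameters.
    """
    manifest = manifest_from_items(items)
    parts = split_dataset(manifest, config)
    train_idx, test_idx = parts["train"], parts["test"]
    if len(test_idx) == 0:
        raise ValueError("empty test partition")

    y = np.array([it.label for it in items])
    classes = sorted(set(y))
    if set(y[train_idx]) != set(classes):
        raise ValueError("a class is absent from the training partition")

    X_train = extract_features([items[i].image for i in train_idx], config)
    X_test = extract_features([items[i].image for i in test_idx], config)
    model = _build_model(config)
    model.fit(X_train, y[train_idx])
    y_pred = model.predict(X_test)

    cm = ConfusionMatrix.from_labels(list(y[test_idx]), list(y_pred), class_names=classes)
    report = classification_report(cm)
    acc = report["accuracy"]
    lo, hi = wilson_ci(acc, cm.total)
    result = {
        "model": config.model,
        "seed": config.seed,
        "confusion_matrix": cm,
        "report": report,
        "accuracy": acc,
        "accuracy_ci95": (lo, hi),
        "macro_f1": macro_f1(cm),
        "balanced_accuracy": balanced_accuracy(cm),
        "cohen_kappa": cohen_kappa(cm),
        "n_train": int(len(train_idx)),
        "n_val": int(len(parts["val"])),
        "n_test": int(len(test_idx)),
    }
    if isinstance(model, GridSearchCV):
        result["best_params"] = model.best_params_
        result["cv_mean_accuracy"] = float(model.best_score_)
    return result
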