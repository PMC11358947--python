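"""Classical baselines on band-power features.

PSD_SVM is the reference method: an RBF-kernel support vector machine on
the 177-dimensional combined band-power vector (θ‖α‖β mean band power per
channel, 3 x 59).  A six-classifier comparison (decision tree, linear
discriminant analysis, naive Bayes, RBF SVM, kNN, shallow neural
network) over the seven classification tasks (fv, fa, fc, fva, fvc, fca,
fvac) mirrors the standard EEG-classifier bake-off, scored by stratified
5-fold cross-validated accuracy.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

#: task code -> class subset (f=focused, v=visual, a=auditory, c=cognitive)
TASKS: dict[str, tuple[str, ...]] = {
    "fv": ("focused", "visual"),
    "fa": ("focused", "auditory"),
    "fc": ("focused", "cognitive"),
    "fva": ("focused", "visual", "auditory"),
    "fvc": ("focused", "visual", "cognitive"),
    "fca": ("focused", "cognitive", "auditory"),
    "fvac": ("focused", "visual", "auditory", "cognitive"),
}

COMBINED_FEATURE_LEN = 177  # 59 channels x 3 bands


def make_classifier(method: str, seed: int | None = None):
    """Factory for the six compared classifiers (library defaults; the
    shallow network is a single 64-unit hidden layer)."""
    factories = {
        "decision_tree": lambda: DecisionTreeClassifier(random_state=seed),
        "discriminant_analysis": lambda: LinearDiscriminantAnalysis(),
        "naive_bayes": lambda: GaussianNB(),
        "svm_rbf": lambda: SVC(kernel="rbf", C=1.0, gamma="scale", random_state=seed),
        "knn": lambda: KNeighborsClassifier(),
        "shallow_nn": lambda: MLPClassifier(hidden_layer_sizes=(64,), max_iter=500,
                                            random_state=seed),
    }
    if method not in factories:
        raise ValueError(f"unknown method {method!r}; choose from {sorted(factories)}")
    return make_pipeline(StandardScaler(), factories[method]())

CLASSIFIER_METHODS = ("decision_tree", "discriminant_analysis", "naive_bayes",
                      "svm_rbf", "knn", "shallow_nn")


def train_psd_svm(features: np.ndarray, labels, seed: int | None = None,
                  expect_width: int | None = COMBINED_FEATURE_LEN):
    """Fit the RBF-kernel SVM (one-vs-one multiclass) on standardized
    band-power features; enforces the 177-wide combined-band layout by
    default (pass ``expect_width=None`` for other feature sets)."""
    features = np.asarray(features, dtype=np.float64)
    labels = np.asarray(labels)
    if features.ndim != 2:
        raise ValueError("features must be 2-D (n_samples, n_features)")
    if expect_width is not None and features.shape[1] != expect_width:
        raise ValueError(
            f"combined-band features must have width {expect_width}; "
            f"got {features.shape[1]}")
    if len(np.unique(labels)) < 2:
        raise ValueError("need at least 2 classes")
    clf = make_classifier("svm_rbf", seed)
    return clf.fit(features, labels)


def _subset(features: np.ndarray, labels: np.ndarray, task: str):
    wanted = set(TASKS[task])
    missing = wanted - set(labels)
    if missing:
        raise ValueError(
            f"task {task!r}: no samples for classes {sorted(missing)}")
    mask = np.isin(labels, list(wanted))
    return features[mask], labels[mask]


def compare_classifiers(features: np.ndarray, labels,
                        tasks: tuple[str, ...] = tuple(TASKS),
                        methods: tuple[str, ...] = CLASSIFIER_METHODS,
                        k: int = 5, seed: int = 0) -> pd.DataFrame:
    """Stratified k-fold CV accuracy, methods x tasks (6 x 7 by default)."""
    features = np.asarray(features, dtype=np.float64)
    labels = np.asarray(labels)
    table = pd.DataFrame(index=list(methods), columns=list(tasks), dtype=float)
    for task in tasks:
        Xs, ys = _subset(features, labels, task)
        cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        for method in methods:
            clf = make_classifier(method, seed)
            table.loc[method, task] = float(
                cross_val_score(clf, Xs, ys, cv=cv, scoring="accuracy").mean())
    return table


def full_vs_band_features(psd: np.ndarray, labels, task: str = "fvac",
                          k: int = 5, seed: int = 0) -> dict:
    """SVM accuracy with full 0–50 Hz PSD features vs the 177-dim
    three-band features, on the same folds and seed.

    ``psd`` is the dB-normalised PSD stack (n, bins, channels).
    """
    from .spectral import BandPowerVectorizer

    psd = np.asarray(psd, dtype=np.float64)
    labels = np.asarray(labels)
    full = BandPowerVectorizer(bands="full").transform(psd)
    band = BandPowerVectorizer(bands="three").transform(psd)
    accs = {}
    for name, feats in (("full", full), ("band", band)):
        Xs, ys = _subset(feats, labels, task)
        cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        clf = make_classifier("svm_rbf", seed)
        accs[name] = float(cross_val_score(clf, Xs, ys, cv=cv).mean())
    accs["difference"] = accs["band"] - accs["full"]
    return accs
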