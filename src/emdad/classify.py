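"""Classifier configurations and a uniform fit/predict surface.

Six classifier kinds are supported: linear discriminant analysis, a
linear-kernel support vector machine, AdaBoost over decision trees, and
three small neural networks (feed-forward, recurrent, convolutional).
Each kind carries a complete default hyperparameter set; configurations
may override individual entries (the test suite shrinks the networks),
but every named default is always present.

Features are standardized with a z-score fit on the training fold only
and applied to the test fold — the margin- and gradient-based
classifiers are scale-sensitive and statistics must never leak across
the split.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import AdaBoostClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .nets import ANNClassifier, CNNClassifier, RNNClassifier

CLASSIFIER_KINDS = ("lda", "svm", "adaboost_tree", "ann", "rnn", "cnn")

_DEFAULTS = {
    "lda": {
        "discriminant_type": "linear",
        "priors": "empirical",
        "score_transform": "none",
    },
    "svm": {
        "kernel": "linear",
        "cache_size": 1000,
        "priors": "empirical",
        "score_transform": "none",
        "max_iter": 1000,
        "method": "least square",
    },
    "adaboost_tree": {
        "method": "AdaBoostM",
        "learner": "decision tree",
        "learning_rate": 0.01,
        "n_learners": 100,
        "priors": "empirical",
    },
    "ann": {
        "hidden_layers": 1,
        "nodes": 10,
        "hidden_activation": "logsig",
        "output_activation": "softmax",
        "loss": "mae",
        "trainer": "trainbr",
        "epochs": 100,
        "learning_rate": 0.01,
    },
    "rnn": {
        "delays": "1:2",
        "hidden_layers": 1,
        "nodes": 10,
        "hidden_activation": "tanh",
        "output_activation": "linear",
        "loss": "mae",
        "trainer": "trainbr",
        "epochs": 100,
        "learning_rate": 0.01,
    },
    "cnn": {
        "conv_layers": 2,
        "dropout_layers": 2,
        "batchnorm_layers": 2,
        "leaky_relu_layers": 2,
        "fc_layers": 2,
        "dropout": 0.25,
        "filter_size": (11, 11),
        "n_filters": 96,
        "batch_size": 64,
        "epochs": 100,
        "optimizer": "adam",
        "lr_schedule": "piecewise",
        "lr_drop_period": 125,
        "lr_drop_factor": 0.2,
        "learning_rate": 0.01,
    },
}


class FoldSkip(Exception):
    """A training fold was degenerate (single class); skip and record."""


@dataclass(frozen=True)
class ClassifierConfig:
    """One classifier kind with its full hyperparameter map and a seed."""

    kind: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.kind not in CLASSIFIER_KINDS:
            raise ValueError(f"unknown classifier kind {self.kind!r}")
        merged = dict(_DEFAULTS[self.kind])
        merged.update(self.hyperparameters)
        object.__setattr__(self, "hyperparameters", merged)


def default_configs(kinds=CLASSIFIER_KINDS, seed: int = 0, overrides=None) -> list:
    overrides = overrides or {}
    return [
        ClassifierConfig(kind=k, hyperparameters=overrides.get(k, {}), seed=seed)
        for k in kinds
    ]


def _build(config: ClassifierConfig, n_features: int):
    hp = config.hyperparameters
    if config.kind == "lda":
        return LinearDiscriminantAnalysis()
    if config.kind == "svm":
        return SVC(
            kernel=hp["kernel"],
            cache_size=hp["cache_size"],
            max_iter=hp["max_iter"],
            random_state=config.seed,
        )
    if config.kind == "adaboost_tree":
        return AdaBoostClassifier(
            estimator=DecisionTreeClassifier(random_state=config.seed),
            n_estimators=hp["n_learners"],
            learning_rate=hp["learning_rate"],
            random_state=config.seed,
        )
    if config.kind == "ann":
        return ANNClassifier(
            hidden=hp["nodes"],
            epochs=hp["epochs"],
            lr=hp["learning_rate"],
            seed=config.seed,
        )
    if config.kind == "rnn":
        return RNNClassifier(
            hidden=hp["nodes"],
            seq_len=8,
            epochs=hp["epochs"],
            lr=hp["learning_rate"],
            seed=config.seed,
        )
    if config.kind == "cnn":
        if n_features % 8:
            raise ValueError("cnn expects a channels x 8-components feature row")
        return CNNClassifier(
            input_shape=(n_features // 8, 8),
            filters=hp["n_filters"],
            filter_size=hp["filter_size"],
            dropout=hp["dropout"],
            epochs=hp["epochs"],
            lr=hp["learning_rate"],
            batch_size=hp["batch_size"],
            seed=config.seed,
            lr_drop_period=hp["lr_drop_period"],
            lr_drop_factor=hp["lr_drop_factor"],
        )
    raise AssertionError(config.kind)


def fit_predict(
    config: ClassifierConfig,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
) -> np.ndarray:
    """Standardize on the training rows, fit, and label the test rows.

    Raises :class:`FoldSkip` when the training fold holds fewer than two
    classes.
    """
    y_train = np.asarray(y_train)
    if len(np.unique(y_train)) < 2:
        raise FoldSkip("training fold contains a single class")
    X_train = np.asarray(X_train, dtype=float)
    X_test = np.asarray(X_test, dtype=float)
    mean = X_train.mean(axis=0)
    sd = X_train.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    est = _build(config, X_train.shape[1])
    est.fit((X_train - mean) / sd, y_train)
    return np.asarray(est.predict((X_test - mean) / sd))
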