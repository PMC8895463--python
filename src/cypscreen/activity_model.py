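"""Fingerprint-based activity classifier emitting a prediction index in [0, 1].

A feed-forward network (two hidden layers, 256/64 by default) over hashed
fingerprint bits, trained with cross-entropy. Class imbalance — curated
bioassay sets run roughly 1 active per 5 inactives — is handled by
deterministic integer replication of the minority class, approximating
inverse-class-frequency loss weights. Training is capped by an epoch budget
rather than wall-clock time, so runs are hardware-independent and
reproducible: the same data and seed always give the same weights.

Compounds at or above the decision threshold (default 0.7) are declared
predicted inhibitors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import joblib
import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.neural_network import MLPClassifier

from .chemstruct import (
    Fingerprint,
    FingerprintConfig,
    Molecule,
    fingerprint,
    fingerprint_matrix,
)
from .curation import LabeledCompound

DEFAULT_THRESHOLD = 0.7

FORMAT_VERSION = 1


class TrainError(ValueError):
    pass


@dataclass
class Hyperparams:
    hidden_layer_sizes: tuple = (256, 64)
    max_epochs: int = 20
    learning_rate: float = 1e-3
    batch_size: int = 200


@dataclass
class TrainedClassifier:
    fingerprint_config: FingerprintConfig
    hyperparams: Hyperparams
    seed: int
    net: MLPClassifier = field(repr=False)
    metadata: Dict = field(default_factory=dict)

    def save(self, path) -> None:
        joblib.dump(
            dict(format_version=FORMAT_VERSION, classifier=self), path
        )

    @staticmethod
    def load(path) -> "TrainedClassifier":
        payload = joblib.load(path)
        if payload.get("format_version") != FORMAT_VERSION:
            raise ValueError("unsupported model file version")
        return payload["classifier"]


def _balance_by_replication(X: np.ndarray, y: np.ndarray):
    """Replicate the minority class round(n_maj/n_min) times.

    Integer replication is an exact, rng-free stand-in for inverse-class-
    frequency sample weights.
    """
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise TrainError("training set must contain both classes")
    minority = 1 if n_pos < n_neg else 0
    k = max(1, int(round(max(n_pos, n_neg) / min(n_pos, n_neg))))
    if k == 1:
        return X, y
    mask = y == minority
    X_bal = np.concatenate([X] + [X[mask]] * (k - 1))
    y_bal = np.concatenate([y] + [y[mask]] * (k - 1))
    return X_bal, y_bal


def _features(compounds: Sequence[LabeledCompound], config: FingerprintConfig):
    fps: List[Fingerprint] = []
    for c in compounds:
        fp = c.molecule.fingerprint
        if fp is None or fp.length != config.n_bits:
            fp = fingerprint(c.molecule, config)
        fps.append(fp)
    return fingerprint_matrix(fps)


def train(
    train_set: Sequence[LabeledCompound],
    hyperparams: Optional[Hyperparams] = None,
    seed: int = 0,
    fingerprint_config: FingerprintConfig = FingerprintConfig(),
) -> TrainedClassifier:
    """Fit the classifier on labeled, fingerprinted compounds.

    Raises :class:`TrainError` when only one class is present. Deterministic
    under a fixed seed.
    """
    hp = hyperparams or Hyperparams()
    labels = {c.label for c in train_set}
    if labels - {"active", "inactive"}:
        raise TrainError(f"unknown labels: {labels - {'active', 'inactive'}}")
    if len(labels) < 2:
        raise TrainError("training set must contain both classes")

    X = _features(train_set, fingerprint_config).astype(np.float32)
    y = np.array([1 if c.label == "active" else 0 for c in train_set])
    X_bal, y_bal = _balance_by_replication(X, y)

    net = MLPClassifier(
        hidden_layer_sizes=hp.hidden_layer_sizes,
        activation="relu",
        solver="adam",
        learning_rate_init=hp.learning_rate,
        batch_size=min(hp.batch_size, len(y_bal)),
        max_iter=hp.max_epochs,
        shuffle=True,
        random_state=seed,
        early_stopping=False,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        net.fit(X_bal, y_bal)

    return TrainedClassifier(
        fingerprint_config=fingerprint_config,
        hyperparams=hp,
        seed=seed,
        net=net,
        metadata=dict(
            n_train=len(y),
            n_active=int(y.sum()),
            n_inactive=int(len(y) - y.sum()),
            n_after_balancing=len(y_bal),
            epochs_run=net.n_iter_,
            loss_trace=list(map(float, net.loss_curve_)),
        ),
    )


def predict_indices(model: TrainedClassifier, molecules: Sequence[Molecule]) -> np.ndarray:
    """Prediction index (probability-like, in [0, 1]) per molecule."""
    fps = []
    for mol in molecules:
        fp = mol.fingerprint
        if fp is None or fp.length != model.fingerprint_config.n_bits:
            fp = fingerprint(mol, model.fingerprint_config)
        fps.append(fp)
    X = fingerprint_matrix(fps).astype(np.float32)
    active_col = list(model.net.classes_).index(1)
    return model.net.predict_proba(X)[:, active_col]


def predict_index(model: TrainedClassifier, mol: Molecule) -> float:
    return float(predict_indices(model, [mol])[0])


def classify(index: float, threshold: float = DEFAULT_THRESHOLD) -> str:
    """'active' iff index >= threshold (inclusive at the boundary)."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    return "active" if index >= threshold else "inactive"
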