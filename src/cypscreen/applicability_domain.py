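"""Applicability domain (APD) from training-set Tanimoto distance statistics.

The APD threshold is derived from the distribution of pairwise Tanimoto
distances among training fingerprints: with mean distance over all n(n-1)/2
unordered pairs written d_all, take the subset of distances strictly below
d_all, and let d and sigma be that subset's mean and (population) standard
deviation. Then

    APD = d + Z * sigma,      Z = 0.5 by default.

A screening compound is reliable iff the Tanimoto distance to its nearest
training neighbor is at or below the APD. When every pairwise distance is
identical the below-mean subset is empty; the degenerate case uses the full
set, giving sigma = 0 and APD = d_all.

Pair enumeration is exact (O(n^2), vectorized over packed bit matrices);
no approximate nearest-neighbor shortcuts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import joblib
import numpy as np

from .chemstruct import Fingerprint, FingerprintConfig, fingerprint_matrix

DEFAULT_Z = 0.5


class ApdError(ValueError):
    pass


def _pairwise_distances(matrix: np.ndarray, chunk: int = 512) -> np.ndarray:
    """Upper-triangle (i<j) Tanimoto distances of a boolean (n, bits) matrix."""
    X = matrix.astype(np.float32)
    pop = X.sum(axis=1)
    n = len(X)
    out: List[np.ndarray] = []
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        inter = X[start:stop] @ X.T  # (chunk, n)
        union = pop[start:stop, None] + pop[None, :] - inter
        with np.errstate(invalid="ignore", divide="ignore"):
            dist = 1.0 - np.where(union > 0, inter / np.where(union > 0, union, 1), 1.0)
        for i in range(start, stop):
            out.append(dist[i - start, i + 1 :])
    return np.concatenate(out) if out else np.empty(0)


def _nn_distances(query: np.ndarray, train: np.ndarray, chunk: int = 512) -> np.ndarray:
    Xq = query.astype(np.float32)
    Xt = train.astype(np.float32)
    pop_q = Xq.sum(axis=1)
    pop_t = Xt.sum(axis=1)
    nn = np.empty(len(Xq))
    for start in range(0, len(Xq), chunk):
        stop = min(start + chunk, len(Xq))
        inter = Xq[start:stop] @ Xt.T
        union = pop_q[start:stop, None] + pop_t[None, :] - inter
        dist = 1.0 - np.where(union > 0, inter / np.where(union > 0, union, 1), 1.0)
        nn[start:stop] = dist.min(axis=1)
    return nn


@dataclass
class ApdModel:
    training_fingerprints: List[Fingerprint] = field(repr=False)
    fingerprint_config: FingerprintConfig
    mean_all: float
    d_sub: float
    sigma_sub: float
    z: float
    apd_threshold: float
    _matrix: np.ndarray = field(default=None, repr=False, compare=False)

    @property
    def matrix(self) -> np.ndarray:
        if self._matrix is None:
            self._matrix = fingerprint_matrix(self.training_fingerprints)
        return self._matrix

    def save(self, path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "ApdModel":
        return joblib.load(path)


def fit_apd(
    train_fps: Sequence[Fingerprint],
    z: float = DEFAULT_Z,
    fingerprint_config: FingerprintConfig = FingerprintConfig(),
) -> ApdModel:
    """Fit the distance statistics over all unordered training pairs."""
    if len(train_fps) < 2:
        raise ApdError("at least 2 training fingerprints required")
    matrix = fingerprint_matrix(train_fps)
    dists = _pairwise_distances(matrix)
    assert len(dists) == len(train_fps) * (len(train_fps) - 1) // 2
    mean_all = float(dists.mean())
    below = dists[dists < mean_all]
    if len(below) == 0:   # all distances equal
        below = dists
    d_sub = float(below.mean())
    sigma_sub = float(below.std(ddof=0))
    return ApdModel(
        training_fingerprints=list(train_fps),
        fingerprint_config=fingerprint_config,
        mean_all=mean_all,
        d_sub=d_sub,
        sigma_sub=sigma_sub,
        z=z,
        apd_threshold=d_sub + z * sigma_sub,
        _matrix=matrix,
    )


def nn_distance(model: ApdModel, query: Fingerprint) -> float:
    """Tanimoto distance from a query to its nearest training neighbor."""
    q = fingerprint_matrix([query])
    return float(_nn_distances(q, model.matrix)[0])


def in_domain(model: ApdModel, query: Fingerprint) -> Tuple[bool, float]:
    """(reliable, nn_distance): reliable iff nn_distance <= APD threshold."""
    d = nn_distance(model, query)
    return d <= model.apd_threshold, d


def in_domain_bulk(model: ApdModel, queries: Sequence[Fingerprint]):
    """Vectorized :func:`in_domain` over many queries."""
    q = fingerprint_matrix(queries)
    d = _nn_distances(q, model.matrix)
    return d <= model.apd_threshold, d
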