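"""Balanced negative sampling and the MLP scoring head.

Known associations are the positives; an equal number of unknown pairs is
drawn uniformly without replacement as negatives (the class imbalance in
real catalogs is ~34:1, so balancing is essential for MLP training).  The
scorer is a two-hidden-layer perceptron

    X^l = ReLU(X^(l-1) W_l + b_l),  l = 1, 2
    score = sigmoid(X^2 W_3 + b_3)

trained full-batch with Adam on the mean binary cross-entropy over the
labeled pairs.  Implemented in numpy with explicit backpropagation so runs
are bit-reproducible under a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._optim import Adam
from .io_data import AssociationMatrix, UnknownEntityError
from .features import build_pair_matrix

__all__ = [
    "MlpConfig",
    "MlpParams",
    "LabeledPairSet",
    "sample_negatives",
    "build_labeled_pairs",
    "init_mlp",
    "mlp_forward",
    "bce_loss",
    "train_mlp",
    "rank_candidates",
]


@dataclass
class MlpConfig:
    hidden: tuple[int, int] = (512, 128)
    epochs: int = 100
    lr: float = 1e-3
    seed: int = 0
    threshold: float = 0.5  # cut for binary metrics on balanced classes

    def __post_init__(self) -> None:
        if len(self.hidden) != 2:
            raise ValueError("exactly two hidden layers are supported")
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must be in (0, 1)")


@dataclass
class MlpParams:
    weights: list[np.ndarray]  # W1, W2, W3
    biases: list[np.ndarray]  # b1, b2, b3

    def as_list(self) -> list[np.ndarray]:
        return [*self.weights, *self.biases]


@dataclass
class LabeledPairSet:
    """Pair indices with binary labels and sampling provenance."""

    pairs: np.ndarray  # (n, 2) int array of (miRNA index, disease index)
    labels: np.ndarray  # (n,) in {0, 1}
    seed: int | None = None
    round_id: int | None = None

    def __post_init__(self) -> None:
        self.pairs = np.asarray(self.pairs, dtype=int)
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.pairs) != len(self.labels):
            raise ValueError("pairs and labels length mismatch")


def sample_negatives(assoc: AssociationMatrix, n: int, seed: int) -> LabeledPairSet:
    """Draw n unknown pairs uniformly without replacement, reproducibly."""
    zero_i, zero_j = np.nonzero(assoc.values == 0)
    if n > len(zero_i):
        raise ValueError(f"requested {n} negatives but only {len(zero_i)} unknown pairs exist")
    rng = np.random.default_rng(seed)
    pick = rng.choice(len(zero_i), size=n, replace=False)
    pairs = np.column_stack([zero_i[pick], zero_j[pick]])
    return LabeledPairSet(pairs, np.zeros(n, dtype=int), seed=seed)


def build_labeled_pairs(assoc: AssociationMatrix, seed: int, round_id: int = 0) -> LabeledPairSet:
    """All positives plus an equal-size random negative sample."""
    pos_i, pos_j = np.nonzero(assoc.values == 1)
    pos = np.column_stack([pos_i, pos_j])
    neg = sample_negatives(assoc, len(pos), seed)
    pairs = np.vstack([pos, neg.pairs])
    labels = np.concatenate([np.ones(len(pos), dtype=int), np.zeros(len(pos), dtype=int)])
    return LabeledPairSet(pairs, labels, seed=seed, round_id=round_id)


def init_mlp(n_features: int, cfg: MlpConfig, rng: np.random.Generator) -> MlpParams:
    sizes = [n_features, *cfg.hidden, 1]
    weights, biases = [], []
    for d_in, d_out in zip(sizes[:-1], sizes[1:]):
        limit = np.sqrt(6.0 / (d_in + d_out))
        weights.append(rng.uniform(-limit, limit, size=(d_in, d_out)))
        biases.append(np.zeros(d_out))
    return MlpParams(weights, biases)


def mlp_forward(x: np.ndarray, params: MlpParams) -> np.ndarray:
    """Scores in (0, 1) for a batch of pair-feature rows."""
    for w in params.as_list():
        if not np.isfinite(w).all():
            raise FloatingPointError("non-finite MLP parameters")
    h = np.asarray(x, dtype=float)
    for w, b in zip(params.weights[:-1], params.biases[:-1]):
        h = np.maximum(h @ w + b, 0.0)
    logits = h @ params.weights[-1] + params.biases[-1]
    return (1.0 / (1.0 + np.exp(-logits))).ravel()


def bce_loss(scores: np.ndarray, labels: np.ndarray, eps: float = 1e-12) -> float:
    """Mean binary cross-entropy over the labeled pair set."""
    s = np.clip(scores, eps, 1 - eps)
    y = np.asarray(labels, dtype=float)
    return float(-np.mean(y * np.log(s) + (1 - y) * np.log(1 - s)))


def train_mlp(
    x: np.ndarray, labels: np.ndarray, cfg: MlpConfig
) -> tuple[MlpParams, list[float]]:
    """Full-batch Adam on mean BCE; returns trained params and loss trace."""
    labels = np.asarray(labels, dtype=float)
    if len(np.unique(labels)) < 2:
        raise ValueError("training set must contain both classes")
    rng = np.random.default_rng(cfg.seed)
    params = init_mlp(x.shape[1], cfg, rng)
    opt = Adam(params.as_list(), lr=cfg.lr)
    x = np.asarray(x, dtype=float)
    n = len(labels)
    trace: list[float] = []
    for _ in range(cfg.epochs):
        # forward with caches
        h1_pre = x @ params.weights[0] + params.biases[0]
        h1 = np.maximum(h1_pre, 0.0)
        h2_pre = h1 @ params.weights[1] + params.biases[1]
        h2 = np.maximum(h2_pre, 0.0)
        logits = (h2 @ params.weights[2] + params.biases[2]).ravel()
        scores = 1.0 / (1.0 + np.exp(-logits))
        trace.append(bce_loss(scores, labels))
        # backward: d mean-BCE / d logits = (s - y) / n
        dlogit = ((scores - labels) / n)[:, None]
        gw3 = h2.T @ dlogit
        gb3 = dlogit.sum(axis=0)
        dh2 = (dlogit @ params.weights[2].T) * (h2_pre > 0)
        gw2 = h1.T @ dh2
        gb2 = dh2.sum(axis=0)
        dh1 = (dh2 @ params.weights[1].T) * (h1_pre > 0)
        gw1 = x.T @ dh1
        gb1 = dh1.sum(axis=0)
        opt.step([gw1, gw2, gw3, gb1, gb2, gb3])
    return params, trace


def rank_candidates(
    params: MlpParams,
    disease: str,
    assoc: AssociationMatrix,
    vm: np.ndarray,
    vd: np.ndarray,
    k: int = 20,
) -> list[tuple[str, float]]:
    """Top-k unknown miRNAs for one disease, by score then name.

    Known positives are filtered out; ties break by miRNA name ascending.
    """
    cat = assoc.catalog
    if disease not in cat.disease_index:
        raise UnknownEntityError(f"disease {disease!r} not in catalog")
    j = cat.disease_index[disease]
    candidates = np.nonzero(assoc.values[:, j] == 0)[0]
    if len(candidates) == 0:
        return []
    pairs = np.column_stack([candidates, np.full(len(candidates), j)])
    scores = mlp_forward(build_pair_matrix(vm, vd, pairs), params)
    ranked = sorted(
        zip((cat.mirna_names[i] for i in candidates), scores),
        key=lambda t: (-t[1], t[0]),
    )
    return [(name, float(s)) for name, s in ranked[:k]]
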