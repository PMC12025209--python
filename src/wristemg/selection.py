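"""ReliefF feature weighting and per-channel feature selection.

ReliefF scores each feature by how well it separates nearby instances
of different classes while keeping nearby same-class instances close.
For every sampled instance the algorithm finds its k nearest *hits*
(same class) and, for each other class, its k nearest *misses*, and
updates each feature weight by

    W[f] -= diff(f, x, hit) / (n_samples * k)
    W[f] += [P(C) / (1 - P(class(x)))] * diff(f, x, miss_C) / (n_samples * k)

with diff the absolute difference on features min-max scaled to [0, 1]
and Manhattan distance for the neighbour search (the canonical
multiclass formulation).  The pipeline keeps the two highest-weight
features of each channel, turning the 40-column matrix of an 8-channel
recording into the 16-dimensional classifier input.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .features import FEATURE_ORDER, FeatureMatrix

_NAME_RE = re.compile(r"^ch(\d+)_([A-Z]+)$")


@dataclass
class FeatureWeights:
    """ReliefF weights aligned with the feature columns they score."""

    weights: np.ndarray
    feature_names: list[str]
    params: dict

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.weights) != len(self.feature_names):
            raise ValueError("one weight per feature required")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("weights must be finite")

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("feature,weight\n")
            for name, w in zip(self.feature_names, self.weights):
                fh.write(f"{name},{w:.10g}\n")


def _minmax_scale(X: np.ndarray) -> np.ndarray:
    lo = X.min(axis=0)
    span = X.max(axis=0) - lo
    span[span == 0] = 1.0  # constant columns scale to 0 -> weight exactly 0
    return (X - lo) / span


def relieff_weights(
    features: FeatureMatrix,
    k_neighbors: int = 10,
    n_iterations: int | None = None,
    seed: int = 0,
) -> FeatureWeights:
    """Multiclass ReliefF weights for every feature column.

    ``n_iterations`` is the number of sampled instances; ``None``
    (default) iterates over every instance exhaustively, which removes
    sampling noise at the dataset sizes this package targets.
    """
    if features.labels is None:
        raise ValueError("ReliefF requires labeled features")
    y = np.asarray(features.labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("ReliefF requires at least 2 classes")
    for cls, cnt in zip(classes, counts):
        if cnt <= k_neighbors:
            raise ValueError(
                f"class {cls!r} has only {cnt} instances; "
                f"need more than k_neighbors={k_neighbors}"
            )
    X = _minmax_scale(features.values)
    n, n_feat = X.shape
    priors = {c: cnt / n for c, cnt in zip(classes, counts)}

    rng = np.random.default_rng(seed)
    if n_iterations is None or n_iterations >= n:
        sampled = np.arange(n)
    else:
        if n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        sampled = rng.choice(n, size=n_iterations, replace=False)

    dist = cdist(X, X, metric="cityblock")
    np.fill_diagonal(dist, np.inf)  # never pick self as a neighbour
    class_idx = {c: np.flatnonzero(y == c) for c in classes}

    m = len(sampled)
    W = np.zeros(n_feat)
    for i in sampled:
        own = y[i]
        for c in classes:
            pool = class_idx[c]
            order = np.argsort(dist[i, pool], kind="stable")[:k_neighbors]
            neighbours = pool[order]
            diffs = np.abs(X[neighbours] - X[i]).mean(axis=0)
            if c == own:
                W -= diffs / m
            else:
                W += (priors[c] / (1.0 - priors[own])) * diffs / m
    return FeatureWeights(
        weights=W,
        feature_names=list(features.feature_names),
        params={
            "k_neighbors": k_neighbors,
            "n_iterations": n_iterations,
            "seed": seed,
        },
    )


def _parse_name(name: str) -> tuple[int, str]:
    m = _NAME_RE.match(name)
    if not m or m.group(2) not in FEATURE_ORDER:
        raise ValueError(
            f"feature name {name!r} is not of the form ch<c>_<feature>"
        )
    return int(m.group(1)), m.group(2)


def select_top_per_channel(
    weights: FeatureWeights, per_channel: int = 2
) -> list[str]:
    """Keep the ``per_channel`` highest-weight features of each channel.

    Output order is channel-major and stable.  Ties at the selection
    boundary are resolved by the fixed feature order MAV < RMS < VAR <
    ZC < WL.
    """
    if per_channel < 1:
        raise ValueError("per_channel must be >= 1")
    by_channel: dict[int, list[tuple[float, int, str]]] = {}
    for name, w in zip(weights.feature_names, weights.weights):
        channel, feat = _parse_name(name)
        by_channel.setdefault(channel, []).append(
            (-w, FEATURE_ORDER.index(feat), name)
        )
    selected = []
    for channel in sorted(by_channel):
        entries = sorted(by_channel[channel])
        kept = entries[:per_channel]
        # restore fixed feature order within a channel for stable output
        kept.sort(key=lambda e: e[1])
        selected.extend(name for _, _, name in kept)
    return selected


def project_features(
    features: FeatureMatrix, selected: list[str]
) -> FeatureMatrix:
    """Column-subset a feature matrix, preserving row order and labels."""
    index = {name: i for i, name in enumerate(features.feature_names)}
    missing = [name for name in selected if name not in index]
    if missing:
        raise ValueError(f"unknown feature names: {missing}")
    cols = [index[name] for name in selected]
    return FeatureMatrix(
        values=features.values[:, cols],
        feature_names=list(selected),
        labels=None if features.labels is None else features.labels.copy(),
    )
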