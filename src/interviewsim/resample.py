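"""Hybrid class rebalancing: SMOTE oversampling followed by Tomek-link removal.

SMOTE creates synthetic minority samples as convex combinations of a
minority point and one of its k nearest minority neighbors; Tomek-link
removal then deletes both members of any cross-class mutual-nearest-
neighbor pair, cleaning the class boundary. Together they shrink the
imbalance ratio of a multiclass training set.
"""

from __future__ import annotations

import numpy as np
from scipy import sparse
from sklearn.neighbors import NearestNeighbors


class ResamplingError(ValueError):
    """Raised when a class is too small for neighbor interpolation."""


def _as_dense(X) -> np.ndarray:
    return X.toarray() if sparse.issparse(X) else np.asarray(X, dtype=float)


def smote_oversample(
    X, y: np.ndarray, *, k_neighbors: int = 5, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Oversample every minority class up to the majority class count.

    Synthetic points are x + u * (neighbor - x) with u ~ Uniform(0, 1),
    where the neighbor is one of the point's k nearest same-class
    neighbors (Euclidean). Requires every oversampled class to have at
    least ``k_neighbors + 1`` members.
    """
    X = _as_dense(X)
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    classes, counts = np.unique(y, return_counts=True)
    target = counts.max()
    new_X: list[np.ndarray] = [X]
    new_y: list[np.ndarray] = [y]
    for cls, count in zip(classes, counts):
        deficit = int(target - count)
        if deficit == 0:
            continue
        if count < k_neighbors + 1:
            raise ResamplingError(
                f"class {cls!r} has {count} samples, fewer than k_neighbors+1="
                f"{k_neighbors + 1}; lower k_neighbors or supply more data"
            )
        Xc = X[y == cls]
        nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(Xc)
        # first neighbor is the point itself
        neigh = nn.kneighbors(Xc, return_distance=False)[:, 1:]
        base = rng.integers(0, len(Xc), size=deficit)
        pick = neigh[base, rng.integers(0, k_neighbors, size=deficit)]
        gap = rng.uniform(0.0, 1.0, size=(deficit, 1))
        synth = Xc[base] + gap * (Xc[pick] - Xc[base])
        new_X.append(synth)
        new_y.append(np.full(deficit, cls, dtype=y.dtype))
    return np.vstack(new_X), np.concatenate(new_y)


def tomek_links(X, y: np.ndarray) -> np.ndarray:
    """Indices of all samples participating in a Tomek link.

    A Tomek link is a pair (i, j) of opposite-class points that are each
    other's single nearest neighbor.
    """
    X = _as_dense(X)
    y = np.asarray(y)
    if len(X) < 2:
        return np.empty(0, dtype=int)
    nn = NearestNeighbors(n_neighbors=2).fit(X)
    nearest = nn.kneighbors(X, return_distance=False)[:, 1]
    linked: set[int] = set()
    for i, j in enumerate(nearest):
        if y[i] != y[j] and nearest[j] == i:
            linked.add(i)
            linked.add(int(j))
    return np.asarray(sorted(linked), dtype=int)


def rebalance_smote_tomek(
    X, y: np.ndarray, *, k_neighbors: int = 5, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """SMOTE to the majority count, then drop Tomek-link pairs.

    Never removes an entire class: a Tomek-link member is kept if deleting
    it would empty its class. The output imbalance ratio (max class count
    over min class count) never exceeds the input ratio.
    """
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ResamplingError("rebalancing needs at least two classes")
    Xs, ys = smote_oversample(X, y, k_neighbors=k_neighbors, seed=seed)
    links = tomek_links(Xs, ys)
    if len(links) == 0:
        return Xs, ys
    keep = np.ones(len(ys), dtype=bool)
    keep[links] = False
    for cls in np.unique(ys):
        if not keep[ys == cls].any():
            keep[np.flatnonzero(ys == cls)] = True
    return Xs[keep], ys[keep]


def imbalance_ratio(y: np.ndarray) -> float:
    """max class count / min class count."""
    _, counts = np.unique(np.asarray(y), return_counts=True)
    return float(counts.max() / counts.min())
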