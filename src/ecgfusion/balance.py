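"""Borderline-SMOTE oversampling of minority heartbeat classes.

Variant 1 of the original algorithm: only minority samples sitting on the
class border ("danger" points - at least half, but not all, of their m
nearest neighbours belong to other classes) seed new samples, and each
synthetic point is a convex combination p + u*(q - p) of a danger point p
and one of its k nearest *minority* neighbours q.  Oversampling operates
on the 1-D beat vectors before image encoding, where linear interpolation
is meaningful.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.neighbors import NearestNeighbors

__all__ = ["SmoteConfig", "danger_set", "oversample"]


@dataclass
class SmoteConfig:
    m_neighbors: int = 10           # neighbourhood size for danger detection
    k_neighbors: int = 5            # minority neighbours used for synthesis
    target_counts: dict = field(default_factory=dict)  # class -> desired count
    seed: int = 0

    def validate(self):
        if self.m_neighbors < 2:
            raise ValueError("m_neighbors must be >= 2")
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")


def danger_set(
    minority_idx: np.ndarray,
    X: np.ndarray,
    y: np.ndarray,
    minority_class: int,
    m: int,
) -> np.ndarray:
    """Indices (into X) of minority points on the class border.

    For each minority point, count majority-class members m' among its m
    nearest neighbours in the full dataset (Euclidean, excluding itself):
    m' == m -> noise, m' < m/2 -> safe, m/2 <= m' < m -> danger.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    if m >= len(X):
        raise ValueError(f"m={m} neighbors requested but only {len(X) - 1} other points")
    nn = NearestNeighbors(n_neighbors=m + 1).fit(X)
    _, nbr = nn.kneighbors(X[minority_idx])
    out = []
    for row, p in zip(nbr, minority_idx):
        neigh = [j for j in row if j != p][:m]
        m_prime = int(np.sum(y[np.array(neigh)] != minority_class))
        if m / 2 <= m_prime < m:
            out.append(p)
    return np.asarray(out, dtype=np.intp)


def oversample(
    X: np.ndarray,
    y: np.ndarray,
    cfg: SmoteConfig | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Raise minority classes to their target counts with Borderline-SMOTE.

    Original rows are preserved and appear first, in input order; synthetic
    rows follow.  Default targets (empty ``target_counts``) raise every
    class to the majority count.  A class with fewer than k+1 members
    falls back to random duplication with a warning.
    """
    cfg = cfg or SmoteConfig()
    cfg.validate()
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    rng = np.random.default_rng(cfg.seed)

    classes, counts = np.unique(y, return_counts=True)
    count_of = dict(zip(classes.tolist(), counts.tolist()))
    targets = cfg.target_counts or {int(c): int(counts.max()) for c in classes}
    for cls, tgt in targets.items():
        if cls in count_of and tgt < count_of[cls]:
            raise ValueError(f"target count {tgt} below current count for class {cls}")

    new_rows, new_labels = [], []
    for cls in classes:
        cls = int(cls)
        need = targets.get(cls, count_of[cls]) - count_of[cls]
        if need <= 0:
            continue
        min_idx = np.flatnonzero(y == cls)
        if len(min_idx) < cfg.k_neighbors + 1:
            warnings.warn(
                f"class {cls} has only {len(min_idx)} members "
                f"(< k+1 = {cfg.k_neighbors + 1}); duplicating instead",
                stacklevel=2,
            )
            dup = rng.choice(min_idx, size=need, replace=True)
            new_rows.append(X[dup])
            new_labels.append(np.full(need, cls, dtype=y.dtype))
            continue

        seeds = danger_set(min_idx, X, y, cls, min(cfg.m_neighbors, len(X) - 1))
        if len(seeds) == 0:
            # nothing borderline: interpolate within the whole minority class
            seeds = min_idx
        nn = NearestNeighbors(n_neighbors=min(cfg.k_neighbors + 1, len(min_idx))).fit(
            X[min_idx]
        )
        _, nbr = nn.kneighbors(X[seeds])  # row i <-> seeds[i], indices into min_idx
        synth = np.empty((need, X.shape[1]), dtype=X.dtype)
        for t in range(need):
            si = rng.integers(len(seeds))
            s = seeds[si]
            cand = [int(min_idx[j]) for j in nbr[si] if min_idx[j] != s][: cfg.k_neighbors]
            q = X[cand[rng.integers(len(cand))]]
            u = rng.random()
            synth[t] = X[s] + u * (q - X[s])
        new_rows.append(synth)
        new_labels.append(np.full(need, cls, dtype=y.dtype))

    if not new_rows:
        return X.copy(), y.copy()
    X_out = np.concatenate([X] + new_rows, axis=0)
    y_out = np.concatenate([y] + new_labels, axis=0)
    return X_out, y_out
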