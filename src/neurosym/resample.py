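"""Training-fold oversampling: SMOTE balancing and Gaussian-noise replication.

Both operations are applied only to training partitions — the
cross-validation driver enforces this; test folds are never resampled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.neighbors import NearestNeighbors

__all__ = ["GaussianAugmentConfig", "smote", "gaussian_augment", "oversample"]


@dataclass(frozen=True)
class GaussianAugmentConfig:
    """Gaussian replication parameters.

    ``factor`` copies of the data are appended, each perturbed by
    independent zero-mean Gaussian noise whose diagonal covariance is
    ``scale`` times the per-feature variance of the input (scale = 1/100 in
    the reference analysis).
    """

    factor: int = 9
    scale: float = 1.0 / 100.0

    def __post_init__(self):
        if self.factor < 0:
            raise ValueError("factor must be >= 0")
        if self.scale <= 0:
            raise ValueError("scale must be > 0")


def smote(
    X: np.ndarray,
    y: np.ndarray,
    k_neighbors: int = 5,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic Minority Oversampling: balance the two classes exactly.

    Each synthetic point is a convex combination ``x + u * (x_nn - x)`` of a
    minority sample and one of its ``k_neighbors`` nearest minority
    neighbours (``u ~ U[0, 1)``).  Originals are preserved; an already
    balanced input is returned unchanged.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    if X.shape[0] != y.size:
        raise ValueError("X and y must have the same number of rows")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("smote requires exactly two classes")
    if counts[0] == counts[1]:
        return X.copy(), y.copy()
    minority = classes[np.argmin(counts)]
    need = int(abs(counts[0] - counts[1]))
    Xm = X[y == minority]
    if Xm.shape[0] < 2:
        raise ValueError("minority class must have at least 2 samples for SMOTE")
    if Xm.shape[0] <= k_neighbors:
        k_eff = Xm.shape[0] - 1
        warnings.warn(
            f"minority class has {Xm.shape[0]} samples; reducing "
            f"k_neighbors from {k_neighbors} to {k_eff}",
            stacklevel=2,
        )
        k_neighbors = k_eff
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(Xm)
    neigh = nn.kneighbors(Xm, return_distance=False)[:, 1:]  # drop self
    base = rng.integers(0, Xm.shape[0], size=need)
    pick = rng.integers(0, k_neighbors, size=need)
    gap = rng.random(need)[:, None]
    partner = Xm[neigh[base, pick]]
    synthetic = Xm[base] + gap * (partner - Xm[base])
    X_out = np.vstack([X, synthetic])
    y_out = np.concatenate([y, np.full(need, minority)])
    return X_out, y_out


def gaussian_augment(
    X: np.ndarray,
    config: GaussianAugmentConfig = GaussianAugmentConfig(),
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Stack ``X`` with ``factor`` noisy replicas.

    Noise is zero-mean Gaussian with diagonal covariance ``scale *
    diag(Sigma0)`` where ``Sigma0`` is the (population) feature covariance
    of ``X``; a zero-variance feature is replicated unchanged.  Output has
    ``(1 + factor) * n`` rows.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("gaussian_augment needs at least 2 samples")
    if config.factor == 0:
        return X.copy()
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    sd = np.sqrt(config.scale * X.var(axis=0, ddof=0))
    reps = np.tile(X, (config.factor, 1))
    noise = rng.standard_normal(reps.shape) * sd[None, :]
    return np.vstack([X, reps + noise])


def oversample(
    X: np.ndarray,
    y: np.ndarray,
    *,
    smote_k: int = 5,
    gaussian: GaussianAugmentConfig = GaussianAugmentConfig(),
    order: str = "smote_then_gaussian",
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Composite oversampling of a training partition.

    Default order balances with SMOTE first and then Gaussian-replicates
    the balanced set; ``order="gaussian_then_smote"`` composes the other
    way.  The composition order is a documented choice (the reference
    analysis lists the two methods without stating one).
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    if order == "smote_then_gaussian":
        Xb, yb = smote(X, y, k_neighbors=smote_k, seed=rng)
        Xg = gaussian_augment(Xb, gaussian, seed=rng)
        yg = np.tile(yb, gaussian.factor + 1)
    elif order == "gaussian_then_smote":
        Xg0 = gaussian_augment(X, gaussian, seed=rng)
        yg0 = np.tile(np.asarray(y, dtype=int), gaussian.factor + 1)
        Xg, yg = smote(Xg0, yg0, k_neighbors=smote_k, seed=rng)
    else:
        raise ValueError(f"unknown oversampling order {order!r}")
    return Xg, yg
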