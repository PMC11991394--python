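"""Feature weighting and subset selection.

Four selectors are provided, all usable as scikit-learn estimators inside a
``Pipeline`` (so selection can be fit inside each CV fold, avoiding
selection leakage):

* :class:`IRelief` — iterative Relief: margin-based feature weighting with
  soft (Gaussian-kernel) nearest hits/misses under the current weighted L1
  distance, iterated to a fixed point.  The primary selector.
* :class:`FCBF` — fast correlation-based filter using symmetrical
  uncertainty for relevance and the predominance rule for redundancy.
* :func:`info_gain_ratio` — information gain normalized by the feature's
  intrinsic information.
* :class:`BinaryPSO` — wrapper selection by binary particle swarm
  optimization with a sigmoid transfer function, fitness = mean CV accuracy
  of a supplied classifier.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, TransformerMixin, clone
from sklearn.model_selection import cross_val_score
from sklearn.utils.validation import check_is_fitted, check_X_y

from .containers import FeatureTable

__all__ = [
    "WeightVector",
    "IRelief",
    "irelief",
    "FCBF",
    "fcbf",
    "info_gain_ratio",
    "PSOConfig",
    "BinaryPSO",
    "pso_select",
    "rank_and_truncate",
]


@dataclass
class WeightVector:
    """Nonnegative per-feature relevance weights, normalized to max 1."""

    weights: np.ndarray
    iterations_run: int
    converged: bool

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(self.weights < 0):
            raise ValueError("weights must be nonnegative")


def _discretize(X: np.ndarray, bins: int = 10) -> np.ndarray:
    """Equal-frequency binning per column (robust to heavy tails)."""
    import pandas as pd

    out = np.empty(X.shape, dtype=int)
    for j in range(X.shape[1]):
        col = X[:, j]
        if np.all(col == col[0]):
            out[:, j] = 0
        else:
            out[:, j] = pd.qcut(col, q=bins, labels=False, duplicates="drop")
    return out


def _entropy(codes: np.ndarray) -> float:
    _, counts = np.unique(codes, return_counts=True)
    p = counts / counts.sum()
    return float(-np.sum(p * np.log2(p)))


def _joint(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    # combine two code vectors into one joint code
    return a * (b.max() + 1) + b


def symmetrical_uncertainty(a: np.ndarray, b: np.ndarray) -> float:
    """SU(a, b) = 2 I(a;b) / (H(a) + H(b)) on discrete codes; 0 if degenerate."""
    ha, hb = _entropy(a), _entropy(b)
    if ha + hb == 0:
        return 0.0
    mi = ha + hb - _entropy(_joint(a, b))
    return float(2.0 * mi / (ha + hb))


class IRelief(BaseEstimator, TransformerMixin):
    """Iterative Relief feature weighting.

    At each iteration the weighted L1 distance
    ``d_w(a, b) = sum_f w_f |a_f - b_f|`` (features z-scored internally)
    defines, for every sample, its ``n_neighbors`` nearest same-class (hit)
    and other-class (miss) neighbors.  Neighbor contributions are softened
    by a Gaussian kernel of width ``sigma`` on the distances.  Weights move
    along the expected margin, ``w <- w + eta (E[miss margin] - E[hit
    margin])`` per feature, are clipped at zero and normalized to maximum 1;
    iteration stops when the L1 change falls below ``theta``.

    Parameters (defaults follow the published configuration): ``max_iter``
    100, ``n_neighbors`` 5, ``eta`` 0.001, ``theta`` 0.01, ``sigma`` 2.0.

    Attributes
    ----------
    weights_ : ndarray (n_features,)
        Final normalized weights.
    n_iter_ : int
    converged_ : bool
    """

    def __init__(
        self,
        n_neighbors: int = 5,
        eta: float = 0.001,
        theta: float = 0.01,
        sigma: float = 2.0,
        max_iter: int = 100,
        top_n: int | None = None,
    ) -> None:
        self.n_neighbors = n_neighbors
        self.eta = eta
        self.theta = theta
        self.sigma = sigma
        self.max_iter = max_iter
        self.top_n = top_n

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        classes, y_enc = np.unique(y, return_inverse=True)
        if len(classes) < 2:
            raise ValueError("iRelief requires at least 2 classes")
        counts = np.bincount(y_enc)
        if np.any(counts < self.n_neighbors + 1):
            raise ValueError(
                f"every class needs more than n_neighbors={self.n_neighbors} "
                f"samples (class sizes: {counts.tolist()})"
            )
        n, nf = X.shape
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        Z = (X - mu) / sd

        same = y_enc[:, None] == y_enc[None, :]
        k = self.n_neighbors
        w = np.ones(nf)
        converged = False
        it = 0
        for it in range(1, self.max_iter + 1):
            D = cdist(Z, Z, metric="minkowski", p=1, w=np.maximum(w, 1e-12))
            np.fill_diagonal(D, np.inf)
            Dh = np.where(same, D, np.inf)
            Dm = np.where(same, np.inf, D)
            hit_idx = np.argpartition(Dh, k - 1, axis=1)[:, :k]
            miss_idx = np.argpartition(Dm, k - 1, axis=1)[:, :k]

            def soft_margin(idx: np.ndarray, dist: np.ndarray) -> np.ndarray:
                dsel = np.take_along_axis(dist, idx, axis=1)  # (n, k)
                g = np.exp(-0.5 * (dsel / self.sigma) ** 2)
                tot = g.sum(axis=1, keepdims=True)
                g = np.where(tot > 0, g / np.maximum(tot, 1e-300), 1.0 / k)
                diffs = np.abs(Z[:, None, :] - Z[idx])  # (n, k, nf)
                return (g[..., None] * diffs).sum(axis=1).mean(axis=0)

            hit_m = soft_margin(hit_idx, Dh)
            miss_m = soft_margin(miss_idx, Dm)
            w_new = np.clip(w + self.eta * (miss_m - hit_m), 0.0, None)
            top = w_new.max()
            w_new = w_new / top if top > 0 else np.ones(nf)
            delta = np.abs(w_new - w).sum()
            w = w_new
            if delta < self.theta:
                converged = True
                break

        self.classes_ = classes
        self.weights_ = w
        self.n_iter_ = it
        self.converged_ = converged
        self.n_features_in_ = nf
        self.selected_idx_ = (
            rank_and_truncate(w, self.top_n) if self.top_n is not None
            else np.arange(nf)
        )
        return self

    def transform(self, X):
        check_is_fitted(self, "weights_")
        X = np.asarray(X)
        if self.top_n is not None:
            return X[:, self.selected_idx_]
        return X * self.weights_


def irelief(
    table: FeatureTable,
    n_neighbors: int = 5,
    eta: float = 0.001,
    theta: float = 0.01,
    sigma: float = 2.0,
    max_iter: int = 100,
) -> WeightVector:
    """Functional wrapper: iRelief weights for a labeled feature table."""
    est = IRelief(n_neighbors, eta, theta, sigma, max_iter)
    est.fit(table.values, table.labels)
    return WeightVector(est.weights_, est.n_iter_, est.converged_)


class FCBF(BaseEstimator, TransformerMixin):
    """Fast correlation-based filter.

    Features are discretized into equal-frequency bins; relevance is the
    symmetrical uncertainty SU(f, class).  Ranked by relevance, a feature is
    kept unless some already-kept feature g is predominant over it
    (``SU(f, g) >= SU(f, class)``).
    """

    def __init__(self, su_threshold: float = 0.0, bins: int = 10) -> None:
        self.su_threshold = su_threshold
        self.bins = bins

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        codes = _discretize(X, self.bins)
        _, y_codes = np.unique(y, return_inverse=True)
        su_class = np.array(
            [symmetrical_uncertainty(codes[:, j], y_codes)
             for j in range(X.shape[1])]
        )
        order = np.argsort(-su_class, kind="stable")
        kept: list[int] = []
        for j in order:
            if su_class[j] <= self.su_threshold:
                continue
            if any(
                symmetrical_uncertainty(codes[:, j], codes[:, g]) >= su_class[j]
                for g in kept
            ):
                continue
            kept.append(int(j))
        if not kept:
            warnings.warn(
                "FCBF kept no feature at this threshold; "
                "falling back to the single most relevant feature",
                RuntimeWarning, stacklevel=2,
            )
            kept = [int(order[0])]
        self.su_class_ = su_class
        self.selected_idx_ = np.asarray(sorted(kept))
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "selected_idx_")
        return np.asarray(X)[:, self.selected_idx_]


def fcbf(table: FeatureTable, su_threshold: float = 0.0) -> list[str]:
    """Functional wrapper: names of the features FCBF keeps."""
    est = FCBF(su_threshold).fit(table.values, table.labels)
    return [table.feature_names[j] for j in est.selected_idx_]


def info_gain_ratio(table: FeatureTable, bins: int = 10) -> np.ndarray:
    """Per-feature gain ratio ``(H(class) - H(class|f)) / H(f)``.

    Features are discretized into equal-frequency bins; a feature with zero
    intrinsic information scores 0.
    """
    codes = _discretize(table.values, bins)
    _, y_codes = np.unique(table.labels, return_inverse=True)
    hy = _entropy(y_codes)
    scores = np.zeros(table.n_features)
    for j in range(table.n_features):
        hf = _entropy(codes[:, j])
        if hf == 0:
            continue
        mi = hy + hf - _entropy(_joint(codes[:, j], y_codes))
        scores[j] = mi / hf
    return scores


@dataclass
class PSOConfig:
    """Binary PSO settings (published defaults)."""

    n_particles: int = 10
    max_iters: int = 100
    c1: float = 2.0
    c2: float = 2.0
    v_max: float = 6.0
    w_max: float = 0.9
    w_min: float = 0.4

    def __post_init__(self) -> None:
        if min(self.n_particles, self.c1, self.c2, self.v_max,
               self.w_max, self.w_min) <= 0:
            raise ValueError("all PSO parameters must be positive")
        if self.w_min > self.w_max:
            raise ValueError("w_min must not exceed w_max")


class BinaryPSO(BaseEstimator, TransformerMixin):
    """Wrapper feature selection by binary particle swarm optimization.

    Each particle is a feature mask; velocities are real-valued, clamped at
    ``±v_max`` and squashed by a sigmoid into bit-flip probabilities.
    Inertia decreases linearly from ``w_max`` to ``w_min``.  Fitness of a
    mask is the mean cross-validated accuracy of ``estimator`` on the masked
    features; all-zero masks are repaired to a random single feature.

    Attributes: ``mask_`` (best mask), ``fitness_`` (its fitness),
    ``trace_`` (global-best fitness per iteration, non-decreasing).
    """

    def __init__(
        self,
        estimator=None,
        cv: int = 3,
        config: PSOConfig | None = None,
        random_state: int = 0,
    ) -> None:
        self.estimator = estimator
        self.cv = cv
        self.config = config
        self.random_state = random_state

    def _fitness(self, X, y, mask: np.ndarray) -> float:
        est = clone(self.estimator) if self.estimator is not None else None
        if est is None:
            from .classify import FWKNN

            est = FWKNN(k=5)
        cols = np.nonzero(mask)[0]
        return float(np.mean(cross_val_score(est, X[:, cols], y, cv=self.cv)))

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        if X.shape[0] < 20:
            raise ValueError("PSO wrapper selection needs >= 20 samples")
        cfg = self.config or PSOConfig()
        rng = np.random.default_rng(self.random_state)
        nf = X.shape[1]
        npart = cfg.n_particles
        pos = (rng.random((npart, nf)) < 0.5).astype(int)
        vel = rng.uniform(-cfg.v_max, cfg.v_max, (npart, nf))
        for p in range(npart):
            if not pos[p].any():
                pos[p, rng.integers(nf)] = 1
        pbest = pos.copy()
        pbest_fit = np.array([self._fitness(X, y, m) for m in pos])
        g = int(np.argmax(pbest_fit))
        gbest, gbest_fit = pbest[g].copy(), float(pbest_fit[g])
        trace = [gbest_fit]
        for it in range(cfg.max_iters):
            inertia = cfg.w_max - (cfg.w_max - cfg.w_min) * (
                it / max(cfg.max_iters - 1, 1)
            )
            r1 = rng.random((npart, nf))
            r2 = rng.random((npart, nf))
            vel = (
                inertia * vel
                + cfg.c1 * r1 * (pbest - pos)
                + cfg.c2 * r2 * (gbest[None, :] - pos)
            )
            vel = np.clip(vel, -cfg.v_max, cfg.v_max)
            prob = 1.0 / (1.0 + np.exp(-vel))
            pos = (rng.random((npart, nf)) < prob).astype(int)
            for p in range(npart):
                if not pos[p].any():
                    pos[p, rng.integers(nf)] = 1
                fit = self._fitness(X, y, pos[p])
                if fit > pbest_fit[p]:
                    pbest_fit[p] = fit
                    pbest[p] = pos[p].copy()
                    if fit > gbest_fit:
                        gbest_fit = float(fit)
                        gbest = pos[p].copy()
            trace.append(gbest_fit)
        self.mask_ = gbest.astype(bool)
        self.fitness_ = gbest_fit
        self.trace_ = np.asarray(trace)
        self.n_features_in_ = nf
        self.selected_idx_ = np.nonzero(self.mask_)[0]
        return self

    def transform(self, X):
        check_is_fitted(self, "mask_")
        return np.asarray(X)[:, self.mask_]


def pso_select(
    table: FeatureTable,
    estimator=None,
    cv: int = 3,
    config: PSOConfig | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, float, np.ndarray]:
    """Functional wrapper: (mask, fitness, trace) for a labeled table."""
    est = BinaryPSO(estimator, cv, config, seed).fit(table.values, table.labels)
    return est.mask_, est.fitness_, est.trace_


def rank_and_truncate(weights, top_n: int | None) -> np.ndarray:
    """Indices of the ``top_n`` largest weights (stable; ties by index)."""
    w = weights.weights if isinstance(weights, WeightVector) else np.asarray(weights)
    order = np.argsort(-w, kind="stable")
    if top_n is None or top_n >= len(w):
        return order
    return order[:top_n]
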