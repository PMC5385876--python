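"""Radial-basis-function network relevance between components and a factor.

A small Gaussian RBF network captures nonlinear component-effect
association that the linear stages miss.  Inputs are standardized, hidden
centers are placed by seeded k-means, each center's width is its distance
to the nearest other center divided by sqrt(2) (floored at a small
epsilon), and the output layer is solved by least squares with a bias
term.  Per-component contribution is measured by seeded permutation
importance: the mean increase in squared prediction error when one input
column is shuffled, negatives clipped to zero and the vector normalized
to sum one.  Raw hidden-to-output connection weights are not per-input
quantities, so permutation importance is the seedable stand-in for a
per-component "connection weight".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .regression import ImportanceVector, MethodRelevance

logger = logging.getLogger("spectrum_effect.rbf")

__all__ = ["RBFModel", "fit_rbf", "rbf_importance", "rbf_relevance"]

_WIDTH_EPS = 1e-8


@dataclass
class RBFModel:
    centers: np.ndarray          # h x p, in standardized input space
    widths: np.ndarray           # h, positive
    output_weights: np.ndarray   # h + 1 (bias last)
    seed: int
    train_rmse: float
    feature_ids: list[str]
    x_mean: np.ndarray
    x_sd: np.ndarray
    train_X: pd.DataFrame
    train_y: np.ndarray

    @property
    def n_hidden(self) -> int:
        return self.centers.shape[0]

    def _activations(self, Z: np.ndarray) -> np.ndarray:
        d2 = ((Z[:, None, :] - self.centers[None, :, :]) ** 2).sum(axis=2)
        return np.exp(-d2 / (2.0 * self.widths[None, :] ** 2))

    def predict(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = X[self.feature_ids].to_numpy(dtype=float)
        Z = (np.asarray(X, dtype=float) - self.x_mean) / self.x_sd
        phi = self._activations(Z)
        return phi @ self.output_weights[:-1] + self.output_weights[-1]


def fit_rbf(X: pd.DataFrame, y, n_hidden: int = 3, seed: int = 0) -> RBFModel:
    """Fit a Gaussian RBF network by k-means centers + least squares.

    With ``n_hidden`` equal to the number of (distinct) samples the
    network interpolates the training data exactly.  Identical seeds give
    identical models.
    """
    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(np.atleast_2d(np.asarray(X, dtype=float)))
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    if y.size != n:
        raise ValueError("X and y row counts differ")
    if not 1 <= n_hidden <= n:
        raise ValueError(f"n_hidden must lie in [1, n_samples={n}], got {n_hidden}")
    data = X.to_numpy(dtype=float)
    n_distinct = np.unique(data, axis=0).shape[0]
    if n_hidden > n_distinct:
        raise ValueError(
            f"n_hidden={n_hidden} exceeds the {n_distinct} distinct input rows")
    x_mean = data.mean(axis=0)
    x_sd = data.std(axis=0, ddof=0)
    x_sd = np.where(x_sd == 0, 1.0, x_sd)
    Z = (data - x_mean) / x_sd

    km = KMeans(n_clusters=n_hidden, random_state=int(seed) % (2**32), n_init=10)
    km.fit(Z)
    centers = km.cluster_centers_

    if n_hidden == 1:
        spread = np.sqrt(((Z - centers[0]) ** 2).sum(axis=1)).max()
        widths = np.array([max(spread / np.sqrt(2.0), _WIDTH_EPS)])
    else:
        d = np.sqrt(((centers[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2))
        np.fill_diagonal(d, np.inf)
        widths = np.maximum(d.min(axis=1) / np.sqrt(2.0), _WIDTH_EPS)

    d2 = ((Z[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    phi = np.exp(-d2 / (2.0 * widths[None, :] ** 2))
    A = np.hstack([phi, np.ones((n, 1))])
    weights, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ weights
    rmse = float(np.sqrt(np.mean(resid**2)))
    return RBFModel(
        centers=centers, widths=widths, output_weights=weights, seed=int(seed),
        train_rmse=rmse, feature_ids=list(X.columns), x_mean=x_mean, x_sd=x_sd,
        train_X=X.copy(), train_y=y.copy(),
    )


def rbf_importance(model: RBFModel, X: pd.DataFrame | None = None,
                   y: np.ndarray | None = None, n_permutations: int = 30,
                   seed: int = 0) -> ImportanceVector:
    """Seeded permutation importance of each input column.

    Defaults to the training data.  A flat model (zero total importance)
    yields a uniform vector with a warning.
    """
    X = model.train_X if X is None else X[model.feature_ids]
    y = model.train_y if y is None else np.asarray(y, dtype=float).ravel()
    rng = np.random.default_rng(seed)
    base_err = (y - model.predict(X)) ** 2
    base_mse = base_err.mean()
    raw = {}
    for c in model.feature_ids:
        increase = 0.0
        for _ in range(n_permutations):
            Xp = X.copy()
            Xp[c] = rng.permutation(Xp[c].to_numpy())
            mse = ((y - model.predict(Xp)) ** 2).mean()
            increase += mse - base_mse
        raw[c] = max(increase / n_permutations, 0.0)
    w = pd.Series(raw)
    total = w.sum()
    if total == 0:
        logger.warning("flat RBF model: uniform importance returned")
        w = pd.Series(1.0, index=model.feature_ids)
        total = w.sum()
    return ImportanceVector(weights=w / total, method="rbf_permutation")


def rbf_relevance(scores: pd.DataFrame, fingerprints: pd.DataFrame,
                  n_hidden: int = 3, seed: int = 0, n_permutations: int = 30,
                  ) -> tuple[MethodRelevance, dict[str, RBFModel]]:
    """Factor x component importance matrix from one RBF network per factor."""
    if list(scores.index) != list(fingerprints.index):
        raise ValueError("sample ids of factor scores and fingerprints do not match")
    rows, models = {}, {}
    for i, fid in enumerate(scores.columns):
        model = fit_rbf(fingerprints, scores[fid], n_hidden=n_hidden,
                        seed=int(seed) + i)
        imp = rbf_importance(model, n_permutations=n_permutations,
                             seed=int(seed) + 10_000 + i)
        models[fid] = model
        rows[fid] = imp.weights
    matrix = pd.DataFrame(rows).T
    matrix.index.name = "factor"
    return MethodRelevance(method="rbf", scores=matrix, signed=False), models
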