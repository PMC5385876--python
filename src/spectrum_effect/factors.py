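"""Bioactivity factor extraction from the oriented, dimensionless index panel.

The ten hemorheology/coagulation indices are strongly intercorrelated;
principal-component extraction from their correlation matrix followed by a
varimax rotation reduces them to a handful of independent "bioactivity
factors" (blood viscosity, clotting activity, RBC aggregation /
deformability, platelet aggregation), whose regression-method scores over
the formulation samples become the reference series for the relevance
stages.

Conventions follow the common statistical-package defaults: extraction by
principal components of the correlation matrix, varimax rotation with
Kaiser normalization, regression (Thompson) factor scores, and a sign flip
so each factor's largest-magnitude loading is positive (score signs are
otherwise arbitrary).  Rotated factors are reordered by explained variance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("spectrum_effect.factors")

__all__ = ["FactorModel", "fit_factors", "label_factors", "varimax"]

#: Clinical grouping of the bioassay indices, used to label factors.
INDEX_GROUPS: dict[str, str] = {
    "WBV_5": "blood viscosity",
    "WBV_50": "blood viscosity",
    "WBV_200": "blood viscosity",
    "PV": "blood viscosity",
    "EAI": "RBC aggregation",
    "RCEI": "RBC aggregation",
    "ERI": "RBC deformability",
    "PT": "extrinsic clotting activity",
    "APTT": "intrinsic clotting activity",
    "MPAR": "platelet aggregation",
}


@dataclass
class FactorModel:
    correlation_matrix: pd.DataFrame
    eigenvalues: np.ndarray              # all p, nonincreasing
    loadings: pd.DataFrame               # p x m, varimax-rotated
    rotation: np.ndarray                 # m x m orthogonal
    scores: pd.DataFrame                 # n x m, regression method
    cumulative_variance_pct: float
    labels: dict[str, str] = field(default_factory=dict)

    @property
    def n_factors(self) -> int:
        return self.loadings.shape[1]

    @property
    def factor_ids(self) -> list[str]:
        return list(self.loadings.columns)

    def communalities(self) -> pd.Series:
        return (self.loadings**2).sum(axis=1)


def varimax(loadings: np.ndarray, kaiser_normalize: bool = True,
            max_iter: int = 100, tol: float = 1e-12) -> tuple[np.ndarray, np.ndarray]:
    """Varimax rotation; returns (rotated loadings, orthogonal rotation).

    Maximises the variance of squared loadings within each factor by the
    classical pairwise planar-rotation algorithm (closed-form optimal
    angle per factor pair, swept to convergence), which also handles the
    degenerate equal-eigenvalue case where gradient fixed-point schemes
    stall.  With Kaiser normalization rows are scaled to unit communality
    during the iteration, keeping high- and low-communality variables on
    equal footing.  Row communalities are invariant under the rotation.
    """
    L = np.asarray(loadings, dtype=float).copy()
    p, m = L.shape
    if m < 2:
        return L, np.eye(m)
    comm = np.sqrt((L**2).sum(axis=1))
    if kaiser_normalize:
        safe = np.where(comm > 0, comm, 1.0)
        L = L / safe[:, None]
    R = np.eye(m)
    for _ in range(max_iter):
        total_angle = 0.0
        for j in range(m - 1):
            for l in range(j + 1, m):
                x, y = L[:, j], L[:, l]
                u = x**2 - y**2
                v = 2.0 * x * y
                A, B = u.sum(), v.sum()
                num = (2.0 * u * v).sum() - 2.0 * A * B / p
                den = (u**2 - v**2).sum() - (A**2 - B**2) / p
                phi = 0.25 * np.arctan2(num, den)
                if abs(phi) < 1e-15:
                    continue
                total_angle += abs(phi)
                c, s = np.cos(phi), np.sin(phi)
                G = np.array([[c, -s], [s, c]])
                L[:, [j, l]] = L[:, [j, l]] @ G
                R[:, [j, l]] = R[:, [j, l]] @ G
        if total_angle < tol:
            break
    if kaiser_normalize:
        L = L * np.where(comm > 0, comm, 1.0)[:, None]
    return L, R


def fit_factors(X, n_factors: int | str = 5) -> FactorModel:
    """Principal-component factor model of an n x p data matrix.

    Parameters
    ----------
    X
        DataFrame (rows = formulation samples, columns = indices) or a
        :class:`~spectrum_effect.preprocess.NormalizedMatrix`.
    n_factors
        Number of factors to retain, or ``"kaiser"`` for the
        eigenvalue-greater-than-one rule.

    The model standardizes columns internally (correlation matrix), so
    score columns have zero mean over the samples.
    """
    if isinstance(X, pd.DataFrame):
        values = X
    elif isinstance(getattr(X, "values", None), pd.DataFrame):
        values = X.values            # NormalizedMatrix carries a DataFrame
    else:
        values = pd.DataFrame(np.asarray(X, dtype=float))
    data = values.to_numpy(dtype=float)
    n, p = data.shape
    sd = data.std(axis=0, ddof=1)
    if (sd == 0).any():
        bad = values.columns[sd == 0].tolist()
        raise ValueError(f"constant columns cannot be standardized: {bad}")
    Z = (data - data.mean(axis=0)) / sd
    corr = np.corrcoef(data, rowvar=False)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    eigval = np.clip(eigval, 0.0, None)

    rank = int((eigval > 1e-10).sum())
    if n_factors == "kaiser":
        m = int((eigval > 1.0).sum())
        m = max(m, 1)
    else:
        m = int(n_factors)
    if m > rank:
        raise ValueError(
            f"n_factors={m} exceeds the rank ({rank}) of the correlation matrix"
        )
    if n < m + 1:
        raise ValueError("need at least n_factors + 1 samples")

    loadings = eigvec[:, :m] * np.sqrt(eigval[:m])
    rotated, R = varimax(loadings)

    # sign convention: largest-|loading| entry of each factor is positive
    for j in range(m):
        idx = np.argmax(np.abs(rotated[:, j]))
        if rotated[idx, j] < 0:
            rotated[:, j] *= -1
            R[:, j] *= -1

    # order rotated factors by explained variance (sum of squared loadings)
    ssq = (rotated**2).sum(axis=0)
    perm = np.argsort(ssq)[::-1]
    rotated = rotated[:, perm]
    R = R[:, perm]

    # regression (Thompson) scores: F = Z R^-1 Lambda; pinv tolerates the
    # rank deficiency that n < p implies
    scores = Z @ np.linalg.pinv(corr) @ rotated

    factor_ids = [f"F{j + 1}" for j in range(m)]
    cum_var = 100.0 * eigval[:m].sum() / p
    return FactorModel(
        correlation_matrix=pd.DataFrame(corr, index=values.columns, columns=values.columns),
        eigenvalues=eigval,
        loadings=pd.DataFrame(rotated, index=values.columns, columns=factor_ids),
        rotation=R,
        scores=pd.DataFrame(scores, index=values.index, columns=factor_ids),
        cumulative_variance_pct=float(cum_var),
    )


def label_factors(model: FactorModel, index_groups: dict[str, str] | None = None,
                  dominance: float = 0.9) -> FactorModel:
    """Attach a clinical label to each factor from its dominant loadings.

    Every index whose absolute loading is within ``dominance`` of the
    factor's maximum contributes its clinical group; distinct groups are
    joined with " & ".  An exact tie across groups is logged as a warning.
    Indices absent from the group map label as themselves.
    """
    groups = INDEX_GROUPS if index_groups is None else index_groups
    labels: dict[str, str] = {}
    for fid in model.factor_ids:
        col = model.loadings[fid].abs()
        top = col.max()
        dominant = col.index[col >= dominance * top]
        seen: list[str] = []
        for ix in dominant:
            g = groups.get(ix, str(ix))
            if g not in seen:
                seen.append(g)
        exact_ties = col.index[np.isclose(col, top, rtol=0, atol=1e-12)]
        if len({groups.get(ix, str(ix)) for ix in exact_ties}) > 1:
            logger.warning("factor %s has tied maximal loadings across groups: %s",
                           fid, list(exact_ties))
        labels[fid] = " & ".join(seen)
    model.labels = labels
    return model
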