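"""Gated stepwise regression of factor scores on component peak areas.

Each bioactivity factor is regressed on the component variables by
forward/backward stepwise selection (entry when the partial-F p-value is
at most ``entry_alpha``, removal when it rises to ``removal_alpha`` or
beyond, iterated to a fixpoint).  A model is *valid* only when its overall
F-test clears the gate (p < 0.05 by default); the signed standardized
coefficients of a valid model quantify each selected component's
contribution.  When no valid model exists the stage falls back to a
relative-importance score: the squared marginal Pearson correlation of
each component with the factor, normalized to sum one.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger("spectrum_effect.regression")

__all__ = [
    "StepwiseModel",
    "ImportanceVector",
    "MethodRelevance",
    "stepwise_fit",
    "relative_importance",
    "mlr_relevance",
]

_COND_LIMIT = 1e10


@dataclass
class StepwiseModel:
    response_id: str
    selected: list[str]
    intercept: float
    coefficients: pd.Series        # raw, aligned with selected
    std_coefficients: pd.Series    # beta weights for cross-component comparison
    overall_p: float
    r2: float
    adj_r2: float
    valid: bool


@dataclass
class ImportanceVector:
    weights: pd.Series             # nonnegative, sums to 1
    method: str = "marginal_r2"

    def __post_init__(self) -> None:
        w = self.weights.to_numpy(dtype=float)
        if (w < 0).any():
            raise ValueError("importance weights must be nonnegative")
        total = w.sum()
        if not np.isclose(total, 1.0, atol=1e-10):
            raise ValueError(f"importance weights must sum to 1, got {total}")


@dataclass
class MethodRelevance:
    """Per-factor, per-component relevance scores from one method."""

    method: str                         # gra | mlr | rbf
    scores: pd.DataFrame                # factors x components
    signed: bool
    signs: dict[str, dict[str, int]] = field(default_factory=dict)
    tags: dict[str, str] = field(default_factory=dict)   # factor -> sub-method


def _ols(y: np.ndarray, X: pd.DataFrame):
    return sm.OLS(y, sm.add_constant(X, has_constant="add")).fit()


def stepwise_fit(y, X: pd.DataFrame, entry_alpha: float = 0.05,
                 removal_alpha: float = 0.10, response_id: str = "y",
                 gate_alpha: float = 0.05, max_iter: int = 100) -> StepwiseModel:
    """Forward/backward stepwise OLS with partial-F entry and removal tests.

    The partial F for adding one term equals the squared t of its
    coefficient in the augmented model, so entry uses the candidate's
    t-test p-value.  Selection is capped at ``n - 2`` terms so the final
    fit never saturates.  A near-singular selected set (condition number
    beyond 1e10) drops the latest entrant with a warning.
    """
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if n < 4:
        raise ValueError("stepwise regression needs at least 4 observations")
    if not entry_alpha <= removal_alpha:
        raise ValueError("entry_alpha must not exceed removal_alpha")
    if X.shape[0] != n:
        raise ValueError("row count of X must match y")

    selected: list[str] = []
    banned: set[str] = set()
    max_terms = n - 2
    for _ in range(max_iter):
        changed = False
        # forward step
        if len(selected) < max_terms:
            best_p, best_c = np.inf, None
            for c in X.columns:
                if c in selected or c in banned:
                    continue
                trial = selected + [c]
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    fit = _ols(y, X[trial])
                p = fit.pvalues.get(c, np.nan)
                if np.isnan(p):
                    continue
                if p < best_p:
                    best_p, best_c = p, c
            if best_c is not None and best_p <= entry_alpha:
                cand = X[selected + [best_c]].to_numpy()
                cond = np.linalg.cond(cand - cand.mean(axis=0)) if cand.shape[1] > 1 else 1.0
                if cond > _COND_LIMIT:
                    logger.warning(
                        "dropping %s: selected set would be numerically collinear "
                        "(cond=%.2e)", best_c, cond)
                    banned.add(best_c)
                else:
                    selected.append(best_c)
                changed = True
        # backward step
        while len(selected) > 0:
            fit = _ols(y, X[selected])
            pvals = fit.pvalues.drop("const", errors="ignore")
            worst = pvals.idxmax()
            if pvals[worst] >= removal_alpha:
                selected.remove(worst)
                changed = True
            else:
                break
        if not changed:
            break

    if not selected:
        return StepwiseModel(
            response_id=response_id, selected=[], intercept=float(np.mean(y)),
            coefficients=pd.Series(dtype=float), std_coefficients=pd.Series(dtype=float),
            overall_p=float("nan"), r2=0.0, adj_r2=0.0, valid=False,
        )

    fit = _ols(y, X[selected])
    coefs = fit.params.drop("const", errors="ignore")
    sd_y = y.std(ddof=1)
    sd_x = X[selected].std(ddof=1)
    std_coefs = coefs * sd_x / sd_y if sd_y > 0 else coefs * 0.0
    overall_p = float(fit.f_pvalue)
    return StepwiseModel(
        response_id=response_id,
        selected=list(selected),
        intercept=float(fit.params.get("const", 0.0)),
        coefficients=coefs.astype(float),
        std_coefficients=std_coefs.astype(float),
        overall_p=overall_p,
        r2=float(fit.rsquared),
        adj_r2=float(fit.rsquared_adj),
        valid=bool(overall_p < gate_alpha),
    )


def relative_importance(y, X: pd.DataFrame, method: str = "marginal_r2",
                        ridge: float = 1e-3) -> ImportanceVector:
    """Nonnegative per-component importance weights summing to one.

    ``marginal_r2`` (default): squared Pearson correlation of each column
    with ``y``, normalized — simple, deterministic and monotone in the
    marginal association.  ``loo_ridge``: drop in fitted sum of squares
    when one column is removed from a ridge-stabilized full model.
    Constant columns get importance 0 (warned); if every weight is zero
    the vector falls back to uniform.
    """
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if n < 3:
        raise ValueError("relative importance needs at least 3 observations")
    if method == "marginal_r2":
        raw = {}
        sd_y = y.std()
        for c in X.columns:
            x = X[c].to_numpy(dtype=float)
            if x.std() == 0 or sd_y == 0:
                if x.std() == 0:
                    logger.warning("constant predictor %s: importance set to 0", c)
                raw[c] = 0.0
            else:
                raw[c] = float(np.corrcoef(x, y)[0, 1] ** 2)
        w = pd.Series(raw)
    elif method == "loo_ridge":
        Z = (X - X.mean()) / X.std(ddof=1).replace(0, 1.0)
        yc = y - y.mean()

        def _sse(cols):
            A = Z[cols].to_numpy()
            G = A.T @ A + ridge * np.eye(len(cols))
            beta = np.linalg.solve(G, A.T @ yc)
            return float(((yc - A @ beta) ** 2).sum())

        full = _sse(list(X.columns))
        w = pd.Series({c: max(_sse([k for k in X.columns if k != c]) - full, 0.0)
                       for c in X.columns})
    else:
        raise ValueError(f"unknown importance method {method!r}")
    total = w.sum()
    if total == 0:
        logger.warning("all importances zero: falling back to uniform weights")
        w = pd.Series(1.0, index=X.columns)
        total = w.sum()
    return ImportanceVector(weights=w / total, method=method)


def mlr_relevance(scores: pd.DataFrame, fingerprints: pd.DataFrame,
                  gate_alpha: float = 0.05, entry_alpha: float = 0.05,
                  removal_alpha: float = 0.10,
                  importance_method: str = "marginal_r2",
                  ) -> tuple[MethodRelevance, dict[str, StepwiseModel]]:
    """Per-factor regression relevance with the P<gate fallback rule.

    For each factor: if the stepwise model clears the overall-F gate, the
    signed standardized coefficients of its selected components are the
    scores (zero elsewhere); otherwise the unsigned relative-importance
    weights are used.  The per-factor tag records which path was taken so
    the consensus stage knows whether signs are available.
    """
    if list(scores.index) != list(fingerprints.index):
        raise ValueError("sample ids of factor scores and fingerprints do not match")
    rows, signs, tags, models = {}, {}, {}, {}
    for fid in scores.columns:
        model = stepwise_fit(scores[fid], fingerprints, entry_alpha=entry_alpha,
                             removal_alpha=removal_alpha, response_id=fid,
                             gate_alpha=gate_alpha)
        models[fid] = model
        if model.valid:
            row = pd.Series(0.0, index=fingerprints.columns)
            row[model.std_coefficients.index] = model.std_coefficients
            rows[fid] = row
            signs[fid] = {c: int(np.sign(v)) for c, v in model.std_coefficients.items()}
            tags[fid] = "stepwise_coefficients"
        else:
            imp = relative_importance(scores[fid], fingerprints, method=importance_method)
            rows[fid] = imp.weights
            signs[fid] = {}
            tags[fid] = f"relative_importance:{imp.method}"
    matrix = pd.DataFrame(rows).T
    matrix.index.name = "factor"
    rel = MethodRelevance(method="mlr", scores=matrix, signed=True,
                          signs=signs, tags=tags)
    return rel, models
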