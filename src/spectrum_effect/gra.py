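"""Grey relational analysis (GRA) between factor scores and peak series.

GRA ranks how closely each comparative series (the dimensionless peak
areas of one component across the formulation samples) tracks a reference
series (one bioactivity factor's scores), without distributional
assumptions.  For reference ``x0`` and comparatives ``x_i`` over points
``k = 1..n``:

* deviations              ``d_i(k)  = |x0(k) - x_i(k)|``
* extreme deviations      ``d_min, d_max`` over all i and k
* relational coefficient  ``xi_i(k) = (d_min + rho*d_max) / (d_i(k) + rho*d_max)``
* relational degree (GRD) ``GRD_i   = mean_k xi_i(k)``

``rho`` in (0, 1] is the distinguishing coefficient (default 0.5); smaller
values sharpen the contrast between series.  A higher GRD means the
component moves with the factor more tightly.  The extreme deviations are
pooled over all comparatives *within one reference series* (one factor),
not across factors; per-series pooling is available for sensitivity
checks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("spectrum_effect.gra")

__all__ = ["GreySeriesSet", "GreyResult", "grey_coefficients", "grey_degree", "gra_relevance"]


@dataclass
class GreySeriesSet:
    """A reference series plus comparative series of equal length."""

    reference: np.ndarray            # shape (n,)
    comparatives: pd.DataFrame       # rows = series ids, columns = points
    rho: float = 0.5
    reference_scaling: str = "raw"   # raw | mean_one | zscore | match

    def __post_init__(self) -> None:
        ref = np.asarray(self.reference, dtype=float).ravel()
        if not isinstance(self.comparatives, pd.DataFrame):
            comp = np.atleast_2d(np.asarray(self.comparatives, dtype=float))
            self.comparatives = pd.DataFrame(
                comp, index=[f"x{i + 1}" for i in range(comp.shape[0])]
            )
        if self.comparatives.shape[1] != ref.size:
            raise ValueError(
                f"length mismatch: reference has {ref.size} points, "
                f"comparatives have {self.comparatives.shape[1]}"
            )
        if self.comparatives.shape[0] == 0 or ref.size == 0:
            raise ValueError("empty series set")
        if not (0 < self.rho <= 1):
            raise ValueError(f"rho must lie in (0, 1], got {self.rho}")
        if self.reference_scaling not in ("raw", "mean_one", "zscore", "match"):
            raise ValueError(f"unknown reference_scaling {self.reference_scaling!r}")
        if self.reference_scaling == "mean_one":
            mean = ref.mean()
            if abs(mean) < 1e-300:
                raise ValueError("mean_one scaling undefined: reference mean is zero")
            ref = ref / mean
        elif self.reference_scaling == "zscore":
            sd = ref.std(ddof=1)
            if sd == 0:
                raise ValueError("zscore scaling undefined: constant reference")
            ref = (ref - ref.mean()) / sd
        elif self.reference_scaling == "match":
            # grey relational generation puts every series on one
            # dimensionless scale; a zero-mean score series compared with
            # mean-one comparatives would otherwise measure the offset, not
            # the shape, so the reference is affinely mapped to the
            # comparatives' grand mean and average spread
            sd = ref.std(ddof=1)
            if sd == 0:
                raise ValueError("match scaling undefined: constant reference")
            comp = self.comparatives.to_numpy(dtype=float)
            target_sd = comp.std(axis=1, ddof=1).mean()
            ref = comp.mean() + target_sd * (ref - ref.mean()) / sd
        self.reference = ref

    @property
    def n(self) -> int:
        """Number of performance characteristics (series length)."""
        return self.reference.size


@dataclass
class GreyResult:
    deviations: pd.DataFrame          # |x0 - x_i|, rows = series
    delta_min: float
    delta_max: float
    coefficients: pd.DataFrame        # xi_i(k)
    rho: float
    grd: pd.Series = field(default=None)      # filled by grey_degree
    ranking: list[str] = field(default_factory=list)


def grey_coefficients(series: GreySeriesSet) -> GreyResult:
    """Deviations, extreme deviations and grey relational coefficients.

    If every comparative coincides with the reference (``d_max = 0``) all
    coefficients are 1 by the limit convention (logged).
    """
    ref = series.reference
    comp = series.comparatives.to_numpy(dtype=float)
    dev = np.abs(comp - ref[None, :])
    d_min = float(dev.min())
    d_max = float(dev.max())
    if d_max == 0.0:
        logger.info("all comparatives identical to reference: coefficients set to 1")
        xi = np.ones_like(dev)
    else:
        xi = (d_min + series.rho * d_max) / (dev + series.rho * d_max)
    ids = series.comparatives.index
    cols = series.comparatives.columns
    return GreyResult(
        deviations=pd.DataFrame(dev, index=ids, columns=cols),
        delta_min=d_min,
        delta_max=d_max,
        coefficients=pd.DataFrame(xi, index=ids, columns=cols),
        rho=series.rho,
    )


def grey_degree(result: GreyResult) -> GreyResult:
    """Grey relational degree: mean coefficient per comparative, plus ranking.

    Ranking is by GRD descending; ties keep the comparative-id input
    order (stable sort).
    """
    grd = result.coefficients.mean(axis=1)
    order = np.argsort(-grd.to_numpy(), kind="stable")
    result.grd = grd
    result.ranking = [grd.index[i] for i in order]
    return result


def gra_relevance(scores: pd.DataFrame, fingerprints: pd.DataFrame,
                  rho: float = 0.5, reference_scaling: str = "raw"
                  ) -> tuple[pd.DataFrame, dict[str, GreyResult]]:
    """Factor x component GRD matrix.

    ``scores`` holds one column per factor over the formulation samples;
    ``fingerprints`` the dimensionless peak areas over the same samples in
    the same row order.  Extreme deviations are pooled per factor.
    Returns the GRD matrix (rows = factors) plus the per-factor
    :class:`GreyResult` details.
    """
    if list(scores.index) != list(fingerprints.index):
        raise ValueError(
            "sample ids of factor scores and fingerprints do not match: "
            f"{list(scores.index)} vs {list(fingerprints.index)}"
        )
    rows = {}
    details: dict[str, GreyResult] = {}
    for fid in scores.columns:
        series = GreySeriesSet(
            reference=scores[fid].to_numpy(dtype=float),
            comparatives=fingerprints.T,
            rho=rho,
            reference_scaling=reference_scaling,
        )
        res = grey_degree(grey_coefficients(series))
        details[fid] = res
        rows[fid] = res.grd
    matrix = pd.DataFrame(rows).T
    matrix.index.name = "factor"
    return matrix, details
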