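"""Normalisation, orientation and clustering of fingerprint/bioassay tables.

The relevance stages compare dimensionless series, so raw data pass through
a fixed chain:

* fingerprint peak areas are divided by their mean over the formulation
  samples (nondimensionalization, unit column mean over those samples);
* pharmacology indices are averaged per animal group, indices where a
  *larger* value means a *weaker* drug effect (viscosity, aggregation and
  rigidity indices) are inverted by taking the reciprocal, and the oriented
  means are nondimensionalized the same way, using only the formulation
  (S) groups as the reference for the divisor;
* fingerprints are clustered by average ("between-groups") linkage on the
  Pearson-correlation distance, with merge heights rescaled to the 0-25
  dendrogram scale familiar from SPSS output.

No missing data are tolerated anywhere: absent values raise immediately.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

logger = logging.getLogger("spectrum_effect.preprocess")

__all__ = [
    "FingerprintTable",
    "PharmacologyPanel",
    "NormalizedMatrix",
    "GroupStats",
    "ClusterResult",
    "DEFAULT_ORIENTATION",
    "INDEX_IDS",
    "group_means",
    "orient",
    "nondimensionalize",
    "cluster_fingerprints",
    "tissue_ratio",
]

#: The ten hemorheology / coagulation indices of the bioassay panel.
INDEX_IDS = (
    "WBV_5", "WBV_50", "WBV_200", "PV",
    "EAI", "RCEI", "ERI", "APTT", "PT", "MPAR",
)

#: Default orientation of each index.  "inverse" marks indices where a
#: larger value means thicker / more aggregable blood, i.e. a weaker drug
#: effect, so they are inverted by the reciprocal before comparison;
#: clotting times (APTT, PT) lengthen under an effective drug and stay
#: "direct".  Fully overridable per run.
DEFAULT_ORIENTATION: dict[str, str] = {
    "WBV_5": "inverse",
    "WBV_50": "inverse",
    "WBV_200": "inverse",
    "PV": "inverse",
    "EAI": "inverse",
    "RCEI": "inverse",
    "ERI": "inverse",
    "APTT": "direct",
    "PT": "direct",
    "MPAR": "inverse",
}

_S_GROUP_RE = re.compile(r"^S\d+$")


def s_groups(labels) -> list[str]:
    """The formulation-sample group labels (S1, S2, ...) in input order."""
    return [g for g in labels if _S_GROUP_RE.match(str(g))]


@dataclass
class FingerprintTable:
    """Samples x components peak-area matrix (strictly positive areas)."""

    areas: pd.DataFrame  # index = sample ids, columns = component ids

    def __post_init__(self) -> None:
        df = self.areas
        if df.index.has_duplicates or df.columns.has_duplicates:
            raise ValueError("sample and component ids must be unique")
        if df.isna().any().any():
            raise ValueError("fingerprint table contains missing values")
        if (df.to_numpy(dtype=float) <= 0).any():
            bad = np.argwhere(df.to_numpy(dtype=float) <= 0)[0]
            raise ValueError(
                "peak areas must be strictly positive; offending entry at "
                f"sample {df.index[bad[0]]!r}, component {df.columns[bad[1]]!r}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.areas.index)

    @property
    def component_ids(self) -> list[str]:
        return list(self.areas.columns)

    def to_csv(self, path) -> None:
        out = self.areas.copy()
        out.insert(0, "sample_id", out.index)
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "FingerprintTable":
        df = pd.read_csv(path)
        if "sample_id" not in df.columns:
            raise ValueError("fingerprints.csv must have a sample_id column")
        df = df.set_index("sample_id")
        df.index = df.index.astype(str)
        return cls(areas=df)


@dataclass
class PharmacologyPanel:
    """Per-animal index measurements with group labels and orientations."""

    values: pd.DataFrame  # columns: group_id, animal_id, one column per index
    orientation: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.values
        for col in ("group_id", "animal_id"):
            if col not in df.columns:
                raise ValueError(f"pharmacology table must have a {col} column")
        if df[self.index_ids].isna().any().any():
            raise ValueError("pharmacology table contains missing values")
        if not self.orientation:
            self.orientation = {
                ix: DEFAULT_ORIENTATION.get(ix, "direct") for ix in self.index_ids
            }
        missing = [ix for ix in self.index_ids if ix not in self.orientation]
        if missing:
            raise ValueError(f"indices without orientation: {missing}")
        bad = {ix: o for ix, o in self.orientation.items() if o not in ("direct", "inverse")}
        if bad:
            raise ValueError(f"orientation must be 'direct' or 'inverse', got {bad}")

    @property
    def index_ids(self) -> list[str]:
        return [c for c in self.values.columns if c not in ("group_id", "animal_id")]

    @property
    def group_ids(self) -> list[str]:
        return list(dict.fromkeys(self.values["group_id"].astype(str)))

    def to_csv(self, path) -> None:
        self.values.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, orientation: dict[str, str] | None = None) -> "PharmacologyPanel":
        df = pd.read_csv(path)
        df["group_id"] = df["group_id"].astype(str)
        return cls(values=df, orientation=dict(orientation or {}))


@dataclass
class GroupStats:
    """Per-(group, index) mean, SD and animal count."""

    means: pd.DataFrame
    sds: pd.DataFrame
    counts: pd.Series


@dataclass
class NormalizedMatrix:
    """Dimensionless matrix whose reference-row column means are one."""

    values: pd.DataFrame
    reference_rows: list[str]
    provenance: list[str] = field(default_factory=list)


@dataclass
class ClusterResult:
    labels: dict[str, int]
    n_classes: int
    linkage: np.ndarray
    rescaled_heights: np.ndarray
    cut: float


def group_means(panel: PharmacologyPanel) -> GroupStats:
    """Arithmetic mean (plus SD, n) of every index per animal group.

    Missing values and empty groups are hard errors: no imputation.
    """
    df = panel.values
    if df.empty:
        raise ValueError("pharmacology panel is empty")
    grouped = df.groupby("group_id", sort=False)[panel.index_ids]
    means = grouped.mean()
    sds = grouped.std(ddof=1)
    counts = grouped.size()
    if (counts == 0).any():
        raise ValueError("empty group encountered")
    return GroupStats(means=means, sds=sds, counts=counts)


def orient(means: pd.DataFrame, orientation: dict[str, str]) -> pd.DataFrame:
    """Flip inverse-oriented indices by the reciprocal; leave direct ones.

    Applying the map twice restores the original matrix.
    """
    out = means.copy().astype(float)
    for col in out.columns:
        how = orientation.get(col, "direct")
        if how == "inverse":
            vals = out[col].to_numpy()
            if (vals <= 0).any():
                raise ValueError(
                    f"index {col!r} is inverse-oriented but contains a "
                    "nonpositive value; reciprocal undefined"
                )
            out[col] = 1.0 / vals
        elif how != "direct":
            raise ValueError(f"unknown orientation {how!r} for index {col!r}")
    return out


def nondimensionalize(matrix: pd.DataFrame, reference_rows) -> NormalizedMatrix:
    """Divide each column by its mean over ``reference_rows``.

    Rows outside the reference set (control, model, positive-control
    groups) are scaled by the same divisor so the whole table stays
    comparable, but they do not influence the divisor.  Column means over
    the reference rows equal one afterwards.
    """
    reference_rows = [str(r) for r in reference_rows]
    missing = [r for r in reference_rows if r not in matrix.index]
    if missing:
        raise ValueError(f"reference rows not present: {missing}")
    divisor = matrix.loc[reference_rows].mean(axis=0)
    if (np.abs(divisor.to_numpy(dtype=float)) < 1e-300).any():
        bad = divisor.index[np.abs(divisor.to_numpy(dtype=float)) < 1e-300].tolist()
        raise ValueError(f"zero column mean over reference rows for: {bad}")
    values = matrix / divisor
    return NormalizedMatrix(
        values=values,
        reference_rows=reference_rows,
        provenance=[f"divided columns by mean over {len(reference_rows)} reference rows"],
    )


def cluster_fingerprints(fp: FingerprintTable, cut: float = 5.0) -> ClusterResult:
    """Average-linkage clustering on Pearson-correlation distance.

    Distance between two samples is ``1 - r`` where ``r`` is the Pearson
    correlation of their peak-area vectors; merge heights are rescaled so
    the final merge sits at 25 (the SPSS dendrogram convention) and classes
    are read off at the rescaled ``cut`` (default 5).
    """
    X = fp.areas.to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise ValueError("clustering needs at least two samples")
    if (X.std(axis=1) == 0).any():
        which = fp.areas.index[X.std(axis=1) == 0].tolist()
        raise ValueError(f"constant peak vector (correlation undefined) for: {which}")
    dist = pdist(X, metric="correlation")  # 1 - Pearson r
    Z = hierarchy.linkage(dist, method="average")
    max_h = Z[:, 2].max()
    if max_h <= 0:
        # all samples identical: a single class at any positive cut
        labels = {s: 1 for s in fp.sample_ids}
        return ClusterResult(labels=labels, n_classes=1, linkage=Z,
                             rescaled_heights=np.zeros(len(Z)), cut=cut)
    rescaled = Z[:, 2] * 25.0 / max_h
    raw_cut = cut * max_h / 25.0
    assign = hierarchy.fcluster(Z, t=raw_cut, criterion="distance")
    labels = {s: int(c) for s, c in zip(fp.sample_ids, assign)}
    return ClusterResult(
        labels=labels,
        n_classes=int(assign.max()),
        linkage=Z,
        rescaled_heights=rescaled,
        cut=cut,
    )


@dataclass
class TissueRatio:
    ratios: np.ndarray
    median: float
    q1: float
    q3: float


def tissue_ratio(tissue_conc, blood_conc) -> TissueRatio:
    """Tissue/blood partition ratio (amount per g over amount per mL).

    Accepts scalars or per-animal vectors; vectors are reduced to median
    and quartiles for reporting.
    """
    tissue = np.atleast_1d(np.asarray(tissue_conc, dtype=float))
    blood = np.atleast_1d(np.asarray(blood_conc, dtype=float))
    if (blood <= 0).any():
        raise ValueError("blood concentration must be strictly positive")
    ratios = tissue / blood
    q1, med, q3 = np.percentile(ratios, [25, 50, 75])
    return TissueRatio(ratios=ratios, median=float(med), q1=float(q1), q3=float(q3))
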