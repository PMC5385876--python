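"""Consensus core-bioactive-component selection across relevance methods.

Each relevance method (grey relational analysis, gated stepwise
regression, RBF-network importance) ranks the components per bioactivity
factor.  A component joins the consensus core set when

* it sits in the top-k (default 3) of at least ``min_methods`` (default 2)
  methods for at least ``min_factors`` (default 1) of the factors, and
* wherever a valid regression model selected it among those qualifying
  factors, its coefficient is nonnegative in at least one of them —
  a component whose only regression evidence is harmful (negative) is
  excluded and listed with the reason.

Scores of exactly zero carry no evidence and never occupy a top-k slot.
The chosen thresholds are recorded in the report's audit block, and the
core subset of the fingerprint table is emitted as the "bioactive
fingerprint" for quality-control monitoring.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .preprocess import FingerprintTable
from .regression import MethodRelevance

logger = logging.getLogger("spectrum_effect.consensus")

__all__ = ["CoreComponentReport", "per_factor_topk", "select_core", "bioactive_fingerprint"]


@dataclass
class CoreComponentReport:
    per_factor_topk: dict[str, dict[str, list[str]]]   # factor -> method -> ids
    core_set: list[str]                                # in component-id order
    exclusions: dict[str, str]
    herb_attribution: dict[str, str] = field(default_factory=dict)
    audit: dict = field(default_factory=dict)


def per_factor_topk(relevances: list[MethodRelevance], k: int = 3
                    ) -> dict[str, dict[str, list[str]]]:
    """Top-k component ids per (factor, method), by score magnitude.

    Signed scores rank by absolute value (a strongly negative regression
    coefficient still *ranks*; the sign rule is applied later).  Exact
    ties break to component-id input order; zero scores are omitted.
    """
    if not relevances:
        raise ValueError("no relevance matrices given")
    components = list(relevances[0].scores.columns)
    for rel in relevances:
        if list(rel.scores.columns) != components:
            raise ValueError("relevance matrices disagree on the component set")
    if k > len(components):
        raise ValueError(f"k={k} exceeds the {len(components)} components")
    table: dict[str, dict[str, list[str]]] = {}
    for rel in relevances:
        mag = rel.scores.abs() if rel.signed else rel.scores
        for fid in rel.scores.index:
            row = mag.loc[fid]
            ranked = sorted(
                (c for c in components if row[c] > 0),
                key=lambda c: (-row[c], components.index(c)),
            )[:k]
            table.setdefault(str(fid), {})[rel.method] = ranked
    return table


def select_core(relevances: list[MethodRelevance], k: int = 3,
                min_methods: int = 2, min_factors: int = 1,
                herb_attribution: dict[str, str] | None = None
                ) -> CoreComponentReport:
    """Apply the top-k / multi-method / nonnegative-sign consensus rule."""
    n_methods = len({rel.method for rel in relevances})
    if n_methods < min_methods:
        logger.info("only %d method(s) available: min_methods forced to %d",
                    n_methods, n_methods)
        min_methods = n_methods
    topk = per_factor_topk(relevances, k=k)
    components = list(relevances[0].scores.columns)
    signs: dict[str, dict[str, int]] = {}
    for rel in relevances:
        for fid, sign_map in getattr(rel, "signs", {}).items():
            signs.setdefault(str(fid), {}).update(sign_map)

    core: list[str] = []
    exclusions: dict[str, str] = {}
    for comp in components:
        qualifying = [
            fid for fid, per_method in topk.items()
            if sum(comp in ids for ids in per_method.values()) >= min_methods
        ]
        if len(qualifying) < min_factors:
            continue
        comp_signs = {fid: signs[fid][comp]
                      for fid in qualifying
                      if fid in signs and comp in signs[fid]}
        if comp_signs and all(s < 0 for s in comp_signs.values()):
            exclusions[comp] = (
                "negative regression coefficient in every qualifying factor: "
                + ", ".join(sorted(comp_signs))
            )
            continue
        core.append(comp)

    if not core:
        logger.warning("consensus core set is empty under the current thresholds")
    attribution = {c: (herb_attribution or {}).get(c, "unassigned") for c in core}
    return CoreComponentReport(
        per_factor_topk=topk,
        core_set=core,
        exclusions=exclusions,
        herb_attribution=attribution,
        audit={
            "k": k,
            "min_methods": min_methods,
            "min_factors": min_factors,
            "methods": sorted({rel.method for rel in relevances}),
            "rule": "top-k of >=min_methods methods for >=min_factors factors, "
                    "nonnegative regression sign in at least one qualifying factor",
        },
    )


def bioactive_fingerprint(core: CoreComponentReport, fp: FingerprintTable
                          ) -> FingerprintTable:
    """The core-component subset of the peak table, for QC monitoring."""
    missing = [c for c in core.core_set if c not in fp.component_ids]
    if missing:
        raise ValueError(f"core components missing from fingerprint table: {missing}")
    cols = [c for c in fp.component_ids if c in core.core_set]
    return FingerprintTable(areas=fp.areas[cols].copy())
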