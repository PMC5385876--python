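"""End-to-end orchestration: data -> preprocessing -> factors -> relevance -> core set.

A single :class:`RunConfig` (built in code or loaded from YAML/JSON)
drives the fixed stage order

    load-or-simulate -> nondimensionalize fingerprints -> cluster
    -> group means -> orient -> nondimensionalize panel
    -> factor model -> GRA + stepwise MLR + RBF relevance -> consensus

persisting every intermediate artifact as CSV/JSON so a run is diffable
and re-runnable bit-identically from its own summary.  All randomness is
explicitly seeded; wall-clock seeding is never used.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import consensus as consensus_mod
from . import factors as factors_mod
from .gra import gra_relevance
from .preprocess import (FingerprintTable, PharmacologyPanel, cluster_fingerprints,
                         group_means, nondimensionalize, orient, s_groups)
from .rbf import rbf_relevance
from .regression import MethodRelevance, mlr_relevance
from .synthetic import SimulationConfig, simulate_study

logger = logging.getLogger("spectrum_effect.pipeline")

__all__ = ["RunConfig", "RunSummary", "ValidationIssue", "validate_inputs", "run_all"]


@dataclass
class RunConfig:
    """Everything one pipeline run needs, with explicit seeds throughout."""

    fingerprints: str | None = None        # path to fingerprints.csv
    pharmacology: str | None = None        # path to pharmacology.csv
    simulation: dict | SimulationConfig | None = None  # simulate instead of files
    orientation: dict[str, str] = field(default_factory=dict)  # overrides
    rho: float = 0.5
    reference_scaling: str = "match"
    n_factors: int | str = "kaiser"        # integer, or eigenvalue>1 rule
    entry_alpha: float = 0.05
    removal_alpha: float = 0.10
    gate_alpha: float = 0.05
    importance_method: str = "marginal_r2"
    rbf_hidden: int = 3
    rbf_permutations: int = 30
    seed: int = 0
    cluster_cut: float = 5.0
    top_k: int = 3
    min_methods: int = 2
    min_factors: int = 1
    herb_attribution: dict[str, str] = field(default_factory=dict)
    out_dir: str | None = None

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls(**data)

    def to_dict(self) -> dict:
        return _jsonable(asdict(self))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, SimulationConfig):
        return _jsonable(asdict(obj))
    return obj


@dataclass
class ValidationIssue:
    stage: str
    message: str


@dataclass
class RunSummary:
    config: dict
    n_factors_used: int
    factor_labels: dict[str, str]
    cumulative_variance_pct: float
    cluster_classes: dict[str, int]
    mlr_tags: dict[str, str]
    core_set: list[str]
    exclusions: dict[str, str]
    warnings_per_stage: dict[str, int]
    artifacts: list[str]
    elapsed_s: float

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))


class _StageWarningCounter(logging.Handler):
    def __init__(self) -> None:
        super().__init__(level=logging.WARNING)
        self.counts: dict[str, int] = {}

    def emit(self, record: logging.LogRecord) -> None:
        stage = record.name.rsplit(".", 1)[-1]
        self.counts[stage] = self.counts.get(stage, 0) + 1


def _load_inputs(config: RunConfig) -> tuple[FingerprintTable, PharmacologyPanel]:
    if config.simulation is not None:
        if isinstance(config.simulation, SimulationConfig):
            sim = config.simulation
        else:
            sim = SimulationConfig(**{**config.simulation,
                                      "seed": config.simulation.get("seed", config.seed)})
        study = simulate_study(sim)
        return study.fingerprints, study.pharmacology
    if config.fingerprints is None or config.pharmacology is None:
        raise ValueError("config needs either input file paths or a simulation block")
    fp = FingerprintTable.from_csv(config.fingerprints)
    panel = PharmacologyPanel.from_csv(config.pharmacology, orientation=config.orientation or None)
    return fp, panel


def validate_inputs(config: RunConfig) -> list[ValidationIssue]:
    """Schema/consistency checks; reports issues instead of raising."""
    issues: list[ValidationIssue] = []
    if config.simulation is None:
        for name in ("fingerprints", "pharmacology"):
            path = getattr(config, name)
            if path is None:
                issues.append(ValidationIssue("inputs", f"no {name} path and no simulation block"))
            elif not Path(path).exists():
                issues.append(ValidationIssue("inputs", f"{name} file not found: {path}"))
        if issues:
            return issues
        try:
            raw = pd.read_csv(config.fingerprints)
            if "sample_id" not in raw.columns:
                issues.append(ValidationIssue("fingerprints", "missing sample_id column"))
            else:
                areas = raw.set_index("sample_id")
                bad = np.argwhere(areas.to_numpy(dtype=float) <= 0)
                for r, c in bad:
                    issues.append(ValidationIssue(
                        "fingerprints",
                        f"nonpositive area at sample {areas.index[r]!r}, "
                        f"component {areas.columns[c]!r}"))
        except Exception as exc:  # malformed file is an issue, not a crash
            issues.append(ValidationIssue("fingerprints", f"unreadable: {exc}"))
        try:
            panel = PharmacologyPanel.from_csv(
                config.pharmacology, orientation=config.orientation or None)
            if not s_groups(panel.group_ids):
                issues.append(ValidationIssue("pharmacology", "no S-sample groups present"))
            missing = [ix for ix in panel.index_ids
                       if ix not in config.orientation and ix not in panel.orientation]
            for ix in missing:
                issues.append(ValidationIssue("pharmacology", f"index without orientation: {ix}"))
        except Exception as exc:
            issues.append(ValidationIssue("pharmacology", f"invalid: {exc}"))
    elif not isinstance(config.simulation, SimulationConfig):
        try:
            SimulationConfig(**config.simulation)
        except Exception as exc:
            issues.append(ValidationIssue("simulation", f"invalid simulation block: {exc}"))
    if not (0 < config.rho <= 1):
        issues.append(ValidationIssue("gra", f"rho must lie in (0,1], got {config.rho}"))
    return issues


def run_all(config: RunConfig) -> RunSummary:
    """Execute every stage in order and persist all artifacts."""
    t0 = time.perf_counter()
    counter = _StageWarningCounter()
    root = logging.getLogger("spectrum_effect")
    root.addHandler(counter)
    out = Path(config.out_dir) if config.out_dir else None
    artifacts: list[str] = []

    def _save_df(df: pd.DataFrame, name: str, index_label: str) -> None:
        if out is None:
            return
        out.mkdir(parents=True, exist_ok=True)
        df.to_csv(out / name, index_label=index_label)
        artifacts.append(name)

    def _save_json(payload, name: str) -> None:
        if out is None:
            return
        out.mkdir(parents=True, exist_ok=True)
        (out / name).write_text(json.dumps(payload, indent=2, sort_keys=True))
        artifacts.append(name)

    try:
        fp, panel = _stage("inputs", _load_inputs, config)
        if config.orientation:
            panel.orientation.update(config.orientation)

        # -- preprocessing ------------------------------------------------
        fp_norm = _stage("preprocess", nondimensionalize, fp.areas, fp.sample_ids)
        _save_df(fp_norm.values, "normalized_fingerprints.csv", "sample_id")
        clusters = _stage("preprocess", cluster_fingerprints, fp, config.cluster_cut)
        _save_json({"labels": clusters.labels, "n_classes": clusters.n_classes,
                    "cut": clusters.cut}, "clusters.json")

        stats = _stage("preprocess", group_means, panel)
        oriented = _stage("preprocess", orient, stats.means, panel.orientation)
        ref_groups = s_groups(oriented.index)
        if not ref_groups:
            raise ValueError("pharmacology panel has no S-sample groups")
        panel_norm = _stage("preprocess", nondimensionalize, oriented, ref_groups)
        _save_df(panel_norm.values, "oriented_means.csv", "group_id")

        # -- factor stage -------------------------------------------------
        sample_matrix = panel_norm.values.loc[ref_groups]
        model = _stage("factors", factors_mod.fit_factors, sample_matrix, config.n_factors)
        model = factors_mod.label_factors(model)
        _save_json({
            "eigenvalues": model.eigenvalues.tolist(),
            "cumulative_variance_pct": model.cumulative_variance_pct,
            "loadings": {f: model.loadings[f].round(6).to_dict() for f in model.factor_ids},
            "labels": model.labels,
        }, "factors.json")
        _save_df(model.scores.round(6), "factor_scores.csv", "group_id")

        # reference series live on the S samples; fingerprints share order
        scores = model.scores.copy()
        scores.index = [g for g in ref_groups]
        fp_for_rel = fp_norm.values.loc[scores.index]

        # -- relevance methods --------------------------------------------
        grd, _details = _stage("gra", gra_relevance, scores, fp_for_rel,
                               config.rho, config.reference_scaling)
        _save_df(grd.round(6), "gra.csv", "factor")
        gra_rel = MethodRelevance(method="gra", scores=grd, signed=False)
        _save_json({f: list(res) for f, res in
                    ((fid, grd.loc[fid].sort_values(ascending=False).index) for fid in grd.index)},
                   "gra_ranks.json")

        mlr_rel, models = _stage("mlr", mlr_relevance, scores, fp_for_rel,
                                 config.gate_alpha, config.entry_alpha,
                                 config.removal_alpha, config.importance_method)
        _save_json({
            fid: {
                "selected": m.selected,
                "intercept": m.intercept,
                "coefficients": m.coefficients.round(8).to_dict(),
                "std_coefficients": m.std_coefficients.round(8).to_dict(),
                "overall_p": None if np.isnan(m.overall_p) else m.overall_p,
                "r2": m.r2,
                "adj_r2": m.adj_r2,
                "valid": m.valid,
                "tag": mlr_rel.tags[fid],
            } for fid, m in models.items()
        }, "mlr.json")

        rbf_rel, rbf_models = _stage("rbf", rbf_relevance, scores, fp_for_rel,
                                     config.rbf_hidden, config.seed,
                                     config.rbf_permutations)
        _save_json({
            fid: {
                "n_hidden": m.n_hidden,
                "seed": m.seed,
                "train_rmse": m.train_rmse,
                "importance": rbf_rel.scores.loc[fid].round(8).to_dict(),
            } for fid, m in rbf_models.items()
        }, "rbf.json")

        # -- consensus ----------------------------------------------------
        report = _stage("consensus", consensus_mod.select_core,
                        [gra_rel, mlr_rel, rbf_rel], config.top_k,
                        config.min_methods, config.min_factors,
                        config.herb_attribution or None)
        _save_json({
            "core_set": report.core_set,
            "exclusions": report.exclusions,
            "per_factor_topk": report.per_factor_topk,
            "herb_attribution": report.herb_attribution,
            "audit": report.audit,
        }, "core_report.json")
        designated = consensus_mod.bioactive_fingerprint(report, fp)
        if out is not None:
            designated.to_csv(out / "bioactive_fingerprint.csv")
            artifacts.append("bioactive_fingerprint.csv")

        summary = RunSummary(
            config=config.to_dict(),
            n_factors_used=model.n_factors,
            factor_labels=model.labels,
            cumulative_variance_pct=model.cumulative_variance_pct,
            cluster_classes=clusters.labels,
            mlr_tags=mlr_rel.tags,
            core_set=report.core_set,
            exclusions=report.exclusions,
            warnings_per_stage=dict(counter.counts),
            artifacts=artifacts,
            elapsed_s=round(time.perf_counter() - t0, 3),
        )
        if out is not None:
            summary.to_json(out / "run_summary.json")
        return summary
    finally:
        root.removeHandler(counter)


def _stage(name: str, fn, *args):
    logger.info("stage=%s start", name)
    try:
        return fn(*args)
    except Exception as exc:
        raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
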