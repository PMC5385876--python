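"""Synthetic spectrum-effect studies with planted component-effect structure.

The generator emulates the structure of a two-herb, nine-sample
formulation study: herb doses follow a uniform design, each fingerprint
peak is a nonnegative mixture of the herb doses with multiplicative
lognormal instrument noise (peak areas are positive and their error is
scale-proportional), and each bioassay index is a sparse signed linear
function of the peak areas plus additive Gaussian animal-level noise.

Effects are planted on the *latent drug-effect scale*: for an index whose
orientation is "inverse" (higher observed value = weaker effect) the
observed measurement is the reciprocal of the latent value, so the
analysis pipeline's reciprocal-orientation step recovers the planted
linear structure.  Control and model groups are emitted with configured
latent offsets and no component effects, giving the panel the same shape
as a real multi-group experiment.

Ground truth (which components are active, where, and with what sign)
travels with the study so recovery tests never re-derive it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .design import DesignTable, search_design
from .preprocess import DEFAULT_ORIENTATION, INDEX_IDS, FingerprintTable, PharmacologyPanel

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SyntheticStudy",
    "RECOVERY_ACTIVES",
    "default_attribution",
    "default_effect_matrix",
    "recovery_benchmark",
    "null_benchmark",
    "simulate_fingerprints",
    "simulate_pharmacology",
    "simulate_study",
]


def default_attribution(n_components: int = 13, n_herbs: int = 2,
                        active_components: list[int] | None = None) -> np.ndarray:
    """Assign each component to one source herb with unit area-per-dose.

    When the planted active set is known, the actives are attributed to
    the first herb (the bioactivity-carrying herb) and the inert
    components are spread round-robin over the remaining herbs — the
    typical two-herb situation where one ingredient herb contributes the
    pharmacologically dominant constituents.  Without an active set,
    components alternate over herbs.
    """
    attribution = np.zeros((n_components, n_herbs))
    if active_components is None:
        for k in range(n_components):
            attribution[k, k % n_herbs] = 1.0
        return attribution
    active = set(active_components)
    other = 0
    for k in range(n_components):
        if k in active:
            attribution[k, 0] = 1.0
        else:
            attribution[k, 1 + other % (n_herbs - 1)] = 1.0
            other += 1
    return attribution


def default_effect_matrix(n_indices: int = 10, n_components: int = 13,
                          n_active: int = 4) -> np.ndarray:
    """Sparse positive effect matrix with a planted block-factor structure.

    ``n_active`` components (spread over the component axis) are active;
    the indices are partitioned into ``n_active`` contiguous blocks (as
    equal as possible) and every index in block ``b`` is driven by active
    ``b`` alone, with weights cycling through (2.0, 1.5, 1.2) inside the
    block.  Disjoint blocks give the bioassay panel a clean factor
    structure of dimension ``n_active``, one factor per active.  With
    unit-dose peak columns whose across-sample SD is about 2.6, the
    weakest weight contributes more than three animal-noise SDs at the
    default noise level.
    """
    if n_active < 1 or n_active > n_components:
        raise ValueError("n_active must lie in [1, n_components]")
    if n_active > n_indices:
        raise ValueError("n_active cannot exceed n_indices")
    step = max(n_components // n_active, 1)
    actives = [min(1 + i * step, n_components - 1) for i in range(n_active)]
    weights = (2.0, 1.5, 1.2)
    base, extra = divmod(n_indices, n_active)
    B = np.zeros((n_indices, n_components))
    j = 0
    for b, k in enumerate(actives):
        size = base + (1 if b < extra else 0)
        for i in range(size):
            B[j, k] = weights[i % len(weights)]
            j += 1
    return B


def _index_ids(n_indices: int) -> list[str]:
    if n_indices == len(INDEX_IDS):
        return list(INDEX_IDS)
    return [f"I{j + 1}" for j in range(n_indices)]


def _orientation_for(index_ids: list[str]) -> dict[str, str]:
    return {ix: DEFAULT_ORIENTATION.get(ix, "direct") for ix in index_ids}


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic spectrum-effect experiment.

    Defaults mirror the nine-sample / thirteen-component / ten-index
    layout with four planted active components whose per-index effect
    exceeds three animal-noise SDs.  Fingerprint noise is lognormal with
    sigma 0.2: each formulation variant is a separately prepared
    decoction, so per-component variability reflects extraction and
    preparation chemistry (tens of percent), not just instrument
    repeatability.  This per-component variability is what makes
    individual components statistically identifiable at all: with pure
    dose mixing and instrument-level noise only, every peak from the same
    herb would carry an identical profile across samples and no relevance
    method could separate an active component from an inert herb-mate.
    """

    n_samples: int = 9
    n_herbs: int = 2
    n_components: int = 13
    n_indices: int = 10
    attribution: np.ndarray | None = None        # n_components x n_herbs
    effect_matrix: np.ndarray | None = None      # n_indices x n_components
    baseline: np.ndarray | float = 50.0
    fingerprint_noise_sd: float = 0.2
    index_noise_sd: float = 1.0
    animals_per_group: int = 10
    control_offset: float = 15.0
    model_offset: float = -15.0
    dose_offset: float = 0.0                     # level -> dose affine map
    dose_scale: float = 1.0
    orientation: dict[str, str] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_samples", "n_herbs", "n_components", "n_indices"):
            if getattr(self, name) < 2:
                raise ValueError(f"{name} must be at least 2")
        if self.animals_per_group < 1:
            raise ValueError("animals_per_group must be positive")
        if self.effect_matrix is not None:
            self.effect_matrix = np.asarray(self.effect_matrix, dtype=float)
            if self.effect_matrix.shape != (self.n_indices, self.n_components):
                raise ValueError(
                    f"effect_matrix must be {self.n_indices} x {self.n_components}, "
                    f"got {self.effect_matrix.shape}")
        if self.attribution is None:
            B = (self.effect_matrix if self.effect_matrix is not None
                 else default_effect_matrix(self.n_indices, self.n_components))
            active_idx = [k for k in range(self.n_components) if B[:, k].any()]
            self.attribution = default_attribution(
                self.n_components, self.n_herbs, active_idx or None)
        self.attribution = np.asarray(self.attribution, dtype=float)
        if self.attribution.shape != (self.n_components, self.n_herbs):
            raise ValueError(
                f"attribution must be {self.n_components} x {self.n_herbs}, "
                f"got {self.attribution.shape}")
        if (self.attribution < 0).any():
            raise ValueError("attribution coefficients must be nonnegative")
        if (self.attribution.sum(axis=1) == 0).any():
            raise ValueError("every component needs a nonzero attribution entry")
        if self.effect_matrix is None:
            self.effect_matrix = default_effect_matrix(self.n_indices, self.n_components)
        self.effect_matrix = np.asarray(self.effect_matrix, dtype=float)
        if self.effect_matrix.shape != (self.n_indices, self.n_components):
            raise ValueError(
                f"effect_matrix must be {self.n_indices} x {self.n_components}, "
                f"got {self.effect_matrix.shape}")
        self.baseline = np.broadcast_to(
            np.asarray(self.baseline, dtype=float), (self.n_indices,)).copy()
        if self.fingerprint_noise_sd < 0 or self.index_noise_sd < 0:
            raise ValueError("noise SDs must be nonnegative")
        if self.orientation is None:
            self.orientation = _orientation_for(_index_ids(self.n_indices))

    @property
    def index_ids(self) -> list[str]:
        return _index_ids(self.n_indices)

    @property
    def component_ids(self) -> list[str]:
        return [f"P{k + 1}" for k in range(self.n_components)]

    @property
    def sample_ids(self) -> list[str]:
        return [f"S{i + 1}" for i in range(self.n_samples)]

    def doses(self, design: DesignTable) -> np.ndarray:
        doses = self.dose_offset + self.dose_scale * design.levels.astype(float)
        if (doses <= 0).any():
            raise ValueError("level-to-dose map produced a nonpositive dose")
        return doses


@dataclass
class GroundTruth:
    active_components: list[str]
    per_index_actives: dict[str, dict[str, int]]   # index -> component -> sign
    effect_matrix: pd.DataFrame

    def __post_init__(self) -> None:
        union = sorted({c for m in self.per_index_actives.values() for c in m},
                       key=lambda c: int(c[1:]))
        if union != sorted(self.active_components, key=lambda c: int(c[1:])):
            raise ValueError("active_components must equal the union of per-index actives")

    def to_json(self, path) -> None:
        payload = {
            "active_components": self.active_components,
            "per_index_actives": self.per_index_actives,
            "effect_matrix": {
                "index_ids": list(self.effect_matrix.index),
                "component_ids": list(self.effect_matrix.columns),
                "values": self.effect_matrix.to_numpy().tolist(),
            },
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_config(cls, config: SimulationConfig) -> "GroundTruth":
        B = pd.DataFrame(config.effect_matrix, index=config.index_ids,
                         columns=config.component_ids)
        per_index = {
            ix: {c: int(np.sign(B.loc[ix, c])) for c in B.columns if B.loc[ix, c] != 0}
            for ix in B.index
        }
        per_index = {ix: m for ix, m in per_index.items() if m}
        active = [c for c in B.columns if (B[c] != 0).any()]
        return cls(active_components=active, per_index_actives=per_index,
                   effect_matrix=B)


@dataclass
class SyntheticStudy:
    design: DesignTable
    fingerprints: FingerprintTable
    pharmacology: PharmacologyPanel
    truth: GroundTruth
    seed: int

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.design.to_csv(out / "design.csv")
        self.fingerprints.to_csv(out / "fingerprints.csv")
        self.pharmacology.to_csv(out / "pharmacology.csv")
        self.truth.to_json(out / "truth.json")


#: Component ids planted as active by :func:`recovery_benchmark`.
RECOVERY_ACTIVES = ("P2", "P5", "P8", "P11")


def recovery_benchmark(seed: int) -> SimulationConfig:
    """The canonical parameter-recovery study: 4 actives, 9 inerts.

    Three source herbs: two bioactivity-carrying herbs contribute two
    active constituents each (P2, P5 from herb 1; P8, P11 from herb 2)
    and a third herb contributes the nine inert peaks, so inert
    components do not share a dose direction with any active.  The ten
    indices split into two five-index blocks, one per bioactive herb;
    within a block the herb's own pair carries weights 2.4 and 1.2
    (dominance alternating) and the opposite herb's pair contributes 1.4
    (alternating member), so every factor sees at least three active
    components well above any inert.  All planted weights put the
    per-index effect above three animal-noise SDs (weakest: 1.2 on peak
    columns of across-sample SD about 2.6 against noise SD 0.5).

    Fingerprint noise sigma 0.1 reflects between-preparation variability
    of separately decocted variants; animal noise SD 0.5 on a baseline of
    50 is a few-percent within-group CV.
    """
    actives = [1, 4, 7, 10]
    n_components, n_indices = 13, 10
    attribution = np.zeros((n_components, 3))
    attribution[1, 0] = attribution[4, 0] = 1.0
    attribution[7, 1] = attribution[10, 1] = 1.0
    for k in range(n_components):
        if k not in actives:
            attribution[k, 2] = 1.0
    B = np.zeros((n_indices, n_components))
    for j in range(n_indices):
        herb = 0 if j < n_indices // 2 else 1
        own = [1, 4] if herb == 0 else [7, 10]
        other = [7, 10] if herb == 0 else [1, 4]
        dom = j % 2
        B[j, own[dom]] = 2.4
        B[j, own[1 - dom]] = 1.2
        B[j, other[j % 2]] = 1.4
    return SimulationConfig(
        n_herbs=3, attribution=attribution, effect_matrix=B,
        fingerprint_noise_sd=0.1, index_noise_sd=0.5, seed=int(seed))


def null_benchmark(seed: int) -> SimulationConfig:
    """The null-calibration study: zero effect matrix.

    Chemistry is deterministic (no fingerprint noise): the thirteen peaks
    are exact two-herb dose mixtures, as in a single-batch fingerprint
    measurement, and the only randomness is animal-level bioassay noise.
    This isolates the type-I behaviour of the stepwise gate under the
    design's intrinsic peak collinearity.
    """
    return SimulationConfig(
        effect_matrix=np.zeros((10, 13)), fingerprint_noise_sd=0.0,
        seed=int(seed))


def simulate_fingerprints(design: DesignTable, config: SimulationConfig
                          ) -> FingerprintTable:
    """Peak areas: herb-dose mixtures with multiplicative lognormal noise.

    ``peak_k(i) = sum_h c_kh * dose_h(i) * exp(eps)``, eps ~ N(0, sigma).
    """
    if design.n_factors != config.n_herbs:
        raise ValueError(
            f"design has {design.n_factors} factors but config expects "
            f"{config.n_herbs} herbs")
    if design.n_runs != config.n_samples:
        raise ValueError("design run count differs from n_samples")
    doses = config.doses(design)                     # n x h
    base = doses @ config.attribution.T              # n x k
    rng = np.random.default_rng([int(config.seed), 1])
    noise = rng.normal(0.0, config.fingerprint_noise_sd, size=base.shape)
    areas = base * np.exp(noise)
    return FingerprintTable(areas=pd.DataFrame(
        areas, index=config.sample_ids, columns=config.component_ids))


def simulate_pharmacology(fingerprints: FingerprintTable, config: SimulationConfig
                          ) -> PharmacologyPanel:
    """Per-animal index values with planted linear effects on the latent scale.

    Latent value for an animal of S-group i, index j:
    ``mu_j + sum_k B_jk * peak_k(i) + N(0, sigma)``; control and model
    groups use ``mu_j + offset`` with no component effects.  Indices with
    "inverse" orientation are observed as the reciprocal of the latent
    value, which must stay positive.
    """
    peaks = fingerprints.areas
    if list(peaks.columns) != config.component_ids:
        raise ValueError("fingerprint components do not match effect_matrix columns")
    rng = np.random.default_rng([int(config.seed), 2])
    latent_means = {
        "control": config.baseline + config.control_offset,
        "model": config.baseline + config.model_offset,
    }
    for sid in peaks.index:
        latent_means[str(sid)] = (
            config.baseline + config.effect_matrix @ peaks.loc[sid].to_numpy())
    records = []
    for gid, mu in latent_means.items():
        noise = rng.normal(0.0, config.index_noise_sd,
                           size=(config.animals_per_group, config.n_indices))
        latent = mu[None, :] + noise
        if (latent <= 0).any():
            raise ValueError(
                f"latent index value nonpositive in group {gid}: raise the "
                "baseline or shrink effects/noise")
        observed = latent.copy()
        for j, ix in enumerate(config.index_ids):
            if config.orientation.get(ix, "direct") == "inverse":
                observed[:, j] = 1.0 / latent[:, j]
        for a in range(config.animals_per_group):
            records.append({"group_id": gid, "animal_id": f"{gid}_a{a + 1}",
                            **dict(zip(config.index_ids, observed[a]))})
    return PharmacologyPanel(values=pd.DataFrame(records),
                             orientation=dict(config.orientation))


def simulate_study(config: SimulationConfig, out_dir=None) -> SyntheticStudy:
    """Bundle design, fingerprints, pharmacology and ground truth.

    The design table comes from the deterministic uniform-design search,
    so two seeds share the design and differ only in noise realisations.
    Writes the fixture bundle to ``out_dir`` when given.
    """
    design = search_design(config.n_samples, config.n_herbs)
    fingerprints = simulate_fingerprints(design, config)
    pharmacology = simulate_pharmacology(fingerprints, config)
    truth = GroundTruth.from_config(config)
    study = SyntheticStudy(design=design, fingerprints=fingerprints,
                           pharmacology=pharmacology, truth=truth,
                           seed=int(config.seed))
    if out_dir is not None:
        study.write(out_dir)
    return study
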