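"""Seeded synthetic multi-modal cohort generator.

The generator emulates the structure of a TCGA-style breast-cancer cohort:
six modality views (clinical, GISTIC-thresholded copy number, methylation
beta values, miRNA expression, mRNA expression, WSI patch-embedding bags)
of one shared low-dimensional patient state ``u``, plus a survival table
from which the 5-year short/long-term label is derived.

The class signal is planted in ``u``: conditional on the label, ``u`` is
Gaussian with mean ``+delta/2`` (short-term) or ``-delta/2`` (long-term) on
every coordinate and unit variance.  Each modality observes ``W @ u`` through
its own random linear map plus independent noise, then squashes the values
into its native domain.  Because every view reads the same ``u``, the views
are complementary: fusing them reduces noise, which is exactly the property
the downstream ablation is meant to detect.

All randomness flows from ``SimConfig.seed`` through fixed per-stage spawn
keys (see ``_STAGE``), so each stage is independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import (
    MODALITIES,
    ConfigError,
    ModalityMatrix,
    MultiModalDataset,
    SurvivalTable,
    ValidationError,
)
from .wsi import PatchBag

#: fixed spawn-key offsets: seed -> SeedSequence(seed, spawn_key=(offset,))
_STAGE = {
    "labels": 0,
    "latents": 1,
    "survival": 2,
    "cln": 10,
    "cnv": 11,
    "dna": 12,
    "mir": 13,
    "mrna": 14,
    "wsi": 15,
    "missing": 30,
    "absence": 31,
}

#: scaled-down per-modality feature counts (tabular modalities)
DEFAULT_FEATURES = {"cln": 21, "cnv": 600, "dna": 600, "mir": 200, "mrna": 600}

CUTOFF_MONTHS = 60.0


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Child generator for one pipeline stage, derived from the global seed."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STAGE[stage],)))


@dataclass
class SimConfig:
    """Study conditions for one synthetic cohort.

    ``effect_size`` (delta) is the class-mean separation per coordinate of the
    shared latent ``u``; ``noise_sd`` is the per-modality observation noise on
    the linear view of ``u`` (scalar applies to all modalities).
    """

    n_patients: int = 600
    prevalence: float = 0.77  # fraction of short-term (label 1) patients
    latent_dim_true: int = 8
    effect_size: float = 3.0
    n_features: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_FEATURES))
    wsi_patches: int = 8
    wsi_dim: int = 64
    noise_sd: float | dict[str, float] = 1.0
    feature_missing_rate: float = 0.02
    modality_absence_rate: dict[str, float] = field(
        default_factory=lambda: {m: 0.05 for m in MODALITIES if m != "cln"}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.prevalence < 1.0:
            raise ConfigError(f"prevalence must be in (0,1), got {self.prevalence}")
        for name in ("n_patients", "latent_dim_true", "wsi_patches", "wsi_dim"):
            if int(getattr(self, name)) < 1:
                raise ConfigError(f"{name} must be >= 1, got {getattr(self, name)}")
        if self.effect_size < 0:
            raise ConfigError(f"effect_size must be non-negative, got {self.effect_size}")
        for tag, p in self.n_features.items():
            if tag not in MODALITIES:
                raise ConfigError(f"n_features: unknown modality {tag!r}")
            if p < 1:
                raise ConfigError(f"n_features[{tag}] must be >= 1, got {p}")
        for tag in self.n_features:
            if self.sd(tag) <= 0:
                raise ConfigError(f"noise_sd[{tag}] must be positive")
        if not 0.0 <= self.feature_missing_rate < 1.0:
            raise ConfigError(f"feature_missing_rate must be in [0,1), got {self.feature_missing_rate}")
        for tag, r in self.modality_absence_rate.items():
            if tag not in MODALITIES:
                raise ConfigError(f"modality_absence_rate: unknown modality {tag!r}")
            if not 0.0 <= r < 1.0:
                raise ConfigError(f"modality_absence_rate[{tag}] must be in [0,1), got {r}")

    def sd(self, tag: str) -> float:
        if isinstance(self.noise_sd, dict):
            return float(self.noise_sd.get(tag, 1.0))
        return float(self.noise_sd)


def simulate_latents(config: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    """Draw labels ~ Bernoulli(prevalence) and the shared latent matrix u.

    u | label ~ N(sign * delta/2 * 1, I) with sign +1 for short-term patients.
    """
    n, L = config.n_patients, config.latent_dim_true
    labels = (stage_rng(config.seed, "labels").random(n) < config.prevalence).astype(int)
    u = stage_rng(config.seed, "latents").standard_normal((n, L))
    u += (2 * labels - 1)[:, None] * (config.effect_size / 2.0)
    return labels, u


def _patient_ids(n: int) -> np.ndarray:
    width = max(4, len(str(n)))
    return np.array([f"P{i:0{width}d}" for i in range(n)], dtype=object)


def _linear_view(u: np.ndarray, p: int, sd: float, rng: np.random.Generator) -> np.ndarray:
    """W @ u + noise with unit-norm random rows of W."""
    W = rng.standard_normal((p, u.shape[1]))
    W /= np.linalg.norm(W, axis=1, keepdims=True)
    return u @ W.T + sd * rng.standard_normal((u.shape[0], p))


def render_modality(u: np.ndarray, labels: np.ndarray, tag: str, config: SimConfig):
    """Observe u through one modality's random map and native value domain.

    Tabular tags return a :class:`ModalityMatrix`; ``wsi`` returns a dict of
    per-patient :class:`PatchBag` (the long-format patch-embedding view).
    """
    if tag not in MODALITIES:
        raise ConfigError(f"unknown modality tag {tag!r}")
    rng = stage_rng(config.seed, tag)
    ids = _patient_ids(config.n_patients)
    sd = config.sd(tag)
    scale = np.sqrt(1.0 + sd * sd)  # marginal sd of a linear-view feature

    if tag == "wsi":
        base = _linear_view(u, config.wsi_dim, 0.0, rng)
        bags: dict[str, PatchBag] = {}
        for i, pid in enumerate(ids):
            patches = base[i][None, :] + sd * rng.standard_normal((config.wsi_patches, config.wsi_dim))
            density = rng.gamma(shape=4.0, scale=0.25, size=config.wsi_patches)
            bags[pid] = PatchBag(patient_id=pid, patches=patches, density=density)
        return bags

    p = config.n_features[tag]
    x = _linear_view(u, p, sd, rng)
    feats = np.array([f"{tag}_f{j:04d}" for j in range(p)], dtype=object)

    if tag == "cnv":
        cuts = np.array([-1.5, -0.5, 0.5, 1.5]) * scale
        vals = np.digitize(x, cuts).astype(float) - 2.0  # {-2,...,2}
        return ModalityMatrix(tag, ids, feats, vals, "cnv5")
    if tag == "dna":
        return ModalityMatrix(tag, ids, feats, 1.0 / (1.0 + np.exp(-x)), "beta")
    if tag == "mir":
        return ModalityMatrix(tag, ids, feats, np.logaddexp(0.0, x), "nonneg")
    if tag == "mrna":
        return ModalityMatrix(tag, ids, feats, x, "continuous")
    # cln: first column is continuous age, the rest small categorical integers
    feats = np.concatenate([["age"], [f"cln_f{j:04d}" for j in range(1, p)]]).astype(object)
    vals = np.empty_like(x)
    vals[:, 0] = 30.0 + 50.0 / (1.0 + np.exp(-x[:, 0] / scale))
    quartiles = np.array([-0.6745, 0.0, 0.6745]) * scale
    vals[:, 1:] = np.digitize(x[:, 1:], quartiles).astype(float)  # {0,1,2,3}
    return ModalityMatrix(tag, ids, feats, vals, "categorical")


def _simulate_survival(labels: np.ndarray, config: SimConfig) -> SurvivalTable:
    """Survival times consistent with the planted labels.

    Short-term: death before the 60-month cutoff.  Long-term: follow-up past
    the cutoff, event status mixed (censoring after the cutoff does not affect
    the label).
    """
    rng = stage_rng(config.seed, "survival")
    n = len(labels)
    t = np.where(
        labels == 1,
        rng.uniform(2.0, CUTOFF_MONTHS - 0.5, n),
        rng.uniform(CUTOFF_MONTHS + 0.5, 240.0, n),
    )
    event = np.where(labels == 1, 1, (rng.random(n) < 0.5).astype(int))
    return SurvivalTable(_patient_ids(n), t, event)


def generate_labels_from_times(
    survival: SurvivalTable, cutoff_months: float = CUTOFF_MONTHS, censored_policy: str = "exclude"
) -> tuple[np.ndarray, np.ndarray]:
    """Binary 5-year survival labels from a survival table.

    Returns ``(labels, excluded)``.  Label 1 (short-term survivor, the
    positive class) iff the death event occurred before the cutoff; label 0
    (long-term) iff follow-up reached the cutoff.  Patients censored before
    the cutoff carry no label under the rule; with the default policy they
    are flagged excluded, with ``censored_policy="long_term"`` they are
    labelled 0.
    """
    if np.any(survival.time_months < 0):
        raise ValidationError("negative follow-up time")
    if censored_policy not in ("exclude", "long_term"):
        raise ConfigError(f"censored_policy must be 'exclude' or 'long_term', got {censored_policy!r}")
    t, e = survival.time_months, survival.event
    labels = ((e == 1) & (t < cutoff_months)).astype(int)
    excluded = (e == 0) & (t < cutoff_months)
    if censored_policy == "long_term":
        excluded = np.zeros_like(excluded)
    return labels, excluded


def inject_missingness(dataset: MultiModalDataset, config: SimConfig) -> MultiModalDataset:
    """Plant feature-level NaNs and patient-level modality absence.

    Cells of tabular modalities go missing i.i.d. at ``feature_missing_rate``;
    whole patients are removed from a modality (rows of the matrix, or WSI
    bags) at ``modality_absence_rate[tag]``.  The survival table and the
    planted truth are never touched.
    """
    rng_missing = stage_rng(config.seed, "missing")
    rng_absence = stage_rng(config.seed, "absence")
    modalities: dict[str, ModalityMatrix] = {}
    for tag, m in dataset.modalities.items():
        vals = m.values.copy()
        if config.feature_missing_rate > 0:
            mask = rng_missing.random(vals.shape) < config.feature_missing_rate
            vals[mask] = np.nan
        m = ModalityMatrix(m.modality, m.patient_ids.copy(), m.feature_ids.copy(), vals, m.domain)
        rate = config.modality_absence_rate.get(tag, 0.0)
        if rate > 0:
            keep = rng_absence.random(m.n_patients) >= rate
            m = m.subset_patients(m.patient_ids[keep])
        modalities[tag] = m
    bags = dataset.wsi_bags
    rate = config.modality_absence_rate.get("wsi", 0.0)
    if bags and rate > 0:
        pids = sorted(bags)
        keep = rng_absence.random(len(pids)) >= rate
        bags = {pid: bags[pid] for pid, k in zip(pids, keep) if k}
    return MultiModalDataset(
        modalities=modalities, survival=dataset.survival, truth=dataset.truth, wsi_bags=dict(bags)
    )


def simulate_cohort(config: SimConfig) -> MultiModalDataset:
    """Full cohort: latents -> six modality views -> survival -> missingness."""
    labels, u = simulate_latents(config)
    modalities = {tag: render_modality(u, labels, tag, config) for tag in config.n_features}
    bags = render_modality(u, labels, "wsi", config)
    survival = _simulate_survival(labels, config)
    dataset = MultiModalDataset(
        modalities=modalities,
        survival=survival,
        truth={"labels": labels, "u": u, "patient_ids": _patient_ids(config.n_patients)},
        wsi_bags=bags,
    )
    return inject_missingness(dataset, config)
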