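"""Per-modality cleaning, imputation, normalization and selection.

The fixed pipeline order per modality is:

    drop_high_missing_features -> impute_weighted_knn
    -> modality-specific step (age min-max for clinical, z-score
       discretization for mRNA)
    -> drop_constant_features -> select_top_variance (cnv and mrna only
       by default) -> intersect_cohort across the chosen modalities.

Features with more than 10% missing cells are discarded outright; the rest
are filled by an inverse-distance-weighted mean over the k nearest patients
(Euclidean distance on mutually observed features).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.impute import KNNImputer

from .containers import CohortIndex, ModalityMatrix, ValidationError


@dataclass
class PreprocessConfig:
    missing_threshold: float = 0.10
    knn_k: int = 10
    z_threshold: float = 1.0
    top_k: int = 500
    variance_warn: float = 0.98
    #: modalities whose feature space is truncated to the top-variance subset
    top_k_modalities: tuple[str, ...] = ("cnv", "mrna")


def drop_high_missing_features(
    m: ModalityMatrix, threshold: float = 0.10
) -> tuple[ModalityMatrix, list[str]]:
    """Remove features whose missing fraction strictly exceeds ``threshold``.

    Exactly-at-threshold features are kept (the rule is "more than").
    Returns the reduced matrix and the dropped feature ids.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValidationError(f"threshold must be in [0,1], got {threshold}")
    frac = np.isnan(m.values).mean(axis=0)
    keep = frac <= threshold
    if not keep.any():
        raise ValidationError(f"{m.modality}: every feature exceeds the missingness threshold")
    dropped = [str(f) for f in m.feature_ids[~keep]]
    return replace(m, feature_ids=m.feature_ids[keep], values=m.values[:, keep]), dropped


def impute_weighted_knn(m: ModalityMatrix, k: int = 10) -> ModalityMatrix:
    """Weighted nearest-neighbour imputation of the remaining missing cells.

    Each missing cell becomes the inverse-distance-weighted mean of the value
    in the k nearest patients that observe that feature; observed cells are
    never altered.
    """
    if not np.isnan(m.values).any():
        return m
    all_missing = np.isnan(m.values).all(axis=1)
    if all_missing.any():
        bad = m.patient_ids[all_missing][0]
        raise ValidationError(f"{m.modality}: patient {bad} has no observed features")
    if m.n_patients < 2:
        raise ValidationError(f"{m.modality}: need at least 2 patients to impute")
    k_eff = min(k, m.n_patients - 1)
    imputer = KNNImputer(n_neighbors=k_eff, weights="distance")
    filled = imputer.fit_transform(m.values)
    observed = ~np.isnan(m.values)
    out = m.values.copy()
    out[~observed] = filled[~observed]
    return replace(m, values=out)


def minmax_normalize(column: np.ndarray) -> np.ndarray:
    """Map a non-constant vector linearly onto [0,1]."""
    column = np.asarray(column, dtype=float)
    lo, hi = np.nanmin(column), np.nanmax(column)
    if hi == lo:
        raise ValidationError("constant column cannot be min-max normalized")
    return (column - lo) / (hi - lo)


def discretize_expression(m: ModalityMatrix, z_threshold: float = 1.0) -> ModalityMatrix:
    """Trichotomize expression per gene: under (-1) / baseline (0) / over (+1).

    Genes are standardized over patients; |z| beyond the threshold maps to
    the corresponding extreme.  Zero-variance genes map to all-baseline.
    """
    if z_threshold <= 0:
        raise ValidationError(f"z_threshold must be positive, got {z_threshold}")
    mu = m.values.mean(axis=0)
    sd = m.values.std(axis=0)
    flat = sd == 0.0
    if flat.any():
        warnings.warn(
            f"{m.modality}: {int(flat.sum())} zero-variance genes mapped to baseline",
            stacklevel=2,
        )
    z = (m.values - mu) / np.where(flat, 1.0, sd)
    out = np.zeros_like(z)
    out[z > z_threshold] = 1.0
    out[z < -z_threshold] = -1.0
    out[:, flat] = 0.0
    return replace(m, values=out, domain="continuous")


def drop_constant_features(m: ModalityMatrix) -> ModalityMatrix:
    """Remove zero-variance features (identical value for every patient)."""
    keep = m.values.std(axis=0) > 0.0
    if not keep.any():
        raise ValidationError(f"{m.modality}: all features are constant")
    return replace(m, feature_ids=m.feature_ids[keep], values=m.values[:, keep])


def select_top_variance(m: ModalityMatrix, k: int = 500) -> tuple[ModalityMatrix, float]:
    """Keep the k highest-variance features; report the variance captured.

    Ties are broken lexicographically on feature id for determinism.  Emits a
    warning when the captured fraction falls below 98%.
    """
    if k < 1:
        raise ValidationError(f"k must be >= 1, got {k}")
    var = m.values.var(axis=0)
    order = sorted(range(m.n_features), key=lambda j: (-var[j], str(m.feature_ids[j])))
    kept = sorted(order[: min(k, m.n_features)])
    total = float(var.sum())
    captured = float(var[kept].sum() / total) if total > 0 else 1.0
    if captured < 0.98:
        warnings.warn(
            f"{m.modality}: top-{k} features capture only {captured:.3f} of total variance",
            stacklevel=2,
        )
    reduced = replace(m, feature_ids=m.feature_ids[kept], values=m.values[:, kept])
    return reduced, captured


def intersect_cohort(matrices: list[ModalityMatrix]) -> tuple[CohortIndex, list[ModalityMatrix]]:
    """Sorted common patient ids, with every matrix re-ordered to them."""
    if not matrices:
        raise ValidationError("intersect_cohort needs at least one matrix")
    common = set(matrices[0].patient_ids)
    for m in matrices[1:]:
        common &= set(m.patient_ids)
    if not common:
        raise ValidationError("empty patient-id intersection across modalities")
    index = CohortIndex(np.array(sorted(common, key=str), dtype=object))
    return index, [m.subset_patients(index.patient_ids) for m in matrices]


@dataclass
class PreprocessReport:
    """What each rule did to one modality, for the JSON preprocessing report."""

    modality: str
    dropped_high_missing: list[str] = field(default_factory=list)
    n_imputed_cells: int = 0
    dropped_constant: list[str] = field(default_factory=list)
    n_selected: int | None = None
    captured_variance: float | None = None

    def to_dict(self) -> dict:
        return {
            "modality": self.modality,
            "dropped_high_missing": self.dropped_high_missing,
            "n_imputed_cells": self.n_imputed_cells,
            "dropped_constant": self.dropped_constant,
            "n_selected": self.n_selected,
            "captured_variance": self.captured_variance,
        }


def preprocess_modality(
    m: ModalityMatrix, config: PreprocessConfig | None = None
) -> tuple[ModalityMatrix, PreprocessReport]:
    """Run the fixed per-modality pipeline (everything before intersection)."""
    config = config or PreprocessConfig()
    report = PreprocessReport(modality=m.modality)
    m, report.dropped_high_missing = drop_high_missing_features(m, config.missing_threshold)
    report.n_imputed_cells = int(np.isnan(m.values).sum())
    m = impute_weighted_knn(m, config.knn_k)
    if m.modality == "cln" and "age" in set(m.feature_ids):
        j = int(np.where(m.feature_ids == "age")[0][0])
        vals = m.values.copy()
        vals[:, j] = minmax_normalize(vals[:, j])
        m = replace(m, values=vals)
    elif m.modality == "mrna":
        m = discretize_expression(m, config.z_threshold)
    before = set(map(str, m.feature_ids))
    m = drop_constant_features(m)
    report.dropped_constant = sorted(before - set(map(str, m.feature_ids)))
    if m.modality in config.top_k_modalities:
        m, report.captured_variance = select_top_variance(m, config.top_k)
        report.n_selected = m.n_features
    return m, report
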