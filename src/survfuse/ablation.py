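"""Modality-combination ablation and stability analysis.

All unordered subsets of the available modalities (uni- through hexa-modal)
are evaluated: per combination the cohort is the patient-id intersection,
labels come from the survival table at the 60-month cutoff, features are
built per pathway (raw / PCA / VAE) and fused by column concatenation in
sorted-tag order, then each classifier is scored under the CV protocol.

The stability analysis aggregates, per (arity, feature kind, classifier),
the mean and population standard deviation of each metric across the
combinations of that arity — the quantity whose decline with arity is the
signature of complementary modalities.
"""

from __future__ import annotations

import itertools
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import ClassifierSpec, EvalResult, cross_validate
from .containers import CohortIndex, ModalityMatrix, MultiModalDataset, ValidationError
from .pca import apply_pca, fit_pca
from .preprocess import intersect_cohort
from .synthetic import generate_labels_from_times
from .vae import VAEConfig, default_vae_config, encode, fit_vae

FEATURE_KINDS = ("raw", "pca", "vae")


@dataclass
class ProtocolConfig:
    """Evaluation protocol shared by every ablation record."""

    n_folds: int = 10
    seed: int = 0
    cutoff_months: float = 60.0
    censored_policy: str = "exclude"
    pca_variance: float = 0.95
    fit_scope: str = "full"  # "full" (reducers fitted before CV) or "per-fold" (leakage-safe)
    sample_std: bool = False  # population std by default


@dataclass
class AblationRecord:
    combination: tuple[str, ...]
    feature_kind: str
    classifier_kind: str
    cohort_size: int
    result: EvalResult | None = None
    error: str | None = None

    @property
    def arity(self) -> int:
        return len(self.combination)


@dataclass
class AblationReport:
    records: list[AblationRecord] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row = {
                "combination": "_".join(r.combination),
                "arity": r.arity,
                "feature_kind": r.feature_kind,
                "classifier": r.classifier_kind,
                "cohort_size": r.cohort_size,
                "error": r.error or "",
            }
            if r.result is not None:
                mean, std = r.result.mean(), r.result.std()
                for k in ("acc", "pre", "sn", "f1"):
                    row[f"mean_{k}"] = getattr(mean, k)
                    row[f"std_{k}"] = getattr(std, k)
            rows.append(row)
        return pd.DataFrame(rows)


def enumerate_combinations(
    tags, min_arity: int = 1, max_arity: int = 6
) -> list[tuple[str, ...]]:
    """All unordered modality subsets, lexicographic within each arity."""
    tags = sorted(set(tags))
    if not 1 <= min_arity <= max_arity <= len(tags):
        raise ValidationError(
            f"inconsistent arity bounds [{min_arity}, {max_arity}] for {len(tags)} tags"
        )
    out: list[tuple[str, ...]] = []
    for k in range(min_arity, max_arity + 1):
        out.extend(itertools.combinations(tags, k))
    return out


def fuse_features(reduced: dict[str, np.ndarray], cohort: CohortIndex) -> np.ndarray:
    """Column-concatenate per-modality feature blocks in sorted-tag order.

    Every block must carry exactly ``len(cohort)`` rows already aligned to
    the cohort order; a mismatch is an error, never a silent reindex.
    """
    n = len(cohort)
    blocks = []
    for tag in sorted(reduced):
        block = np.atleast_2d(np.asarray(reduced[tag], dtype=float))
        if block.shape[0] != n:
            raise ValidationError(
                f"{tag}: block has {block.shape[0]} rows but the cohort has {n}"
            )
        blocks.append(block)
    return np.hstack(blocks)


def _record_seed(protocol_seed: int, combination: tuple[str, ...], kind: str, clf: str) -> int:
    key = f"{'_'.join(combination)}|{kind}|{clf}|{protocol_seed}"
    return (zlib.crc32(key.encode()) ^ protocol_seed) % (2**31)


class FeatureBuilder:
    """Fits the per-modality reducers once and serves aligned feature blocks.

    In ``full`` fit scope each reducer (PCA at 95% variance, or the log-cosh
    VAE) is fitted on the modality's complete preprocessed patient set before
    any cross-validation; the leakage-safe per-fold
    alternative is wired through :func:`cross_validate`'s transform factory.
    """

    def __init__(
        self,
        modalities: dict[str, ModalityMatrix],
        protocol: ProtocolConfig,
        vae_configs: dict[str, VAEConfig] | None = None,
    ):
        self.modalities = modalities
        self.protocol = protocol
        self.vae_configs = vae_configs or {}
        self._pca_cache: dict[str, np.ndarray] = {}
        self._vae_cache: dict[str, np.ndarray] = {}

    def vae_config(self, tag: str) -> VAEConfig:
        return self.vae_configs.get(tag) or default_vae_config(tag, seed=self.protocol.seed)

    def _full_block(self, tag: str, kind: str) -> np.ndarray:
        m = self.modalities[tag]
        if kind == "raw":
            return m.values
        cache = self._pca_cache if kind == "pca" else self._vae_cache
        if tag not in cache:
            if kind == "pca":
                model = fit_pca(m.values, variance=self.protocol.pca_variance)
                cache[tag] = apply_pca(model, m.values)
            else:
                model = fit_vae(m, self.vae_config(tag))
                cache[tag] = encode(model, m)
        return cache[tag]

    def block(self, tag: str, kind: str, cohort: CohortIndex) -> np.ndarray:
        if kind not in FEATURE_KINDS:
            raise ValidationError(f"unknown feature kind {kind!r}")
        m = self.modalities[tag]
        full = self._full_block(tag, kind)
        pos = {p: i for i, p in enumerate(m.patient_ids)}
        idx = np.array([pos[p] for p in cohort.patient_ids], dtype=int)
        return full[idx]

    def per_fold_factory(self, combination: tuple[str, ...], kind: str, cohort: CohortIndex):
        """Transform factory for leakage-safe reduction of the fused raw block."""
        if kind == "raw":
            return None
        spans, start = {}, 0
        for tag in sorted(combination):
            w = self.modalities[tag].n_features
            spans[tag] = (start, start + w)
            start += w

        def factory(X_train: np.ndarray):
            models = {}
            for tag, (a, b) in spans.items():
                if kind == "pca":
                    models[tag] = ("pca", fit_pca(X_train[:, a:b], variance=self.protocol.pca_variance))
                else:
                    models[tag] = ("vae", fit_vae(X_train[:, a:b], self.vae_config(tag)))

            def transform(X: np.ndarray) -> np.ndarray:
                blocks = []
                for tag, (a, b) in spans.items():
                    mkind, model = models[tag]
                    blocks.append(
                        apply_pca(model, X[:, a:b]) if mkind == "pca" else encode(model, X[:, a:b])
                    )
                return np.hstack(blocks)

            return transform

        return factory


def run_ablation(
    dataset: MultiModalDataset,
    feature_kinds=FEATURE_KINDS,
    classifier_specs: list[ClassifierSpec] | None = None,
    protocol: ProtocolConfig | None = None,
    vae_configs: dict[str, VAEConfig] | None = None,
    min_arity: int = 1,
    max_arity: int | None = None,
) -> AblationReport:
    """Evaluate every (combination x feature kind x classifier) cell.

    Failures in one record are captured in that record and the run continues
    (fail-soft); identical inputs produce an identical report.
    """
    protocol = protocol or ProtocolConfig()
    specs = classifier_specs or [ClassifierSpec(kind=k) for k in
                                 ("rbf_svm", "linear_svm", "polynomial_svm", "sigmoid_svm", "random_forest")]
    modalities = dataset.modalities
    if len(modalities) < 1:
        raise ValidationError("ablation needs at least one preprocessed modality")
    tags = sorted(modalities)
    combos = enumerate_combinations(tags, min_arity, max_arity or len(tags))
    builder = FeatureBuilder(modalities, protocol, vae_configs)
    report = AblationReport()
    for combination in combos:
        try:
            cohort, _ = intersect_cohort([modalities[t] for t in combination])
            surv = dataset.survival.subset(cohort.patient_ids)
            labels, excluded = generate_labels_from_times(
                surv, protocol.cutoff_months, protocol.censored_policy
            )
            if excluded.any():
                keep = ~excluded
                cohort = CohortIndex(cohort.patient_ids[keep])
                labels = labels[keep]
        except Exception as exc:  # fail-soft per combination
            for kind in feature_kinds:
                for spec in specs:
                    report.records.append(
                        AblationRecord(combination, kind, spec.kind, 0, error=str(exc))
                    )
            continue
        for kind in feature_kinds:
            try:
                if protocol.fit_scope == "per-fold" and kind != "raw":
                    fused = fuse_features(
                        {t: builder.block(t, "raw", cohort) for t in combination}, cohort
                    )
                    factory = builder.per_fold_factory(combination, kind, cohort)
                else:
                    fused = fuse_features(
                        {t: builder.block(t, kind, cohort) for t in combination}, cohort
                    )
                    factory = None
            except Exception as exc:
                for spec in specs:
                    report.records.append(
                        AblationRecord(combination, kind, spec.kind, len(cohort), error=str(exc))
                    )
                continue
            for spec in specs:
                rec_seed = _record_seed(protocol.seed, combination, kind, spec.kind)
                try:
                    result = cross_validate(
                        fused,
                        labels,
                        ClassifierSpec(
                            kind=spec.kind, C=spec.C, degree=spec.degree,
                            n_trees=spec.n_trees, seed=rec_seed,
                        ),
                        n_folds=protocol.n_folds,
                        seed=rec_seed,
                        transform_factory=factory,
                    )
                    result.feature_kind = kind
                    report.records.append(
                        AblationRecord(combination, kind, spec.kind, len(cohort), result=result)
                    )
                except Exception as exc:
                    report.records.append(
                        AblationRecord(combination, kind, spec.kind, len(cohort), error=str(exc))
                    )
    return report


def aggregate_by_arity(report: AblationReport, sample_std: bool = False) -> pd.DataFrame:
    """Across-combination mean and std of each metric per (arity, kind, classifier).

    Folds are first averaged within each record; the std is the population
    standard deviation across combinations (a single combination — the
    hexa-modal cell — therefore has std exactly 0).
    """
    ok = [r for r in report.records if r.result is not None]
    if not ok:
        raise ValidationError("no successful records to aggregate")
    rows = []
    for r in ok:
        mean = r.result.mean()
        rows.append(
            {
                "arity": r.arity,
                "feature_kind": r.feature_kind,
                "classifier": r.classifier_kind,
                "combination": "_".join(r.combination),
                **mean.as_dict(),
            }
        )
    df = pd.DataFrame(rows)
    ddof = 1 if sample_std else 0
    agg = df.groupby(["arity", "feature_kind", "classifier"]).agg(
        n_combinations=("combination", "count"),
        **{
            f"{stat}_{k}": (k, (lambda s, d=ddof: float(np.std(s, ddof=d))) if stat == "std" else "mean")
            for k in ("acc", "pre", "sn", "f1")
            for stat in ("mean", "std")
        },
    )
    return agg.reset_index()
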