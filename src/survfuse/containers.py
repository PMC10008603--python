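"""Core in-memory containers shared by every pipeline stage.

A cohort is a collection of per-modality patient x feature matrices plus a
survival table.  Patients are identified by string ids; every matrix keeps its
rows sorted by patient id so that row alignment across modalities is purely an
id-set question.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: canonical modality tags, in the fixed sorted order used for fusion
MODALITIES = ("cln", "cnv", "dna", "mir", "mrna", "wsi")

#: value-domain descriptors per modality
DOMAINS = {
    "cln": "categorical",
    "cnv": "cnv5",
    "dna": "beta",
    "mir": "nonneg",
    "mrna": "continuous",
    "wsi": "embedding",
}

CNV_LEVELS = (-2.0, -1.0, 0.0, 1.0, 2.0)


class SurvfuseError(Exception):
    """Base class for package errors."""


class ConfigError(SurvfuseError):
    """Invalid configuration value; message names the offending field."""


class ValidationError(SurvfuseError):
    """Input data violates a structural or domain contract."""


@dataclass
class ModalityMatrix:
    """One modality's patient x feature table.

    ``values`` is float64 throughout; missing cells are NaN.  ``domain``
    describes the native value range (``categorical``, ``cnv5``, ``beta``,
    ``nonneg``, ``continuous``, ``embedding``) and is used for validation on
    I/O, not enforced on every mutation.
    """

    modality: str
    patient_ids: np.ndarray  # shape (n,), dtype=object/str
    feature_ids: np.ndarray  # shape (p,), dtype=object/str
    values: np.ndarray  # shape (n, p), float64
    domain: str = "continuous"

    def __post_init__(self) -> None:
        self.patient_ids = np.asarray(self.patient_ids, dtype=object)
        self.feature_ids = np.asarray(self.feature_ids, dtype=object)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.patient_ids), len(self.feature_ids)):
            raise ValidationError(
                f"{self.modality}: values shape {self.values.shape} does not match "
                f"{len(self.patient_ids)} patients x {len(self.feature_ids)} features"
            )
        for name, ids in (("patient", self.patient_ids), ("feature", self.feature_ids)):
            if len(set(ids)) != len(ids):
                raise ValidationError(f"{self.modality}: duplicate {name} ids")

    @property
    def n_patients(self) -> int:
        return len(self.patient_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def sorted_by_patient(self) -> "ModalityMatrix":
        order = np.argsort(self.patient_ids.astype(str), kind="stable")
        return replace(self, patient_ids=self.patient_ids[order], values=self.values[order])

    def subset_patients(self, ids) -> "ModalityMatrix":
        """Row-subset and re-order to ``ids`` (all must be present)."""
        pos = {p: i for i, p in enumerate(self.patient_ids)}
        missing = [p for p in ids if p not in pos]
        if missing:
            raise ValidationError(f"{self.modality}: patients absent from matrix: {missing[:5]}")
        idx = np.array([pos[p] for p in ids], dtype=int)
        return replace(self, patient_ids=np.asarray(list(ids), dtype=object), values=self.values[idx])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.feature_ids))
        df.insert(0, "patient_id", list(self.patient_ids))
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, modality: str, domain: str | None = None) -> "ModalityMatrix":
        if "patient_id" not in df.columns[:1].tolist():
            raise ValidationError(f"{modality}: first column must be 'patient_id'")
        ids = df["patient_id"].astype(str).to_numpy(dtype=object)
        feats = df.columns[1:].to_numpy(dtype=object)
        vals = df.iloc[:, 1:].to_numpy(dtype=float)
        return cls(modality, ids, feats, vals, domain or DOMAINS.get(modality, "continuous"))


@dataclass
class SurvivalTable:
    """Per-patient follow-up time (months) and event indicator (1 = death)."""

    patient_ids: np.ndarray
    time_months: np.ndarray
    event: np.ndarray

    def __post_init__(self) -> None:
        self.patient_ids = np.asarray(self.patient_ids, dtype=object)
        self.time_months = np.asarray(self.time_months, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        if not (len(self.patient_ids) == len(self.time_months) == len(self.event)):
            raise ValidationError("survival: column lengths differ")
        if len(set(self.patient_ids)) != len(self.patient_ids):
            raise ValidationError("survival: duplicate patient ids")
        if np.any(self.time_months < 0):
            raise ValidationError("survival: negative follow-up time")

    def subset(self, ids) -> "SurvivalTable":
        pos = {p: i for i, p in enumerate(self.patient_ids)}
        missing = [p for p in ids if p not in pos]
        if missing:
            raise ValidationError(f"survival: patients absent: {missing[:5]}")
        idx = np.array([pos[p] for p in ids], dtype=int)
        return SurvivalTable(np.asarray(list(ids), dtype=object), self.time_months[idx], self.event[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"patient_id": list(self.patient_ids), "time_months": self.time_months, "event": self.event}
        )


@dataclass
class CohortIndex:
    """Sorted patient ids common to a set of modalities."""

    patient_ids: np.ndarray

    def __post_init__(self) -> None:
        self.patient_ids = np.asarray(self.patient_ids, dtype=object)

    def __len__(self) -> int:
        return len(self.patient_ids)


@dataclass
class MultiModalDataset:
    """Modality matrices + survival + (for synthetic cohorts) planted truth.

    ``wsi_bags`` holds the raw per-patient patch-embedding bags before the
    WSI aggregation stage turns them into ``modalities["wsi"]``.
    """

    modalities: dict[str, ModalityMatrix]
    survival: SurvivalTable
    truth: dict = field(default_factory=dict)
    wsi_bags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        known = set(self.survival.patient_ids)
        for tag, m in self.modalities.items():
            extra = set(m.patient_ids) - known
            if extra:
                raise ValidationError(f"{tag}: patients missing from survival table: {sorted(extra)[:5]}")
        extra = set(self.wsi_bags) - known
        if extra:
            raise ValidationError(f"wsi bags: patients missing from survival table: {sorted(extra)[:5]}")
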