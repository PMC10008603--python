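"""Whole-slide-image patch-embedding aggregation.

Upstream tiling and CNN inference are out of scope; the input here is the
per-patient *patch bag*: an ``n_patches x D`` embedding matrix with a positive
density score per patch (denser tiles contain more tissue).  The pathway is:

1. keep the densest patches — ``min(cap, ceil(fraction * n))``, padded
   cyclically up to ``cap`` rows so every patient yields the same width;
2. PCA the pooled patch rows of the cohort down to ``patch_dim``;
3. concatenate each patient's reduced patches (density-rank order) into one
   vector of length ``cap * patch_dim``;
4. PCA those vectors to ``final_dim`` while retaining ``variance``.

At real scale the numbers are 40 patches x 2048 -> 512 -> 20,480 -> 800;
synthetic cohorts use the same machinery at reduced size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .containers import ModalityMatrix, ValidationError
from .pca import PCAModel, apply_pca, fit_pca


@dataclass
class PatchBag:
    """One patient's WSI patch embeddings plus per-patch density scores."""

    patient_id: str
    patches: np.ndarray  # (n_patches, D)
    density: np.ndarray  # (n_patches,), positive

    def __post_init__(self) -> None:
        self.patches = np.atleast_2d(np.asarray(self.patches, dtype=float))
        self.density = np.asarray(self.density, dtype=float)
        if self.patches.shape[0] != self.density.shape[0]:
            raise ValidationError(f"{self.patient_id}: patch/density length mismatch")
        if self.patches.shape[0] < 1:
            raise ValidationError(f"{self.patient_id}: empty patch bag")
        if not np.isfinite(self.density).all():
            raise ValidationError(f"{self.patient_id}: non-finite density")

    @property
    def n_patches(self) -> int:
        return self.patches.shape[0]


@dataclass
class WsiConfig:
    """Aggregation sizes; defaults are the real-data scale."""

    fraction: float = 0.20
    cap: int = 40
    patch_dim: int = 512
    final_dim: int = 800
    variance: float = 0.95

    def __post_init__(self) -> None:
        if not 0.0 < self.fraction <= 1.0:
            raise ValidationError(f"fraction must be in (0,1], got {self.fraction}")
        if self.cap < 1 or self.patch_dim < 1 or self.final_dim < 1:
            raise ValidationError("cap, patch_dim and final_dim must be >= 1")


def select_dense_patches(bag: PatchBag, fraction: float = 0.20, cap: int = 40) -> PatchBag:
    """Keep the ``min(cap, ceil(fraction*n))`` densest patches, pad to ``cap``.

    Order is density-descending with ties broken by original patch index.  If
    fewer than ``cap`` patches survive, the kept patches are duplicated
    cyclically so the output always has exactly ``cap`` rows (keeps the fused
    width constant without distorting the downstream PCA centering).
    """
    if bag.n_patches < 1:
        raise ValidationError(f"{bag.patient_id}: empty patch bag")
    n_keep = min(cap, math.ceil(fraction * bag.n_patches))
    # stable sort on -density preserves index order among ties
    order = np.argsort(-bag.density, kind="stable")[:n_keep]
    idx = order[np.arange(cap) % n_keep]
    return replace(bag, patches=bag.patches[idx], density=bag.density[idx])


def reduce_patch_embeddings(
    bags: dict[str, PatchBag], target_dim: int = 512
) -> tuple[dict[str, PatchBag], PCAModel]:
    """Project every patch to ``target_dim`` via one PCA pooled over all bags."""
    if not bags:
        raise ValidationError("no patch bags given")
    pooled = np.vstack([b.patches for b in bags.values()])
    if np.allclose(pooled, pooled[0], atol=0.0):
        raise ValidationError("degenerate patch set: all patches identical")
    model = fit_pca(pooled, variance=1.0, max_components=target_dim)
    reduced = {
        pid: replace(b, patches=apply_pca(model, b.patches)) for pid, b in bags.items()
    }
    return reduced, model


def assemble_wsi_vector(bag: PatchBag, cap: int = 40) -> np.ndarray:
    """Concatenate the reduced patches (density-rank order) into one vector."""
    if bag.n_patches != cap:
        raise ValidationError(
            f"{bag.patient_id}: expected exactly {cap} patches, got {bag.n_patches}"
        )
    return bag.patches.reshape(-1)


def reduce_wsi_features(
    vectors: np.ndarray,
    patient_ids,
    target_dim: int = 800,
    variance: float = 0.95,
) -> tuple[ModalityMatrix, PCAModel]:
    """Cohort-level PCA of the concatenated patch vectors -> WSI modality matrix."""
    vectors = np.asarray(vectors, dtype=float)
    if vectors.shape[0] < 2:
        raise ValidationError("WSI reduction requires at least 2 patients")
    model = fit_pca(vectors, variance=variance, max_components=target_dim)
    reduced = apply_pca(model, vectors)
    feats = np.array([f"wsi_c{j:04d}" for j in range(reduced.shape[1])], dtype=object)
    return ModalityMatrix("wsi", np.asarray(patient_ids, dtype=object), feats, reduced, "embedding"), model


def embed_wsi(bags: dict[str, PatchBag], config: WsiConfig | None = None) -> ModalityMatrix:
    """Full bag-to-matrix pathway for one cohort (patients sorted by id)."""
    config = config or WsiConfig()
    if not bags:
        raise ValidationError("no patch bags given")
    selected = {
        pid: select_dense_patches(bags[pid], config.fraction, config.cap) for pid in sorted(bags)
    }
    reduced, _ = reduce_patch_embeddings(selected, config.patch_dim)
    pids = sorted(reduced)
    vectors = np.stack([assemble_wsi_vector(reduced[pid], config.cap) for pid in pids])
    matrix, _ = reduce_wsi_features(vectors, pids, config.final_dim, config.variance)
    return matrix
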