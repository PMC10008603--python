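"""PCA feature pathway.

Thin, deterministic wrapper around a full-SVD PCA: components are selected as
the smallest count whose cumulative explained-variance fraction reaches the
requested level (capped by rank and an optional hard cap), and each
component's sign is fixed so its largest-magnitude loading is positive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA as _SkPCA

from .containers import ValidationError


@dataclass
class PCAModel:
    """Fitted PCA: centering vector, orthonormal components, variance fractions."""

    mean: np.ndarray  # (p,)
    components: np.ndarray  # (n_comp, p), rows orthonormal
    explained_fraction: np.ndarray  # (n_comp,), non-increasing
    feature_ids: np.ndarray | None = None

    @property
    def n_components(self) -> int:
        return self.components.shape[0]


def _fix_signs(components: np.ndarray) -> np.ndarray:
    """Flip each component so its largest-|loading| entry is positive."""
    out = components.copy()
    for i, row in enumerate(out):
        j = int(np.argmax(np.abs(row)))
        if row[j] < 0:
            out[i] = -row
    return out


def fit_pca(
    X: np.ndarray,
    variance: float = 0.95,
    max_components: int | None = None,
    feature_ids=None,
) -> PCAModel:
    """Fit PCA keeping the smallest component count reaching ``variance``.

    ``max_components`` additionally caps the count (used by the WSI pathway's
    fixed 512/800-dimensional projections). Rank always caps it.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValidationError("PCA requires a 2-d matrix with at least 2 rows")
    if np.isnan(X).any():
        raise ValidationError("PCA input contains missing values")
    if not 0.0 < variance <= 1.0:
        raise ValidationError(f"variance must be in (0,1], got {variance}")
    sk = _SkPCA(n_components=None, svd_solver="full")
    sk.fit(X)
    ratios = sk.explained_variance_ratio_
    total_var = float(sk.explained_variance_.sum())
    if total_var <= 0.0:
        raise ValidationError("PCA input has zero variance")
    # rank of the centered matrix: components with non-negligible variance
    tol = max(X.shape) * np.finfo(float).eps * max(sk.singular_values_.max(), 1.0)
    rank = int((sk.singular_values_ > tol).sum())
    cum = np.cumsum(ratios)
    n_comp = int(np.searchsorted(cum, variance - 1e-12) + 1)
    n_comp = min(n_comp, rank)
    if max_components is not None:
        if n_comp > max_components:
            n_comp = max_components
        if max_components > rank:
            warnings.warn(
                f"requested {max_components} components but rank is {rank}; capping",
                stacklevel=2,
            )
    n_comp = max(n_comp, 1)
    return PCAModel(
        mean=sk.mean_.copy(),
        components=_fix_signs(sk.components_[:n_comp]),
        explained_fraction=ratios[:n_comp].copy(),
        feature_ids=None if feature_ids is None else np.asarray(feature_ids, dtype=object),
    )


def apply_pca(model: PCAModel, X: np.ndarray, feature_ids=None) -> np.ndarray:
    """Project rows: (x - mean) @ components.T."""
    X = np.asarray(X, dtype=float)
    if X.shape[-1] != model.mean.shape[0]:
        raise ValidationError(
            f"feature count {X.shape[-1]} does not match fitted {model.mean.shape[0]}"
        )
    if feature_ids is not None and model.feature_ids is not None:
        got = np.asarray(feature_ids, dtype=object)
        if not np.array_equal(got, model.feature_ids):
            bad = [str(f) for f in got if f not in set(model.feature_ids)]
            raise ValidationError(f"feature ids do not match the fit; offenders: {bad[:5]}")
    return (X - model.mean) @ model.components.T
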