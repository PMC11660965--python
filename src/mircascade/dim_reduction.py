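"""PCA with cumulative-explained-variance component selection.

The feature rows are mean-centred and projected onto principal components;
the number of retained components is the smallest k whose cumulative
explained-variance ratio reaches a threshold (0.95 by default).  A deterministic
sign convention (largest-magnitude loading of each component made positive)
keeps projections reproducible across runs and BLAS backends.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.decomposition import PCA

from .data_io import ValidationError
from .similarity import DegenerateInputError

ARTIFACT_VERSION = 1


@dataclass
class PcaModel:
    """Fitted PCA with a cumulative-variance component-selection rule."""

    mean_vector: np.ndarray
    components: np.ndarray  # (k_max, p), orthonormal rows
    explained_variance_ratio: np.ndarray
    threshold: float = 0.95
    selected_k: int | None = None

    def select(self, threshold: float | None = None) -> int:
        """Fix ``selected_k`` by the cumulative-variance rule and return it."""
        if threshold is not None:
            self.threshold = float(threshold)
        self.selected_k = select_components(self.explained_variance_ratio, self.threshold)
        return self.selected_k

    @property
    def n_features(self) -> int:
        return self.components.shape[1]

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Project onto the first ``selected_k`` components after centring."""
        if self.selected_k is None:
            raise ValidationError("selected_k unset; call select() first")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.n_features:
            raise ValidationError(
                f"X has {X.shape[1]} columns, model expects {self.n_features}"
            )
        return (X - self.mean_vector) @ self.components[: self.selected_k].T

    def inverse_transform(self, Z: np.ndarray) -> np.ndarray:
        if self.selected_k is None:
            raise ValidationError("selected_k unset; call select() first")
        return np.asarray(Z) @ self.components[: self.selected_k] + self.mean_vector

    def save(self, path: str | Path) -> None:
        """Persist as a versioned npz + JSON manifest."""
        path = Path(path)
        np.savez_compressed(
            path.with_suffix(".npz"),
            mean_vector=self.mean_vector,
            components=self.components,
            explained_variance_ratio=self.explained_variance_ratio,
        )
        manifest = {
            "artifact": "pca_model",
            "version": ARTIFACT_VERSION,
            "threshold": self.threshold,
            "selected_k": self.selected_k,
        }
        path.with_suffix(".json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "PcaModel":
        path = Path(path)
        manifest = json.loads(path.with_suffix(".json").read_text())
        if manifest.get("artifact") != "pca_model":
            raise ValidationError(f"{path}: not a PCA model artifact")
        arrays = np.load(path.with_suffix(".npz"))
        return cls(
            mean_vector=arrays["mean_vector"],
            components=arrays["components"],
            explained_variance_ratio=arrays["explained_variance_ratio"],
            threshold=manifest["threshold"],
            selected_k=manifest["selected_k"],
        )


def _fix_signs(components: np.ndarray) -> np.ndarray:
    # make each component's largest-magnitude loading positive
    idx = np.argmax(np.abs(components), axis=1)
    signs = np.sign(components[np.arange(components.shape[0]), idx])
    signs[signs == 0] = 1.0
    return components * signs[:, None]


def fit_pca(X: np.ndarray, threshold: float = 0.95) -> PcaModel:
    """Fit mean-centred PCA on X (N x p) without selecting k yet.

    Explained-variance ratios are the covariance eigenvalues normalised to sum
    to 1.  A constant X (zero total variance) raises
    :class:`DegenerateInputError`.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 1:
        raise ValidationError(f"X must be N x p with N >= 2, got shape {X.shape}")
    if np.allclose(X.var(axis=0), 0.0):
        raise DegenerateInputError("X has zero total variance; PCA undefined")
    pca = PCA(svd_solver="full")
    pca.fit(X)
    return PcaModel(
        mean_vector=pca.mean_,
        components=_fix_signs(pca.components_),
        explained_variance_ratio=pca.explained_variance_ratio_,
        threshold=threshold,
    )


def select_components(ratios: np.ndarray, threshold: float = 0.95) -> int:
    """Smallest k whose cumulative explained-variance ratio reaches threshold.

    "Reaches" is implemented as >= so an exact hit counts.  If the full sum
    stays below the threshold (rank-deficient tail dropped by the solver), all
    components are kept with a warning.
    """
    ratios = np.asarray(ratios, dtype=float)
    if ratios.size == 0:
        raise ValidationError("empty explained-variance ratio sequence")
    if np.any(ratios < -1e-12):
        raise ValidationError("explained-variance ratios must be nonnegative")
    if not (0.0 < threshold <= 1.0):
        raise ValidationError(f"threshold must be in (0, 1], got {threshold}")
    cumulative = np.cumsum(ratios)
    hits = np.nonzero(cumulative >= threshold - 1e-12)[0]
    if hits.size == 0:
        warnings.warn(
            f"cumulative variance tops out at {cumulative[-1]:.4f} < {threshold}; "
            "keeping all components",
            stacklevel=2,
        )
        return int(ratios.size)
    return int(hits[0]) + 1


def fit_transform(
    X: np.ndarray, threshold: float = 0.95
) -> tuple[np.ndarray, PcaModel]:
    """Fit, select k at ``threshold`` and project X in one call."""
    model = fit_pca(X, threshold)
    model.select()
    return model.transform(X), model


def threshold_scan(
    ratios: np.ndarray, thresholds: np.ndarray | None = None
) -> list[tuple[float, int]]:
    """Component counts over a grid of cumulative-variance thresholds.

    Default grid: 5% to 100% in 5% steps (0% would select nothing and is not a
    valid threshold).
    """
    if thresholds is None:
        thresholds = np.arange(0.05, 1.0001, 0.05)
    return [(float(t), select_components(ratios, float(t))) for t in thresholds]
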