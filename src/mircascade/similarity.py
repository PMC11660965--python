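"""Gaussian interaction-profile (GIP) kernel similarity and similarity fusion.

The GIP kernel measures how similarly two miRNAs (or diseases) behave across
the association matrix: K(i, j) = exp(-gamma * ||IP_i - IP_j||^2), with the
bandwidth gamma normalised by the mean squared profile norm,

    gamma = gamma' / ( (1/n) * sum_i ||IP_i||^2 ),   gamma' = 1 by default,

so that the kernel scale adapts to the density of the adjacency.

Fusion combines a precomputed similarity (miRNA functional similarity MFS, or
disease semantic similarity DSS) with the GIP kernel: where the precomputed
entry is nonzero the two are averaged; where it is zero (no curated similarity
available for that pair) the GIP value is used alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .data_io import AssociationMatrix, SimilarityMatrix, ValidationError


class DegenerateInputError(ValueError):
    """The input admits no well-defined result (e.g. all-zero profiles)."""


@dataclass(frozen=True)
class GipBandwidth:
    """GIP kernel bandwidth: gamma = gamma_prime / mean squared profile norm."""

    gamma: float
    gamma_prime: float
    n_profiles: int
    mean_sq_norm: float

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise DegenerateInputError("bandwidth gamma must be positive")


def gip_bandwidth(profiles: np.ndarray, gamma_prime: float = 1.0) -> GipBandwidth:
    """Compute the profile-normalised kernel bandwidth.

    Parameters
    ----------
    profiles : (n, p) array
        Binary interaction profiles, one per row (miRNA rows of A, or disease
        columns of A transposed).
    gamma_prime : float
        Numerator constant, 1 by default.

    Raises
    ------
    DegenerateInputError
        If every profile is all-zero: the mean squared norm is 0 and the
        bandwidth is undefined.
    """
    profiles = np.asarray(profiles, dtype=float)
    if profiles.ndim != 2 or profiles.shape[0] < 1:
        raise ValidationError("profiles must be a non-empty 2-D array")
    if gamma_prime <= 0:
        raise ValidationError("gamma_prime must be positive")
    mean_sq_norm = float((profiles**2).sum(axis=1).mean())
    if mean_sq_norm == 0.0:
        raise DegenerateInputError(
            "all interaction profiles are zero; GIP bandwidth undefined"
        )
    return GipBandwidth(
        gamma=gamma_prime / mean_sq_norm,
        gamma_prime=gamma_prime,
        n_profiles=profiles.shape[0],
        mean_sq_norm=mean_sq_norm,
    )


def gip_kernel(
    profiles: np.ndarray,
    bandwidth: GipBandwidth | None = None,
    *,
    ids: list[str] | None = None,
    kind: str = "GIP_m",
) -> SimilarityMatrix:
    """Gaussian interaction-profile kernel matrix over profile rows.

    K[i, j] = exp(-gamma * ||IP_i - IP_j||^2); symmetric, unit diagonal,
    entries in (0, 1].  ``bandwidth`` defaults to :func:`gip_bandwidth` of the
    same profiles with gamma' = 1.
    """
    profiles = np.asarray(profiles, dtype=float)
    if bandwidth is None:
        bandwidth = gip_bandwidth(profiles)
    sq_dists = squareform(pdist(profiles, metric="sqeuclidean"))
    values = np.exp(-bandwidth.gamma * sq_dists)
    np.fill_diagonal(values, 1.0)
    values = 0.5 * (values + values.T)  # guard against fp asymmetry
    if ids is None:
        ids = [f"p{i}" for i in range(profiles.shape[0])]
    return SimilarityMatrix(values, ids, kind)


def mirna_gip(adjacency: AssociationMatrix, gamma_prime: float = 1.0) -> SimilarityMatrix:
    """GIP kernel over miRNA interaction profiles (rows of A)."""
    bw = gip_bandwidth(adjacency.values, gamma_prime)
    return gip_kernel(adjacency.values, bw, ids=adjacency.mirna_ids, kind="GIP_m")


def disease_gip(adjacency: AssociationMatrix, gamma_prime: float = 1.0) -> SimilarityMatrix:
    """GIP kernel over disease interaction profiles (columns of A)."""
    bw = gip_bandwidth(adjacency.values.T, gamma_prime)
    return gip_kernel(adjacency.values.T, bw, ids=adjacency.disease_ids, kind="GIP_d")


def fuse(primary: SimilarityMatrix, gip: SimilarityMatrix) -> SimilarityMatrix:
    """Fuse a precomputed similarity with the GIP kernel, elementwise.

    Where the precomputed entry is nonzero: (primary + gip) / 2.
    Where it is exactly zero (no curated similarity): the GIP value alone.
    A zero on the primary diagonal therefore falls back to gip = 1, so the
    fused diagonal is always 1.
    """
    if primary.values.shape != gip.values.shape:
        raise ValidationError(
            f"shape mismatch: {primary.values.shape} vs {gip.values.shape}"
        )
    if primary.ids != gip.ids:
        raise ValidationError("id order mismatch between primary and GIP matrices")
    exists = primary.values != 0.0
    fused = np.where(exists, 0.5 * (primary.values + gip.values), gip.values)
    kind = "SM" if gip.kind == "GIP_m" else "SD"
    return SimilarityMatrix(fused, list(primary.ids), kind)


def fused_similarities(
    adjacency: AssociationMatrix,
    mfs: SimilarityMatrix,
    dss: SimilarityMatrix,
    gamma_prime: float = 1.0,
) -> tuple[SimilarityMatrix, SimilarityMatrix]:
    """Convenience: compute both fused matrices SM and SD from A, MFS, DSS."""
    mfs = mfs.reindex(adjacency.mirna_ids)
    dss = dss.reindex(adjacency.disease_ids)
    sm = fuse(mfs, mirna_gip(adjacency, gamma_prime))
    sd = fuse(dss, disease_gip(adjacency, gamma_prime))
    return sm, sd
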