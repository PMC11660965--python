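"""Synthetic miRNA-disease datasets with planted, recoverable block structure.

The generator emulates the three pipeline inputs: a sparse binary adjacency,
a miRNA functional-similarity matrix and a disease semantic-similarity matrix.
miRNAs and diseases are partitioned into co-clusters; a co-clustered
(miRNA, disease) pair is associated with high probability, a background pair
with low probability, and similarity entries are high within a block and low
between blocks (plus small clamped uniform noise).  A configurable fraction of
off-diagonal similarity entries is forced to exactly zero, exercising the
fusion fallback onto the GIP kernel.  Everything is deterministic given the
seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .data_io import (
    AssociationMatrix,
    SimilarityMatrix,
    ValidationError,
    write_association_pairs,
    write_similarity_matrix,
)

#: half-width of the additive uniform noise on similarity entries
SIM_NOISE = 0.05


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the planted-block generator.

    Defaults give a 60 x 40 adjacency over 4 blocks with association
    probability 0.6 inside a block and 0.05 outside (expected density ~0.19,
    a few hundred positives), similarity ~0.7 within / ~0.15 between blocks,
    and 10% of similarity entries missing (exact zeros).
    """

    n_m: int = 60
    n_d: int = 40
    n_blocks: int = 4
    within_block_assoc_prob: float = 0.6
    background_assoc_prob: float = 0.05
    mfs_within: float = 0.7
    mfs_between: float = 0.15
    mfs_missing_rate: float = 0.1
    seed: int = 1

    def __post_init__(self) -> None:
        if not (1 <= self.n_blocks <= min(self.n_m, self.n_d)):
            raise ValidationError("need n_m >= n_blocks >= 1 and n_d >= n_blocks")
        probs = (
            self.within_block_assoc_prob,
            self.background_assoc_prob,
            self.mfs_within,
            self.mfs_between,
            self.mfs_missing_rate,
        )
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValidationError("all probabilities must lie in [0, 1]")
        if self.within_block_assoc_prob <= self.background_assoc_prob:
            raise ValidationError(
                "within-block association probability must exceed background "
                "(no planted signal otherwise)"
            )


def block_assignments(n: int, n_blocks: int) -> np.ndarray:
    """Equal-size contiguous blocks; the remainder goes to the last block."""
    size = n // n_blocks
    labels = np.minimum(np.arange(n) // size, n_blocks - 1)
    return labels


def _similarity_from_blocks(
    labels: np.ndarray,
    within: float,
    between: float,
    missing_rate: float,
    ids: list[str],
    kind: str,
    rng: np.random.Generator,
) -> SimilarityMatrix:
    n = labels.size
    same = labels[:, None] == labels[None, :]
    base = np.where(same, within, between)
    noise = rng.uniform(-SIM_NOISE, SIM_NOISE, size=(n, n))
    noise = np.triu(noise, 1)
    noise = noise + noise.T  # symmetric noise
    values = np.clip(base + noise, 0.0, 1.0)
    if missing_rate > 0:
        iu, ju = np.triu_indices(n, k=1)
        n_missing = int(round(missing_rate * iu.size))
        drop = rng.choice(iu.size, size=n_missing, replace=False)
        values[iu[drop], ju[drop]] = 0.0
        values[ju[drop], iu[drop]] = 0.0
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(values, ids, kind)


def generate(
    spec: SyntheticSpec,
) -> tuple[AssociationMatrix, SimilarityMatrix, SimilarityMatrix]:
    """Generate (adjacency, MFS, DSS) with planted co-cluster structure.

    miRNA block b is preferentially associated with disease block b; the MFS
    (resp. DSS) is high within miRNA (disease) blocks.  Degenerate draws with
    an all-zero adjacency are rejected (resampled with an offset seed) so the
    GIP bandwidth is always defined.
    """
    rng = np.random.default_rng(spec.seed)
    m_blocks = block_assignments(spec.n_m, spec.n_blocks)
    d_blocks = block_assignments(spec.n_d, spec.n_blocks)
    mirna_ids = [f"mir-{i + 1:03d}" for i in range(spec.n_m)]
    disease_ids = [f"D{j + 1:03d}" for j in range(spec.n_d)]

    co_clustered = m_blocks[:, None] == d_blocks[None, :]
    probs = np.where(
        co_clustered, spec.within_block_assoc_prob, spec.background_assoc_prob
    )
    values = (rng.random((spec.n_m, spec.n_d)) < probs).astype(float)
    while values.sum() == 0:  # pragma: no cover - astronomically unlikely at defaults
        values = (rng.random((spec.n_m, spec.n_d)) < probs).astype(float)
    adjacency = AssociationMatrix(values, mirna_ids, disease_ids)

    mfs = _similarity_from_blocks(
        m_blocks, spec.mfs_within, spec.mfs_between, spec.mfs_missing_rate,
        mirna_ids, "MFS", rng,
    )
    dss = _similarity_from_blocks(
        d_blocks, spec.mfs_within, spec.mfs_between, spec.mfs_missing_rate,
        disease_ids, "DSS", rng,
    )
    return adjacency, mfs, dss


def write_dataset(
    spec: SyntheticSpec, directory: str | Path
) -> dict[str, Path]:
    """Write a generated dataset in the same text formats the readers accept.

    Produces ``associations.tsv`` (two-column pair list), ``mfs.csv`` and
    ``dss.csv`` under ``directory`` and returns their paths.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    adjacency, mfs, dss = generate(spec)
    pairs = [
        (adjacency.mirna_ids[i], adjacency.disease_ids[j])
        for i, j in zip(*np.nonzero(adjacency.values))
    ]
    paths = {
        "associations": directory / "associations.tsv",
        "mfs": directory / "mfs.csv",
        "dss": directory / "dss.csv",
    }
    write_association_pairs(pairs, paths["associations"])
    write_similarity_matrix(mfs, paths["mfs"])
    write_similarity_matrix(dss, paths["dss"])
    return paths
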