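"""Per-pair feature construction and balanced sampling.

Each (miRNA i, disease j) pair is described by the concatenation

    [ SM[i, :] | A[:, j] | SD[j, :] | A[i, :] ]

i.e. the miRNA's fused-similarity row plus the disease's interaction profile
(the miRNA-side block, 2 * n_m columns), followed by the disease's
fused-similarity row plus the miRNA's interaction profile (the disease-side
block, 2 * n_d columns).  Over all pairs this yields n_m * n_d rows and
2 * n_m + 2 * n_d columns.

Training sets are balanced: every known association is a positive, and an
equal number of unknown pairs is drawn uniformly at random (seeded, without
replacement) as negatives.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data_io import AssociationMatrix, SimilarityMatrix, ValidationError


@dataclass
class PairFeatureTable:
    """Feature rows for (miRNA, disease) pairs.

    ``features`` has one row per pair in ``rows`` and
    ``2 * n_mirnas + 2 * n_diseases`` columns; ``labels`` is optional.
    """

    rows: list[tuple[int, int]]
    features: np.ndarray
    n_mirnas: int
    n_diseases: int
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=np.float64)
        if self.features.shape != (len(self.rows), self.n_columns):
            raise ValidationError(
                f"feature matrix shape {self.features.shape} != "
                f"({len(self.rows)}, {self.n_columns})"
            )
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape != (len(self.rows),):
                raise ValidationError("label vector length does not match rows")

    @property
    def n_columns(self) -> int:
        return 2 * self.n_mirnas + 2 * self.n_diseases

    @property
    def mirna_block_width(self) -> int:
        """Width of the miRNA-side block [SM row | A column]."""
        return 2 * self.n_mirnas

    @property
    def disease_block_width(self) -> int:
        """Width of the disease-side block [SD row | A row]."""
        return 2 * self.n_diseases

    def column_blocks(self) -> dict[str, slice]:
        """Column slices of the four concatenated segments of each row."""
        n_m, n_d = self.n_mirnas, self.n_diseases
        return {
            "sm_row": slice(0, n_m),
            "a_col": slice(n_m, 2 * n_m),
            "sd_row": slice(2 * n_m, 2 * n_m + n_d),
            "a_row": slice(2 * n_m + n_d, 2 * n_m + 2 * n_d),
        }

    def to_frame(self) -> pd.DataFrame:
        """Export as a DataFrame: pair_i, pair_j, [label,] f_0001..f_k."""
        width = len(str(self.n_columns))
        cols = [f"f_{c + 1:0{width}d}" for c in range(self.n_columns)]
        frame = pd.DataFrame(self.features, columns=cols)
        frame.insert(0, "pair_j", [j for _, j in self.rows])
        frame.insert(0, "pair_i", [i for i, _ in self.rows])
        if self.labels is not None:
            frame.insert(2, "label", self.labels)
        return frame

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def save(self, path: str | Path) -> None:
        """Compact binary cache (npz) for fast reload of large tables."""
        np.savez_compressed(
            path,
            rows=np.asarray(self.rows, dtype=np.int64),
            features=self.features,
            n_mirnas=self.n_mirnas,
            n_diseases=self.n_diseases,
            labels=np.asarray([]) if self.labels is None else self.labels,
        )

    @classmethod
    def load(cls, path: str | Path) -> "PairFeatureTable":
        data = np.load(path)
        labels = data["labels"] if data["labels"].size else None
        return cls(
            rows=[tuple(r) for r in data["rows"]],
            features=data["features"],
            n_mirnas=int(data["n_mirnas"]),
            n_diseases=int(data["n_diseases"]),
            labels=labels,
        )


@dataclass(frozen=True)
class BalancedSample:
    """Row indices of the balanced training set: all positives + sampled negatives."""

    positive_rows: list[tuple[int, int]]
    negative_rows: list[tuple[int, int]]
    seed: int

    def __post_init__(self) -> None:
        if len(self.positive_rows) != len(self.negative_rows):
            raise ValidationError("balanced sample requires equal class sizes")
        if set(self.positive_rows) & set(self.negative_rows):
            raise ValidationError("positive and negative pair sets overlap")


def build_feature_table(
    sm: SimilarityMatrix,
    sd: SimilarityMatrix,
    adjacency: AssociationMatrix,
    pair_subset: list[tuple[int, int]] | None = None,
) -> PairFeatureTable:
    """Assemble feature rows [SM[i,:] | A[:,j] | SD[j,:] | A[i,:]] per pair.

    ``pair_subset`` restricts to the given (i, j) index pairs; the default is
    all n_m * n_d pairs in row-major order.
    """
    A = adjacency.values
    n_m, n_d = A.shape
    if sm.n != n_m:
        raise ValidationError(f"SM is {sm.n}x{sm.n} but A has {n_m} miRNA rows")
    if sd.n != n_d:
        raise ValidationError(f"SD is {sd.n}x{sd.n} but A has {n_d} disease columns")
    if pair_subset is None:
        pairs = [(i, j) for i in range(n_m) for j in range(n_d)]
    else:
        pairs = [(int(i), int(j)) for i, j in pair_subset]
        for i, j in pairs:
            if not (0 <= i < n_m and 0 <= j < n_d):
                raise ValidationError(f"pair index ({i}, {j}) out of range")
    ii = np.array([i for i, _ in pairs], dtype=np.intp)
    jj = np.array([j for _, j in pairs], dtype=np.intp)
    features = np.hstack([sm.values[ii], A[:, jj].T, sd.values[jj], A[ii, :]])
    return PairFeatureTable(pairs, features, n_m, n_d)


def sample_negatives(
    adjacency: AssociationMatrix,
    count: int,
    seed: int,
    exclude_disease: int | None = None,
) -> list[tuple[int, int]]:
    """Uniform sample without replacement over the zero entries of A.

    ``exclude_disease`` removes one disease column from the candidate pool —
    used by the leave-one-disease-out protocol so the pairs being ranked are
    never handed to the model as labeled negatives.
    """
    eligible = adjacency.values == 0.0
    if exclude_disease is not None:
        eligible = eligible.copy()
        eligible[:, exclude_disease] = False
    zero_i, zero_j = np.nonzero(eligible)
    n_zero = zero_i.size
    if count > n_zero:
        raise ValidationError(
            f"requested {count} negatives but only {n_zero} unknown pairs exist"
        )
    rng = np.random.default_rng(seed)
    picked = rng.choice(n_zero, size=count, replace=False)
    return [(int(zero_i[k]), int(zero_j[k])) for k in picked]


def assemble_balanced(
    sm: SimilarityMatrix,
    sd: SimilarityMatrix,
    adjacency: AssociationMatrix,
    seed: int,
    exclude_disease: int | None = None,
) -> tuple[PairFeatureTable, BalancedSample]:
    """Build the labeled balanced training table.

    All known associations (label 1, row-major order) followed by an
    equal-size seeded negative sample (label 0, sample order).
    ``exclude_disease`` is forwarded to :func:`sample_negatives`.
    """
    pos_i, pos_j = np.nonzero(adjacency.values == 1.0)
    positives = [(int(i), int(j)) for i, j in zip(pos_i, pos_j)]
    n_pos = len(positives)
    if n_pos == 0:
        raise ValidationError("adjacency contains no known associations")
    if adjacency.n_unknown < n_pos:
        raise ValidationError("fewer unknown pairs than known associations")
    negatives = sample_negatives(adjacency, n_pos, seed, exclude_disease)
    table = build_feature_table(sm, sd, adjacency, positives + negatives)
    table.labels = np.concatenate([np.ones(n_pos), np.zeros(n_pos)])
    return table, BalancedSample(positives, negatives, seed)
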