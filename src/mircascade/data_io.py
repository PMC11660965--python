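"""Reading, writing and validation of association lists and similarity matrices.

The central objects are :class:`AssociationMatrix` — the binary miRNA x disease
adjacency ``A`` whose rows are miRNA interaction profiles and whose columns are
disease interaction profiles — and :class:`SimilarityMatrix`, a square symmetric
matrix in [0, 1] holding any of the similarity kinds used by the pipeline
(precomputed functional/semantic similarity, Gaussian interaction-profile
kernels, or the fused matrices).

Association lists are two-column delimited text (miRNA id, disease id), one
association per line, as distributed with HMDD-style datasets.  Similarity
matrices are CSV/TSV with an id header row and an id first column.  Id matching
is exact and case-sensitive after trimming surrounding whitespace.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: tolerance for symmetry / diagonal checks on similarity matrices
SYMMETRY_TOL = 1e-10

SIMILARITY_KINDS = ("MFS", "DSS", "GIP_m", "GIP_d", "SM", "SD")


class ValidationError(ValueError):
    """An input matrix or record failed a structural validation check."""


class ParseError(ValidationError):
    """A delimited record could not be parsed; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


@dataclass
class AssociationMatrix:
    """Binary adjacency between miRNAs (rows) and diseases (columns).

    ``values[i, j] == 1`` iff miRNA ``mirna_ids[i]`` is associated with disease
    ``disease_ids[j]``.  Row ``i`` is the interaction profile IP(m_i) of the
    i-th miRNA; column ``j`` is IP(d_j).
    """

    values: np.ndarray
    mirna_ids: list[str]
    disease_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mirna_ids = [str(m) for m in self.mirna_ids]
        self.disease_ids = [str(d) for d in self.disease_ids]
        self.validate()

    def validate(self) -> None:
        n_m, n_d = self.values.shape
        if len(self.mirna_ids) != n_m or len(self.disease_ids) != n_d:
            raise ValidationError(
                f"id lists ({len(self.mirna_ids)}, {len(self.disease_ids)}) do not "
                f"match matrix shape {self.values.shape}"
            )
        for name, ids in (("miRNA", self.mirna_ids), ("disease", self.disease_ids)):
            if len(set(ids)) != len(ids):
                raise ValidationError(f"duplicate {name} ids")
        if not np.isin(self.values, (0.0, 1.0)).all():
            raise ValidationError("adjacency entries must be exactly 0 or 1")

    @property
    def n_mirnas(self) -> int:
        return self.values.shape[0]

    @property
    def n_diseases(self) -> int:
        return self.values.shape[1]

    @property
    def n_positives(self) -> int:
        """Number of known associations (ones in A)."""
        return int(self.values.sum())

    @property
    def n_unknown(self) -> int:
        """Number of unvalidated pairs (zeros in A)."""
        return self.values.size - self.n_positives

    def mirna_profile(self, i: int) -> np.ndarray:
        """Interaction profile IP(m_i): row i of A."""
        return self.values[i, :]

    def disease_profile(self, j: int) -> np.ndarray:
        """Interaction profile IP(d_j): column j of A."""
        return self.values[:, j]

    def mask_disease(self, disease_id: str) -> "AssociationMatrix":
        """Return a copy with the given disease's column zeroed (case study)."""
        try:
            j = self.disease_ids.index(disease_id)
        except ValueError:
            raise KeyError(f"unknown disease id: {disease_id!r}") from None
        values = self.values.copy()
        values[:, j] = 0.0
        return AssociationMatrix(values, list(self.mirna_ids), list(self.disease_ids))


@dataclass
class SimilarityMatrix:
    """Square symmetric similarity matrix with entries in [0, 1].

    ``kind`` records the provenance: MFS/DSS (precomputed inputs), GIP_m/GIP_d
    (Gaussian interaction-profile kernels) or SM/SD (fused).  GIP and fused
    matrices additionally have a unit diagonal; precomputed MFS/DSS are allowed
    an arbitrary diagonal in [0, 1] (zero diagonals occur in real data and are
    handled by the fusion fallback).
    """

    values: np.ndarray
    ids: list[str]
    kind: str = "MFS"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.ids = [str(i) for i in self.ids]
        self.validate()

    def validate(self) -> None:
        if self.kind not in SIMILARITY_KINDS:
            raise ValidationError(f"unknown similarity kind {self.kind!r}")
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValidationError(f"similarity matrix must be square, got {v.shape}")
        if len(self.ids) != v.shape[0]:
            raise ValidationError("id list length does not match matrix size")
        if len(set(self.ids)) != len(self.ids):
            raise ValidationError("duplicate ids in similarity matrix")
        max_asym = float(np.abs(v - v.T).max(initial=0.0))
        if max_asym > SYMMETRY_TOL:
            raise ValidationError(f"matrix asymmetric (max |S - S^T| = {max_asym:.3g})")
        if v.size and (v.min() < -SYMMETRY_TOL or v.max() > 1 + SYMMETRY_TOL):
            raise ValidationError(
                f"entries outside [0, 1] (min {v.min():.3g}, max {v.max():.3g})"
            )
        if self.kind in ("GIP_m", "GIP_d", "SM", "SD"):
            diag_err = float(np.abs(np.diag(v) - 1.0).max(initial=0.0))
            if diag_err > SYMMETRY_TOL:
                raise ValidationError(
                    f"{self.kind} diagonal must be 1 (max deviation {diag_err:.3g})"
                )

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def reindex(self, ids: Sequence[str]) -> "SimilarityMatrix":
        """Return a copy with rows/columns permuted into the given id order."""
        ids = [str(i) for i in ids]
        missing = set(ids) - set(self.ids)
        extra = set(self.ids) - set(ids)
        if missing or extra:
            raise ValidationError(
                f"id mismatch: missing {sorted(missing)[:5]}, unexpected {sorted(extra)[:5]}"
            )
        pos = {s: k for k, s in enumerate(self.ids)}
        perm = np.array([pos[s] for s in ids])
        return SimilarityMatrix(self.values[np.ix_(perm, perm)], ids, self.kind)


def parse_association_pairs(
    text_lines: Iterable[str], delimiter: str = "\t"
) -> list[tuple[str, str]]:
    """Parse delimited (miRNA id, disease id) records into de-duplicated pairs.

    First-seen order is preserved; duplicates are collapsed with a log message
    (HMDD lists one association per evidence line, so repeats are expected).
    A record with fewer than two non-empty fields raises :class:`ParseError`
    naming the offending line.
    """
    seen: dict[tuple[str, str], None] = {}
    n_dupes = 0
    for lineno, raw in enumerate(text_lines, start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        fields = [f.strip() for f in line.split(delimiter)]
        fields = [f for f in fields if f]
        if len(fields) < 2:
            raise ParseError(
                f"expected at least 2 fields separated by {delimiter!r}, got {line!r}",
                lineno,
            )
        pair = (fields[0], fields[1])
        if pair in seen:
            n_dupes += 1
        else:
            seen[pair] = None
    if n_dupes:
        logger.warning("collapsed %d duplicate association record(s)", n_dupes)
    return list(seen)


def build_adjacency(
    pairs: Iterable[tuple[str, str]],
    mirna_ids: Sequence[str],
    disease_ids: Sequence[str],
) -> AssociationMatrix:
    """Build the binary adjacency A from (miRNA, disease) pairs.

    A[i, j] = 1 iff (mirna_ids[i], disease_ids[j]) appears in ``pairs``.
    An id absent from the corresponding list raises :class:`ValidationError`
    naming it.
    """
    mirna_ids = [str(m).strip() for m in mirna_ids]
    disease_ids = [str(d).strip() for d in disease_ids]
    m_index = {m: i for i, m in enumerate(mirna_ids)}
    d_index = {d: j for j, d in enumerate(disease_ids)}
    values = np.zeros((len(mirna_ids), len(disease_ids)))
    for m, d in pairs:
        m, d = str(m).strip(), str(d).strip()
        if m not in m_index:
            raise ValidationError(f"unknown miRNA id in pair list: {m!r}")
        if d not in d_index:
            raise ValidationError(f"unknown disease id in pair list: {d!r}")
        values[m_index[m], d_index[d]] = 1.0
    return AssociationMatrix(values, mirna_ids, disease_ids)


def _detect_delimiter(path: Path) -> str:
    with open(path) as fh:
        first = fh.readline()
    return "\t" if first.count("\t") >= first.count(",") else ","


def read_association_pairs(path: str | Path, delimiter: str | None = None) -> list[tuple[str, str]]:
    """Read a 2-column association list; a non-numeric-free header is tolerated."""
    path = Path(path)
    if delimiter is None:
        delimiter = _detect_delimiter(path)
    with open(path) as fh:
        return parse_association_pairs(fh, delimiter=delimiter)


def read_similarity_matrix(
    path: str | Path,
    expected_ids: Sequence[str] | None = None,
    kind: str = "MFS",
) -> SimilarityMatrix:
    """Read a similarity matrix from CSV/TSV with id header row and column.

    The matrix is validated (square, symmetric within tolerance, entries in
    [0, 1]) and, when ``expected_ids`` is given, reindexed into that order;
    an id mismatch is an error.
    """
    path = Path(path)
    sep = _detect_delimiter(path)
    frame = pd.read_csv(path, sep=sep, index_col=0)
    ids = [str(i).strip() for i in frame.index]
    col_ids = [str(c).strip() for c in frame.columns]
    if ids != col_ids:
        raise ValidationError("row ids and column ids differ (matrix must be square)")
    sim = SimilarityMatrix(frame.to_numpy(dtype=float), ids, kind)
    if expected_ids is not None:
        sim = sim.reindex(expected_ids)
    return sim


def write_similarity_matrix(sim: SimilarityMatrix, path: str | Path) -> None:
    """Write a similarity matrix as delimited text (TSV for .tsv, else CSV)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    frame = pd.DataFrame(sim.values, index=sim.ids, columns=sim.ids)
    frame.to_csv(path, sep=sep, float_format="%.17g")


def write_association_pairs(
    pairs: Iterable[tuple[str, str]], path: str | Path, delimiter: str = "\t"
) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for m, d in pairs:
            fh.write(f"{m}{delimiter}{d}\n")
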