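"""Pairwise protein sequence similarity under a substitution matrix.

The raw score ``bl(i, j)`` is the optimal global (Needleman-Wunsch)
alignment score of sequences *i* and *j* under BLOSUM50 with affine gap
penalties.  Raw scores are then normalized row-wise as

    bl~(i, j) = (bl(i, j) - min_k bl(i, k)) / max_k bl(i, k)

with the minimum and maximum taken over the full row, self-score included.
Because the denominator is the row maximum (not the max-min range), the
normalized values are not guaranteed to lie in [0, 1] when a row contains
negative scores; the formula is applied as stated rather than corrected.
The row-wise normalization is asymmetric, so pair ranking uses the
symmetrized mean ``s(i, j) = (bl~(i, j) + bl~(j, i)) / 2``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices

from .data_io import STANDARD_RESIDUES, DataError, ProteinSet


@dataclass
class SubstitutionMatrix:
    """A residue substitution scoring scheme with affine gap penalties.

    A gap of length L costs ``gap_open + (L - 1) * gap_extend`` (the first
    gapped position pays the opening penalty, each further position the
    extension penalty).  End gaps are penalized like internal ones.
    """

    scores: "substitution_matrices.Array"
    gap_open: float = 10.0
    gap_extend: float = 0.5
    name: str = "BLOSUM50"

    def __post_init__(self) -> None:
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be non-negative")
        arr = np.asarray(self.scores)
        if not np.array_equal(arr, arr.T):
            raise ValueError("substitution matrix must be symmetric")

    def score(self, a: str, b: str) -> float:
        return float(self.scores[a, b])

    @classmethod
    def blosum50(cls, gap_open: float = 10.0, gap_extend: float = 0.5
                 ) -> "SubstitutionMatrix":
        return cls(substitution_matrices.load("BLOSUM50"), gap_open, gap_extend)

    @classmethod
    def from_file(cls, path: str | Path, gap_open: float = 10.0,
                  gap_extend: float = 0.5) -> "SubstitutionMatrix":
        """Load a matrix in NCBI/EMBOSS text format."""
        with open(path) as fh:
            scores = substitution_matrices.read(fh)
        return cls(scores, gap_open, gap_extend, name=Path(path).stem)


def _make_aligner(matrix: SubstitutionMatrix) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = matrix.scores
    aligner.open_gap_score = -matrix.gap_open
    aligner.extend_gap_score = -matrix.gap_extend
    return aligner


def _check_sequence(seq: str) -> None:
    if not seq:
        raise DataError("sequence must be non-empty")
    bad = set(seq) - STANDARD_RESIDUES
    if bad:
        raise DataError(f"non-standard residue(s) {sorted(bad)}")


def alignment_score(
    seq_a: str, seq_b: str, matrix: SubstitutionMatrix | None = None
) -> float:
    """Optimal global alignment score of two sequences.

    Symmetric in its arguments.  Defaults to BLOSUM50 with gap_open=10,
    gap_extend=0.5.
    """
    if matrix is None:
        matrix = SubstitutionMatrix.blosum50()
    _check_sequence(seq_a)
    _check_sequence(seq_b)
    return float(_make_aligner(matrix).score(seq_a, seq_b))


def normalize_row(raw_row: np.ndarray) -> np.ndarray:
    """Row-wise score normalization: subtract the row min, divide by the
    row max.  The row max must be nonzero."""
    row = np.asarray(raw_row, dtype=float)
    if row.ndim != 1 or row.size < 1:
        raise ValueError("raw_row must be a non-empty 1-D array")
    row_max = row.max()
    if row_max == 0:
        raise ValueError("degenerate row: row maximum is 0")
    return (row - row.min()) / row_max


class SimilarityTable:
    """Raw, normalized and symmetrized pairwise similarity over a universe.

    Attributes
    ----------
    ids : list of protein ids fixing the row/column order
    raw : symmetric matrix of alignment scores bl(i, j)
    normalized : row-normalized scores (asymmetric in general)
    symmetrized : (normalized + normalized.T) / 2, used for pair ranking
    """

    def __init__(self, ids: list[str], raw: np.ndarray) -> None:
        raw = np.asarray(raw, dtype=float)
        n = len(ids)
        if raw.shape != (n, n):
            raise ValueError("raw matrix shape does not match id list")
        if not np.allclose(raw, raw.T):
            raise ValueError("raw score matrix must be symmetric")
        self.ids = list(ids)
        self._index = {pid: i for i, pid in enumerate(self.ids)}
        self.raw = raw
        self.normalized = np.vstack([normalize_row(raw[i]) for i in range(n)])
        self.symmetrized = (self.normalized + self.normalized.T) / 2.0

    def __len__(self) -> int:
        return len(self.ids)

    def s(self, a: str, b: str) -> float:
        """Symmetrized normalized similarity of an id pair."""
        return float(self.symmetrized[self._index[a], self._index[b]])

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("id\t" + "\t".join(self.ids) + "\n")
            for pid, row in zip(self.ids, self.raw):
                fh.write(pid + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SimilarityTable":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            ids = header[1:]
            raw = np.loadtxt(fh, usecols=range(1, len(ids) + 1), ndmin=2)
        return cls(ids, raw)


def pairwise_similarity(
    proteins: ProteinSet, matrix: SubstitutionMatrix | None = None
) -> SimilarityTable:
    """Compute the full similarity table over a protein universe.

    Exploits symmetry: each unordered pair (and each self-score) is aligned
    once, k(k+1)/2 alignments for k proteins.
    """
    if len(proteins) < 2:
        raise DataError("need at least 2 proteins")
    if matrix is None:
        matrix = SubstitutionMatrix.blosum50()
    for p in proteins:
        _check_sequence(p.sequence)
    aligner = _make_aligner(matrix)
    ids = proteins.ids
    seqs = [proteins[pid].sequence for pid in ids]
    n = len(ids)
    raw = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            score = aligner.score(seqs[i], seqs[j])
            raw[i, j] = raw[j, i] = score
    return SimilarityTable(ids, raw)
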