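"""Auto-covariance (AC) encoding of amino-acid sequences.

Each residue is described by seven physicochemical properties relevant to
the four PPI interaction modes (electrostatic, hydrophobic, hydrogen bond,
steric): hydrophobicity (H1), hydrophilicity (H2), side-chain volume (V),
polarity (P1), polarizability (P2), solvent-accessible surface area (SASA)
and the net charge index of the side chain (NCI).  Property columns are
standardized to zero mean and unit standard deviation over the 20 standard
residues before encoding.

A sequence of length l becomes, for each property j and lag in 1..lg,

    AC(lag, j) = 1/(l - lag) * sum_{i=1}^{l-lag}
                 (A[i, j] - mean_j(A)) * (A[i+lag, j] - mean_j(A))

where A[i, j] is the (normalized) property value of residue i and
mean_j(A) is the mean of property j over the sequence.  With the default
maximum lag lg = 30 each sequence is encoded by a 7 * 30 = 210-dimensional
vector, laid out lag-major: (lag 1, properties 1..7), (lag 2, ...), ...
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .data_io import DataError, Protein, ProteinSet

PROPERTY_NAMES = ("H1", "H2", "V", "P1", "P2", "SASA", "NCI")
DEFAULT_MAX_LAG = 30


class PropertyTable:
    """The 20-residue x 7-property table, raw and column-standardized.

    Standardization uses the population standard deviation (divide by 20):
    the 20 standard residues are the complete alphabet, not a sample.
    """

    def __init__(self, raw: pd.DataFrame) -> None:
        if list(raw.columns) != list(PROPERTY_NAMES):
            raise DataError(f"expected property columns {PROPERTY_NAMES}")
        if raw.shape[0] != 20:
            raise DataError("property table must have exactly 20 residue rows")
        self.raw = raw.astype(float)
        self.normalized = normalize_properties(self.raw)
        self._residue_index = {r: i for i, r in enumerate(self.raw.index)}
        self._norm_values = self.normalized.to_numpy()

    @classmethod
    def default(cls) -> "PropertyTable":
        """The bundled property values."""
        path = resources.files("nipkit") / "data" / "physicochemical_properties.tsv"
        return cls.from_tsv(path)

    @classmethod
    def from_tsv(cls, path) -> "PropertyTable":
        raw = pd.read_csv(path, sep="\t", index_col=0)
        return cls(raw)

    def encode_residues(self, sequence: str) -> np.ndarray:
        """Map a sequence to its (l, 7) matrix of normalized property values."""
        try:
            rows = [self._residue_index[r] for r in sequence]
        except KeyError as exc:
            raise DataError(f"unknown residue {exc.args[0]!r}") from None
        return self._norm_values[rows]


def normalize_properties(raw: pd.DataFrame) -> pd.DataFrame:
    """Standardize each property column to zero mean, unit (population) sd."""
    means = raw.mean(axis=0)
    sds = raw.std(axis=0, ddof=0)
    if (sds == 0).any():
        bad = list(sds.index[sds == 0])
        raise DataError(f"property column(s) with zero standard deviation: {bad}")
    return (raw - means) / sds


def autocovariance(values: np.ndarray, lg: int) -> np.ndarray:
    """Lagged auto-covariance of an (l, p) per-position property matrix.

    Centering uses each property's mean over the sequence; the lag-``lag``
    term averages the ``l - lag`` products of centered values ``lag``
    positions apart.  Output is an ``lg * p`` vector in lag-major order.
    """
    values = np.asarray(values, dtype=float)
    if lg < 1:
        raise ValueError("lg must be >= 1")
    l = values.shape[0]
    if l < lg + 1:
        raise DataError(
            f"sequence length {l} too short for lg={lg}; need at least {lg + 1}"
        )
    centered = values - values.mean(axis=0)
    out = np.empty((lg, values.shape[1]))
    for lag in range(1, lg + 1):
        out[lag - 1] = (centered[:-lag] * centered[lag:]).sum(axis=0) / (l - lag)
    return out.ravel()


def encode_ac(
    sequence: str | Protein,
    lg: int = DEFAULT_MAX_LAG,
    table: PropertyTable | None = None,
) -> np.ndarray:
    """Encode one sequence as its auto-covariance vector.

    Returns a vector of length ``lg * 7`` in lag-major order.  The sequence
    must have length at least ``lg + 1`` so that every lag leaves at least
    one product term.
    """
    if isinstance(sequence, Protein):
        sequence = sequence.sequence
    if table is None:
        table = PropertyTable.default()
    return autocovariance(table.encode_residues(sequence), lg)


def feature_names(lg: int = DEFAULT_MAX_LAG) -> list[str]:
    """Column names matching the lag-major vector layout, e.g. ``lag03_V``."""
    return [
        f"lag{lag:02d}_{prop}"
        for lag in range(1, lg + 1)
        for prop in PROPERTY_NAMES
    ]


def encode_pair(
    prot_a: Protein,
    prot_b: Protein,
    lg: int = DEFAULT_MAX_LAG,
    table: PropertyTable | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Encode a protein pair, ordered canonically (lexicographic by id)."""
    if prot_b.id < prot_a.id:
        prot_a, prot_b = prot_b, prot_a
    return encode_ac(prot_a, lg, table), encode_ac(prot_b, lg, table)


class EncodedPairDataset:
    """AC-encoded labeled pairs ready for the two-tower classifier.

    ``xa`` and ``xb`` hold the encodings of the first and second protein of
    each (canonical) pair; ``y`` the 0/1 labels; ``pairs`` the id pairs.
    """

    def __init__(
        self,
        pairs: list[tuple[str, str]],
        xa: np.ndarray,
        xb: np.ndarray,
        y: np.ndarray,
    ) -> None:
        if not (len(pairs) == len(xa) == len(xb) == len(y)):
            raise ValueError("inconsistent dataset component lengths")
        self.pairs = pairs
        self.xa = np.asarray(xa, dtype=float)
        self.xb = np.asarray(xb, dtype=float)
        self.y = np.asarray(y, dtype=int)

    def __len__(self) -> int:
        return len(self.pairs)

    def subset(self, idx: np.ndarray) -> "EncodedPairDataset":
        return EncodedPairDataset(
            [self.pairs[i] for i in idx], self.xa[idx], self.xb[idx], self.y[idx]
        )

    def augmented(self) -> "EncodedPairDataset":
        """Both orientations of every pair: N pairs become 2N rows.

        The tower architecture is not symmetric in its two inputs, so
        training on both orderings removes the dependence on the canonical
        orientation.
        """
        pairs = self.pairs + [(b, a) for a, b in self.pairs]
        xa = np.vstack([self.xa, self.xb])
        xb = np.vstack([self.xb, self.xa])
        y = np.concatenate([self.y, self.y])
        return EncodedPairDataset(pairs, xa, xb, y)

    def to_tsv(self, path: str | Path, lg: int = DEFAULT_MAX_LAG) -> None:
        names = feature_names(lg)
        cols = (
            ["protein_a", "protein_b", "label"]
            + [f"a_{n}" for n in names]
            + [f"b_{n}" for n in names]
        )
        with open(path, "w") as fh:
            fh.write("\t".join(cols) + "\n")
            for (a, b), ra, rb, label in zip(self.pairs, self.xa, self.xb, self.y):
                vals = [a, b, str(int(label))]
                vals += [repr(float(v)) for v in ra] + [repr(float(v)) for v in rb]
                fh.write("\t".join(vals) + "\n")


def encode_dataset(
    labeled_rows,
    proteins: ProteinSet,
    lg: int = DEFAULT_MAX_LAG,
    table: PropertyTable | None = None,
    augment: bool = False,
) -> EncodedPairDataset:
    """Encode a labeled pair dataset; each distinct protein is encoded once."""
    if table is None:
        table = PropertyTable.default()
    cache: dict[str, np.ndarray] = {}

    def enc(pid: str) -> np.ndarray:
        if pid not in cache:
            cache[pid] = encode_ac(proteins[pid], lg, table)
        return cache[pid]

    pairs: list[tuple[str, str]] = []
    xa, xb, y = [], [], []
    for a, b, label in labeled_rows:
        a, b = (a, b) if a < b else (b, a)
        pairs.append((a, b))
        xa.append(enc(a))
        xb.append(enc(b))
        y.append(label)
    dataset = EncodedPairDataset(pairs, np.array(xa), np.array(xb), np.array(y))
    return dataset.augmented() if augment else dataset
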