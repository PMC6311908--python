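"""Reading, writing and assembly of the datasets the pipeline touches.

Protein universes come in as FASTA, interaction networks as two-column TSV
edge lists, and labeled training sets leave as three-column TSV.  All pair
containers store undirected pairs in canonical form: ``(a, b)`` with
``a < b`` lexicographically, so set operations between positive and negative
sets are well defined.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO

logger = logging.getLogger(__name__)

#: The 20 standard amino-acid one-letter codes.
STANDARD_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")


class DataError(ValueError):
    """Malformed or inconsistent input data."""


@dataclass(frozen=True)
class Protein:
    """A protein identifier with its amino-acid sequence.

    The sequence must be non-empty and contain only the 20 standard
    residues; ambiguous codes (B, J, O, U, X, Z) are rejected because the
    physicochemical property table used downstream covers the standard
    alphabet only.
    """

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise DataError("protein id must be non-empty")
        if not self.sequence:
            raise DataError(f"protein {self.id!r}: sequence must be non-empty")
        bad = set(self.sequence) - STANDARD_RESIDUES
        if bad:
            raise DataError(
                f"protein {self.id!r}: non-standard residue(s) {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


class ProteinSet:
    """An insertion-ordered collection of proteins, indexed by id."""

    def __init__(self, proteins: Iterable[Protein] = ()) -> None:
        self._by_id: dict[str, Protein] = {}
        for p in proteins:
            self.add(p)

    def add(self, protein: Protein) -> None:
        if protein.id in self._by_id:
            raise DataError(f"duplicate protein id {protein.id!r}")
        self._by_id[protein.id] = protein

    def __len__(self) -> int:
        return len(self._by_id)

    def __iter__(self) -> Iterator[Protein]:
        return iter(self._by_id.values())

    def __contains__(self, pid: object) -> bool:
        return pid in self._by_id

    def __getitem__(self, pid: str) -> Protein:
        return self._by_id[pid]

    @property
    def ids(self) -> list[str]:
        return list(self._by_id)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ProteinSet):
            return NotImplemented
        return [(p.id, p.sequence) for p in self] == [
            (p.id, p.sequence) for p in other
        ]


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Return the undirected pair in canonical (lexicographic) order."""
    if a == b:
        raise DataError(f"self-pair ({a!r}, {a!r}) is not a valid pair")
    return (a, b) if a < b else (b, a)


class InteractionSet:
    """A set of canonical undirected protein pairs with a single label."""

    def __init__(
        self, pairs: Iterable[tuple[str, str]] = (), label: str = "positive"
    ) -> None:
        if label not in ("positive", "negative"):
            raise DataError(f"label must be 'positive' or 'negative', got {label!r}")
        self.label = label
        self._pairs: set[tuple[str, str]] = set()
        for a, b in pairs:
            self._pairs.add(canonical_pair(a, b))

    def add(self, a: str, b: str) -> None:
        self._pairs.add(canonical_pair(a, b))

    def __len__(self) -> int:
        return len(self._pairs)

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(sorted(self._pairs))

    def __contains__(self, pair: object) -> bool:
        if isinstance(pair, tuple) and len(pair) == 2:
            a, b = pair
            return ((a, b) if a < b else (b, a)) in self._pairs
        return False

    @property
    def pairs(self) -> frozenset[tuple[str, str]]:
        return frozenset(self._pairs)

    def protein_ids(self) -> list[str]:
        """Sorted distinct ids appearing in at least one pair."""
        seen: set[str] = set()
        for a, b in self._pairs:
            seen.add(a)
            seen.add(b)
        return sorted(seen)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, InteractionSet):
            return NotImplemented
        return self._pairs == other._pairs and self.label == other.label


@dataclass
class LabeledPairSet:
    """Rows of ``(id_a, id_b, label)`` with label 1 = interacting."""

    rows: list[tuple[str, str, int]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self) -> Iterator[tuple[str, str, int]]:
        return iter(self.rows)


def read_fasta(path: str | Path) -> ProteinSet:
    """Load a FASTA file into a :class:`ProteinSet`.

    The id is the header token up to the first whitespace; sequences are
    uppercased.  Records containing non-standard residues are rejected with
    a logged warning rather than silently assigned invented property
    values.  Duplicate ids raise :class:`DataError`.
    """
    proteins = ProteinSet()
    for record in SeqIO.parse(str(path), "fasta"):
        seq = str(record.seq).upper()
        try:
            protein = Protein(record.id, seq, description=record.description)
        except DataError as exc:
            logger.warning("skipping FASTA record %r: %s", record.id, exc)
            continue
        proteins.add(protein)
    return proteins


def write_fasta(proteins: ProteinSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in proteins:
            header = f">{p.id}"
            if p.description and p.description != p.id:
                header = f">{p.description}"
            fh.write(header + "\n")
            for i in range(0, len(p.sequence), 60):
                fh.write(p.sequence[i : i + 60] + "\n")


def filter_min_length(proteins: ProteinSet, min_len: int = 50) -> ProteinSet:
    """Drop proteins shorter than ``min_len`` residues.

    Short sequences carry little interaction-relevant information and break
    the auto-covariance encoder's lag precondition, so the pipeline excludes
    proteins with fewer than 50 amino acids by default.
    """
    if min_len < 1:
        raise DataError("min_len must be >= 1")
    return ProteinSet(p for p in proteins if len(p) >= min_len)


def read_interactions(
    path: str | Path, proteins: ProteinSet, label: str = "positive"
) -> InteractionSet:
    """Read a two-column TSV edge list into an :class:`InteractionSet`.

    Pairs are canonicalized; duplicates, self-pairs and pairs referencing
    ids absent from ``proteins`` are dropped with logged counts.  A header
    line is auto-detected: if neither token of the first line is a known
    protein id, the line is treated as a header.
    """
    result = InteractionSet(label=label)
    n_self = n_dup = n_unknown = 0
    with open(path) as fh:
        lines = fh.read().splitlines()
    start = 0
    if lines:
        first = lines[0].split("\t")
        if len(first) >= 2 and first[0] not in proteins and first[1] not in proteins:
            start = 1
    for lineno, line in enumerate(lines[start:], start=start + 1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise DataError(f"{path}: line {lineno}: expected 2 columns")
        a, b = fields[0].strip(), fields[1].strip()
        if a == b:
            n_self += 1
            continue
        if a not in proteins or b not in proteins:
            n_unknown += 1
            continue
        pair = canonical_pair(a, b)
        if pair in result:
            n_dup += 1
            continue
        result.add(*pair)
    if n_self or n_dup or n_unknown:
        logger.warning(
            "%s: dropped %d self-pairs, %d duplicates, %d pairs with unknown ids",
            path,
            n_self,
            n_dup,
            n_unknown,
        )
    return result


def write_interactions(pairs: InteractionSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_a\tprotein_b\n")
        for a, b in pairs:
            fh.write(f"{a}\t{b}\n")


def assemble_dataset(
    positives: InteractionSet, negatives: InteractionSet
) -> LabeledPairSet:
    """Merge positive and negative pair sets into one labeled dataset.

    Output order is deterministic: sorted positives (label 1) followed by
    sorted negatives (label 0).  Overlapping pairs are a contract violation
    and raise with the offending pairs listed.
    """
    overlap = positives.pairs & negatives.pairs
    if overlap:
        raise DataError(
            f"positives and negatives overlap on {len(overlap)} pair(s): "
            f"{sorted(overlap)[:10]}"
        )
    rows = [(a, b, 1) for a, b in positives] + [(a, b, 0) for a, b in negatives]
    return LabeledPairSet(rows)


def write_labeled(dataset: LabeledPairSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_a\tprotein_b\tlabel\n")
        for a, b, y in dataset:
            fh.write(f"{a}\t{b}\t{y}\n")


def read_localizations(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV of (protein id, subcellular compartment)."""
    table: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 2:
                raise DataError(f"{path}: line {lineno}: expected 2 columns")
            if lineno == 1 and fields[0].lower() in ("protein", "id", "protein_id"):
                continue
            table[fields[0].strip()] = fields[1].strip()
    return table


def write_localizations(table: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tcompartment\n")
        for pid in sorted(table):
            fh.write(f"{pid}\t{table[pid]}\n")
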