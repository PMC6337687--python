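"""FASTA input/output, residue normalization and strand utilities.

Every other module works on :class:`SequenceRecord` objects whose residues
are guaranteed to be uppercase over the alphabet ``{A, C, G, T, N}``.
Coordinates throughout the package are 1-based and fully inclusive.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

__all__ = [
    "SequenceRecord",
    "GenotypeSet",
    "FastaError",
    "EmptyFastaError",
    "MissingHeaderError",
    "DuplicateIdError",
    "AlphabetError",
    "normalize_residues",
    "read_fasta",
    "write_fasta",
    "reverse_complement",
]

_AMBIGUITY_TO_N = str.maketrans({c: "N" for c in "RYSWKMBDHVU"})
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID = frozenset("ACGTN")


class FastaError(ValueError):
    """Base class for FASTA parsing problems."""


class EmptyFastaError(FastaError):
    """The file contains no sequence data at all."""


class MissingHeaderError(FastaError):
    """The first non-blank character is not '>'."""


class DuplicateIdError(FastaError):
    """Two records in one file share the same id."""


class AlphabetError(FastaError):
    """A residue outside the IUPAC nucleotide alphabet was encountered."""


def normalize_residues(raw: str, context: str = "") -> str:
    """Uppercase ``raw`` and map IUPAC ambiguity codes (other than N) to N.

    Raises :class:`AlphabetError` for any character that is not an IUPAC
    nucleotide code. Real assemblies contain ambiguity codes; the pipeline
    treats them as unmatchable, hence the collapse onto N.
    """
    s = raw.upper().translate(_AMBIGUITY_TO_N)
    bad = set(s) - _VALID
    if bad:
        where = f" in {context}" if context else ""
        raise AlphabetError(
            f"invalid residue(s) {sorted(bad)!r}{where}; expected IUPAC nucleotide codes"
        )
    return s


@dataclass(frozen=True)
class SequenceRecord:
    """One FASTA record with normalized residues.

    ``id`` is the first whitespace-delimited token of the header; the full
    header is kept in ``description``.
    """

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise FastaError("record id must be non-empty")
        bad = set(self.residues) - _VALID
        if bad:
            raise AlphabetError(
                f"record {self.id!r} contains non-normalized residues {sorted(bad)!r}"
            )

    @property
    def length(self) -> int:
        return len(self.residues)

    def __len__(self) -> int:  # pragma: no cover - convenience
        return len(self.residues)


@dataclass
class GenotypeSet:
    """An ordered collection of records belonging to one genotype/assembly."""

    genotype_id: str
    records: list[SequenceRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.genotype_id:
            raise ValueError("genotype_id must be non-empty")
        ids = [r.id for r in self.records]
        if len(ids) != len(set(ids)):
            raise DuplicateIdError(
                f"duplicate record ids within genotype {self.genotype_id!r}"
            )

    def __iter__(self):
        return iter(self.records)

    def get(self, seq_id: str) -> SequenceRecord:
        for r in self.records:
            if r.id == seq_id:
                return r
        raise KeyError(seq_id)


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a multi-record FASTA file into normalized records.

    Line breaks inside sequences are removed, lowercase is uppercased and
    ambiguity codes are mapped to N. Distinct errors are raised for an empty
    file, a missing '>' header, duplicate ids and invalid residues.
    """
    path = Path(path)
    text = path.read_text()
    stripped = text.lstrip()
    if not stripped:
        raise EmptyFastaError(f"{path}: file is empty")
    if not stripped.startswith(">"):
        raise MissingHeaderError(f"{path}: first non-blank character is not '>'")

    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        if rec.id in seen:
            raise DuplicateIdError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        residues = normalize_residues(str(rec.seq), context=f"record {rec.id!r}")
        records.append(
            SequenceRecord(id=rec.id, residues=residues, description=rec.description)
        )
    if not records:
        raise EmptyFastaError(f"{path}: no records found")
    return records


def write_fasta(
    records: Iterable[SequenceRecord], path: str | Path, width: int = 60
) -> Path:
    """Write records to ``path`` with fixed line ``width`` (default 60)."""
    if width < 1:
        raise ValueError("width must be >= 1")
    path = Path(path)
    with open(path, "w") as fh:
        for rec in records:
            header = rec.description if rec.description else rec.id
            if not header.startswith(rec.id):
                header = f"{rec.id} {header}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")
    return path


def reverse_complement(seq: str) -> str:
    """Reverse-complement of a normalized residue string (N maps to N)."""
    bad = set(seq) - _VALID
    if bad:
        raise AlphabetError(f"invalid residue(s) {sorted(bad)!r} in reverse_complement")
    return seq.translate(_COMPLEMENT)[::-1]


def load_genotype(path: str | Path, genotype_id: str | None = None) -> GenotypeSet:
    """Read one genotype's FASTA; the id defaults to the file stem."""
    path = Path(path)
    gid = genotype_id if genotype_id is not None else path.stem
    return GenotypeSet(genotype_id=gid, records=read_fasta(path))
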