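"""Reading, validating and transforming sequence records.

Sequences are read from FASTA/FASTQ files (optionally gzip-compressed) into
lightweight :class:`SequenceRecord` objects over a declared :class:`Alphabet`.
Three alphabets are supported: 4-letter DNA, the 20 canonical amino acids, and
a 10-character reduced amino-acid alphabet in which physico-chemically similar
residues share a group symbol.

Ambiguity symbols (N for DNA; X/B/Z/J/U/O for protein) are tolerated on input
but never counted as k-mers: brittle rejection of records containing an
occasional IUPAC code is a well-known practical failure mode of sequence
parsers, so validation is strict only for characters that belong to neither
the canonical nor the ambiguity set.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

from Bio import SeqIO

__all__ = [
    "Alphabet",
    "SequenceRecord",
    "DNA",
    "PROTEIN",
    "RAA10",
    "MURPHY10_GROUPS",
    "get_alphabet",
    "read_sequences",
    "write_fasta",
    "reduce_alphabet",
]


@dataclass(frozen=True)
class Alphabet:
    """An ordered residue alphabet with an explicit ambiguity policy.

    Parameters
    ----------
    name:
        One of ``dna``, ``aa``, ``raa10``.
    symbols:
        Ordered canonical characters; their number defines the word-space
        base (4, 20 or 10).
    ambiguity_symbols:
        Characters tolerated on input but skipped during k-mer counting.
    """

    name: str
    symbols: str
    ambiguity_symbols: str = ""

    def __post_init__(self) -> None:
        if len(set(self.symbols)) != len(self.symbols):
            raise ValueError("alphabet symbols must be unique")
        overlap = set(self.symbols) & set(self.ambiguity_symbols)
        if overlap:
            raise ValueError(f"symbols double as ambiguity codes: {overlap}")

    @property
    def size(self) -> int:
        return len(self.symbols)

    def index(self, symbol: str) -> int:
        return self.symbols.index(symbol)

    def is_canonical(self, symbol: str) -> bool:
        return symbol in self.symbols

    def is_valid(self, symbol: str) -> bool:
        return symbol in self.symbols or symbol in self.ambiguity_symbols


DNA = Alphabet(name="dna", symbols="ACGT", ambiguity_symbols="NRYSWKMBDHV")
PROTEIN = Alphabet(name="aa", symbols="ACDEFGHIKLMNPQRSTVWY", ambiguity_symbols="XBZJUO*")

#: Murphy 10-group reduction of the 20 amino acids.  Each group is written
#: with its representative (first) letter; the mapping below sends every
#: member to that representative.
MURPHY10_GROUPS: tuple[str, ...] = (
    "LVIM",
    "C",
    "A",
    "G",
    "ST",
    "P",
    "FYW",
    "EDNQ",
    "KR",
    "H",
)

RAA10 = Alphabet(
    name="raa10",
    symbols="".join(g[0] for g in MURPHY10_GROUPS),
    ambiguity_symbols="XBZJUO*",
)

_ALPHABETS = {"dna": DNA, "aa": PROTEIN, "raa10": RAA10}


def get_alphabet(name: str) -> Alphabet:
    """Look up a built-in alphabet by name (``dna``, ``aa`` or ``raa10``)."""
    try:
        return _ALPHABETS[name]
    except KeyError:
        raise ValueError(f"unknown alphabet {name!r}; expected one of {sorted(_ALPHABETS)}") from None


@dataclass(frozen=True)
class SequenceRecord:
    """One sequence with its identifier and free-text description.

    ``id`` is the first whitespace-delimited token of the source header; the
    full header is retained as ``description`` because objective functions map
    identifiers onto external tables.
    """

    id: str
    residues: str
    description: str = ""
    alphabet: Alphabet = field(default=DNA)

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        bad = {c for c in self.residues if not self.alphabet.is_valid(c)}
        if bad:
            raise ValueError(
                f"record {self.id!r} contains characters outside alphabet "
                f"{self.alphabet.name!r}: {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.residues)

    @property
    def ambiguous_positions(self) -> tuple[int, ...]:
        """Positions holding ambiguity symbols (skipped during counting)."""
        amb = set(self.alphabet.ambiguity_symbols)
        return tuple(i for i, c in enumerate(self.residues) if c in amb)


_FASTA_EXT = {".fa", ".fasta", ".fna", ".faa"}
_FASTQ_EXT = {".fq", ".fastq"}


def _sniff_format(path: Path) -> tuple[str, bool]:
    """Infer (format, gzipped) from the file name."""
    suffixes = [s.lower() for s in path.suffixes]
    gzipped = bool(suffixes) and suffixes[-1] == ".gz"
    if gzipped:
        suffixes = suffixes[:-1]
    ext = suffixes[-1] if suffixes else ""
    if ext in _FASTA_EXT:
        return "fasta", gzipped
    if ext in _FASTQ_EXT:
        return "fastq", gzipped
    raise ValueError(f"cannot infer sequence format from extension of {path.name!r}")


def read_sequences(path: str | Path, alphabet: Alphabet) -> list[SequenceRecord]:
    """Read all records from a FASTA/FASTQ file, in file order.

    Residues are upper-cased before validation.  Characters outside the
    canonical and ambiguity sets raise ``ValueError``; an empty file raises
    too, since a sequence set with no members is never a meaningful input.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt, gzipped = _sniff_format(path)
    opener = gzip.open if gzipped else open
    records: list[SequenceRecord] = []
    with opener(path, "rt") as handle:
        for rec in SeqIO.parse(handle, fmt):
            records.append(
                SequenceRecord(
                    id=rec.id,
                    residues=str(rec.seq).upper(),
                    description=rec.description,
                    alphabet=alphabet,
                )
            )
    if not records:
        raise ValueError(f"no sequence records found in {path}")
    return records


def write_fasta(records: Sequence[SequenceRecord], path: str | Path, width: int = 70) -> None:
    """Write records as FASTA, preserving order (used for interleaved pair files)."""
    path = Path(path)
    with open(path, "w") as out:
        for rec in records:
            header = rec.description if rec.description else rec.id
            out.write(f">{header}\n")
            for start in range(0, rec.length, width):
                out.write(rec.residues[start : start + width] + "\n")


def _reduction_table(groups: Sequence[str]) -> dict[str, str]:
    table: dict[str, str] = {}
    for group in groups:
        rep = group[0]
        for member in group:
            table[member] = rep
    return table


def reduce_alphabet(
    record: SequenceRecord, groups: Sequence[str] = MURPHY10_GROUPS
) -> SequenceRecord:
    """Map an amino-acid record onto the 10-character reduced alphabet.

    Every residue is replaced by its group representative; length and
    ambiguity symbols are preserved.  The grouping defaults to the Murphy
    10-class scheme but any partition of the 20 residues may be supplied.
    """
    if record.alphabet.name != "aa":
        raise ValueError(f"reduce_alphabet expects an aa record, got {record.alphabet.name!r}")
    table = _reduction_table(groups)
    covered = set(table)
    missing = set(PROTEIN.symbols) - covered
    if missing:
        raise ValueError(f"grouping does not cover residues: {sorted(missing)}")
    reduced = "".join(table.get(c, c) for c in record.residues)
    target = RAA10 if tuple(groups) == MURPHY10_GROUPS else Alphabet(
        name="raa10", symbols="".join(g[0] for g in groups), ambiguity_symbols=PROTEIN.ambiguity_symbols
    )
    return SequenceRecord(
        id=record.id, residues=reduced, description=record.description, alphabet=target
    )


def iter_pairs(records: Sequence[SequenceRecord]) -> Iterator[tuple[SequenceRecord, SequenceRecord]]:
    """Yield consecutive (even, odd) record pairs for interleaved comparison."""
    if len(records) % 2:
        raise ValueError(f"interleaved input needs an even record count, got {len(records)}")
    for i in range(0, len(records), 2):
        yield records[i], records[i + 1]
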