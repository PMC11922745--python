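"""Genome sequences and FASTA input/output.

A :class:`GenomeSequence` is an ordered collection of named nucleotide
sequences over the alphabet A/C/G/T/N, each carrying a ``circular`` flag.
Circular sequences (plasmid substrates such as pUC19) wrap in every
position-based operation; linear sequences (chromosomes) have ends.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from Bio import SeqIO

VALID_RESIDUES = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def complement(base: str) -> str:
    """Complement of a single base (N maps to N)."""
    return base.translate(_COMPLEMENT)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class GenomeFormatError(ValueError):
    """Raised for malformed FASTA input or invalid residues."""


@dataclass
class GenomeSequence:
    """Ordered, named nucleotide sequences with per-sequence circularity.

    Parameters
    ----------
    sequences
        Mapping of name -> residue string (A/C/G/T/N, uppercase).
    circular
        Names of sequences that are circular. Circularity is an input flag,
        never auto-detected.
    """

    sequences: dict[str, str]
    circular: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.circular = frozenset(self.circular)
        seen: set[str] = set()
        for name, residues in self.sequences.items():
            if name in seen:
                raise GenomeFormatError(f"duplicate sequence name {name!r}")
            seen.add(name)
            if len(residues) == 0:
                raise GenomeFormatError(f"sequence {name!r} is empty")
            bad = set(residues) - VALID_RESIDUES
            if bad:
                pos = next(
                    i for i, c in enumerate(residues) if c not in VALID_RESIDUES
                )
                raise GenomeFormatError(
                    f"sequence {name!r}: invalid residue {residues[pos]!r} "
                    f"at position {pos + 1}"
                )
        unknown = self.circular - set(self.sequences)
        if unknown:
            raise GenomeFormatError(
                f"circular flag for unknown sequence(s): {sorted(unknown)}"
            )

    @property
    def names(self) -> list[str]:
        return list(self.sequences)

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    def __len__(self) -> int:
        return len(self.sequences)

    def __contains__(self, name: str) -> bool:
        return name in self.sequences

    def __getitem__(self, name: str) -> str:
        return self.sequences[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self.sequences)

    def length(self, name: str) -> int:
        return len(self.sequences[name])

    def is_circular(self, name: str) -> bool:
        return name in self.circular

    def fetch(self, name: str, start: int, end: int) -> str:
        """Residues in [start, end) (0-based, half-open).

        On circular sequences the coordinates wrap; on linear sequences
        out-of-bounds coordinates raise ``IndexError``.
        """
        seq = self.sequences[name]
        n = len(seq)
        if start > end:
            raise IndexError(f"window [{start}, {end}) has negative length")
        if self.is_circular(name):
            if end - start > n:
                raise IndexError(f"window longer than circular sequence {name!r}")
            s = start % n
            e = s + (end - start)
            return (seq + seq)[s:e]
        if start < 0 or end > n:
            raise IndexError(
                f"window [{start}, {end}) out of bounds for linear "
                f"sequence {name!r} of length {n}"
            )
        return seq[start:end]


def read_fasta(path: str | Path, circular_names: Iterable[str] = ()) -> GenomeSequence:
    """Read a FASTA file into a :class:`GenomeSequence`.

    Residues are uppercased; names are taken up to the first whitespace.
    ``circular_names`` flags the listed sequences as circular.
    """
    path = Path(path)
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        name = record.id
        if name in sequences:
            raise GenomeFormatError(f"duplicate sequence name {name!r} in {path}")
        sequences[name] = str(record.seq).upper()
    circular = frozenset(circular_names)
    missing = circular - set(sequences)
    if missing:
        raise GenomeFormatError(
            f"circular_names not present in {path}: {sorted(missing)}"
        )
    return GenomeSequence(sequences, circular)


def write_fasta(genome: GenomeSequence, path: str | Path, width: int = 70) -> None:
    """Write sequences as FASTA, ``width`` residues per line."""
    with open(path, "w") as fh:
        for name, seq in genome.sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def gc_content(
    genome: GenomeSequence, exclude: Iterable[str] = ()
) -> float:
    """Average G+C fraction over all sequences not listed in ``exclude``.

    N residues are excluded from both numerator and denominator. Used for
    the sequence-logo background; chromosomes such as mitochondrial DNA can
    be excluded to obtain a nuclear-genome average.
    """
    exclude = set(exclude)
    gc = 0
    total = 0
    for name, seq in genome.sequences.items():
        if name in exclude:
            continue
        gc += seq.count("G") + seq.count("C")
        total += len(seq) - seq.count("N")
    if total == 0:
        raise ValueError("no unambiguous residues to compute GC content from")
    return gc / total
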