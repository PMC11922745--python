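"""Strand-specific per-nucleotide 5'-end count tracks.

A :class:`StrandTrack` holds, for every genome sequence, one top-strand and
one bottom-strand vector of non-negative values — the number (or RPM) of
sequencing reads whose 5'-most template base was assigned to each position.
Reads on the plus strand increment the top vector at their start; reads on
the minus strand increment the bottom vector at their 5' end (end - 1 in
0-based half-open coordinates).

Masked positions are flagged *missing*, distinct from zero, and are excluded
from peak calling, correlations and composition backgrounds.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import numpy as np

from .genome import GenomeSequence

RAW_COUNTS = "raw_counts"
RPM = "RPM"

STRANDS = ("top", "bottom")


class TrackFormatError(ValueError):
    """Raised for malformed BED/bedGraph input or unit mismatches."""


@dataclass
class StrandTrack:
    """Paired top/bottom per-nucleotide signal vectors over a genome.

    Attributes
    ----------
    lengths
        Sequence name -> length (nt); defines the coordinate frame.
    circular
        Names of circular sequences (wrap in smoothing/neighbour lookups).
    top, bottom
        name -> float vector of length ``lengths[name]``.
    units
        ``"raw_counts"`` or ``"RPM"``.
    total_mapped
        Reads in the library; the RPM denominator (shared by both strands).
    missing
        name -> boolean vector, True where masked, or None if no mask applied.
    smoothed
        True after display smoothing; smoothed tracks are refused by the
        peak caller.
    """

    lengths: dict[str, int]
    circular: frozenset[str]
    top: dict[str, np.ndarray]
    bottom: dict[str, np.ndarray]
    units: str = RAW_COUNTS
    total_mapped: float = 0.0
    missing: dict[str, np.ndarray] | None = None
    smoothed: bool = False

    @classmethod
    def zeros(cls, genome: GenomeSequence, units: str = RAW_COUNTS) -> "StrandTrack":
        lengths = {n: genome.length(n) for n in genome.names}
        return cls(
            lengths=lengths,
            circular=frozenset(genome.circular),
            top={n: np.zeros(L) for n, L in lengths.items()},
            bottom={n: np.zeros(L) for n, L in lengths.items()},
            units=units,
            total_mapped=0.0,
        )

    def __post_init__(self) -> None:
        if self.units not in (RAW_COUNTS, RPM):
            raise ValueError(f"unknown units {self.units!r}")
        for n, L in self.lengths.items():
            for strand in (self.top, self.bottom):
                if len(strand[n]) != L:
                    raise ValueError(
                        f"strand vector length mismatch on {n!r}: "
                        f"{len(strand[n])} != {L}"
                    )

    @property
    def names(self) -> list[str]:
        return list(self.lengths)

    @property
    def mask_applied(self) -> bool:
        return self.missing is not None

    def is_circular(self, name: str) -> bool:
        return name in self.circular

    def strand(self, which: str) -> dict[str, np.ndarray]:
        if which == "top":
            return self.top
        if which == "bottom":
            return self.bottom
        raise ValueError(f"unknown strand {which!r}")

    def copy(self) -> "StrandTrack":
        return StrandTrack(
            lengths=dict(self.lengths),
            circular=self.circular,
            top={n: v.copy() for n, v in self.top.items()},
            bottom={n: v.copy() for n, v in self.bottom.items()},
            units=self.units,
            total_mapped=self.total_mapped,
            missing=None
            if self.missing is None
            else {n: v.copy() for n, v in self.missing.items()},
            smoothed=self.smoothed,
        )

    def missing_mask(self, name: str) -> np.ndarray:
        """Boolean missing vector for ``name`` (all False if no mask applied)."""
        if self.missing is None:
            return np.zeros(self.lengths[name], dtype=bool)
        return self.missing[name]

    def total_signal(self) -> float:
        """Sum of both strands over all (non-missing) positions."""
        total = 0.0
        for n in self.names:
            keep = ~self.missing_mask(n)
            total += float(self.top[n][keep].sum() + self.bottom[n][keep].sum())
        return total

    def same_frame(self, other: "StrandTrack") -> bool:
        return self.lengths == other.lengths and self.circular == other.circular


def read_end_bed(path: str | Path, genome: GenomeSequence) -> StrandTrack:
    """Build a raw-count track from a BED6 file of reads.

    Each record contributes one count at the read's 5'-most base on its own
    strand: ``start`` for ``+`` records (top strand), ``end - 1`` for ``-``
    records (bottom strand) — the nucleotide immediately adjacent to the
    ligated adaptor in an end-capture library.
    """
    track = StrandTrack.zeros(genome)
    n_records = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise TrackFormatError(
                    f"{path}:{lineno}: BED6 record needs 6 fields, got "
                    f"{len(fields)}"
                )
            name, start, end, _, _, strand = fields[:6]
            if name not in genome:
                raise TrackFormatError(
                    f"{path}:{lineno}: unknown sequence {name!r}"
                )
            start, end = int(start), int(end)
            L = genome.length(name)
            if not (0 <= start < end <= L):
                raise TrackFormatError(
                    f"{path}:{lineno}: interval [{start}, {end}) out of "
                    f"bounds for {name!r} (length {L})"
                )
            if strand == "+":
                track.top[name][start] += 1
            elif strand == "-":
                track.bottom[name][end - 1] += 1
            else:
                raise TrackFormatError(
                    f"{path}:{lineno}: strand must be '+' or '-', got "
                    f"{strand!r}"
                )
            n_records += 1
    track.total_mapped = float(n_records)
    return track


def _format_value(x: float) -> str:
    """Lossless, compact decimal rendering (ints without a trailing .0)."""
    if float(x).is_integer() and abs(x) < 2**53:
        return str(int(x))
    return repr(float(x))


def _iter_runs(values: np.ndarray) -> Iterator[tuple[int, int, float]]:
    """Yield (start, end, value) runs of equal nonzero value."""
    nonzero = np.flatnonzero(values)
    if nonzero.size == 0:
        return
    run_start = nonzero[0]
    prev = nonzero[0]
    for i in nonzero[1:]:
        if i == prev + 1 and values[i] == values[run_start]:
            prev = i
            continue
        yield int(run_start), int(prev) + 1, float(values[run_start])
        run_start = prev = i
    yield int(run_start), int(prev) + 1, float(values[run_start])


def write_track(
    track: StrandTrack, plus_path: str | Path, minus_path: str | Path
) -> None:
    """Write one bedGraph per strand (0-based half-open; zero runs omitted).

    The header comment records units and total_mapped so that reading back
    restores the track exactly.
    """
    for which, path in (("top", plus_path), ("bottom", minus_path)):
        with open(path, "w") as fh:
            fh.write(
                f"# breakmap bedGraph strand={which} units={track.units} "
                f"total_mapped={_format_value(track.total_mapped)}\n"
            )
            for name in track.names:
                for start, end, value in _iter_runs(track.strand(which)[name]):
                    fh.write(f"{name}\t{start}\t{end}\t{_format_value(value)}\n")


def _read_bedgraph(
    path: str | Path, genome: GenomeSequence, expect_units: str | None
) -> tuple[dict[str, np.ndarray], str, float]:
    vectors = {n: np.zeros(genome.length(n)) for n in genome.names}
    units = RAW_COUNTS
    total_mapped = 0.0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if line.startswith("#"):
                for token in line.lstrip("# ").split():
                    if token.startswith("units="):
                        units = token.split("=", 1)[1]
                    elif token.startswith("total_mapped="):
                        total_mapped = float(token.split("=", 1)[1])
                continue
            if not line or line.startswith(("track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise TrackFormatError(
                    f"{path}:{lineno}: bedGraph needs 4 fields"
                )
            name, start, end, value = fields
            if name not in genome:
                raise TrackFormatError(
                    f"{path}:{lineno}: unknown sequence {name!r}"
                )
            vectors[name][int(start) : int(end)] = float(value)
    if expect_units is not None and units != expect_units:
        raise TrackFormatError(
            f"{path}: file units {units!r} do not match requested "
            f"{expect_units!r}"
        )
    return vectors, units, total_mapped


def read_track(
    plus_path: str | Path,
    minus_path: str | Path,
    genome: GenomeSequence,
    expect_units: str | None = None,
) -> StrandTrack:
    """Read a bedGraph pair written by :func:`write_track`."""
    top, units_p, tm_p = _read_bedgraph(plus_path, genome, expect_units)
    bottom, units_m, tm_m = _read_bedgraph(minus_path, genome, expect_units)
    if units_p != units_m:
        raise TrackFormatError(
            f"strand files disagree on units: {units_p!r} vs {units_m!r}"
        )
    return StrandTrack(
        lengths={n: genome.length(n) for n in genome.names},
        circular=frozenset(genome.circular),
        top=top,
        bottom=bottom,
        units=units_p,
        total_mapped=tm_p,
    )
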