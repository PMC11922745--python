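"""Genomic masks: telomere ends, user intervals, and whole-sequence exclusions.

Masked positions are *missing*, not zero: they are excluded from peak calling,
correlation and composition backgrounds rather than contributing zeros.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .genome import GenomeSequence


def merge_intervals(intervals: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    """Sort and merge 0-based half-open intervals (adjacent intervals merge)."""
    merged: list[tuple[int, int]] = []
    for start, end in sorted((int(s), int(e)) for s, e in intervals):
        if start >= end:
            continue
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


@dataclass
class MaskSet:
    """Per-sequence masked intervals plus whole-sequence exclusions.

    Intervals are 0-based half-open, sorted, merged and within bounds.
    """

    intervals: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    excluded: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.excluded = frozenset(self.excluded)
        self.intervals = {
            name: merge_intervals(ivs) for name, ivs in self.intervals.items()
        }

    def masked_length(self) -> int:
        return sum(e - s for ivs in self.intervals.values() for s, e in ivs)

    def boolean_mask(self, name: str, length: int) -> np.ndarray:
        """Boolean vector, True where masked."""
        mask = np.zeros(length, dtype=bool)
        for start, end in self.intervals.get(name, []):
            mask[start:end] = True
        return mask

    def is_masked(self, name: str, pos: int) -> bool:
        if name in self.excluded:
            return True
        return any(s <= pos < e for s, e in self.intervals.get(name, []))


def build_masks(
    genome: GenomeSequence,
    telomere_bp: int = 0,
    intervals: Mapping[str, Sequence[tuple[int, int]]] | None = None,
    excluded: Iterable[str] = (),
) -> MaskSet:
    """Construct a mask set from telomere ends, user intervals and exclusions.

    Each *linear* sequence is masked over ``[0, telomere_bp)`` and
    ``[len - telomere_bp, len)``; circular sequences have no ends and get no
    telomere masks. User intervals are merged in. ``excluded`` names whole
    sequences (e.g. mitochondrial DNA) dropped from all analyses.
    """
    if telomere_bp < 0:
        raise ValueError("telomere_bp must be >= 0")
    excluded = frozenset(excluded)
    unknown = excluded - set(genome.names)
    if unknown:
        raise ValueError(f"excluded sequence(s) not in genome: {sorted(unknown)}")

    out: dict[str, list[tuple[int, int]]] = {}
    for name in genome.names:
        ivs: list[tuple[int, int]] = []
        n = genome.length(name)
        if telomere_bp > 0 and not genome.is_circular(name):
            t = min(telomere_bp, n)
            ivs.append((0, t))
            ivs.append((max(0, n - t), n))
        for start, end in (intervals or {}).get(name, []):
            if start < 0 or end > n or start >= end:
                raise ValueError(
                    f"mask interval [{start}, {end}) out of bounds for "
                    f"{name!r} (length {n})"
                )
            ivs.append((int(start), int(end)))
        merged = merge_intervals(ivs)
        if merged:
            out[name] = merged
    for name in (intervals or {}):
        if name not in genome:
            raise ValueError(f"mask interval on unknown sequence {name!r}")
    return MaskSet(out, excluded)


def read_bed3(path) -> dict[str, list[tuple[int, int]]]:
    """Read BED3 intervals (chrom, start, end) grouped by sequence name."""
    out: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed BED line: {line!r}")
            out.setdefault(fields[0], []).append((int(fields[1]), int(fields[2])))
    return out


def write_bed3(intervals: Mapping[str, Sequence[tuple[int, int]]], path) -> None:
    with open(path, "w") as fh:
        for name, ivs in intervals.items():
            for start, end in ivs:
                fh.write(f"{name}\t{start}\t{end}\n")
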