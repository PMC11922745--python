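"""Dyad-centred base composition, GC-corrected logos and signal profiles.

Every called peak marks the 5'-end base of a cleavage site, dyad-relative
offset -1 on the strand the read came from. Top-strand peaks are read
directly; bottom-strand peaks are reverse-complemented ("reoriented") so
that their adaptor-proximal base also sits at offset -1, putting both
strands of a rotationally symmetric signature into one frame.

Logo letter heights are per-letter relative entropy against a GC-split
background: q_G = q_C = gc/2, q_A = q_T = (1-gc)/2, with
s[b, k] = f[b, k] * log2(f[b, k] / q_b) in bits. The background GC can be
the genome average or a local override when the neighbourhood of mapped
sites differs substantially from the genome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .coords import offset_labels
from .genome import GenomeSequence, reverse_complement
from .peaks import PeakSet
from .track import RPM, StrandTrack

log = logging.getLogger("breakmap.seqbias")

BASES = "ACGT"


@dataclass
class CompositionProfile:
    """Dyad-relative base fractions, logo scores and signal profiles.

    ``fractions`` and ``scores`` are (4, 2h) arrays, rows A/C/G/T, columns
    in offset order -h..-1,+1..+h; ``background`` is the 4-vector q.
    ``signal`` maps oriented strand -> per-offset mean RPM.
    """

    h: int
    fractions: np.ndarray
    n_windows: int
    background: np.ndarray | None = None
    scores: np.ndarray | None = None
    signal: dict[str, np.ndarray] | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, dtype=float)
        if self.fractions.shape != (4, 2 * self.h):
            raise ValueError("fractions must be (4, 2h)")
        if self.n_windows < 1:
            raise ValueError("need at least one window")
        sums = self.fractions.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("base fractions must sum to 1 at every offset")

    @property
    def offsets(self) -> list[int]:
        return offset_labels(self.h)

    def fraction(self, base: str, k: int) -> float:
        return float(self.fractions[BASES.index(base), self._col(k)])

    def score(self, base: str, k: int) -> float:
        if self.scores is None:
            raise ValueError("logo scores not computed yet")
        return float(self.scores[BASES.index(base), self._col(k)])

    def _col(self, k: int) -> int:
        if k == 0 or abs(k) > self.h:
            raise ValueError(f"offset {k} outside the profile")
        return self.h + k if k < 0 else self.h + k - 1

    def to_frame(self, which: str = "fractions") -> pd.DataFrame:
        mat = {"fractions": self.fractions, "scores": self.scores}[which]
        if mat is None:
            raise ValueError(f"{which} not computed")
        return pd.DataFrame(mat, index=list(BASES), columns=self.offsets)


def oriented_windows(
    peaks: PeakSet, genome: GenomeSequence, h: int = 10
) -> list[str]:
    """Extract 2h-nt sequence windows around peaks, dyad-oriented.

    Top-strand peak at q: genomic [q-(h-1), q+h] read as-is, base at q at
    offset -1 (dyad pair q, q+1). Bottom-strand peak at q: genomic
    [q-h, q+h-1] reverse-complemented, complement of the base at q at
    offset -1 (dyad pair q, q-1). Windows that run off a linear sequence
    or contain N are dropped with a logged count.
    """
    if h < 1:
        raise ValueError("h must be >= 1")
    if len(peaks) == 0:
        raise ValueError("empty peak set")
    windows: list[str] = []
    dropped = 0
    for p in peaks:
        L = genome.length(p.sequence)
        if p.strand == "top":
            start, end = p.position - (h - 1), p.position + h + 1
        else:
            start, end = p.position - h, p.position + h
        try:
            seq = genome.fetch(p.sequence, start, end)
        except IndexError:
            dropped += 1
            continue
        if "N" in seq:
            dropped += 1
            continue
        windows.append(seq if p.strand == "top" else reverse_complement(seq))
    if dropped:
        log.info("dropped %d window(s) off linear ends or containing N",
                 dropped)
    if not windows:
        raise ValueError("no usable windows (all dropped)")
    return windows


def base_composition(windows: list[str]) -> CompositionProfile:
    """Unweighted per-offset base fractions across equal-length windows."""
    if not windows:
        raise ValueError("need at least one window")
    width = len(windows[0])
    if any(len(w) != width for w in windows):
        raise ValueError("windows must all have the same length")
    if width % 2 != 0:
        raise ValueError("window width must be even (2h, no zero offset)")
    h = width // 2
    counts = np.zeros((4, width))
    for w in windows:
        for j, c in enumerate(w):
            counts[BASES.index(c), j] += 1
    return CompositionProfile(
        h=h,
        fractions=counts / len(windows),
        n_windows=len(windows),
    )


def logo_scores(
    profile: CompositionProfile, background_gc: float
) -> CompositionProfile:
    """Fill per-letter relative-entropy logo scores (bits) into a profile.

    Background: q_G = q_C = background_gc / 2, q_A = q_T =
    (1 - background_gc) / 2. s[b, k] = f * log2(f / q_b), 0 where f = 0;
    display column height is the sum of positive scores.
    """
    if not 0.0 < background_gc < 1.0:
        raise ValueError("background_gc must lie strictly between 0 and 1")
    at = (1.0 - background_gc) / 2.0
    gc = background_gc / 2.0
    q = np.array([at, gc, gc, at])  # A C G T
    f = profile.fractions
    with np.errstate(divide="ignore", invalid="ignore"):
        s = f * np.log2(f / q[:, None])
    s[f == 0] = 0.0
    return CompositionProfile(
        h=profile.h,
        fractions=f,
        n_windows=profile.n_windows,
        background=q,
        scores=s,
        signal=profile.signal,
        provenance={**profile.provenance, "background_gc": background_gc},
    )


def _oriented_positions(strand: str, q: int, labels: np.ndarray) -> np.ndarray:
    """Genomic positions of oriented offsets for a peak at q."""
    if strand == "top":
        return q + np.where(labels < 0, labels + 1, labels)
    return q + np.where(labels < 0, -labels - 1, -labels)


def averaged_profile(
    peaks: PeakSet, track: StrandTrack, h: int = 10
) -> dict[str, np.ndarray]:
    """Mean oriented strand-specific RPM by dyad-relative offset.

    For each peak the signal window is extracted in dyad orientation:
    bottom-strand peaks are flipped and strand-swapped, so the oriented
    'top' profile always carries the adaptor-proximal strand (its maximum
    sits at offset -1 for genuine cleavage signal) and the oriented
    'bottom' profile the partner strand (maximum at +1).
    Peaks whose window leaves a linear sequence are dropped.
    """
    if track.units != RPM:
        raise ValueError("averaged_profile needs RPM units")
    if len(peaks) == 0:
        raise ValueError("empty peak set")
    labels = np.array(offset_labels(h))
    acc = {"top": np.zeros(labels.size), "bottom": np.zeros(labels.size)}
    used = 0
    for p in peaks:
        L = track.lengths[p.sequence]
        pos = _oriented_positions(p.strand, p.position, labels)
        if track.is_circular(p.sequence):
            pos = pos % L
        elif pos.min() < 0 or pos.max() >= L:
            continue
        if p.strand == "top":
            src = {"top": track.top, "bottom": track.bottom}
        else:  # flipped: oriented top reads the genomic bottom strand
            src = {"top": track.bottom, "bottom": track.top}
        for oriented in ("top", "bottom"):
            acc[oriented] += src[oriented][p.sequence][pos]
        used += 1
    if used == 0:
        raise ValueError("no peak had a full in-bounds window")
    return {k: v / used for k, v in acc.items()}


def write_profile_tsv(
    profile: CompositionProfile, path: str | Path, **params
) -> None:
    """Fractions (and scores if present) as TSV with a parameter header."""
    with open(path, "w") as fh:
        meta = " ".join(f"{k}={v}" for k, v in params.items())
        fh.write(f"# breakmap composition n_windows={profile.n_windows} "
                 f"{meta}\n")
        profile.to_frame("fractions").to_csv(fh, sep="\t")
        if profile.scores is not None:
            fh.write("# logo scores (bits)\n")
            profile.to_frame("scores").to_csv(fh, sep="\t")
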