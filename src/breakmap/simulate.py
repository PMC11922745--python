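"""Synthetic break-map generator.

Produces random genomes, planted cleavage landscapes and strand-specific
5'-end count tracks that mimic an end-capture sequencing experiment on a
topoisomerase-like enzyme that cuts with a 2-nt 5' overhang:

* each double-strand break (DSB) at dyad index ``g`` (the genomic position
  of the relative -1 base) yields one top-strand 5' end at ``g`` and one
  bottom-strand 5' end at ``g + 1``;
* with probability ``phi`` per end, incomplete fill-in of the overhang
  before adaptor ligation shifts the recorded end inward by ``s`` nt
  (top end to ``g + s``, bottom end to ``g + 1 - s``) — the library
  artifact the peak caller must reject;
* a fraction ``beta`` of DSBs fall at background dyads drawn uniformly,
  emulating the random landscape of a catalytically-dead control.

Cleavage preference is a product position-weight model over dyad-relative
offsets -h..-1,+1..+h. A rotationally symmetric model — weight of base b at
+k equal to the weight of its complement at -k — encodes the expected
signature of two protomers engaging two half-sites.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .coords import offset_labels, relative_to_genomic
from .genome import GenomeSequence
from .track import StrandTrack

log = logging.getLogger("breakmap.simulate")

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT_INDEX = np.array([3, 2, 1, 0])  # A<->T, C<->G

#: Study-condition defaults for end-to-end simulations.
DEFAULTS = dict(
    genome_length=50_000,
    gc=0.45,
    n_breaks=2_000,
    beta=0.05,
    phi=0.1,
    shift=1,
    h=10,
)


@dataclass
class CleavagePreferenceModel:
    """Product position-weight model of cleavage preference.

    Attributes
    ----------
    h
        Half-width: offsets -h..-1,+1..+h are scored (2h columns).
    weights
        (4, 2h) positive array; rows A, C, G, T; columns in offset order.
    beta
        Background fraction: probability a DSB ignores the preference and
        falls at a uniformly random valid dyad.
    phi
        Per-end incomplete-fill-in probability (artifact rate).
    shift
        Artifact shift in nt (default 1).
    symmetric
        Declares rotational symmetry; validated exactly on construction.
    """

    h: int
    weights: np.ndarray
    beta: float = 0.0
    phi: float = 0.0
    shift: int = 1
    symmetric: bool = False

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (4, 2 * self.h):
            raise ValueError(
                f"weights must be (4, {2 * self.h}), got {self.weights.shape}"
            )
        if not np.all(self.weights > 0):
            raise ValueError("all weights must be > 0")
        if not (0.0 <= self.beta <= 1.0 and 0.0 <= self.phi <= 1.0):
            raise ValueError("beta and phi must lie in [0, 1]")
        if self.symmetric and not self.is_symmetric():
            raise ValueError("weights violate the declared rotational symmetry")

    def column(self, k: int) -> int:
        """Column index of dyad-relative offset k (no zero)."""
        if k == 0 or abs(k) > self.h:
            raise ValueError(f"offset {k} outside -{self.h}..+{self.h} (no zero)")
        return self.h + k if k < 0 else self.h + k - 1

    def weight(self, base: str, k: int) -> float:
        return float(self.weights[_BASE_INDEX[base], self.column(k)])

    def is_symmetric(self) -> bool:
        """True iff weight(b, +k) == weight(complement(b), -k) for all b, k."""
        for k in range(1, self.h + 1):
            plus = self.weights[:, self.column(k)]
            minus = self.weights[_COMPLEMENT_INDEX, self.column(-k)]
            if not np.array_equal(plus, minus):
                return False
        return True

    @property
    def offsets(self) -> list[int]:
        return offset_labels(self.h)


def default_model(
    h: int = 10,
    beta: float = DEFAULTS["beta"],
    phi: float = DEFAULTS["phi"],
    shift: int = DEFAULTS["shift"],
    strength: float = 4.0,
) -> CleavagePreferenceModel:
    """Rotationally symmetric preference with the canonical core signature.

    Elevates G at -3, A at -1, T at +1 and C at +3 (weight ``strength``
    against a unit background), so the best-scoring hexamer over offsets
    -3..+3 matches GNATNC (every choice of N ties for the maximum) and the
    reverse pattern CNTANG scores worst.
    """
    if h < 3:
        raise ValueError("h must be >= 3 to hold the -3..+3 core signature")
    weights = np.ones((4, 2 * h))
    model = CleavagePreferenceModel(h=h, weights=weights, beta=beta, phi=phi,
                                    shift=shift)
    for base, k in (("G", -3), ("A", -1), ("T", +1), ("C", +3)):
        weights[_BASE_INDEX[base], model.column(k)] = strength
    return CleavagePreferenceModel(
        h=h, weights=weights, beta=beta, phi=phi, shift=shift, symmetric=True
    )


@dataclass
class SimTruth:
    """Planted ground truth: per-dyad DSB counts plus the generating model.

    ``sites`` holds (sequence name, dyad index g, DSB count) sorted by
    (name, g); counts sum to ``n_breaks``.
    """

    sites: list[tuple[str, int, int]]
    n_breaks: int
    seed: int
    model: CleavagePreferenceModel

    def __post_init__(self) -> None:
        if sum(c for _, _, c in self.sites) != self.n_breaks:
            raise ValueError("site counts do not sum to n_breaks")

    def counts(self, name: str, length: int) -> np.ndarray:
        out = np.zeros(length, dtype=int)
        for n, g, c in self.sites:
            if n == name:
                out[g] = c
        return out


def simulate_genome(
    length: int, gc: float, circular: bool = False, seed: int = 0,
    name: str = "sim",
) -> GenomeSequence:
    """Random i.i.d. genome: P(G)=P(C)=gc/2, P(A)=P(T)=(1-gc)/2."""
    if not 0.0 < gc < 1.0:
        raise ValueError("gc must lie strictly between 0 and 1")
    if length < 1:
        raise ValueError("length must be positive")
    rng = np.random.default_rng(seed)
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    residues = "".join(np.array(list(BASES))[rng.choice(4, size=length, p=p)])
    return GenomeSequence(
        {name: residues}, frozenset({name}) if circular else frozenset()
    )


def _base_indices(seq: str) -> np.ndarray:
    """Residues as 0..3 (A,C,G,T); N becomes -1."""
    lut = np.full(128, -1, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        lut[ord(b)] = i
    return lut[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _valid_dyads(length: int, h: int, circular: bool) -> tuple[int, int]:
    """Half-open dyad range [lo, hi) scoreable on a linear sequence."""
    if circular:
        return 0, length
    lo, hi = h - 1, length - h
    if hi <= lo:
        raise ValueError(
            f"sequence of length {length} shorter than the 2h={2 * h} window"
        )
    return lo, hi


def site_probabilities(
    genome: GenomeSequence, model: CleavagePreferenceModel
) -> dict[str, np.ndarray]:
    """Per-dyad cleavage probabilities, normalised over the whole genome.

    The score of dyad ``g`` is the product over offsets k of the weight of
    the base at the genomic position of k. Dyads whose window leaves a
    linear sequence or contains N get probability zero.
    """
    scores: dict[str, np.ndarray] = {}
    for name in genome.names:
        seq = genome[name]
        L = len(seq)
        circ = genome.is_circular(name)
        lo, hi = _valid_dyads(L, model.h, circ)
        idx = _base_indices(seq)
        logw = np.log(model.weights)
        total = np.zeros(L)
        valid = np.ones(L, dtype=bool)
        g = np.arange(L)
        for k in model.offsets:
            pos = g + (k + 1 if k < 0 else k)  # relative_to_genomic, vectorised
            if circ:
                pos %= L
            else:
                pos = np.clip(pos, 0, L - 1)  # out-of-range dyads zeroed below
            b = idx[pos]
            has_n = b < 0
            valid &= ~has_n
            total += np.where(has_n, 0.0, logw[np.where(has_n, 0, b),
                                               model.column(k)])
        score = np.exp(total)
        score[~valid] = 0.0
        if not circ:
            score[:lo] = 0.0
            score[hi:] = 0.0
        scores[name] = score
    grand = sum(float(s.sum()) for s in scores.values())
    if grand <= 0:
        raise ValueError("no valid dyads in genome")
    return {n: s / grand for n, s in scores.items()}


def simulate_breaks(
    genome: GenomeSequence,
    model: CleavagePreferenceModel,
    n_breaks: int,
    seed: int,
) -> SimTruth:
    """Draw DSB dyads: background (prob. beta) uniform over valid dyads,
    otherwise from :func:`site_probabilities`; aggregate counts per dyad."""
    if n_breaks < 1:
        raise ValueError("n_breaks must be >= 1")
    rng = np.random.default_rng(seed)
    probs = site_probabilities(genome, model)
    names = list(probs)
    flat_p = np.concatenate([probs[n] for n in names])
    # background is uniform over *valid* dyads, not weighted by score
    uniform = np.concatenate([_valid_indicator(genome, n, model) for n in names])
    uniform /= uniform.sum()
    n_bg = rng.binomial(n_breaks, model.beta) if model.beta > 0 else 0
    counts = np.zeros(flat_p.size, dtype=int)
    if n_breaks - n_bg > 0:
        counts += rng.multinomial(n_breaks - n_bg, flat_p)
    if n_bg > 0:
        counts += rng.multinomial(n_bg, uniform)
    sites: list[tuple[str, int, int]] = []
    pos = 0
    for n in names:
        L = probs[n].size
        nz = np.flatnonzero(counts[pos : pos + L])
        sites.extend((n, int(g), int(counts[pos + g])) for g in nz)
        pos += L
    return SimTruth(sites=sites, n_breaks=n_breaks, seed=seed, model=model)


def _valid_indicator(
    genome: GenomeSequence, name: str, model: CleavagePreferenceModel
) -> np.ndarray:
    """1.0 at dyads whose window fits the sequence (N allowed), else 0."""
    L = genome.length(name)
    out = np.zeros(L)
    lo, hi = _valid_dyads(L, model.h, genome.is_circular(name))
    out[lo:hi] = 1.0
    return out


def simulate_tracks(
    truth: SimTruth, genome: GenomeSequence, seed: int
) -> StrandTrack:
    """Convert planted DSBs into a raw-count 5'-end track.

    Each DSB at dyad g places one top-strand end at g and one bottom-strand
    end at g + 1. Independently per end, with probability ``phi`` the end is
    shifted by ``s`` nt inward (top to g+s, bottom to g+1-s) — the
    incomplete-fill-in artifact. On linear sequences, ends shifted off the
    sequence are dropped with a logged warning; on circular sequences
    positions wrap.
    """
    model = truth.model
    rng = np.random.default_rng(seed)
    track = StrandTrack.zeros(genome)
    dropped = 0
    for name, g, c in truth.sites:
        L = genome.length(name)
        circ = genome.is_circular(name)
        for strand, true_pos, art_pos in (
            ("top", g, g + model.shift),
            ("bottom", g + 1, g + 1 - model.shift),
        ):
            n_art = rng.binomial(c, model.phi) if model.phi > 0 else 0
            vec = track.strand(strand)[name]
            for pos, n in ((true_pos, c - n_art), (art_pos, n_art)):
                if n == 0:
                    continue
                if circ:
                    vec[pos % L] += n
                elif 0 <= pos < L:
                    vec[pos] += n
                else:
                    dropped += n
    if dropped:
        log.warning(
            "%d read end(s) fell outside a linear sequence and were dropped",
            dropped,
        )
    track.total_mapped = 2.0 * truth.n_breaks - dropped
    return track


def simulate_control(
    genome: GenomeSequence, n_breaks: int, seed: int, h: int = DEFAULTS["h"]
) -> StrandTrack:
    """Pure-background library (catalytically-dead control).

    Random breakage leaves no overhang phasing between strands, so the
    control places ``n_breaks`` top-strand and ``n_breaks`` bottom-strand
    5' ends *independently*, each uniform over the sequence — 2N reads in
    total, with no dyad pairing and hence no +1 cross-correlation signal.
    """
    if n_breaks < 1:
        raise ValueError("n_breaks must be >= 1")
    rng = np.random.default_rng(seed)
    track = StrandTrack.zeros(genome)
    names = genome.names
    lengths = np.array([genome.length(n) for n in names])
    p = lengths / lengths.sum()
    for strand in ("top", "bottom"):
        per_seq = rng.multinomial(n_breaks, p)
        for name, n in zip(names, per_seq):
            pos = rng.integers(0, genome.length(name), size=n)
            np.add.at(track.strand(strand)[name], pos, 1.0)
    track.total_mapped = 2.0 * n_breaks
    return track


def simulate_dataset(
    seed: int,
    genome_length: int = DEFAULTS["genome_length"],
    gc: float = DEFAULTS["gc"],
    n_breaks: int = DEFAULTS["n_breaks"],
    beta: float = DEFAULTS["beta"],
    phi: float = DEFAULTS["phi"],
    shift: int = DEFAULTS["shift"],
    h: int = DEFAULTS["h"],
    circular: bool = False,
) -> tuple[GenomeSequence, SimTruth, StrandTrack]:
    """End-to-end convenience: genome -> planted breaks -> raw-count track.

    Derives one sub-seed per stage from ``seed`` so stages stay independent
    but the whole dataset is reproducible from a single integer.
    """
    ss = np.random.SeedSequence(seed).spawn(3)
    seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss]
    genome = simulate_genome(genome_length, gc, circular=circular, seed=seeds[0])
    model = default_model(h=h, beta=beta, phi=phi, shift=shift)
    truth = simulate_breaks(genome, model, n_breaks, seeds[1])
    track = simulate_tracks(truth, genome, seeds[2])
    return genome, truth, track


def write_truth_tsv(truth: SimTruth, path: str | Path) -> None:
    """Ground-truth TSV: sequence, dyad g, DSB count; parameter echo header."""
    m = truth.model
    with open(path, "w") as fh:
        fh.write(
            f"# breakmap truth seed={truth.seed} n_breaks={truth.n_breaks} "
            f"h={m.h} beta={m.beta} phi={m.phi} shift={m.shift}\n"
        )
        fh.write("sequence\tdyad\tcount\n")
        for name, g, c in truth.sites:
            fh.write(f"{name}\t{g}\t{c}\n")
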