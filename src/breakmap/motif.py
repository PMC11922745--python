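"""IUPAC degenerate-motif scanning and motif-site signal averaging.

Even-length degenerate patterns (e.g. the preferred cleavage signature
GNATNC and its non-preferred reverse CNTANG) are scanned on the top strand;
each match defines a dyad whose central two pattern positions sit at
offsets -1/+1. Strand-specific signal averaged over all such dyads shows,
for a genuinely preferred pattern, top-strand enrichment at -1 and
bottom-strand enrichment at +1 — the fingerprint of cleavage with a 2-nt
5' overhang centred on the pattern.

Both canonical patterns are self-reverse-complementary, so a single
top-strand scan is complete for them.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .coords import offset_labels
from .genome import GenomeSequence, reverse_complement
from .seqbias import _oriented_positions
from .track import RPM, StrandTrack

#: IUPAC degenerate nucleotide codes. A genomic N matches only pattern N.
IUPAC_CODES: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}


@dataclass
class MotifSiteSet:
    """Dyads of all top-strand matches of one degenerate pattern.

    ``sites`` holds (sequence name, dyad index g) with g aligned to pattern
    offset -1; sorted and unique. Overlapping matches are all retained.
    """

    pattern: str
    sites: list[tuple[str, int]]

    def __post_init__(self) -> None:
        self.sites = sorted(set(self.sites))

    def __len__(self) -> int:
        return len(self.sites)


def _pattern_regex(pattern: str) -> re.Pattern:
    classes = []
    for code in pattern:
        bases = IUPAC_CODES[code]
        # genomic N is ambiguous: it matches only the fully degenerate code
        cls = bases + ("N" if code == "N" else "")
        classes.append(f"[{cls}]")
    # lookahead so overlapping matches are all found
    return re.compile("(?=" + "".join(classes) + ")")


def scan_iupac(genome: GenomeSequence, pattern: str) -> MotifSiteSet:
    """All top-strand matches of an even-length IUPAC pattern.

    The dyad g of a match starting at p is ``p + len(pattern)//2 - 1``, so
    the two central pattern positions sit at dyad offsets -1 and +1.
    Circular sequences are scanned across the origin.
    """
    pattern = pattern.strip().upper()
    if len(pattern) < 2 or len(pattern) % 2 != 0:
        raise ValueError(
            "pattern length must be even and >= 2 (a central dyad is needed)"
        )
    bad = set(pattern) - set(IUPAC_CODES)
    if bad:
        raise ValueError(f"invalid IUPAC code(s): {''.join(sorted(bad))}")
    regex = _pattern_regex(pattern)
    m = len(pattern) // 2
    sites: list[tuple[str, int]] = []
    for name in genome.names:
        seq = genome[name]
        L = len(seq)
        if genome.is_circular(name):
            extended = seq + seq[: len(pattern) - 1]
            starts = {match.start() % L for match in regex.finditer(extended)}
        else:
            starts = {
                match.start()
                for match in regex.finditer(seq)
                if match.start() + len(pattern) <= L
            }
        sites.extend((name, (p + m - 1) % L if genome.is_circular(name)
                      else p + m - 1) for p in starts)
    return MotifSiteSet(pattern=pattern, sites=sites)


def is_self_reverse_complementary(pattern: str) -> bool:
    """True if the degenerate pattern equals its reverse complement
    (complementing degenerate codes by their base sets)."""
    comp = {code: _complement_code(code) for code in IUPAC_CODES}
    return pattern == "".join(comp[c] for c in reversed(pattern.upper()))


def _complement_code(code: str) -> str:
    bases = frozenset(reverse_complement(b) for b in IUPAC_CODES[code])
    for other, expansion in IUPAC_CODES.items():
        if frozenset(expansion) == bases:
            return other
    raise ValueError(code)


def motif_site_profiles(
    sites: MotifSiteSet, track: StrandTrack, h: int = 20
) -> dict[str, np.ndarray]:
    """Mean strand-specific RPM by dyad-relative offset across motif sites.

    Sites are top-strand dyads, so no reorientation is needed: the top
    profile reads the top strand at offsets -h..+h relative to each dyad,
    the bottom profile the bottom strand. Sites whose window leaves a
    linear sequence are skipped.
    """
    if track.units != RPM:
        raise ValueError("motif_site_profiles needs RPM units")
    if len(sites) == 0:
        raise ValueError("empty motif site set")
    labels = np.array(offset_labels(h))
    acc = {"top": np.zeros(labels.size), "bottom": np.zeros(labels.size)}
    used = 0
    for name, g in sites.sites:
        L = track.lengths[name]
        pos = _oriented_positions("top", g, labels)
        if track.is_circular(name):
            pos = pos % L
        elif pos.min() < 0 or pos.max() >= L:
            continue
        acc["top"] += track.top[name][pos]
        acc["bottom"] += track.bottom[name][pos]
        used += 1
    if used == 0:
        raise ValueError("no motif site had a full in-bounds window")
    return {k: v / used for k, v in acc.items()}


def profile_enrichment(profiles: dict[str, np.ndarray], h: int) -> float:
    """Central enrichment E of a dyad profile pair.

    E = (top mean at -1 + bottom mean at +1) / median of both strands over
    flank offsets |k| > 5. E ~ 1 for flat (background) profiles.
    """
    labels = np.array(offset_labels(h))
    top, bottom = profiles["top"], profiles["bottom"]
    centre = float(top[labels == -1][0] + bottom[labels == 1][0])
    flank = np.concatenate([top[np.abs(labels) > 5],
                            bottom[np.abs(labels) > 5]])
    med = float(np.median(flank))
    if med == 0:
        raise ValueError("flank median is zero; enrichment undefined")
    return centre / (2.0 * med)


def preferred_vs_reverse(
    pref: dict[str, np.ndarray], rev: dict[str, np.ndarray], h: int
) -> dict[str, float]:
    """Contrast central enrichment of a preferred vs a reverse pattern.

    Returns E_pref, E_rev and their ratio; a planted preference gives
    ratio > 1, identical profiles give exactly 1.
    """
    e_pref = profile_enrichment(pref, h)
    e_rev = profile_enrichment(rev, h)
    return {"E_pref": e_pref, "E_rev": e_rev, "ratio": e_pref / e_rev}


def write_sites_bed(sites: MotifSiteSet, path: str | Path) -> None:
    """Sites as 1-nt BED features at the dyad-left base, strand '+'."""
    with open(path, "w") as fh:
        for name, g in sites.sites:
            fh.write(f"{name}\t{g}\t{g + 1}\t{sites.pattern}\t0\t+\n")
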