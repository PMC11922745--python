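"""Coordinate conventions.

All internal coordinates are 0-based, half-open. Dyad-relative positions use
the no-zero labelling ...,-2,-1,+1,+2,... centred on the 2-nt overhang: for a
dyad pair of genomic positions (g, g+1), relative -k maps to g-(k-1) and +k
maps to (g+1)+(k-1). The dyad index g is, by convention, the genomic position
of the relative -1 base.
"""

from __future__ import annotations

import numpy as np


def offset_labels(h: int) -> list[int]:
    """No-zero offset labels -h..-1, +1..+h (length 2h)."""
    if h < 1:
        raise ValueError("h must be >= 1")
    return list(range(-h, 0)) + list(range(1, h + 1))


def relative_to_genomic(g: int, k: int) -> int:
    """Genomic position of dyad-relative offset ``k`` for dyad index ``g``.

    ``k`` must be nonzero: -k maps to g-(k-1), +k maps to (g+1)+(k-1).
    """
    if k == 0:
        raise ValueError("dyad-relative offsets have no zero")
    if k < 0:
        return g - (-k - 1)
    return (g + 1) + (k - 1)


def genomic_to_relative(g: int, pos: int) -> int:
    """Dyad-relative offset of genomic position ``pos`` for dyad index ``g``."""
    if pos <= g:
        return -(g - pos + 1)
    return pos - g


def relative_window(g: int, h: int) -> tuple[int, int]:
    """Genomic half-open span [start, end) covering offsets -h..+h."""
    return relative_to_genomic(g, -h), relative_to_genomic(g, h) + 1


def offsets_array(h: int) -> np.ndarray:
    return np.array(offset_labels(h), dtype=int)
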