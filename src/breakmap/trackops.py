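"""Track operations: RPM normalisation, masking, smoothing, reproducibility.

RPM (reads per million mapped reads) uses one denominator — the library's
total mapped reads — shared by both strands, so the genome-wide sum over
both strands of an unmasked RPM track is exactly 1,000,000.

Hann smoothing is a display aid only: the raised-cosine kernel blurs the
single-nucleotide signal, so smoothed tracks are refused by the peak caller
and by cross-correlation.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .masks import MaskSet
from .track import RAW_COUNTS, RPM, StrandTrack


def normalize_rpm(track: StrandTrack) -> StrandTrack:
    """Scale raw counts to reads per million mapped reads.

    Every value is multiplied by 1e6 / total_mapped; both strands share the
    one denominator.
    """
    if track.units != RAW_COUNTS:
        raise ValueError("track is already normalised (units != raw_counts)")
    if track.total_mapped <= 0:
        raise ValueError("cannot normalise a track with zero mapped reads")
    out = track.copy()
    factor = 1_000_000.0 / track.total_mapped
    for name in out.names:
        out.top[name] *= factor
        out.bottom[name] *= factor
    out.units = RPM
    return out


def apply_mask(track: StrandTrack, masks: MaskSet) -> StrandTrack:
    """Flag masked positions missing and drop excluded sequences.

    Missing is distinct from zero: masked positions are excluded from peak
    calling, correlations and composition backgrounds. Values at unmasked
    positions are untouched, so normalisation and masking commute there.
    """
    keep = [n for n in track.names if n not in masks.excluded]
    missing = {}
    for name in keep:
        m = track.missing_mask(name).copy()
        m |= masks.boolean_mask(name, track.lengths[name])
        missing[name] = m
    return StrandTrack(
        lengths={n: track.lengths[n] for n in keep},
        circular=frozenset(n for n in track.circular if n in keep),
        top={n: track.top[n].copy() for n in keep},
        bottom={n: track.bottom[n].copy() for n in keep},
        units=track.units,
        total_mapped=track.total_mapped,
        missing=missing,
        smoothed=track.smoothed,
    )


def hann_kernel(width: int) -> np.ndarray:
    """Raised-cosine weights w[n] = 0.5(1 - cos(2*pi*n/(width-1))),
    n = 0..width-1, normalised to sum 1. Endpoints are exactly zero."""
    if width < 3 or width % 2 == 0:
        raise ValueError("width must be odd and >= 3")
    n = np.arange(width)
    w = 0.5 * (1.0 - np.cos(2.0 * np.pi * n / (width - 1)))
    return w / w.sum()


def smooth_hann(track: StrandTrack, width: int = 21) -> StrandTrack:
    """Smooth each strand with a Hann window (display only).

    Circular sequences wrap; linear sequences truncate the kernel at the
    edges and renormalise, so total signal is conserved exactly on circular
    sequences and edge values are unbiased on linear ones.
    """
    kernel = hann_kernel(width)
    out = track.copy()
    half = width // 2
    for name in out.names:
        circ = track.is_circular(name)
        for strand in (out.top, out.bottom):
            v = strand[name]
            if circ:
                L = v.size
                padded = np.concatenate([v[-half:], v, v[:half]])
                strand[name] = np.convolve(padded, kernel, mode="valid")[:L]
            else:
                num = np.convolve(v, kernel, mode="same")
                den = np.convolve(np.ones_like(v), kernel, mode="same")
                strand[name] = num / den
    out.smoothed = True
    return out


def _paired_values(
    a: StrandTrack,
    b: StrandTrack,
    positions=None,
) -> tuple[np.ndarray, np.ndarray]:
    """Strand-concatenated value pairs over common unmasked positions."""
    xs, ys = [], []
    if positions is None:
        for name in a.names:
            if name not in b.lengths:
                continue
            keep = ~(a.missing_mask(name) | b.missing_mask(name))
            for strand in ("top", "bottom"):
                xs.append(a.strand(strand)[name][keep])
                ys.append(b.strand(strand)[name][keep])
    else:
        for peak in positions:
            name, pos, strand = peak.sequence, peak.position, peak.strand
            if a.missing_mask(name)[pos] or b.missing_mask(name)[pos]:
                continue
            xs.append(np.array([a.strand(strand)[name][pos]]))
            ys.append(np.array([b.strand(strand)[name][pos]]))
    return np.concatenate(xs), np.concatenate(ys)


def replicate_correlation(
    a: StrandTrack,
    b: StrandTrack,
    positions=None,
    log_transform: bool = False,
) -> float:
    """Pearson correlation between two libraries' per-position signals.

    Values from both strands are concatenated position-wise over all
    unmasked positions (or over the given peak positions). With
    ``log_transform`` the correlation is computed on log10(x + 1).
    """
    if a.units != b.units:
        raise ValueError("tracks must share units")
    x, y = _paired_values(a, b, positions)
    if x.size < 2:
        raise ValueError("need at least two positions to correlate")
    if log_transform:
        x, y = np.log10(x + 1.0), np.log10(y + 1.0)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined: zero variance on one side")
    return float(stats.pearsonr(x, y).statistic)
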