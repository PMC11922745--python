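# Methods

## Coordinate and orientation conventions

All internal coordinates are 0-based, half-open; BED and bedGraph files use
their standard dialects. Dyad-relative positions are labelled
…,−2,−1,+1,+2,… with no zero: for a dyad pair of genomic positions
(*g*, *g* + 1), relative −*k* maps to *g* − (*k* − 1) and +*k* to
(*g* + 1) + (*k* − 1). The dyad index *g* is the genomic position of the
relative −1 base. Circularity (plasmid substrates) is an explicit
per-sequence input flag, never auto-detected; circular sequences wrap in
window extraction, smoothing, neighbour lookups, cross-correlation and
motif scanning, while linear sequences have ends (telomere masks, dropped
windows, zero out-of-range neighbours).

A top-strand read 5′ end at *q* marks offset −1 of dyad (*q*, *q* + 1);
a bottom-strand read 5′ end at *q* marks offset −1 *on its own strand*, so
its window is reverse-complemented and its dyad pair is (*q*, *q* − 1) in
genomic coordinates. This "reorientation" puts both strands of a
rotationally symmetric cleavage signature into one frame.

## The cleavage-preference model and simulator

Cleavage preference is a product position-weight model over offsets
−*h*…−1,+1…+*h* (default *h* = 10): the score of dyad *g* is the product of
per-base weights at each offset, and site probabilities are scores
normalised over all valid dyads. Rotational symmetry — weight(*b*, +*k*) =
weight(complement(*b*), −*k*) — encodes two protomers engaging two DNA
half-sites; it is validated exactly on construction when declared.

The default model elevates G at −3, A at −1, T at +1 and C at +3 with
weight 4 against a unit background. Weight 4 makes the favoured base reach
a fraction of roughly 0.6 at the core offsets among cleavages on a
GC-0.45 genome — a strong but not deterministic composition bias, not a
strict motif; by exhaustive enumeration the best-scoring hexamer set over
offsets −3…+3 is exactly the GNATNC matches (all N choices tie). The
elevation strength is a free generator parameter, fixed once.

Each simulated DSB at dyad *g* yields one top-strand end at *g* and one
bottom-strand end at *g* + 1. Independently per end, with probability φ
(default 0.1) the end is shifted *s* nt inward (top to *g* + *s*, bottom to
*g* + 1 − *s*; default *s* = 1), emulating incomplete fill-in of the 5′
overhang before adaptor ligation — the artifact the peak caller's exclusion
rule targets. A fraction β (default 0.05) of DSBs fall at uniformly random
valid dyads. Default scales: 50-kb genome, GC 0.45, 2,000 DSBs. φ is a free
parameter of the generator, not an estimate of any real library.

The catalytically-dead control is modelled as pure random breakage: *N* top
and *N* bottom 5′ ends placed independently and uniformly, with no dyad
pairing. This is deliberate — random background has no overhang phasing, so
control maps must show no preferred cross-correlation lag; pairing control
ends at dyads would build the +1 offset into the negative control and make
the polarity analysis unfalsifiable.

What the simulator does *not* model: fragment lengths and shearing,
sequencing errors, nicks (the library chemistry captures DSB ends only),
resection, mappability variation, and real-genome sequence heterogeneity
(simulated genomes are i.i.d.). Passing tests therefore demonstrate
correctness of the analysis logic under the stated generative model, not
performance on real libraries.

## Normalisation, masking, smoothing, reproducibility

RPM uses one denominator — total mapped reads in the library — shared by
both strands, so an unmasked RPM track sums to exactly 10⁶ over both
strands. Masked positions are flagged *missing*, distinct from zero, and
excluded from peak calling, correlations and composition backgrounds;
serialisation keeps values and writes masks separately, because writing
zeros would bias correlations and backgrounds. Telomere masks
([0, *t*) and [len − *t*, len), default *t* = 500 bp) apply to linear
sequences only.

Hann smoothing (width 21 by default, endpoints of the raised cosine exactly
zero, kernel normalised to sum 1) is display-only: smoothed tracks are
refused by the peak caller and by cross-correlation, which both depend on
single-nucleotide structure. Circular sequences wrap (conserving totals to
float precision); linear edges truncate the kernel and renormalise.

Replicate reproducibility is Pearson correlation of per-position,
strand-concatenated values over unmasked positions, on untransformed RPM by
default with a log10(x + 1) option; the statistic itself is this package's
choice of reproducibility measure and is reported as such. Note that with
the generator's exactly-two-reads-per-DSB design, replicates sharing one
planted landscape differ only through independent fill-in draws, which at
default φ = 0.1 and mean per-site multiplicity ≈ 2 bounds the attainable
per-position r near 0.89.

## Peak calling

A top-strand position *q* is a peak iff top[*q*] > threshold (strict) and
top[*q*] ≥ top[*q* − *w*]; a bottom-strand position iff
bottom[*q*] > threshold and bottom[*q*] ≥ bottom[*q* + *w*] (*w* = 1 by
default, configurable to probe a 2-nt comparison span). The compared
neighbour is the position that would carry the genuine signal if the
candidate were a fill-in artifact. Rejection requires *strict* inferiority:
equal neighbours are both called, so genuine adjacent sites of equal
strength are not suppressed. Masked or out-of-range neighbours count as
zero. Thresholds are fixed strand-specific RPM presets by substrate scale
(plasmid 3,000; bacterial 10; yeast 15); no multiple-testing machinery is
attached, matching the fixed-threshold design. Peaks are single
nucleotides by construction.

## Polarity

r(*k*) is the Pearson correlation of (top[*i*], bottom[*i* + *k*]) over all
unmasked *i* valid at lag *k*, for *k* = −10…+10; positive *k* means the
bottom-strand signal sits *k* nt to the right. Pearson over lags is the
standard strand-shift estimator; the tie-break prefers the smallest |*k*|,
then the positive lag. Overhang length is *L* = *k\** + 1 (enumerating cut
geometries: blunt ⇒ both 5′ ends at the same duplex position offset −1/0 ⇒
*k\** = −1; 1-nt 5′ overhang ⇒ *k\** = 0; 2-nt ⇒ *k\** = +1); *k\** < −1
would imply a 3′ overhang and is rejected rather than extrapolated. A
rotation-permutation null (circularly shifting the bottom strand) provides
a significance check for control libraries.

## Composition, logos, motif averaging

Base composition across peak windows is unweighted (each peak counts once);
a read-count-weighted variant exists behind a flag since weighting is a
genuinely open choice. Windows containing N, or running off a linear end,
are dropped and counted. Logo letter heights are per-letter relative
entropy *f* log₂(*f*/*q*) in bits against the GC-split background; the
background GC may be the genome average or a local override when the
neighbourhood of mapped sites differs substantially from the genome
average. Degenerate patterns must have even length so the central dyad is
unambiguous; overlapping matches are all retained; a genomic N matches only
the fully degenerate pattern code. The preferred/reverse contrast statistic
is E = (top mean at −1 + bottom mean at +1) / (2 × median of both strands
at |k| > 5), normalised so a flat profile gives E = 1, reported for each
pattern together with their ratio.

## Numerical and degenerate-input choices

bedGraph round-trips are lossless: values are written as shortest
re-readable decimals, runs of equal value merged, zero runs omitted, and
units plus the RPM denominator carried in a header comment. Simulated
stage seeds are spawned from one user seed via `numpy` `SeedSequence`, so
every stage is independently reproducible. Ends shifted off a linear
sequence by the artifact are dropped with a logged warning, never
silently. Zero-variance inputs to any correlation raise errors rather than
returning NaN. The protein-mass utility sums standard average residue
masses plus one water per chain (via Biopython) and accepts only the 20
standard one-letter codes.

## Problem sizes

Default verification runs use 50-kb genomes with 2,000–20,000 DSBs
(parameter-recovery analyses use 20,000 breaks with no background), 1-kb
sequences for exhaustive scanner cross-checks, and ≤10-kb tracks for
position-by-position peak-caller oracles; these scales give stable
statistics for every claim checked while keeping the full suite fast.

## Known limitations

- The artifact comparison window *w* = 1 is the default interpretation of
  the exclusion rule; whether real pipelines compare across the full 2-nt
  overhang is unstated, hence *w* is configurable.
- The reproducibility statistic, logo formula and enrichment statistic are
  reasonable standard choices where the field's descriptions name only the
  concept.
- Hotspot-restricted in vivo analyses (external hotspot coordinate sets)
  are representable via masks but no hotspot caller is included.
- bigWig output and BAM input are out of scope; tracks are exchanged as
  bedGraph pairs, read ends as BED6.
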