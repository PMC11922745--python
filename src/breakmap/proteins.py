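"""Small protein-mass utility.

Used to predict the mass of protein complexes (e.g. a 1:1 heterodimer of a
topoisomerase-like catalytic subunit and its B-subunit partner) from their
amino-acid sequences, for comparison with size-exclusion chromatography and
mass photometry estimates.
"""

from __future__ import annotations

from Bio.SeqUtils import molecular_weight

STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")


def average_protein_mass(aa_sequence: str) -> float:
    """Average (isotope-abundance-weighted) mass of a protein, in daltons.

    Sum of standard average residue masses plus one water per chain.
    Only the 20 standard one-letter codes are accepted.
    """
    seq = aa_sequence.strip().upper()
    if not seq:
        raise ValueError("empty amino-acid sequence")
    bad = set(seq) - STANDARD_AA
    if bad:
        raise ValueError(
            f"invalid amino-acid letter(s): {''.join(sorted(bad))}"
        )
    return float(
        molecular_weight(seq, seq_type="protein", monoisotopic=False)
    )


def complex_mass(*aa_sequences: str) -> float:
    """Predicted mass (Da) of a complex: sum of chain masses."""
    if not aa_sequences:
        raise ValueError("at least one chain required")
    return sum(average_protein_mass(s) for s in aa_sequences)
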