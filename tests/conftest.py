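import numpy as np
import pytest

from breakmap import (
    GenomeSequence,
    StrandTrack,
    default_model,
    normalize_rpm,
    simulate_dataset,
)


@pytest.fixture
def toy_genome() -> GenomeSequence:
    """100-nt linear sequence with a known composition."""
    rng = np.random.default_rng(42)
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 100)])
    return GenomeSequence({"p": seq})


@pytest.fixture
def circular_genome() -> GenomeSequence:
    rng = np.random.default_rng(43)
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 200)])
    return GenomeSequence({"plasmid": seq}, circular={"plasmid"})


def make_track(genome, top=(), bottom=(), units="raw_counts", total=None):
    """Track with counts placed at (name, pos, value) triples."""
    track = StrandTrack.zeros(genome, units=units)
    for name, pos, value in top:
        track.top[name][pos] = value
    for name, pos, value in bottom:
        track.bottom[name][pos] = value
    track.total_mapped = (
        total
        if total is not None
        else float(sum(v for *_, v in top) + sum(v for *_, v in bottom))
    )
    return track


@pytest.fixture(scope="session")
def default_simulation():
    """One default-parameter artifact-free simulation shared across tests."""
    genome, truth, raw = simulate_dataset(seed=11, phi=0.0)
    return genome, truth, raw, normalize_rpm(raw)
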