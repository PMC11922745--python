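"""Simulator: preference model, planted breaks, overhang/artifact geometry."""

import itertools

import numpy as np
import pytest
from scipy import stats

from breakmap import (
    CleavagePreferenceModel,
    GenomeSequence,
    default_model,
    simulate_breaks,
    simulate_control,
    simulate_genome,
    simulate_tracks,
    site_probabilities,
)
from breakmap.simulate import DEFAULTS


class TestSimulateGenome:
    def test_reproducible_and_gc_within_binomial_ci(self):
        length, gc = 10_000, 0.5
        g1 = simulate_genome(length, gc, seed=5)
        g2 = simulate_genome(length, gc, seed=5)
        assert g1.sequences == g2.sequences
        observed = (g1["sim"].count("G") + g1["sim"].count("C")) / length
        half_width = 2.576 * np.sqrt(gc * (1 - gc) / length)  # 99% CI
        assert abs(observed - gc) < half_width

    def test_different_seeds_differ(self):
        assert simulate_genome(1000, 0.5, seed=1)["sim"] != \
            simulate_genome(1000, 0.5, seed=2)["sim"]

    @pytest.mark.parametrize("gc", [0.0, 1.0, -0.1])
    def test_degenerate_gc_rejected(self, gc):
        with pytest.raises(ValueError):
            simulate_genome(1000, gc)


class TestDefaultModel:
    def test_core_signature_weights(self):
        m = default_model()
        assert m.weight("G", -3) > m.weight("A", -3)
        assert m.weight("G", -3) == m.weight("C", +3)  # rotational symmetry
        assert m.weight("A", -1) == m.weight("T", +1)

    def test_rotational_symmetry_exact(self):
        assert default_model().is_symmetric()

    def test_asymmetric_weights_fail_declared_symmetry(self):
        m = default_model()
        weights = m.weights.copy()
        weights[0, 0] *= 2
        with pytest.raises(ValueError, match="symmetry"):
            CleavagePreferenceModel(h=m.h, weights=weights, symmetric=True)

    def test_h_below_core_rejected(self):
        with pytest.raises(ValueError):
            default_model(h=2)

    def test_best_hexamers_are_exactly_gnatnc(self):
        """Enumerate all 4^6 hexamers over offsets -3..+3; the argmax set
        must be exactly the GNATNC matches (all N choices tying)."""
        m = default_model()
        offsets = [-3, -2, -1, 1, 2, 3]

        def score(hexamer):
            return np.prod([m.weight(b, k) for b, k in zip(hexamer, offsets)])

        scores = {
            "".join(h): score(h)
            for h in itertools.product("ACGT", repeat=6)
        }
        best = max(scores.values())
        argmax = {h for h, s in scores.items() if s == best}
        gnatnc = {
            f"G{n1}AT{n2}C" for n1 in "ACGT" for n2 in "ACGT"
        }
        assert argmax == gnatnc


class TestSiteProbabilities:
    def test_uniform_model_gives_uniform_probabilities(self):
        genome = simulate_genome(200, 0.5, seed=3)
        m = CleavagePreferenceModel(h=3, weights=np.ones((4, 6)))
        probs = site_probabilities(genome, m)["sim"]
        valid = probs > 0
        assert valid.sum() == 200 - 2 * 3 + 1
        np.testing.assert_allclose(probs[valid], 1.0 / valid.sum())

    def test_probabilities_sum_to_one(self, circular_genome):
        probs = site_probabilities(circular_genome, default_model(h=5))
        assert sum(p.sum() for p in probs.values()) == pytest.approx(1.0)

    def test_matches_brute_force_product_on_toy_genome(self):
        """Hand-multiplied per-dyad weight products on a 12-nt sequence."""
        genome = GenomeSequence({"t": "GGATCCAGATTC"})
        rng = np.random.default_rng(9)
        weights = rng.uniform(0.5, 2.0, size=(4, 6))
        m = CleavagePreferenceModel(h=3, weights=weights)
        probs = site_probabilities(genome, m)["t"]

        def brute(g):
            total = 1.0
            for k in [-3, -2, -1, 1, 2, 3]:
                pos = g - (-k - 1) if k < 0 else (g + 1) + (k - 1)
                total *= m.weight(genome["t"][pos], k)
            return total

        expected = np.zeros(12)
        for g in range(2, 9):  # h-1 .. L-1-h
            expected[g] = brute(g)
        expected /= expected.sum()
        np.testing.assert_allclose(probs, expected, rtol=1e-12)

    def test_n_windows_get_zero_probability(self):
        genome = GenomeSequence({"t": "ACGTACNTACGTACGT"})
        m = CleavagePreferenceModel(h=3, weights=np.ones((4, 6)))
        probs = site_probabilities(genome, m)["t"]
        # dyads whose -3..+3 window covers the N at index 6
        for g in range(4, 10):
            window = range(g - 2, g + 4)
            if 6 in window:
                assert probs[g] == 0.0

    def test_too_short_linear_sequence_rejected(self):
        genome = GenomeSequence({"t": "ACGTA"})
        with pytest.raises(ValueError):
            site_probabilities(genome, default_model(h=3))


class TestSimulateBreaks:
    def test_counts_sum_to_n(self):
        genome = simulate_genome(2000, 0.45, seed=2)
        truth = simulate_breaks(genome, default_model(h=5), 500, seed=4)
        assert sum(c for _, _, c in truth.sites) == 500

    def test_pure_background_is_uniform_by_chisquare(self):
        genome = simulate_genome(1000, 0.5, seed=6)
        m = CleavagePreferenceModel(h=3, weights=np.ones((4, 6)), beta=1.0)
        truth = simulate_breaks(genome, m, 10_000, seed=8)
        counts = truth.counts("sim", 1000)
        valid = slice(2, 995)  # h-1 .. L-h
        stat = stats.chisquare(counts[valid])
        assert stat.pvalue > 0.01

    def test_preference_enriches_gnatnc_dyads_over_genome_density(self):
        """With beta=0 the DSB fraction at GNATNC dyads must exceed the
        brute-force genomic density of GNATNC matches."""
        genome = simulate_genome(20_000, 0.45, seed=12)
        m = default_model(beta=0.0)
        truth = simulate_breaks(genome, m, 5_000, seed=13)

        seq = genome["sim"]

        def is_gnatnc(g):
            hexamer = seq[g - 2 : g + 4]
            return (
                len(hexamer) == 6
                and hexamer[0] == "G"
                and hexamer[2:4] == "AT"
                and hexamer[5] == "C"
            )

        valid = range(m.h - 1, len(seq) - m.h)
        density = sum(is_gnatnc(g) for g in valid) / len(valid)
        dsb_at_motif = sum(c for _, g, c in truth.sites if is_gnatnc(g))
        assert dsb_at_motif / truth.n_breaks > density

    def test_determinism(self):
        genome = simulate_genome(2000, 0.45, seed=2)
        m = default_model(h=5)
        t1 = simulate_breaks(genome, m, 300, seed=5)
        t2 = simulate_breaks(genome, m, 300, seed=5)
        assert t1.sites == t2.sites


class TestSimulateTracks:
    def _single_site_truth(self, genome, g, count, **model_kw):
        from breakmap.simulate import SimTruth

        m = default_model(h=3, **model_kw)
        return SimTruth(sites=[("sim", g, count)], n_breaks=count, seed=0,
                        model=m)

    def test_clean_overhang_geometry(self):
        genome = simulate_genome(100, 0.5, seed=1)
        truth = self._single_site_truth(genome, 50, 7, phi=0.0)
        track = simulate_tracks(truth, genome, seed=2)
        assert track.top["sim"][50] == 7
        assert track.bottom["sim"][51] == 7
        assert track.top["sim"].sum() == 7 and track.bottom["sim"].sum() == 7

    def test_full_artifact_shifts_both_ends_inward(self):
        genome = simulate_genome(100, 0.5, seed=1)
        truth = self._single_site_truth(genome, 50, 7, phi=1.0, shift=1)
        track = simulate_tracks(truth, genome, seed=2)
        assert track.top["sim"][51] == 7  # g + s
        assert track.bottom["sim"][50] == 7  # (g+1) - s

    @pytest.mark.parametrize("phi", [0.0, 0.3, 1.0])
    def test_count_conservation_on_circular_genome(self, phi):
        genome = simulate_genome(500, 0.5, circular=True, seed=3)
        m = default_model(h=4, beta=0.2, phi=phi)
        truth = simulate_breaks(genome, m, 400, seed=9)
        track = simulate_tracks(truth, genome, seed=10)
        total = track.top["sim"].sum() + track.bottom["sim"].sum()
        assert total == 2 * truth.n_breaks
        assert track.total_mapped == 2 * truth.n_breaks

    def test_symmetry_propagates_to_composition(self):
        """With a symmetric model and phi=0 the expected dyad-relative
        composition obeys f(b, -k) = f(complement(b), +k) within 3 s.e."""
        genome = simulate_genome(50_000, 0.45, seed=21)
        m = default_model(beta=0.0, phi=0.0)
        truth = simulate_breaks(genome, m, 20_000, seed=22)
        seq = genome["sim"]
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        n = truth.n_breaks
        # breaks cluster on hot dyads, so the independent units are the
        # distinct sites; the estimator's variance uses the site weights
        w2 = sum((c / n) ** 2 for _, _, c in truth.sites)
        for k in (1, 2, 3, 5):
            for base in "ACGT":
                minus = sum(
                    c for _, g, c in truth.sites if seq[g - (k - 1)] == base
                ) / n
                plus = sum(
                    c
                    for _, g, c in truth.sites
                    if seq[g + k] == comp[base]
                ) / n
                se = np.sqrt(
                    (minus * (1 - minus) + plus * (1 - plus)) * w2
                )
                assert abs(minus - plus) <= 3 * max(se, 1e-3)


class TestSimulateControl:
    def test_same_seed_identical(self):
        genome = simulate_genome(5000, 0.45, seed=30)
        a = simulate_control(genome, 1000, seed=31)
        b = simulate_control(genome, 1000, seed=31)
        np.testing.assert_array_equal(a.top["sim"], b.top["sim"])
        np.testing.assert_array_equal(a.bottom["sim"], b.bottom["sim"])

    def test_total_counts_2n(self):
        genome = simulate_genome(5000, 0.45, seed=30)
        track = simulate_control(genome, 1000, seed=32)
        assert track.top["sim"].sum() + track.bottom["sim"].sum() == 2000


def test_dataset_defaults_match_study_conditions(default_simulation):
    genome, truth, raw, _ = default_simulation
    assert genome.total_length == DEFAULTS["genome_length"]
    assert truth.n_breaks == DEFAULTS["n_breaks"]
    assert raw.total_mapped == 2 * DEFAULTS["n_breaks"]
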