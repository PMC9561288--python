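"""Peak-to-product matching: binary search against a quadratic oracle,
tolerance monotonicity, intensity aggregation, coverage round-trips and
the multiplexed-pool specificity report."""

import numpy as np
import pytest

from ribodigest import chemistry as ch
from ribodigest import ms1_match as mm
from ribodigest.coverage import EXCLUDED, UNIQUE, classify_products, predicted_coverage
from ribodigest.digestion import BUILTIN_ENZYMES, complete_digest, digest_with_missed, length_filter
from ribodigest.ms1_match import DeconvolutedPeak
from ribodigest.synthetic import (
    NoiseModel,
    dinucleotide_pool,
    random_transcript,
    simulate_peak_list,
)

HR4 = BUILTIN_ENZYMES["hRNase4"]


def peaks_at(masses, intensity=1.0):
    return [DeconvolutedPeak(m, intensity) for m in masses]


@pytest.fixture
def products():
    seq = random_transcript(600, seed=42)
    return length_filter(digest_with_missed(seq, HR4, 1, "t"), 4, 40)


class TestMatchPeaks:
    def test_exact_mass_matches_at_zero_ppm(self, products):
        peak = DeconvolutedPeak(products[0].mass, 100.0)
        matches = mm.match_peaks([peak], products, 10.0)
        assert any(m.product is products[0] and m.ppm == 0.0 for m in matches)

    def test_out_of_tolerance_peak_unmatched(self, products):
        mass = products[0].mass * (1 + 20e-6)
        if not any(abs(ch.ppm_error(mass, p.mass)) <= 10 for p in products):
            assert mm.match_peaks([DeconvolutedPeak(mass, 1.0)], products, 10.0) == []

    def test_empty_product_list_is_empty_result(self):
        assert mm.match_peaks(peaks_at([500.0]), [], 10.0) == []

    def test_agrees_with_allpairs_bruteforce(self, products, rng):
        masses = rng.uniform(1000, 14000, size=800)
        near = np.array([p.mass * (1 + rng.normal(0, 3e-6)) for p in products[:200]])
        peaks = peaks_at(np.concatenate([masses, near]))
        got = {
            (m.peak.mass, m.product.start, m.product.end, m.product.missed_cleavages)
            for m in mm.match_peaks(peaks, products, 10.0)
        }
        expected = {
            (pk.mass, p.start, p.end, p.missed_cleavages)
            for pk in peaks
            for p in products
            if abs(ch.ppm_error(pk.mass, p.mass)) <= 10.0
        }
        assert got == expected

    def test_tolerance_monotonicity(self, products, rng):
        peaks = peaks_at(
            [p.mass * (1 + rng.normal(0, 5e-6)) for p in products[:150]]
        )
        key = lambda m: (m.peak.mass, m.product.start, m.product.end, m.product.missed_cleavages)
        at5 = {key(m) for m in mm.match_peaks(peaks, products, 5.0)}
        at10 = {key(m) for m in mm.match_peaks(peaks, products, 10.0)}
        assert at5 <= at10

    def test_result_independent_of_input_order(self, products, rng):
        peaks = peaks_at([p.mass for p in products[:50]])
        key = lambda m: (m.peak.mass, m.product.start, m.product.end, m.product.missed_cleavages, m.ambiguous)
        a = sorted(map(key, mm.match_peaks(peaks, products, 10.0)))
        shuffled = list(products)[::-1]
        b = sorted(map(key, mm.match_peaks(peaks[::-1], shuffled, 10.0)))
        assert a == b

    def test_ambiguity_flag_on_multi_sequence_peak(self):
        # two isomeric products (ACG / CAG with same termini) share a mass
        seq = tuple("ACGCAGAA")
        prods = complete_digest(seq, BUILTIN_ENZYMES["RNaseT1"], "t")
        iso = [p for p in prods if len(p) == 3]
        matches = mm.match_peaks([DeconvolutedPeak(iso[0].mass, 1.0)], iso, 5.0)
        assert len(matches) == 2 and all(m.ambiguous for m in matches)


class TestAggregateIntensity:
    def test_single_peak_single_product(self, products):
        matches = mm.match_peaks([DeconvolutedPeak(products[0].mass, 7.5)], products[:1], 5.0)
        assert mm.aggregate_intensity(matches) == {products[0].sequence: 7.5}

    def test_two_peaks_one_sequence_sum(self, products):
        p = products[0]
        peaks = [
            DeconvolutedPeak(p.mass * (1 + 2e-6), 3.0),
            DeconvolutedPeak(p.mass * (1 - 2e-6), 4.0),
        ]
        matches = mm.match_peaks(peaks, [p], 10.0)
        assert mm.aggregate_intensity(matches)[p.sequence] == pytest.approx(7.0)

    def test_intensity_conservation_under_unambiguous_matching(self, products):
        peaks = peaks_at([p.mass for p in products[:30]], intensity=2.0)
        matches = [m for m in mm.match_peaks(peaks, products, 10.0) if not m.ambiguous]
        total = sum(mm.aggregate_intensity(matches).values())
        assert total <= sum(pk.intensity for pk in peaks) + 1e-9


class TestExperimentalCoverage:
    def test_no_peaks_is_zero(self):
        _, frac = mm.experimental_unique_coverage([], 100)
        assert frac == 0.0

    def test_noiseless_round_trip_equals_predicted(self):
        """Simulated peaks at 0 ppm noise and 100% detection recover the
        predicted coverage exactly."""
        seq = random_transcript(800, seed=7)
        prods = length_filter(complete_digest(seq, HR4, "t"), 4, 40)
        labels = classify_products(prods)
        # non-unique-sequence products are dropped before mass comparison
        retained = [p for p in prods if labels[p] != EXCLUDED]
        noise = NoiseModel(ppm_sigma=0.0, detection_prob=1.0, contaminant_rate=0.0, seed=1)
        peaks = simulate_peak_list(retained, noise)
        matches = mm.match_peaks(peaks, retained, 10.0)
        _, frac = mm.experimental_unique_coverage(matches, len(seq))
        assert frac == pytest.approx(
            predicted_coverage(seq, HR4, 4, 40, unique_only=True), abs=1e-12
        )

    def test_high_detection_recovers_most_unique_coverage(self):
        seq = random_transcript(1000, seed=21)
        prods = length_filter(digest_with_missed(seq, HR4, 1, "t"), 4, 40)
        noise = NoiseModel(ppm_sigma=3.0, detection_prob=0.95, contaminant_rate=0.0, seed=3)
        peaks = simulate_peak_list(prods, noise)
        matches = mm.match_peaks(peaks, prods, 10.0)
        _, frac = mm.experimental_unique_coverage(matches, len(seq))
        assert frac >= 0.90 * predicted_coverage(seq, HR4, 4, 40, unique_only=True)


class TestMissedCleavageStats:
    def test_all_mass_in_bin_zero_without_missed(self, products):
        zero = [p for p in products if p.missed_cleavages == 0]
        peaks = peaks_at([p.mass for p in zero[:20]])
        stats = mm.missed_cleavage_stats(mm.match_peaks(peaks, zero, 5.0))
        assert set(stats["missed_cleavages"]) == {0}

    def test_bins_sum_to_total_context_entries(self, products):
        peaks = peaks_at([p.mass for p in products[:60]])
        matches = mm.match_peaks(peaks, products, 5.0)
        stats = mm.missed_cleavage_stats(matches)
        expected = sum(max(1, len(m.product.missed_site_contexts)) for m in matches)
        assert stats["n_matches"].sum() == expected

    def test_ug_biased_dropout_shows_ug_excess(self):
        """If complete-digest products spanning UG sites preferentially
        drop out (remain uncleaved), matched 1-missed products concentrate
        at UG contexts."""
        seq = random_transcript(4000, seed=5)
        prods = length_filter(digest_with_missed(seq, HR4, 1, "t"), 4, 40)
        one_missed = [p for p in prods if p.missed_cleavages == 1]
        ug = [p for p in one_missed if p.missed_site_contexts == ("UG",)]
        ua = [p for p in one_missed if p.missed_site_contexts == ("UA",)]
        # constructed fixture: detect all UG-missed products, a third of UA-missed
        detected = ug + ua[: len(ua) // 3]
        peaks = peaks_at([p.mass for p in detected])
        stats = mm.missed_cleavage_stats(mm.match_peaks(peaks, one_missed, 5.0))
        by_ctx = stats.set_index("site_context")["n_matches"]
        assert by_ctx.get("UG", 0) > by_ctx.get("UA", 0)


class TestPoolSpecificity:
    def test_identical_runs_give_zero_log2fc(self):
        pool = dinucleotide_pool()
        peaks = [DeconvolutedPeak(ch.oligo_mass(rec.codes), 100.0) for rec in pool]
        rep = mm.pool_specificity_report(peaks, peaks, pool, HR4, 10.0)
        vals = rep["oligo_log2fc"]["log2_fold_change"]
        assert np.allclose(vals, 0.0)

    def test_absent_oligo_is_flagged_fully_depleted(self):
        pool = dinucleotide_pool()
        ctl = [DeconvolutedPeak(ch.oligo_mass(rec.codes), 100.0) for rec in pool]
        enz = ctl[1:]  # first oligo absent from the enzyme run
        rep = mm.pool_specificity_report(enz, ctl, pool, HR4, 10.0)
        row = rep["oligo_log2fc"].iloc[0]
        assert row["log2_fold_change"] == -np.inf and row["flag"] == "fully_depleted"

    def test_simulated_ur_cleavage_reproduces_pool_pattern(self):
        """In-silico hRNase 4 digestion of the dinucleotide pool: every
        U-containing oligo except the UC one is depleted, no U-free oligo
        is depleted, and 3'-U products dominate the 5'-product bins."""
        pool = dinucleotide_pool()
        ctl, enz = [], []
        for rec in pool:
            intact_mass = ch.oligo_mass(rec.codes)
            ctl.append(DeconvolutedPeak(intact_mass, 100.0))
            prods = complete_digest(rec.codes, HR4, rec.id)
            if len(prods) == 1:
                enz.append(DeconvolutedPeak(intact_mass, 100.0))  # uncut
            else:
                for p in prods:
                    if len(p) >= 2:
                        enz.append(DeconvolutedPeak(p.mass, 100.0))
        rep = mm.pool_specificity_report(enz, ctl, pool, HR4, 10.0)
        fc = rep["oligo_log2fc"].set_index("oligo_id")["log2_fold_change"]
        for rec in pool:
            has_cut = bool(len(complete_digest(rec.codes, HR4)) > 1)
            if "U" in rec.codes and rec.id != "pool_UC" and has_cut:
                assert fc[rec.id] == -np.inf
            if "U" not in rec.codes or rec.id == "pool_UC":
                assert fc[rec.id] == pytest.approx(0.0)
        bins5 = rep["five_prime_bins"]
        assert bins5.idxmax() == "U"
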