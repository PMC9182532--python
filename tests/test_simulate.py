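"""Trace and digest generators: statistics, ground truth, determinism."""

import numpy as np
import pytest

from ccscore import (
    DigestConfig,
    ProteinSequence,
    SpeciesModel,
    TETRAD_INTERVAL,
    TraceConfig,
    map_read,
    simulate_digest,
    simulate_mixture,
    simulate_trace,
)
from ccscore.exceptions import ConfigurationError, ValidationError


class TestTraceStatistics:
    def test_background_only_counts_are_poisson(self):
        """With no species, each channel is a flat Poisson background."""
        cfg = TraceConfig(duration_s=10.0, background_green=2.0,
                          background_red=3.0, seed=7)
        trace = simulate_trace([], cfg)
        for counts, rate in ((trace.green, 2.0), (trace.red, 3.0)):
            n = counts.size
            se = np.sqrt(rate / n)
            assert abs(counts.mean() - rate) < 3 * se
            # Poisson: variance equals the mean.
            assert abs(counts.var() - rate) < 5 * rate * np.sqrt(2.0 / n)
        assert trace.ground_truth == []

    def test_green_only_species_leaves_red_at_background(self):
        cfg = TraceConfig(duration_s=20.0, seed=3)
        sp = SpeciesModel("homo_green", 2.0, 80.0, 0.0, 2.0)
        trace = simulate_trace([sp], cfg)
        assert len(trace.ground_truth) > 0
        assert all(not b.is_dual for b in trace.ground_truth)
        # Red never sees an envelope: its counts stay Poisson-background-like.
        assert trace.red.max() < cfg.background_red + 10 * np.sqrt(cfg.background_red) + 5
        assert trace.green.max() > 50

    def test_heteromeric_bursts_light_both_channels(self):
        cfg = TraceConfig(duration_s=180.0, seed=5)
        sp = SpeciesModel("dual", 50.0 / 180.0, 100.0, 100.0, 2.0)
        trace = simulate_trace([sp], cfg)
        n = len(trace.ground_truth)
        # Poisson(50) draw, reproducible and within a generous range.
        assert 25 <= n <= 80
        assert trace.ground_truth == simulate_trace([sp], cfg).ground_truth
        for burst in trace.ground_truth:
            assert trace.green[burst.apex_bin] > 20
            assert trace.red[burst.apex_bin] > 20

    def test_expected_envelope_matches_apex_counts(self):
        """Mean count at ground-truth apexes approximates brightness + background."""
        cfg = TraceConfig(duration_s=180.0, seed=9)
        sp = SpeciesModel("dual", 100.0 / 180.0, 100.0, 100.0, 2.0)
        trace = simulate_trace([sp], cfg)
        apex_mean = np.mean([trace.green[b.apex_bin] for b in trace.ground_truth])
        expected = 100.0 + cfg.background_green
        assert abs(apex_mean - expected) < 0.1 * expected

    def test_envelope_never_crosses_record_boundary(self):
        cfg = TraceConfig(duration_s=1.0, seed=2)
        sp = SpeciesModel("wide", 50.0, 100.0, 0.0, 40.0)  # sd 10 bins, extent 30
        trace = simulate_trace([sp], cfg)
        for burst in trace.ground_truth:
            assert 30 <= burst.apex_bin <= trace.n_bins - 1 - 30

    def test_bit_identical_under_seed(self):
        cfg = TraceConfig(duration_s=5.0, seed=123)
        sp = SpeciesModel("dual", 2.0, 60.0, 60.0, 2.0)
        a = simulate_trace([sp], cfg)
        b = simulate_trace([sp], cfg)
        assert np.array_equal(a.green, b.green)
        assert np.array_equal(a.red, b.red)
        assert a.ground_truth == b.ground_truth


class TestTraceValidation:
    def test_non_integer_bin_count_rejected(self):
        with pytest.raises(ConfigurationError):
            TraceConfig(duration_s=0.0015, bin_ms=1.0)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValidationError):
            SpeciesModel("bad", -1.0, 1.0, 0.0, 1.0)

    def test_nothing_to_simulate_rejected(self):
        cfg = TraceConfig(duration_s=1.0, background_green=0.0, background_red=0.0)
        with pytest.raises(ValidationError):
            simulate_trace([], cfg)


class TestMixture:
    def test_hetero_fraction_one_makes_every_event_dual(self):
        trace = simulate_mixture(1.0, 100.0, TraceConfig(duration_s=30.0, seed=1))
        assert trace.ground_truth
        assert all(b.is_dual for b in trace.ground_truth)

    def test_hetero_fraction_zero_makes_no_dual_events(self):
        trace = simulate_mixture(0.0, 100.0, TraceConfig(duration_s=30.0, seed=1))
        assert trace.ground_truth
        assert not any(b.is_dual for b in trace.ground_truth)

    def test_dual_share_of_green_visible_events_matches_target(self):
        """At h=0.4 the realised dual fraction sits in the binomial 99% band."""
        trace = simulate_mixture(0.4, 500.0, TraceConfig(duration_s=180.0, seed=8))
        visible = [b for b in trace.ground_truth if b.species != "red_only"]
        frac = sum(b.is_dual for b in visible) / len(visible)
        se = np.sqrt(0.4 * 0.6 / len(visible))
        assert abs(frac - 0.4) < 2.58 * se

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValidationError):
            simulate_mixture(1.5, 100.0, TraceConfig(duration_s=1.0))


class TestDigest:
    def test_full_prevalence_means_every_read_covers_core(self, trif_like_protein):
        cfg = DigestConfig(protein=trif_like_protein, core_start=654, core_end=709,
                           core_prevalence=1.0, seed=4)
        for read in simulate_digest(cfg):
            start, end = map_read(read, trif_like_protein)
            assert start <= 654 and end >= 709

    def test_reads_are_substrings_inside_construct_span(self, trif_digest_config):
        prot = trif_digest_config.protein
        reads = simulate_digest(trif_digest_config)
        assert len(reads) == trif_digest_config.n_reads
        for read in reads:
            start, end = map_read(read, prot)
            assert 601 <= start <= end <= 712

    def test_anchor_contained_in_every_read(self, trif_digest_config):
        prot = trif_digest_config.protein
        t_lo, t_hi = TETRAD_INTERVAL
        for read in simulate_digest(trif_digest_config):
            start, end = map_read(read, prot)
            assert start <= t_lo and end >= t_hi

    def test_zero_decay_gives_flat_interior_coverage(self):
        """With no flank penalty the core leaves no footprint in coverage."""
        from ccscore import build_profile

        rng = np.random.default_rng(2024)
        prot = ProteinSequence(
            "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=60)), offset=1
        )
        cfg = DigestConfig(protein=prot, core_start=29, core_end=32,
                           core_prevalence=0.25, n_reads=4000,
                           length_range=(6, 60), decay_per_residue=0.0, seed=6)
        profile = build_profile(simulate_digest(cfg), prot, tetrad=(29, 32))
        interior = profile.prevalence[15:45]
        # No sharp enrichment at the core relative to its neighbourhood.
        core_mean = profile.prevalence[28:32].mean()
        assert core_mean - interior.mean() < 0.1

    def test_oxidation_annotations_only_on_methionine(self, trif_digest_config):
        reads = simulate_digest(trif_digest_config)
        n_mods = 0
        for read in reads:
            for pos, name in read.modifications:
                assert read.sequence[pos - 1] == "M"
                assert "Oxidation" in name
                n_mods += 1
        assert n_mods > 0  # the construct contains methionines

    def test_deterministic_under_seed(self, trif_digest_config):
        assert simulate_digest(trif_digest_config) == simulate_digest(trif_digest_config)

    def test_core_wider_than_max_length_rejected(self, trif_like_protein):
        with pytest.raises(ConfigurationError):
            DigestConfig(protein=trif_like_protein, core_start=601, core_end=712,
                         length_range=(10, 50), core_prevalence=0.5)
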