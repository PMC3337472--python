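"""Saturation / total-locus inference from the allele spectrum."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mosaicsat import (
    AlleleSpectrum,
    DegenerateSpectrumError,
    ScreenTally,
    ValidationError,
    allele_recovery_ratio,
    bootstrap_interval,
    f1_recovery_rate,
    mean_alleles_per_locus,
    plug_in_saturation,
    ztp_mean,
    ztp_mle,
)

from conftest import random_spectrum
from oracles import grid_ztp_mle


def spectrum_of(*counts: int) -> AlleleSpectrum:
    return AlleleSpectrum.from_counts({f"L{i}": c for i, c in enumerate(counts)})


class TestAlleleSpectrum:
    def test_packaged_screen_counts(self, screen_spectrum):
        assert screen_spectrum.n_loci == 24
        assert screen_spectrum.n_mutations == 45
        hist = screen_spectrum.histogram
        assert sum(k * v for k, v in hist.items()) == 45
        assert hist[1] == 20  # 15 unidentified groups + 5 identified singletons

    def test_counts_below_one_rejected(self):
        with pytest.raises(ValidationError):
            spectrum_of(2, 0)

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            AlleleSpectrum(locus_ids=(), alleles_per_locus=())

    def test_long_format_aggregation(self):
        spec = AlleleSpectrum.from_assignments(
            [("m1", "A"), ("m2", "A"), ("m3", "B")]
        )
        assert spec.n_loci == 2 and spec.n_mutations == 3

    def test_double_assignment_rejected(self):
        with pytest.raises(ValidationError):
            AlleleSpectrum.from_assignments([("m1", "A"), ("m1", "B")])


class TestMeanAllelesPerLocus:
    def test_screen_headline(self, screen_spectrum):
        mean = mean_alleles_per_locus(screen_spectrum)
        assert mean.value == pytest.approx(1.875)
        assert mean.rounded == 1.9  # ties away from zero, not banker's

    def test_single_singleton(self):
        assert mean_alleles_per_locus(spectrum_of(1)).value == 1.0

    def test_histogram_spectrum(self):
        spec = AlleleSpectrum.from_histogram({1: 10, 3: 2})
        assert mean_alleles_per_locus(spec).value == pytest.approx(16 / 12)


class TestPlugInSaturation:
    def test_screen_headline(self, screen_spectrum):
        est = plug_in_saturation(screen_spectrum)
        assert est.saturation == pytest.approx(1 - math.exp(-1.875))
        assert est.saturation_percent == 85
        assert est.total_loci == pytest.approx(24 / (1 - math.exp(-1.875)))
        assert est.total_loci_rounded == 28
        assert est.trivial_upper_bound == 45

    def test_rounded_mean_variant_agrees_at_percent_level(self, screen_spectrum):
        est = plug_in_saturation(screen_spectrum, use_rounded_mean=True)
        assert est.lambda_hat == 1.9
        assert est.saturation_percent == 85
        assert est.total_loci_rounded == 28

    def test_all_singletons_lower_boundary(self):
        est = plug_in_saturation(spectrum_of(*[1] * 10))
        assert est.saturation == pytest.approx(1 - math.exp(-1))
        assert est.total_loci == pytest.approx(10 / (1 - math.exp(-1)))

    def test_single_heavily_hit_locus(self):
        est = plug_in_saturation(spectrum_of(100))
        assert est.saturation == pytest.approx(1.0, abs=1e-12)
        assert est.total_loci == pytest.approx(1.0, abs=1e-6)


class TestZtpMle:
    def test_screen_spectrum_estimate(self, screen_spectrum):
        est = ztp_mle(screen_spectrum)
        assert est.lambda_hat == pytest.approx(1.424, abs=0.01)
        assert est.saturation == pytest.approx(0.759, abs=0.005)
        assert est.total_loci == pytest.approx(31.6, abs=0.1)
        assert est.total_loci_rounded == 32

    def test_constructed_fixed_point(self):
        # solving at an observed mean constructed as ztp_mean(2) must
        # return exactly lambda = 2 (integer counts cannot realize that
        # mean, so the solver is exercised directly)
        from mosaicsat.saturation import _ztp_solve

        target_mean = 2 / (1 - math.exp(-2))
        assert _ztp_solve(target_mean, 1e-10) == pytest.approx(2.0, abs=1e-9)

    def test_all_singletons_degenerate(self):
        with pytest.raises(DegenerateSpectrumError, match="singleton"):
            ztp_mle(spectrum_of(*[1] * 24))

    def test_round_trip_recovers_observed_mean(self, screen_spectrum):
        est = ztp_mle(screen_spectrum, tol=1e-10)
        assert abs(ztp_mean(est.lambda_hat) - screen_spectrum.mean) <= 1e-10

    def test_limits(self):
        # mean -> infinity: lambda_hat -> mean; mean -> 1+: lambda_hat -> 0
        big = spectrum_of(50, 50)
        est = ztp_mle(big)
        assert est.lambda_hat == pytest.approx(50.0, rel=1e-10)
        near = AlleleSpectrum.from_histogram({1: 9999, 2: 1})  # mean 1.0001
        est = ztp_mle(near)
        assert 0 < est.lambda_hat < 0.001

    def test_matches_dense_grid_likelihood_maximizer(self):
        # the mean equation is the stationarity condition of the ZTP
        # likelihood: both routes must land on the same lambda
        rng = np.random.default_rng(42)
        for _ in range(20):
            spec = random_spectrum(rng)
            lam = ztp_mle(spec).lambda_hat
            lam_grid = grid_ztp_mle(spec.alleles_per_locus)
            assert abs(lam - lam_grid) < 1e-4

    @given(st.integers(0, 2**31 - 1))
    @settings(derandomize=True, deadline=None, max_examples=40)
    def test_ordering_theorem(self, seed):
        """ZTP always says: less saturated, more loci than the plug-in."""
        spec = random_spectrum(np.random.default_rng(seed))
        plug = plug_in_saturation(spec)
        ztp = ztp_mle(spec)
        assert ztp.lambda_hat < spec.mean
        assert ztp.saturation < plug.saturation
        assert ztp.total_loci > plug.total_loci
        assert plug.total_loci >= spec.n_loci
        assert ztp.total_loci >= spec.n_loci


class TestBootstrapInterval:
    def test_reproducible_and_contains_point_estimate(self, screen_spectrum):
        a = bootstrap_interval(screen_spectrum, "plug_in", 0.95, 1000, seed=1)
        b = bootstrap_interval(screen_spectrum, "plug_in", 0.95, 1000, seed=1)
        assert a == b
        point = plug_in_saturation(screen_spectrum).total_loci
        assert a.total_loci[0] <= point <= a.total_loci[1]

    def test_different_seed_differs(self, screen_spectrum):
        a = bootstrap_interval(screen_spectrum, "plug_in", 0.95, 1000, seed=1)
        c = bootstrap_interval(screen_spectrum, "plug_in", 0.95, 1000, seed=2)
        assert a.total_loci != c.total_loci

    def test_single_locus_is_degenerate(self):
        with pytest.raises(DegenerateSpectrumError):
            bootstrap_interval(spectrum_of(5), "plug_in", 0.95, 100, seed=1)

    def test_identical_counts_zero_width(self):
        spec = spectrum_of(*[2] * 12)
        ci = bootstrap_interval(spec, "ztp_mle", 0.95, 200, seed=3)
        assert ci.lambda_hat[0] == ci.lambda_hat[1]

    def test_requires_seed_and_enough_replicates(self, screen_spectrum):
        with pytest.raises(ValidationError):
            bootstrap_interval(screen_spectrum, "plug_in", 0.95, 1000, seed=None)
        with pytest.raises(ValidationError):
            bootstrap_interval(screen_spectrum, "plug_in", 0.95, 99, seed=1)


class TestTallyStatistics:
    def test_screen_recovery_headline(self):
        rate = f1_recovery_rate(ScreenTally(950, 73, 45))
        assert rate.value == pytest.approx(73 / 950)
        assert rate.percent == 8

    @pytest.mark.parametrize(
        "recovered, percent", [(0, 0), (950, 100)]
    )
    def test_recovery_boundaries(self, recovered, percent):
        tally = ScreenTally(950, recovered, recovered)
        assert f1_recovery_rate(tally).percent == percent

    def test_inconsistent_tally_rejected(self):
        with pytest.raises(ValidationError):
            ScreenTally(950, 45, 73)

    def test_allele_recovery_ratio(self):
        ratio = allele_recovery_ratio(1.875, 29_900 / 1_440)
        assert ratio == pytest.approx(0.0903, abs=1e-4)
        assert allele_recovery_ratio(21, 21) == 1.0
        assert allele_recovery_ratio(0, 21) == 0.0
        with pytest.raises(ValidationError):
            allele_recovery_ratio(1.0, 0.0)
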