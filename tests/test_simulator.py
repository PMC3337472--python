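"""The generative screen model and its parameter-recovery harness."""

import math
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from mosaicsat import (
    SimulationParams,
    ValidationError,
    build_groups,
    simulate_screen,
    true_partition,
    validate_estimators,
)


def small_params(**overrides) -> SimulationParams:
    """A scaled-down screen keeping the published attrition regime."""
    defaults = dict(
        seed=0,
        arms_screened=4_600,
        lethal_rate_per_arm=0.65,
        n_essential_genes=1_440,
        n_pathway_genes=30,
        p_recover=0.077,
        p_penetrant=0.62,
    )
    defaults.update(overrides)
    return SimulationParams(**defaults)


class TestSimulateScreen:
    def test_no_recovery_means_empty_spectrum(self):
        screen = simulate_screen(small_params(p_recover=0.0))
        assert screen.n_retained == 0
        assert screen.spectrum is None
        assert screen.matrix.n_mutations == 0

    def test_fates_are_consistent(self):
        screen = simulate_screen(small_params(seed=5))
        table = screen.mutations
        assert set(table["fate"]) <= {"not_detected", "lost_f1", "recovered_weak", "retained"}
        # non-pathway mutations can never be detected
        assert (table.loc[~table["is_pathway_gene"], "fate"] == "not_detected").all()
        # spectrum counts match the retained table
        kept = table[table["fate"] == "retained"]
        if screen.spectrum is not None:
            assert screen.spectrum.n_mutations == len(kept)
            assert dict(
                zip(screen.spectrum.locus_ids, screen.spectrum.alleles_per_locus)
            ) == kept.groupby("true_gene").size().to_dict()

    def test_retained_count_matches_thinned_poisson(self):
        # retained ~ Poisson(arms*rate * pathway_fraction * p_detect *
        # p_recover * p_penetrant); check the sample mean of 100 reps
        # against the closed form within Monte-Carlo error
        params = small_params(arms_screened=4_600)
        mu = (
            4_600 * 0.65 * (30 / 1_440) * params.p_f1_detect * 0.077 * 0.62
        )
        totals = [
            simulate_screen(replace(params, seed=s)).n_retained for s in range(100)
        ]
        se = math.sqrt(mu / 100)
        assert abs(np.mean(totals) - mu) < 4 * se
        # Poisson: variance should be in the same ballpark as the mean
        assert 0.3 * mu < np.var(totals) < 3.0 * mu

    def test_noiseless_complementation_recovers_truth(self):
        for seed in range(10):
            screen = simulate_screen(
                small_params(seed=seed, arms_screened=46_000, n_essential_genes=144)
            )
            if screen.n_retained == 0:
                continue
            assert build_groups(screen.matrix).groups == true_partition(screen)

    def test_test_errors_degrade_grouping_monotonically(self):
        def accuracy(p_err: float) -> float:
            hits = 0
            reps = 20
            for seed in range(reps):
                screen = simulate_screen(
                    small_params(
                        seed=seed,
                        arms_screened=46_000,
                        n_essential_genes=144,
                        p_test_error=p_err,
                    )
                )
                if screen.n_retained and build_groups(screen.matrix).groups == true_partition(screen):
                    hits += 1
            return hits / reps

        acc = [accuracy(p) for p in (0.0, 0.01, 0.05)]
        assert acc[0] == 1.0
        assert acc[0] >= acc[1] >= acc[2]

    def test_seed_determinism(self):
        a = simulate_screen(small_params(seed=123))
        b = simulate_screen(small_params(seed=123))
        pd.testing.assert_frame_equal(a.mutations, b.mutations)
        assert a.matrix == b.matrix
        assert a.spectrum == b.spectrum
        assert a.truth == b.truth

    def test_hypomorphs_break_same_gene_edges(self):
        screen = simulate_screen(
            small_params(
                seed=9, arms_screened=46_000, n_essential_genes=144, p_hypomorph=0.5
            )
        )
        kept = screen.mutations[screen.mutations["fate"] == "retained"]
        hypo = dict(zip(kept["mutation_id"], kept["is_hypomorph"]))
        gene = dict(zip(kept["mutation_id"], kept["true_gene"]))
        for (a, b), res in screen.matrix.results.items():
            if gene[a] == gene[b]:
                expected = "complements" if hypo[a] != hypo[b] else "fails"
                assert res == expected

    def test_invalid_params_rejected(self):
        with pytest.raises(ValidationError):
            small_params(p_recover=1.5)
        with pytest.raises(ValidationError):
            small_params(n_pathway_genes=2_000)
        with pytest.raises(ValidationError):
            SimulationParams(seed=None)


class TestValidateEstimators:
    def test_requires_enough_replicates(self):
        with pytest.raises(ValidationError):
            validate_estimators(small_params(), n_reps=10, seed=1)

    def test_deterministic_report(self):
        params = small_params(arms_screened=4_615, n_essential_genes=100)
        a = validate_estimators(params, n_reps=50, seed=7, n_boot=0)
        b = validate_estimators(params, n_reps=50, seed=7, n_boot=0)
        assert a == b

    def test_saturated_limit_recovers_gene_count_exactly(self):
        # enormous mutagenesis with no attrition: every pathway gene is hit
        # many times, saturation -> 1, both estimators -> the true count
        params = small_params(
            arms_screened=5_000,
            n_essential_genes=100,
            p_recover=1.0,
            p_penetrant=1.0,
        )
        report = validate_estimators(params, n_reps=50, seed=3, n_boot=0)
        assert report["plug_in"]["mean"] == pytest.approx(30, abs=0.01)
        assert report["ztp_mle"]["mean"] == pytest.approx(30, abs=0.01)
        assert report["grouping_exact_fraction"] == 1.0
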