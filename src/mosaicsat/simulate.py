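"""Stochastic twin of an F1 mosaic saturation screen.

The generative process mirrors the screen end to end:

1. **Mutagenesis.** Total induced lethal mutations are Poisson(arms x
   per-arm rate); each is assigned to one of the essential genes on the
   screened arms (multinomial over gene weights — equivalently independent
   Poissons per gene).
2. **Detection.** Only mutations in the detectable *pathway* subset of
   genes can produce a scorable mosaic phenotype in an F1 eye; each does so
   with probability ``p_f1_detect``.
3. **Attrition.** A scored F1 candidate is recovered as a balanced F3
   stock with probability ``p_recover`` and survives the penetrance /
   expressivity filter with probability ``p_penetrant`` (independent
   Bernoulli thinning per mutation).
4. **Complementation.** Retained same-gene pairs fail to complement,
   except that an isoform-restricted hypomorph (probability
   ``p_hypomorph`` per mutation) complements non-hypomorph alleles of its
   own gene; any pairwise call is mis-scored with probability
   ``p_test_error`` (fails <-> complements flip).

Everything is driven by one seeded generator with a fixed draw order
(total, gene assignment, detect, recover, retain, hypomorph, test error),
so a seed reproduces a screen byte for byte. Defaults are the published
screen's regime: 56,000 arms at 0.65 lethals/arm over 1,440 essential
genes, F1->F3 recovery 73/950 and penetrance retention 45/73.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from .complementation import COMPLEMENTS, FAILS, ComplementationMatrix, build_groups
from .errors import DegenerateSpectrumError, ValidationError
from .saturation import AlleleSpectrum, bootstrap_interval, plug_in_saturation, ztp_mle

__all__ = [
    "SimulationParams",
    "SimulatedScreen",
    "simulate_screen",
    "true_partition",
    "validate_estimators",
]

FATES = ("not_detected", "lost_f1", "recovered_weak", "retained")


@dataclass(frozen=True)
class SimulationParams:
    """Knobs of the generative screen model; see the module docstring."""

    seed: int
    arms_screened: int = 56_000
    lethal_rate_per_arm: float = 0.65
    n_essential_genes: int = 1_440
    n_pathway_genes: int = 30
    gene_weights: tuple[float, ...] | None = None  # relative target sizes
    p_f1_detect: float = 1.0
    p_recover: float = 73 / 950
    p_penetrant: float = 45 / 73
    p_hypomorph: float = 0.0
    p_test_error: float = 0.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValidationError("seed is required")
        if self.arms_screened < 0 or self.lethal_rate_per_arm < 0:
            raise ValidationError("arms_screened and lethal_rate_per_arm must be >= 0")
        if self.n_essential_genes < 1:
            raise ValidationError("n_essential_genes must be >= 1")
        if not 0 <= self.n_pathway_genes <= self.n_essential_genes:
            raise ValidationError("need 0 <= n_pathway_genes <= n_essential_genes")
        for name in ("p_f1_detect", "p_recover", "p_penetrant", "p_hypomorph", "p_test_error"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1], got {p!r}")
        if self.gene_weights is not None:
            w = np.asarray(self.gene_weights, dtype=float)
            if w.shape != (self.n_essential_genes,):
                raise ValidationError("gene_weights must have length n_essential_genes")
            if np.any(w < 0) or w.sum() <= 0:
                raise ValidationError("gene_weights must be nonnegative with positive sum")

    @property
    def normalized_weights(self) -> np.ndarray:
        if self.gene_weights is None:
            return np.full(self.n_essential_genes, 1.0 / self.n_essential_genes)
        w = np.asarray(self.gene_weights, dtype=float)
        return w / w.sum()


@dataclass(frozen=True)
class SimulatedScreen:
    """One simulated screen with full ground truth.

    ``mutations`` is the per-mutation table (mutation_id, true_gene,
    is_pathway_gene, is_hypomorph, fate); ``spectrum`` aggregates the
    retained pathway mutations per true gene (None when nothing was
    retained); ``matrix`` is the generated pairwise complementation matrix
    over retained mutations; ``truth`` records what an estimator should
    recover.
    """

    params: SimulationParams
    mutations: pd.DataFrame
    spectrum: AlleleSpectrum | None
    matrix: ComplementationMatrix
    truth: dict = field(default_factory=dict)

    @property
    def n_retained(self) -> int:
        return int((self.mutations["fate"] == "retained").sum())


def simulate_screen(params: SimulationParams) -> SimulatedScreen:
    """Run the generative model once; fully reproducible given the seed."""
    rng = np.random.default_rng(params.seed)
    n_total = int(rng.poisson(params.arms_screened * params.lethal_rate_per_arm))
    per_gene = rng.multinomial(n_total, params.normalized_weights)
    gene_idx = np.repeat(np.arange(params.n_essential_genes), per_gene)
    is_pathway = gene_idx < params.n_pathway_genes

    n_path = int(is_pathway.sum())
    detected = np.zeros(n_total, dtype=bool)
    recovered = np.zeros(n_total, dtype=bool)
    retained = np.zeros(n_total, dtype=bool)
    # cascade of Bernoulli thinnings, one uniform array per stage so the
    # draw order is stage-by-stage regardless of individual fates
    detected[is_pathway] = rng.random(n_path) < params.p_f1_detect
    recovered[is_pathway] = rng.random(n_path) < params.p_recover
    retained[is_pathway] = rng.random(n_path) < params.p_penetrant
    recovered &= detected
    retained &= recovered
    hypomorph = np.zeros(n_total, dtype=bool)
    hypomorph[is_pathway] = rng.random(n_path) < params.p_hypomorph

    fate = np.full(n_total, "not_detected", dtype=object)
    fate[detected & ~recovered] = "lost_f1"
    fate[recovered & ~retained] = "recovered_weak"
    fate[retained] = "retained"

    width = max(5, len(str(max(n_total, 1))))
    gwidth = max(4, len(str(params.n_essential_genes)))
    mutations = pd.DataFrame(
        {
            "mutation_id": [f"m{i:0{width}d}" for i in range(n_total)],
            "true_gene": [f"g{g:0{gwidth}d}" for g in gene_idx],
            "is_pathway_gene": is_pathway,
            "is_hypomorph": hypomorph,
            "fate": fate,
        }
    )

    kept = mutations[mutations["fate"] == "retained"]
    spectrum = None
    if len(kept) > 0:
        counts = kept.groupby("true_gene", sort=True).size()
        spectrum = AlleleSpectrum(
            locus_ids=tuple(counts.index), alleles_per_locus=tuple(int(c) for c in counts)
        )

    # pairwise complementation over retained mutations, pairs visited in
    # sorted-id order so error flips are reproducible
    kept_ids = sorted(kept["mutation_id"])
    gene_of = dict(zip(kept["mutation_id"], kept["true_gene"]))
    hypo_of = dict(zip(kept["mutation_id"], kept["is_hypomorph"]))
    results: dict[tuple[str, str], str] = {}
    pairs = list(combinations(kept_ids, 2))
    flips = rng.random(len(pairs)) < params.p_test_error
    for (a, b), flip in zip(pairs, flips):
        if gene_of[a] == gene_of[b]:
            # an isoform-restricted hypomorph complements full-gene alleles
            # of its own locus; two hypomorphs hit the same isoform class
            res = COMPLEMENTS if hypo_of[a] != hypo_of[b] else FAILS
        else:
            res = COMPLEMENTS
        if flip:
            res = FAILS if res == COMPLEMENTS else COMPLEMENTS
        results[(a, b)] = res
    matrix = ComplementationMatrix(mutation_ids=tuple(kept_ids), results=results)

    hit_pathway = int((per_gene[: params.n_pathway_genes] > 0).sum())
    truth = {
        "n_lethal_mutations": n_total,
        "n_pathway_mutations": n_path,
        "n_detected": int(detected.sum()),
        "n_recovered": int(recovered.sum()),
        "n_retained": int(retained.sum()),
        "n_pathway_genes": params.n_pathway_genes,
        "n_pathway_genes_hit": hit_pathway,
        "retained_per_gene": {
            g: int(c) for g, c in zip(spectrum.locus_ids, spectrum.alleles_per_locus)
        }
        if spectrum is not None
        else {},
    }
    return SimulatedScreen(
        params=params, mutations=mutations, spectrum=spectrum, matrix=matrix, truth=truth
    )


def true_partition(screen: SimulatedScreen) -> tuple[tuple[str, ...], ...]:
    """The ground-truth grouping of retained mutations by their gene."""
    kept = screen.mutations[screen.mutations["fate"] == "retained"]
    groups = [
        tuple(sorted(sub["mutation_id"]))
        for _, sub in kept.groupby("true_gene", sort=True)
    ]
    return tuple(sorted(groups, key=lambda g: g[0]))


def _rep_seeds(seed: int, n: int) -> list[int]:
    # one child seed per replicate from a SeedSequence, kept below 2**31
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
    return [int(s >> 1) for s in state]


def validate_estimators(
    params: SimulationParams,
    n_reps: int,
    seed: int,
    n_boot: int = 200,
    level: float = 0.95,
) -> dict:
    """Parameter-recovery study: do the estimators find the true gene count?

    Runs ``n_reps`` independent screens under ``params`` (per-replicate
    seeds derived from ``seed``), applies both saturation estimators to
    each retained spectrum, and reports mean/SD/bias of the estimated total
    locus count against the true number of pathway genes, the fraction of
    replicates where noise-free complementation grouping recovers the true
    partition, and (when ``n_boot`` >= 100) bootstrap-interval coverage of
    the truth. Replicates whose spectrum is degenerate for the ZTP
    estimator (mean <= 1) are counted and excluded from its summaries.
    """
    if n_reps < 50:
        raise ValidationError("n_reps must be >= 50")
    truth_total = params.n_pathway_genes
    seeds = _rep_seeds(seed, n_reps)
    plug_totals: list[float] = []
    ztp_totals: list[float] = []
    plug_cover = 0
    ztp_cover = 0
    ztp_interval_n = 0
    grouping_exact = 0
    n_degenerate = 0
    n_empty = 0
    for s in seeds:
        screen = simulate_screen(replace(params, seed=s))
        if screen.spectrum is None:
            n_empty += 1
            n_degenerate += 1
            continue
        est_plug = plug_in_saturation(screen.spectrum)
        plug_totals.append(est_plug.total_loci)
        if build_groups(screen.matrix).groups == true_partition(screen):
            grouping_exact += 1
        try:
            est_ztp = ztp_mle(screen.spectrum)
        except DegenerateSpectrumError:
            n_degenerate += 1
        else:
            ztp_totals.append(est_ztp.total_loci)
            if n_boot >= 100:
                ci = bootstrap_interval(
                    screen.spectrum, "ztp_mle", level=level, n_boot=n_boot, seed=s
                )
                ztp_interval_n += 1
                if ci.total_loci[0] <= truth_total <= ci.total_loci[1]:
                    ztp_cover += 1
        if n_boot >= 100:
            ci = bootstrap_interval(
                screen.spectrum, "plug_in", level=level, n_boot=n_boot, seed=s
            )
            if ci.total_loci[0] <= truth_total <= ci.total_loci[1]:
                plug_cover += 1

    def _summary(values: Sequence[float]) -> dict:
        if not values:
            return {"n": 0, "mean": None, "sd": None, "bias": None, "relative_bias": None}
        arr = np.asarray(values)
        mean = float(arr.mean())
        return {
            "n": len(values),
            "mean": mean,
            "sd": float(arr.std(ddof=1)) if len(values) > 1 else 0.0,
            "bias": mean - truth_total,
            "relative_bias": (mean - truth_total) / truth_total,
        }

    report = {
        "seed": seed,
        "n_reps": n_reps,
        "true_total_loci": truth_total,
        "n_degenerate_replicates": n_degenerate,
        "n_empty_replicates": n_empty,
        "grouping_exact_fraction": grouping_exact / max(1, len(plug_totals)),
        "plug_in": _summary(plug_totals),
        "ztp_mle": _summary(ztp_totals),
        "params": {
            "arms_screened": params.arms_screened,
            "lethal_rate_per_arm": params.lethal_rate_per_arm,
            "n_essential_genes": params.n_essential_genes,
            "n_pathway_genes": params.n_pathway_genes,
            "p_f1_detect": params.p_f1_detect,
            "p_recover": params.p_recover,
            "p_penetrant": params.p_penetrant,
            "p_hypomorph": params.p_hypomorph,
            "p_test_error": params.p_test_error,
        },
    }
    if n_boot >= 100:
        report["interval_level"] = level
        report["n_bootstrap"] = n_boot
        report["plug_in_coverage"] = plug_cover / max(1, len(plug_totals))
        report["ztp_mle_coverage"] = ztp_cover / max(1, ztp_interval_n)
    if n_degenerate:
        warnings_msg = (
            f"{n_degenerate} of {n_reps} replicates had degenerate spectra "
            "(mean <= 1) and were excluded from ZTP summaries"
        )
        report["warnings"] = [warnings_msg]
    return report
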