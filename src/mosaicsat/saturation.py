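"""Saturation and total-locus inference from an observed allele spectrum.

The data are the per-locus counts of independently isolated alleles from a
saturation screen. Under the standard model, hits per detectable locus are
Poisson(lambda); a locus enters the spectrum only if hit at least once, so
the observed counts are zero-truncated Poisson (ZTP) and the fraction of
detectable loci observed — the screen's *saturation* — is 1 - exp(-lambda).

Two estimators of lambda are provided:

``plug_in``
    lambda_hat = observed mean alleles per locus. This is the back-of-the-
    envelope rule screen reports use; it ignores zero truncation and
    therefore overstates lambda (and saturation) and understates the total
    locus count.

``ztp_mle``
    lambda_hat solves the ZTP mean equation
    ``lambda / (1 - exp(-lambda)) = observed mean``,
    which is the stationarity condition of the zero-truncated Poisson
    likelihood. Always lambda_hat < observed mean, so ZTP saturation is
    below and total loci above the plug-in values.

Either way, total detectable loci are estimated as
``n_observed_loci / saturation``. Percentile bootstrap intervals come from
resampling loci (the exchangeable units) with replacement.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
from scipy.optimize import brentq

from ._util import percent_report, round_half_away, round_half_away_int
from .errors import BootstrapRedrawWarning, DegenerateSpectrumError, ValidationError

__all__ = [
    "AlleleSpectrum",
    "ScreenTally",
    "SaturationEstimate",
    "BootstrapInterval",
    "MeanAlleles",
    "RecoveryRate",
    "mean_alleles_per_locus",
    "plug_in_saturation",
    "ztp_mle",
    "ztp_mean",
    "bootstrap_interval",
    "f1_recovery_rate",
    "allele_recovery_ratio",
]


@dataclass(frozen=True)
class AlleleSpectrum:
    """Counts of recovered alleles per locus (complementation group).

    Every count is >= 1 by construction: a locus exists in the spectrum
    only because it was observed — the zero class is unobservable.
    """

    locus_ids: tuple[str, ...]
    alleles_per_locus: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.locus_ids) != len(self.alleles_per_locus):
            raise ValidationError("locus_ids and alleles_per_locus differ in length")
        if len(self.locus_ids) == 0:
            raise ValidationError("empty allele spectrum")
        if len(set(self.locus_ids)) != len(self.locus_ids):
            raise ValidationError("duplicate locus_id in spectrum")
        for locus, k in zip(self.locus_ids, self.alleles_per_locus):
            if int(k) != k or k < 1:
                raise ValidationError(
                    f"locus {locus!r}: allele count must be an integer >= 1, got {k!r}"
                )

    @classmethod
    def from_counts(cls, counts: Mapping[str, int]) -> "AlleleSpectrum":
        items = list(counts.items())
        return cls(
            locus_ids=tuple(k for k, _ in items),
            alleles_per_locus=tuple(int(v) for _, v in items),
        )

    @classmethod
    def from_histogram(cls, histogram: Mapping[int, int]) -> "AlleleSpectrum":
        """Build an anonymous spectrum from {allele count: number of loci}."""
        ids: list[str] = []
        counts: list[int] = []
        i = 0
        for k in sorted(histogram):
            for _ in range(histogram[k]):
                ids.append(f"locus{i:04d}")
                counts.append(int(k))
                i += 1
        return cls(locus_ids=tuple(ids), alleles_per_locus=tuple(counts))

    @classmethod
    def from_assignments(cls, pairs: Iterable[tuple[str, str]]) -> "AlleleSpectrum":
        """Aggregate long-format (mutation_id, locus_id) rows into counts."""
        tally: Counter[str] = Counter()
        seen: set[str] = set()
        for mutation, locus in pairs:
            if mutation in seen:
                raise ValidationError(f"mutation {mutation!r} assigned twice")
            seen.add(mutation)
            tally[locus] += 1
        return cls.from_counts(dict(tally))

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    @property
    def n_mutations(self) -> int:
        return int(sum(self.alleles_per_locus))

    @property
    def counts(self) -> np.ndarray:
        return np.asarray(self.alleles_per_locus, dtype=np.int64)

    @property
    def histogram(self) -> dict[int, int]:
        """{k: number of loci observed with exactly k alleles}."""
        return dict(sorted(Counter(self.alleles_per_locus).items()))

    @property
    def mean(self) -> float:
        return self.n_mutations / self.n_loci


@dataclass(frozen=True)
class ScreenTally:
    """Attrition counts through the screen: candidates -> stocks -> kept."""

    n_f1_candidates: int
    n_recovered: int
    n_retained: int

    def __post_init__(self) -> None:
        if min(self.n_f1_candidates, self.n_recovered, self.n_retained) < 0:
            raise ValidationError("tally counts must be >= 0")
        if not self.n_retained <= self.n_recovered <= self.n_f1_candidates:
            raise ValidationError(
                "tally must satisfy n_retained <= n_recovered <= n_f1_candidates"
            )


class MeanAlleles(NamedTuple):
    value: float
    rounded: float  # one-decimal headline report


class RecoveryRate(NamedTuple):
    value: float
    percent: int


@dataclass(frozen=True)
class BootstrapInterval:
    """Percentile bootstrap interval from resampling loci with replacement."""

    level: float
    n_bootstrap: int
    seed: int
    lambda_hat: tuple[float, float]
    saturation: tuple[float, float]
    total_loci: tuple[float, float]
    n_redrawn: int = 0


@dataclass(frozen=True)
class SaturationEstimate:
    """A saturation / total-locus estimate with its headline roundings."""

    method: str  # "plug_in" or "ztp_mle"
    lambda_hat: float
    saturation: float
    total_loci: float
    n_loci: int
    n_mutations: int
    interval: BootstrapInterval | None = field(default=None)

    @property
    def saturation_percent(self) -> int:
        return percent_report(self.saturation)

    @property
    def total_loci_rounded(self) -> int:
        return round_half_away_int(self.total_loci)

    @property
    def trivial_upper_bound(self) -> int:
        """Every mutation a distinct gene: total loci can never exceed this."""
        return self.n_mutations


def mean_alleles_per_locus(spectrum: AlleleSpectrum) -> MeanAlleles:
    """Observed mean alleles per locus, with its one-decimal report."""
    value = spectrum.mean
    return MeanAlleles(value=value, rounded=round_half_away(value, 1))


def _estimate_from_lambda(
    method: str, lambda_hat: float, n_loci: int, n_mutations: int
) -> SaturationEstimate:
    saturation = -math.expm1(-lambda_hat)
    return SaturationEstimate(
        method=method,
        lambda_hat=lambda_hat,
        saturation=saturation,
        total_loci=n_loci / saturation,
        n_loci=n_loci,
        n_mutations=n_mutations,
    )


def plug_in_saturation(
    spectrum: AlleleSpectrum, *, use_rounded_mean: bool = False
) -> SaturationEstimate:
    """Plug-in rule: treat the observed mean as the Poisson mean itself.

    saturation = 1 - exp(-mean); total loci = n_loci / saturation. With
    ``use_rounded_mean`` the one-decimal headline mean is plugged in
    instead of the exact ratio (both conventions round to the same whole
    percent on typical screen data).
    """
    mean = mean_alleles_per_locus(spectrum)
    lam = mean.rounded if use_rounded_mean else mean.value
    return _estimate_from_lambda("plug_in", lam, spectrum.n_loci, spectrum.n_mutations)


def ztp_mean(lam: float) -> float:
    """Mean of a zero-truncated Poisson(lam): lam / (1 - exp(-lam))."""
    if lam <= 0:
        raise ValidationError("ztp_mean requires lam > 0")
    return lam / -math.expm1(-lam)


def _ztp_solve(mean: float, tol: float) -> float:
    """Root of lam/(1-exp(-lam)) = mean on (0, mean); requires mean > 1."""
    lo = 1e-9
    # ztp_mean is strictly increasing with limit 1 at 0+ and ztp_mean(m) > m,
    # so the root is bracketed by (lo, mean] whenever mean > 1.
    lam = brentq(lambda l: ztp_mean(l) - mean, lo, mean, xtol=1e-14, rtol=8.9e-16)
    if abs(ztp_mean(lam) - mean) > tol:
        raise RuntimeError("ZTP mean equation did not converge to tolerance")
    return float(lam)


def ztp_mle(spectrum: AlleleSpectrum, tol: float = 1e-10) -> SaturationEstimate:
    """Zero-truncated Poisson maximum-likelihood saturation estimate.

    Solves the ZTP mean equation for lambda_hat by bisection-safe root
    finding on its strictly increasing mean map (unconditionally
    convergent, unlike Newton steps started far from the root). Raises
    :class:`DegenerateSpectrumError` when the observed mean is <= 1 (an
    all-singleton spectrum): lambda_hat -> 0 at that boundary and
    saturation is unidentifiable.
    """
    if tol <= 0:
        raise ValidationError("tol must be > 0")
    mean = spectrum.mean
    if mean <= 1.0:
        raise DegenerateSpectrumError(
            f"observed mean alleles per locus is {mean:g} <= 1 (all loci "
            "singletons): the ZTP mean equation has no positive root and "
            "saturation cannot be estimated; screen deeper or use the "
            "plug-in rule with the caveat that it is uninformative here"
        )
    lam = _ztp_solve(mean, tol)
    return _estimate_from_lambda("ztp_mle", lam, spectrum.n_loci, spectrum.n_mutations)


def bootstrap_interval(
    spectrum: AlleleSpectrum,
    method: str = "plug_in",
    level: float = 0.95,
    n_boot: int = 1000,
    seed: int | None = None,
    max_redraw_factor: int = 10,
) -> BootstrapInterval:
    """Percentile bootstrap interval for lambda_hat, saturation, total loci.

    Loci — not mutations — are resampled with replacement: loci are the
    exchangeable units of the spectrum, and resampling mutations would
    destroy the zero-truncation structure the estimators rely on. Under
    ``method="ztp_mle"`` a resample whose mean is <= 1 is degenerate and is
    redrawn (warned, capped at ``max_redraw_factor * n_boot`` total draws).
    """
    if method not in ("plug_in", "ztp_mle"):
        raise ValidationError(f"unknown method {method!r}")
    if n_boot < 100:
        raise ValidationError("n_boot must be >= 100")
    if not 0.0 < level < 1.0:
        raise ValidationError("level must lie in (0, 1)")
    if seed is None:
        raise ValidationError("bootstrap_interval requires an explicit seed")
    n = spectrum.n_loci
    if n < 2:
        raise DegenerateSpectrumError(
            "bootstrap over a single-locus spectrum is degenerate: every "
            "resample is the same locus and the interval is undefined"
        )
    counts = spectrum.counts
    rng = np.random.default_rng(seed)
    lams = np.empty(n_boot)
    n_redrawn = 0
    draws_left = max_redraw_factor * n_boot
    i = 0
    while i < n_boot:
        if draws_left == 0:
            raise DegenerateSpectrumError(
                "bootstrap redraw cap exhausted: the spectrum is too close "
                "to all-singletons for a ZTP interval"
            )
        draws_left -= 1
        resample = counts[rng.integers(0, n, n)]
        mean = float(resample.mean())
        if method == "ztp_mle":
            if mean <= 1.0:
                n_redrawn += 1
                continue
            lams[i] = _ztp_solve(mean, 1e-10)
        else:
            lams[i] = mean
        i += 1
    if n_redrawn:
        warnings.warn(
            f"{n_redrawn} degenerate bootstrap resamples (mean <= 1) were redrawn",
            BootstrapRedrawWarning,
            stacklevel=2,
        )
    sats = -np.expm1(-lams)
    totals = n / sats
    qs = [(1.0 - level) / 2.0, (1.0 + level) / 2.0]

    def _pair(a: np.ndarray) -> tuple[float, float]:
        lo, hi = np.quantile(a, qs)
        return (float(lo), float(hi))

    return BootstrapInterval(
        level=level,
        n_bootstrap=n_boot,
        seed=seed,
        lambda_hat=_pair(lams),
        saturation=_pair(sats),
        total_loci=_pair(totals),
        n_redrawn=n_redrawn,
    )


def f1_recovery_rate(tally: ScreenTally) -> RecoveryRate:
    """Fraction of F1 candidates recovered as balanced stocks."""
    if tally.n_f1_candidates < 1:
        raise ValidationError("f1_recovery_rate requires >= 1 F1 candidate")
    value = tally.n_recovered / tally.n_f1_candidates
    return RecoveryRate(value=value, percent=percent_report(value))


def allele_recovery_ratio(observed_mean: float, expected_mean: float) -> float:
    """Observed over expected alleles per locus.

    The ratio of the observed mean allele count to the mutagenesis-predicted
    Poisson mean: the effective per-mutation survival fraction through the
    whole screen (detection, stock recovery, penetrance filtering). Useful
    as an order-of-magnitude cross-check against the directly observed F1
    recovery rate.
    """
    if expected_mean <= 0:
        raise ValidationError("expected_mean must be > 0")
    if observed_mean < 0:
        raise ValidationError("observed_mean must be >= 0")
    return observed_mean / expected_mean
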