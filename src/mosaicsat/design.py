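"""Poisson arithmetic for planning a saturation mutagenesis screen.

An EMS (ethyl methanesulfonate) mutagenesis induces lethal point mutations
at a characterizable rate per chromosome arm. If ``A`` mutagenized arms are
screened at a per-arm lethal rate ``r`` over ``G`` essential genes in the
screened genome fraction, hits per gene are Poisson with mean
``lambda = A * r / G`` and the probability a gene is hit at least once is
``1 - exp(-lambda)``. These identities drive everything here: expected
mutation yield, per-gene hit rate, coverage, and the inverse problem of how
many arms a target coverage requires.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import NamedTuple

from ._util import round_half_away_int
from .errors import InconsistentDesignWarning, ValidationError

__all__ = [
    "ScreenDesign",
    "HitsPerGene",
    "expected_lethal_mutations",
    "expected_hits_per_gene",
    "coverage_probability",
    "arms_needed",
]

#: Relative disagreement between an explicit lethal total and arms x rate
#: above which the design is warned about as internally inconsistent.
_CONSISTENCY_RTOL = 1e-6


@dataclass(frozen=True)
class ScreenDesign:
    """Parameters describing a mosaic-screen mutagenesis.

    Parameters
    ----------
    arms_screened
        Number of mutagenized chromosome arms passed through the screen.
    lethal_rate_per_arm
        Expected lethal mutations induced per mutagenized arm
        (dimensionless rate; ~0.65 for a standard EMS feeding protocol).
    essential_genes_total
        Essential genes genome-wide.
    fraction_screened
        Proportion of the genome covered by the screened arms, in [0, 1].
    essential_genes_in_screen
        Essential genes on the screened arms. When omitted it defaults to
        ``round(essential_genes_total * fraction_screened)``; pass it
        explicitly to reproduce a published rounding convention.
    lethal_mutations_screened
        Optional explicit total of lethal mutations screened. When present
        it is authoritative for downstream arithmetic even if it disagrees
        with ``arms_screened * lethal_rate_per_arm`` (screen reports often
        quote an empirically adjusted total); the disagreement raises
        :class:`InconsistentDesignWarning` when the value is used.
    """

    arms_screened: int
    lethal_rate_per_arm: float
    essential_genes_total: int = 3600
    fraction_screened: float = 0.4
    essential_genes_in_screen: int | None = None
    lethal_mutations_screened: float | None = None

    def __post_init__(self) -> None:
        if self.arms_screened < 0:
            raise ValidationError("arms_screened must be >= 0")
        if self.lethal_rate_per_arm < 0:
            raise ValidationError("lethal_rate_per_arm must be >= 0")
        if self.essential_genes_total < 0:
            raise ValidationError("essential_genes_total must be >= 0")
        if not 0.0 <= self.fraction_screened <= 1.0:
            raise ValidationError("fraction_screened must lie in [0, 1]")
        if self.lethal_mutations_screened is not None and self.lethal_mutations_screened < 0:
            raise ValidationError("lethal_mutations_screened must be >= 0")
        genes = self.genes_in_screen
        if genes < 0:
            raise ValidationError("essential_genes_in_screen must be >= 0")
        if genes > self.essential_genes_total:
            raise ValidationError(
                "essential_genes_in_screen cannot exceed essential_genes_total"
            )

    @property
    def genes_in_screen(self) -> int:
        """Essential genes in the screened fraction (explicit or derived)."""
        if self.essential_genes_in_screen is not None:
            return self.essential_genes_in_screen
        return round_half_away_int(self.essential_genes_total * self.fraction_screened)


class HitsPerGene(NamedTuple):
    """Mean hits per gene with its nearest-integer headline report."""

    value: float
    rounded: int


def expected_lethal_mutations(design: ScreenDesign) -> float:
    """Total lethal mutations passed through the screen.

    Returns ``arms_screened * lethal_rate_per_arm``, unless the design
    carries an explicit ``lethal_mutations_screened`` override, which is
    then returned as authoritative (with a consistency warning if the two
    disagree).
    """
    computed = design.arms_screened * design.lethal_rate_per_arm
    if design.lethal_mutations_screened is None:
        return computed
    override = design.lethal_mutations_screened
    if not math.isclose(override, computed, rel_tol=_CONSISTENCY_RTOL, abs_tol=1e-9):
        warnings.warn(
            f"explicit lethal_mutations_screened={override:g} disagrees with "
            f"arms x rate = {design.arms_screened} x "
            f"{design.lethal_rate_per_arm:g} = {computed:g}; "
            "using the explicit value",
            InconsistentDesignWarning,
            stacklevel=2,
        )
    return override


def expected_hits_per_gene(design: ScreenDesign) -> HitsPerGene:
    """Poisson mean number of mutations per essential gene in the screen.

    The raw ratio (lethals screened / genes in screen) is the ``lambda`` of
    the per-gene hit distribution; the nearest-integer companion is the
    value a screen report would quote.
    """
    genes = design.genes_in_screen
    if genes < 1:
        raise ValidationError("expected_hits_per_gene requires >= 1 gene in the screen")
    value = expected_lethal_mutations(design) / genes
    return HitsPerGene(value=value, rounded=round_half_away_int(value))


def coverage_probability(mean_hits: float) -> float:
    """P(a gene is hit at least once) = 1 - exp(-lambda).

    Strictly increasing in ``lambda`` and bounded in [0, 1).
    """
    if mean_hits < 0:
        raise ValidationError("mean_hits must be >= 0")
    return -math.expm1(-mean_hits)


def arms_needed(target_coverage: float, design: ScreenDesign) -> int:
    """Smallest number of arms whose coverage probability meets a target.

    Inverts ``coverage_probability(A * rate / genes) >= target`` in closed
    form and then nudges to guarantee exact minimality against floating-
    point edge cases: the returned ``A`` meets the target and ``A - 1``
    does not.
    """
    if not 0.0 <= target_coverage < 1.0:
        raise ValidationError("target_coverage must lie in [0, 1); 1 is unattainable")
    if design.lethal_rate_per_arm <= 0:
        raise ValidationError("arms_needed requires lethal_rate_per_arm > 0")
    genes = design.genes_in_screen
    if genes < 1:
        raise ValidationError("arms_needed requires >= 1 gene in the screen")
    if target_coverage == 0.0:
        return 0
    lam_needed = -math.log1p(-target_coverage)
    per_arm = design.lethal_rate_per_arm / genes
    arms = max(0, math.ceil(lam_needed / per_arm))
    while arms > 0 and coverage_probability((arms - 1) * per_arm) >= target_coverage:
        arms -= 1
    while coverage_probability(arms * per_arm) < target_coverage:
        arms += 1
    return arms
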