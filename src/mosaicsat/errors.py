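"""Exception and warning types shared across the package."""


class MosaicSatError(Exception):
    """Base class for all package errors."""


class ValidationError(MosaicSatError, ValueError):
    """An input (parameter, table row, matrix entry) violates a precondition."""


class DegenerateSpectrumError(MosaicSatError):
    """The allele spectrum carries no saturation signal.

    Raised when every observed locus is a singleton (mean alleles per locus
    <= 1): the zero-truncated Poisson mean equation then has no positive
    root and the saturation of the screen is unidentifiable from the data.
    """


class InconsistentDesignWarning(UserWarning):
    """A screen design carries an explicit lethal-mutation total that
    disagrees with arms x per-arm rate; the explicit total is used."""


class BootstrapRedrawWarning(UserWarning):
    """Degenerate bootstrap resamples were discarded and redrawn."""
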