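from __future__ import annotations

import numpy as np
import pytest

from mosaicsat import AlleleSpectrum, ComplementationMatrix, load_screen_spectrum


@pytest.fixture(scope="session")
def screen_spectrum() -> AlleleSpectrum:
    """The packaged 45-mutation / 24-locus screen spectrum."""
    return load_screen_spectrum()


def random_spectrum(rng: np.random.Generator, n_loci: int | None = None) -> AlleleSpectrum:
    """A random non-degenerate spectrum (all counts >= 1, mean > 1)."""
    n = int(n_loci if n_loci is not None else rng.integers(5, 40))
    while True:
        counts = 1 + rng.poisson(rng.uniform(0.3, 3.0), n)
        if counts.sum() > n:
            break
    return AlleleSpectrum(
        locus_ids=tuple(f"L{i:03d}" for i in range(n)),
        alleles_per_locus=tuple(int(c) for c in counts),
    )


def random_matrix(rng: np.random.Generator, n: int = 8) -> ComplementationMatrix:
    """A random symmetric test matrix mixing all three result states."""
    ids = [f"m{i}" for i in range(n)]
    results = {}
    for i in range(n):
        for j in range(i + 1, n):
            state = rng.choice(["fails", "complements", "untested"], p=[0.3, 0.5, 0.2])
            if state != "untested":
                results[(ids[i], ids[j])] = str(state)
    return ComplementationMatrix(mutation_ids=tuple(ids), results=results)


def hypomorph_locus_matrix() -> ComplementationMatrix:
    """A single-gene matrix with an isoform-restricted hypomorph.

    Four point alleles mutually fail to complement and all fail a
    deficiency that removes the locus; a P-element insertion allele
    complements every point allele but only partially complements the
    deficiency — the classic complex-complementation signature of a
    transcript-isoform hypomorph.
    """
    points = ["ptA", "ptB", "ptC", "ptD"]
    p_ins = "P-ins"
    records = [(a, b, "fails") for i, a in enumerate(points) for b in points[i + 1:]]
    records += [(p_ins, p, "complements") for p in points]
    deficiencies = [(p, "Df-locus", "fails") for p in points]
    deficiencies.append((p_ins, "Df-locus", "partial"))
    return ComplementationMatrix.from_records(records, deficiency_records=deficiencies)
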