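"""Independent brute-force oracles used only by the tests.

Each oracle re-derives a quantity by a route deliberately different from
the implementation: dense-grid likelihood maximization instead of root
finding, naive set merging instead of graph components, exhaustive triple
enumeration instead of adjacency scanning.
"""

from __future__ import annotations

from itertools import combinations
from typing import Iterable, Sequence

import numpy as np


def ztp_loglik(lam: np.ndarray, counts: Sequence[int]) -> np.ndarray:
    """Zero-truncated Poisson log-likelihood up to the count-only constant.

    sum_i [k_i ln lam - lam - ln(1 - e^-lam) - ln k_i!]; the ln k_i! term
    does not involve lam and is dropped.
    """
    n = len(counts)
    total = float(sum(counts))
    lam = np.asarray(lam, dtype=float)
    return total * np.log(lam) - n * lam - n * np.log1p(-np.exp(-lam))


def grid_ztp_mle(counts: Sequence[int], coarse: float = 1e-3, fine: float = 1e-6) -> float:
    """Dense-grid maximizer of the ZTP log-likelihood (two-stage grid)."""
    mean = sum(counts) / len(counts)
    assert mean > 1, "grid oracle requires a non-degenerate spectrum"
    grid = np.arange(1e-4, mean + coarse, coarse)
    best = grid[int(np.argmax(ztp_loglik(grid, counts)))]
    grid2 = np.arange(max(1e-7, best - 2 * coarse), best + 2 * coarse, fine)
    return float(grid2[int(np.argmax(ztp_loglik(grid2, counts)))])


def brute_force_groups(
    ids: Iterable[str], merge_pairs: Iterable[tuple[str, str]]
) -> tuple[tuple[str, ...], ...]:
    """Connected components by repeated naive set merging."""
    groups: list[set[str]] = [{m} for m in ids]
    for a, b in merge_pairs:
        ga = next(g for g in groups if a in g)
        gb = next(g for g in groups if b in g)
        if ga is not gb:
            ga |= gb
            groups.remove(gb)
    return tuple(sorted((tuple(sorted(g)) for g in groups), key=lambda g: g[0]))


def brute_force_triangles(matrix) -> list[tuple[str, str, str]]:
    """All intransitive triples by exhaustive enumeration over C(n, 3)."""
    found: set[tuple[str, str, str]] = set()
    for trio in combinations(matrix.mutation_ids, 3):
        for b in trio:
            a, c = sorted(m for m in trio if m != b)
            if (
                matrix.result(a, b) == "fails"
                and matrix.result(b, c) == "fails"
                and matrix.result(a, c) == "complements"
            ):
                found.add((a, b, c))
    return sorted(found)
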