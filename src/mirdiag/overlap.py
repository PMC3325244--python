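"""Significance of marker-set overlaps by permutation from a fixed universe.

Marker sets from different pairwise comparisons (or specimen types) live
in the same miRNA universe of size ``N``.  Under the null that each set is
a uniform random draw (without replacement) from the universe, the
expected pairwise overlap is ``a*b/N`` and the expected mutual overlap of
three independent sets is ``a*b*c/N**2``.  The permutation test draws the
sets repeatedly, counts the mutual overlap, and reports the +1-corrected
one-sided (enrichment) empirical p-value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._util import child_rng

__all__ = ["OverlapTestResult", "expected_overlap", "permutation_overlap_test"]


def expected_overlap(sizes: tuple[int, ...], universe: int) -> float:
    """Closed-form null expectation of the mutual overlap.

    Pairwise this is the hypergeometric mean ``a*b/N``; for three
    independent uniform sets it is ``a*b*c/N**2``.
    """
    sizes = tuple(int(s) for s in sizes)
    if not 2 <= len(sizes) <= 3:
        raise ValueError("2 or 3 set sizes required")
    if universe <= 0:
        raise ValueError("universe size must be positive")
    if any(s < 0 or s > universe for s in sizes):
        raise ValueError("set sizes must lie in [0, universe]")
    if len(sizes) == 2:
        return sizes[0] * sizes[1] / universe
    return sizes[0] * sizes[1] * sizes[2] / universe**2


@dataclass
class OverlapTestResult:
    """Observed overlap against its permutation null."""

    set_sizes: tuple[int, ...]
    universe_size: int
    observed_overlap: int
    perm_mean: float
    perm_sd: float
    empirical_p: float
    n_permutations: int
    closed_form_expectation: float

    def to_dict(self) -> dict:
        return {
            "set_sizes": list(self.set_sizes),
            "universe_size": self.universe_size,
            "observed_overlap": self.observed_overlap,
            "perm_mean": self.perm_mean,
            "perm_sd": self.perm_sd,
            "empirical_p": self.empirical_p,
            "n_permutations": self.n_permutations,
            "closed_form_expectation": self.closed_form_expectation,
        }


def _null_overlaps(sizes: tuple[int, ...], universe: int, n_perm: int,
                   rng: np.random.Generator,
                   block: int = 4096) -> np.ndarray:
    """Mutual-overlap counts for ``n_perm`` independent uniform draws.

    By symmetry the first set can be fixed to {0..a-1}; the remaining sets
    are drawn uniformly without replacement via random-key argpartition,
    processed in blocks to bound memory.
    """
    a, rest = sizes[0], sizes[1:]
    out = np.empty(n_perm, dtype=np.int64)
    done = 0
    while done < n_perm:
        b = min(block, n_perm - done)
        member = np.ones((b, a), dtype=bool)  # membership within {0..a-1}
        for size in rest:
            keys = rng.random((b, universe))
            idx = np.argpartition(keys, size - 1, axis=1)[:, :size]
            mem = np.zeros((b, universe), dtype=bool)
            np.put_along_axis(mem, idx, True, axis=1)
            member &= mem[:, :a]
        out[done:done + b] = member.sum(axis=1)
        done += b
    return out


def permutation_overlap_test(sets: dict[str, set] | None = None,
                             sizes: tuple[int, ...] | None = None,
                             observed: int | None = None,
                             universe: int = 863,
                             n_permutations: int = 100_000,
                             seed: int = 0) -> OverlapTestResult:
    """Permutation test for enrichment of a marker-set overlap.

    Provide either ``sets`` (named miRNA-id sets; the observed mutual
    overlap is computed from them) or ``sizes`` plus ``observed``.  The
    one-sided empirical p-value uses the +1 correction
    ``(#{null >= observed} + 1)/(n_permutations + 1)``, so it can never be
    exactly zero.
    """
    if n_permutations <= 0:
        raise ValueError("n_permutations must be positive")
    if sets is not None:
        members = [set(s) for s in sets.values()]
        if not 2 <= len(members) <= 3:
            raise ValueError("2 or 3 sets required")
        sizes = tuple(len(s) for s in members)
        observed = len(set.intersection(*members))
    if sizes is None or observed is None:
        raise ValueError("give either sets, or sizes and observed")
    sizes = tuple(int(s) for s in sizes)
    expectation = expected_overlap(sizes, universe)  # validates sizes too
    if observed < 0 or observed > min(sizes):
        raise ValueError("observed overlap must lie in [0, min(sizes)]")

    rng = child_rng(seed, "permutation_overlap_test")
    nulls = _null_overlaps(sizes, universe, n_permutations, rng)
    p = (int(np.sum(nulls >= observed)) + 1) / (n_permutations + 1)
    return OverlapTestResult(
        set_sizes=sizes,
        universe_size=universe,
        observed_overlap=int(observed),
        perm_mean=float(nulls.mean()),
        perm_sd=float(nulls.std(ddof=1)),
        empirical_p=float(p),
        n_permutations=int(n_permutations),
        closed_form_expectation=float(expectation),
    )
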