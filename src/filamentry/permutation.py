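"""Exact and Monte-Carlo permutation references for the Kruskal–Wallis test.

For the small per-dose group sizes of a colony assay the chi-square
approximation behind the Kruskal–Wallis p-value deserves an independent
check.  :func:`exact_kruskal_p` enumerates every assignment of the pooled
mid-ranks to the observed group sizes and returns the exact permutation
p-value; :func:`mc_kruskal_p` estimates the same by random shuffling.
Both are deliberately independent of :func:`filamentry.stats.kruskal_wallis`
(which delegates to scipy): the enumeration works directly on rank sums.

Feasible for total N up to ~14; the number of assignments is the
multinomial coefficient N! / Π n_j!.
"""

from __future__ import annotations

from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = ["exact_kruskal_p", "mc_kruskal_p", "exact_h_distribution"]

_EPS = 1e-9


def _rank_stat(rank_sums: Sequence[float], sizes: Sequence[int]) -> float:
    # Sum R_j^2 / n_j: a strictly increasing transform of H for fixed sizes
    # and tie pattern, so tail probabilities computed on it equal those on H.
    return float(sum(s * s / n for s, n in zip(rank_sums, sizes)))


def _enumerate_stats(ranks: np.ndarray, sizes: Sequence[int]) -> np.ndarray:
    """Statistic value for every ordered assignment of ranks to group sizes."""
    out: list[float] = []
    idx = tuple(range(len(ranks)))

    def rec(remaining: tuple[int, ...], gi: int, acc: float) -> None:
        if gi == len(sizes) - 1:
            s = float(ranks[list(remaining)].sum())
            out.append(acc + s * s / sizes[gi])
            return
        for comb in combinations(remaining, sizes[gi]):
            chosen = set(comb)
            s = float(ranks[list(comb)].sum())
            rec(
                tuple(i for i in remaining if i not in chosen),
                gi + 1,
                acc + s * s / sizes[gi],
            )

    rec(idx, 0, 0.0)
    return np.asarray(out)


def exact_kruskal_p(groups: Sequence[Sequence[float]]) -> float:
    """Exact permutation p-value of the Kruskal–Wallis test.

    Enumerates all ``N! / Π n_j!`` assignments of the pooled mid-ranks to
    the observed group sizes and returns ``P(H_perm >= H_obs)``.  Handles
    ties through mid-ranks (the tie correction is constant across
    permutations and cancels from the tail probability).
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    sizes = [a.size for a in arrays]
    pooled = np.concatenate(arrays)
    ranks = sps.rankdata(pooled)
    obs_sums, start = [], 0
    for n in sizes:
        obs_sums.append(float(ranks[start : start + n].sum()))
        start += n
    t_obs = _rank_stat(obs_sums, sizes)
    stats = _enumerate_stats(ranks, sizes)
    return float(np.mean(stats >= t_obs - _EPS))


def mc_kruskal_p(
    groups: Sequence[Sequence[float]], n_shuffles: int = 100_000, seed: int = 0
) -> float:
    """Monte-Carlo permutation p-value (random shuffles of the pooled ranks)."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    sizes = np.array([a.size for a in arrays])
    pooled = np.concatenate(arrays)
    ranks = sps.rankdata(pooled)
    bounds = np.cumsum(sizes)[:-1]
    obs = _rank_stat([g.sum() for g in np.split(ranks, bounds)], sizes)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_shuffles):
        perm = rng.permutation(ranks)
        if _rank_stat([g.sum() for g in np.split(perm, bounds)], sizes) >= obs - _EPS:
            hits += 1
    return hits / n_shuffles


def exact_h_distribution(sizes: Sequence[int]) -> tuple[np.ndarray, np.ndarray]:
    """Exact null distribution of H for untied data with the given sizes.

    Returns ``(h_values, probabilities)`` sorted by H, where H is the
    untied Kruskal–Wallis statistic ``12/(N(N+1))·ΣR_j²/n_j − 3(N+1)``.
    """
    n = int(sum(sizes))
    ranks = np.arange(1, n + 1, dtype=float)
    stats = _enumerate_stats(ranks, list(sizes))
    h = 12.0 / (n * (n + 1)) * stats - 3.0 * (n + 1)
    h = np.round(h, 10)
    values, counts = np.unique(h, return_counts=True)
    return values, counts / counts.sum()
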