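"""Diversity measures: Hill numbers, rarefaction, accumulation, resampled gamma.

The Hill number of order ``q`` for relative abundances ``p_i`` is

    qD = (sum_i p_i^q)^(1/(1-q)),        q != 1
    1D = exp(-sum_i p_i ln p_i)          (the q -> 1 limit, Shannon)

so 0D is species richness, 1D the exponential of Shannon entropy, and 2D
the inverse Simpson concentration.  All three are "effective numbers of
species": a community with qD = n is as diverse as one of n equally common
species.  Landscape (gamma) diversity is made comparable across site classes
of unequal size by resampling a fixed number of sites many times and taking
empirical quantiles of the resampling distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .data import AbundanceMatrix


def _clean_counts(counts) -> np.ndarray:
    x = np.asarray(counts, dtype=float)
    if x.ndim != 1:
        x = x.ravel()
    if (x < 0).any():
        raise ValueError("negative abundance")
    x = x[x > 0]
    if x.size == 0:
        raise ValueError("all-zero abundance vector")
    return x


def hill_number(counts, q: float) -> float:
    """Effective number of species of order ``q`` (zeros ignored).

    ``q = 0`` counts species; ``q = 1`` uses the closed-form Shannon limit;
    larger ``q`` weighs abundant species increasingly strongly.
    """
    if q < 0:
        raise ValueError("order q must be non-negative")
    x = _clean_counts(counts)
    p = x / x.sum()
    if q == 0:
        return float(p.size)
    if q == 1:
        return float(np.exp(-np.sum(p * np.log(p))))
    return float(np.sum(p ** q) ** (1.0 / (1.0 - q)))


def hill_profile(counts, orders=(0.0, 1.0, 2.0)) -> dict[float, float]:
    return {float(q): hill_number(counts, q) for q in orders}


def rarefied_richness(counts, n: int) -> float:
    """Expected species number in a random subsample of ``n`` individuals.

    Exact (hypergeometric) individual-based rarefaction,

        E[S_n] = sum_i 1 - C(N - N_i, n) / C(N, n),

    evaluated with log-gamma arithmetic so large totals are safe.
    """
    x = _clean_counts(counts)
    if abs(x - np.round(x)).max() > 1e-9:
        raise ValueError("rarefaction requires integer counts")
    x = np.round(x).astype(np.int64)
    N = int(x.sum())
    if not 1 <= n <= N:
        raise ValueError(f"subsample size n={n} outside [1, {N}]")
    # log C(N - Ni, n) - log C(N, n); species with N - Ni < n are always seen
    log_denom = gammaln(N + 1) - gammaln(n + 1) - gammaln(N - n + 1)
    rem = N - x
    with np.errstate(invalid="ignore"):
        log_num = gammaln(rem + 1) - gammaln(n + 1) - gammaln(rem - n + 1)
    p_missing = np.where(rem >= n, np.exp(log_num - log_denom), 0.0)
    return float(np.sum(1.0 - p_missing))


@dataclass
class ResampledGamma:
    """Pooled-landscape diversity from repeated random subsets of sites."""

    q: float
    subsample_size: int
    iterations: int
    mean: float
    ci_low: float
    ci_high: float
    values: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.mean + 1e-12 and self.mean <= self.ci_high + 1e-12):
            raise ValueError("quantiles must bracket the mean")


def resampled_gamma(matrix: AbundanceMatrix, subsample_size: int = 12,
                    iterations: int = 1000, q: float = 0.0,
                    seed: int | None = None, replace: bool = False,
                    keep_values: bool = False) -> ResampledGamma:
    """Gamma diversity of ``subsample_size`` pooled units, resampled.

    Each iteration pools the counts of a uniform random subset of units
    (without replacement by default) and evaluates the Hill number; the
    mean and the 0.025 / 0.975 empirical quantiles of the resampling
    distribution are returned.
    """
    counts = matrix.counts
    n_units = counts.shape[0]
    if subsample_size > n_units:
        raise ValueError(f"subsample_size {subsample_size} > {n_units} units")
    rng = np.random.default_rng(seed)
    vals = np.empty(iterations)
    for it in range(iterations):
        idx = rng.choice(n_units, size=subsample_size, replace=replace)
        vals[it] = hill_number(counts[idx].sum(axis=0), q)
    lo, hi = np.quantile(vals, [0.025, 0.975])
    return ResampledGamma(q, subsample_size, iterations, float(vals.mean()),
                          float(lo), float(hi), vals if keep_values else None)


def accumulation_curve(matrix: AbundanceMatrix, iterations: int | None = None,
                       seed: int | None = None) -> np.ndarray:
    """Expected species count after pooling m = 1..M sampling units.

    By default the exact sample-based expectation over random unit orderings
    is used (each species with occupancy ``o`` among ``M`` units is missed by
    a random m-subset with probability C(M-o, m)/C(M, m)); passing
    ``iterations`` switches to Monte-Carlo over random orderings.
    """
    counts = matrix.counts
    M = counts.shape[0]
    if M < 1:
        raise ValueError("empty matrix")
    occ = (counts > 0).sum(axis=0).astype(np.int64)
    occ = occ[occ > 0]
    if iterations is None:
        out = np.empty(M)
        for m in range(1, M + 1):
            log_denom = gammaln(M + 1) - gammaln(m + 1) - gammaln(M - m + 1)
            rem = M - occ
            with np.errstate(invalid="ignore"):
                log_num = gammaln(rem + 1) - gammaln(m + 1) - gammaln(rem - m + 1)
            p_missing = np.where(rem >= m, np.exp(log_num - log_denom), 0.0)
            out[m - 1] = np.sum(1.0 - p_missing)
        return out
    rng = np.random.default_rng(seed)
    acc = np.zeros(M)
    pres = counts > 0
    for _ in range(iterations):
        order = rng.permutation(M)
        seen = np.cumsum(pres[order], axis=0) > 0
        acc += seen.sum(axis=1)
    return acc / iterations
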