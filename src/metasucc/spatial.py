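"""Permutational spatial and multivariate statistics.

* :func:`mantel` — Pearson correlation between two distance matrices, null
  distribution by simultaneous row/column permutation of one matrix.
* :func:`mantel_correlogram` — per-distance-class Mantel statistics against
  the class-membership indicator matrix (sign flipped so positive values
  mean "nearby sites are compositionally similar"), with progressive Holm
  correction across classes.
* :func:`permanova` — one-factor distance-based (non-parametric) MANOVA.
  Implemented through the Gower-centered inner-product matrix
  ``G = -1/2 J D^2 J`` and a design hat matrix ``H``:

      pseudo-F = (tr(HGH)/df_model) / (tr((I-H)G(I-H))/df_resid),
      R^2      = tr(HGH)/tr(G),

  which for a categorical factor coincides with the classical
  within/between pair-sum formulation, and with ``coding="linear"``
  supports the one-degree-of-freedom ordered-class contrast.

All permutation p-values use the add-one convention
``p = (1 + #{perm >= obs}) / (1 + n_perm)`` and are exactly reproducible
under a seed; for small n an exhaustive enumeration over all distinct
relabelings is available.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .similarity import DissimilarityMatrix


@dataclass
class PermutationTestResult:
    statistic: float
    permutations: int
    p_value: float
    seed: int | None = None
    exhaustive: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.p_value <= 1:
            raise ValueError("p-value outside (0, 1]")


def _as_square(d) -> np.ndarray:
    if isinstance(d, DissimilarityMatrix):
        return d.values
    return np.asarray(d, dtype=float)


def _check_aligned(d1, d2) -> tuple[np.ndarray, np.ndarray]:
    m1, m2 = _as_square(d1), _as_square(d2)
    if m1.shape != m2.shape:
        raise ValueError("distance matrices differ in size")
    if isinstance(d1, DissimilarityMatrix) and isinstance(d2, DissimilarityMatrix):
        if d1.units != d2.units:
            raise ValueError("distance matrices have mismatched unit order")
    return m1, m2


def _pearson_lower(a: np.ndarray, b: np.ndarray, iu) -> float:
    return float(np.corrcoef(a[iu], b[iu])[0, 1])


def mantel(d_species, d_geo, permutations: int = 999, seed: int | None = None,
           alternative: str = "greater", exhaustive: bool = False,
           ) -> PermutationTestResult:
    """Mantel test of matrix correlation.

    The statistic is the Pearson correlation between the off-diagonal
    entries; the null permutes rows and columns of the second matrix
    simultaneously.  ``exhaustive=True`` enumerates all n! permutations
    (practical for n <= 7).
    """
    m1, m2 = _check_aligned(d_species, d_geo)
    n = m1.shape[0]
    if n < 4:
        raise ValueError("need at least 4 units")
    iu = np.triu_indices(n, k=1)
    obs = _pearson_lower(m1, m2, iu)

    def _stat(perm) -> float:
        return _pearson_lower(m1, m2[np.ix_(perm, perm)], iu)

    if exhaustive:
        stats = np.array([_stat(list(p)) for p in itertools.permutations(range(n))])
        # identity permutation is among the enumerated relabelings
        p = float(np.mean(_compare(stats, obs, alternative)))
        return PermutationTestResult(obs, stats.size, p, seed, exhaustive=True)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(permutations):
        perm = rng.permutation(n)
        if _compare(np.array([_stat(perm)]), obs, alternative)[0]:
            hits += 1
    p = (1 + hits) / (1 + permutations)
    return PermutationTestResult(obs, permutations, float(p), seed)


def _compare(stats: np.ndarray, obs: float, alternative: str) -> np.ndarray:
    eps = 1e-12
    if alternative == "greater":
        return stats >= obs - eps
    if alternative == "less":
        return stats <= obs + eps
    if alternative == "two-sided":
        return np.abs(stats) >= abs(obs) - eps
    raise ValueError("alternative must be greater/less/two-sided")


# ---------------------------------------------------------------------------
# Mantel correlogram

def sturges_breaks(pair_dists: np.ndarray) -> np.ndarray:
    n_classes = int(np.ceil(np.log2(pair_dists.size)) + 1)
    return np.linspace(pair_dists.min(), pair_dists.max(), n_classes + 1)


def mantel_correlogram(d_species, coords, breaks=None, permutations: int = 999,
                       seed: int | None = None) -> pd.DataFrame:
    """Mantel correlogram over geographic distance classes.

    Per class, the species dissimilarities are tested against the 0/1
    membership matrix of that class; the reported r is negated so that
    positive values indicate similarity at that distance.  Classes with no
    pairs are dropped.  Columns: class_mid, n_pairs, r, p, p_corrected
    (progressive Holm).
    """
    m = _as_square(d_species)
    xy = np.asarray(coords, dtype=float)
    if xy.shape[0] != m.shape[0]:
        raise ValueError("coords do not match dissimilarity matrix")
    geo = np.sqrt(((xy[:, None, :] - xy[None, :, :]) ** 2).sum(axis=-1))
    iu = np.triu_indices(m.shape[0], k=1)
    pd_all = geo[iu]
    edges = np.asarray(breaks, dtype=float) if breaks is not None \
        else sturges_breaks(pd_all)
    rng = np.random.default_rng(seed)
    rows = []
    for k in range(len(edges) - 1):
        lo, hi = edges[k], edges[k + 1]
        if k == len(edges) - 2:
            in_class = (geo >= lo) & (geo <= hi)
        else:
            in_class = (geo >= lo) & (geo < hi)
        np.fill_diagonal(in_class, False)
        n_pairs = int(in_class[iu].sum())
        if n_pairs == 0:
            continue
        indicator = in_class.astype(float)
        child_seed = int(rng.integers(0, 2 ** 31 - 1))
        if n_pairs == iu[0].size:
            # every pair falls in this class: correlation undefined
            rows.append({"class_mid": float((lo + hi) / 2), "n_pairs": n_pairs,
                         "r": 0.0, "p": 1.0})
            continue
        res = mantel(m, indicator, permutations=permutations, seed=child_seed,
                     alternative="less")  # similar (small d) within class
        rows.append({"class_mid": float((lo + hi) / 2), "n_pairs": n_pairs,
                     "r": -res.statistic, "p": res.p_value})
    out = pd.DataFrame(rows)
    # progressive Holm: class k corrected within the first k classes
    corrected = []
    for k in range(len(out)):
        sub = out["p"].to_numpy()[: k + 1]
        corrected.append(_holm(sub)[k])
    out["p_corrected"] = corrected
    return out


def _holm(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p)
    m = p.size
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


# ---------------------------------------------------------------------------
# PERMANOVA

@dataclass
class PermanovaResult:
    pseudo_f: float
    r2: float
    df_model: int
    df_resid: int
    test: PermutationTestResult

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (f"PERMANOVA: F = {self.pseudo_f:.3f}, R^2 = {self.r2:.3f}, "
                f"df = ({self.df_model}, {self.df_resid}), p = {self.test.p_value:.4g}")


def _gower_center(dmat: np.ndarray) -> np.ndarray:
    n = dmat.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return -0.5 * j @ (dmat ** 2) @ j


def _hat(x: np.ndarray) -> np.ndarray:
    q, _ = np.linalg.qr(x)
    return q @ q.T


def _design(groups: np.ndarray, coding: str) -> tuple[np.ndarray, int]:
    n = groups.size
    if coding == "categorical":
        levels = pd.unique(groups)
        x = np.column_stack([np.ones(n)] +
                            [(groups == g).astype(float) for g in levels[1:]])
        return x, len(levels) - 1
    if coding == "linear":
        levels = sorted(pd.unique(groups))
        rank = {g: i for i, g in enumerate(levels)}
        x = np.column_stack([np.ones(n),
                             np.array([rank[g] for g in groups], dtype=float)])
        return x, 1
    raise ValueError("coding must be 'categorical' or 'linear'")


def permanova(d, groups, permutations: int = 999, seed: int | None = None,
              coding: str = "categorical", exhaustive: bool = False,
              ) -> PermanovaResult:
    """One-factor distance-based MANOVA by permutation of unit labels."""
    dmat = _as_square(d)
    groups = np.asarray(list(groups))
    n = dmat.shape[0]
    if groups.size != n:
        raise ValueError("groups do not match distance matrix")
    levels, counts = np.unique(groups, return_counts=True)
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    if (counts < 2).any():
        bad = levels[counts < 2]
        raise ValueError(f"singleton group(s): {list(bad)}")
    g = _gower_center(dmat)
    x, df_model = _design(groups, coding)
    h = _hat(x)
    df_resid = n - df_model - 1

    ident = np.eye(n)
    ss_total = float(np.trace(g))

    def _f(perm: np.ndarray) -> float:
        gp = g[np.ix_(perm, perm)]
        ss_model = float(np.sum(h * gp))          # tr(H Gp), H symmetric
        ss_resid = float(np.sum((ident - h) * gp))
        return (ss_model / df_model) / (ss_resid / df_resid)

    obs_perm = np.arange(n)
    f_obs = _f(obs_perm)
    ss_model_obs = float(np.sum(h * g))
    r2 = ss_model_obs / ss_total

    if exhaustive:
        # enumerate distinct label-to-unit assignments, not raw permutations
        stats = []
        for labs in sorted(set(itertools.permutations(groups))):
            xl, dfm = _design(np.array(labs, dtype=object), coding)
            hl = _hat(xl)
            ss_m = float(np.sum(hl * g))
            ss_r = float(np.sum((ident - hl) * g))
            stats.append((ss_m / dfm) / (ss_r / df_resid))
        stats = np.asarray(stats)
        pval = float(np.mean(stats >= f_obs - 1e-12))
        test = PermutationTestResult(f_obs, stats.size, pval, seed, exhaustive=True)
    else:
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(permutations):
            if _f(rng.permutation(n)) >= f_obs - 1e-12:
                hits += 1
        pval = (1 + hits) / (1 + permutations)
        test = PermutationTestResult(f_obs, permutations, float(pval), seed)
    return PermanovaResult(f_obs, float(r2), df_model, df_resid, test)
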