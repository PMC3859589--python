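"""Pairwise compositional (dis)similarity indices.

Implemented indices:

* **Ružička** — the abundance-based Jaccard dissimilarity,
  ``d = 1 - sum_i min(x_i, y_i) / sum_i max(x_i, y_i)``; on presence/absence
  vectors it reduces exactly to the classical Jaccard.
* **Chao–Jaccard abundance estimator** — a similarity between two *sampled*
  assemblages that corrects for unseen shared species, and is therefore far
  less biased than raw indices when one sample (e.g. seedlings) is much
  smaller than the other.  With shared species set ``S12``, sample totals
  ``n = sum x`` and ``m = sum y``,

      U = sum_{i in S12} x_i/n
          + ((m-1)/m) * f+1/(2 f+2) * sum_{i in S12} (x_i/n) [y_i = 1]

  where ``f+1`` (``f+2``) is the number of shared species occurring as
  singletons (doubletons) in sample *y*; ``V`` is defined symmetrically,
  both are capped at 1, and the estimated Jaccard similarity is
  ``UV / (U + V - UV)``.
* **Morisita–Horn** — provided as an alternative abundance index; not used
  in default reports.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .data import AbundanceMatrix


@dataclass
class DissimilarityMatrix:
    """Square symmetric pairwise dissimilarities among sampling units."""

    units: list[str]
    values: np.ndarray
    index_name: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.units):
            raise ValueError("values must be square and match units")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("dissimilarity matrix must be symmetric")
        if np.abs(np.diag(v)).max(initial=0.0) > 1e-12:
            raise ValueError("diagonal must be zero")
        if (v < -1e-12).any():
            raise ValueError("dissimilarities must be non-negative")
        np.fill_diagonal(v, 0.0)
        self.values = v

    @property
    def n(self) -> int:
        return len(self.units)

    def condensed(self) -> np.ndarray:
        """Lower-triangle entries in scipy ``pdist`` order."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.units, columns=self.units)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index_label="unit")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, index_name: str = "") -> "DissimilarityMatrix":
        return cls(list(df.index.astype(str)), df.to_numpy(dtype=float), index_name)


def _check_pair(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("negative abundance")
    if x.sum() == 0 and y.sum() == 0:
        raise ValueError("both vectors are all-zero; dissimilarity undefined")
    return x, y


def ruzicka(x, y) -> float:
    """Abundance-based Jaccard (Ružička) dissimilarity in [0, 1]."""
    x, y = _check_pair(x, y)
    return float(1.0 - np.minimum(x, y).sum() / np.maximum(x, y).sum())


def jaccard_presence(x, y) -> float:
    """Presence/absence Jaccard dissimilarity, 1 - |A∩B| / |A∪B|."""
    x, y = _check_pair(x, y)
    a, b = x > 0, y > 0
    return float(1.0 - (a & b).sum() / (a | b).sum())


def morisita_horn(x, y) -> float:
    """Morisita-Horn dissimilarity (abundance-based, dominance-weighted)."""
    x, y = _check_pair(x, y)
    if x.sum() == 0 or y.sum() == 0:
        return 1.0
    px, py = x / x.sum(), y / y.sum()
    denom = (px ** 2).sum() + (py ** 2).sum()
    return float(1.0 - 2.0 * (px * py).sum() / denom)


def chao_jaccard_abundance(x, y, corrected: bool = True) -> float:
    """Chao-Jaccard abundance-based estimated *similarity* in [0, 1].

    ``corrected=True`` (default) applies the unseen-shared-species
    correction term; the raw version (U, V as plain shared-abundance
    fractions) is available for sensitivity checks.  When a sample has no
    doubletons among shared species the correction denominator ``2 f+2`` is
    replaced by ``2 (f+2 + 1)``, the usual bias-correction convention for
    empty doubleton counts.
    """
    x, y = _check_pair(x, y)
    n, m = x.sum(), y.sum()
    if n == 0 or m == 0:
        raise ValueError("zero sample total")
    shared = (x > 0) & (y > 0)
    if not shared.any():
        return 0.0

    def _u_hat(a, b, na, nb) -> float:
        # estimated total relative abundance in sample a of species shared with b
        u = (a[shared] / na).sum()
        if corrected:
            f1 = int(np.sum(shared & (b == 1)))
            f2 = int(np.sum(shared & (b == 2)))
            denom = 2.0 * (f2 if f2 > 0 else f2 + 1)
            add = (nb - 1.0) / nb * f1 / denom * (a[shared] / na)[b[shared] == 1].sum()
            u += add
        return min(u, 1.0)

    u = _u_hat(x, y, n, m)
    v = _u_hat(y, x, m, n)
    if u == 0 or v == 0:
        return 0.0
    return float(u * v / (u + v - u * v))


def chao_jaccard_dissimilarity(x, y, corrected: bool = True) -> float:
    return 1.0 - chao_jaccard_abundance(x, y, corrected=corrected)


_INDEX_FUNCS: dict[str, Callable] = {
    "ruzicka": ruzicka,
    "jaccard": jaccard_presence,
    "chao_jaccard": chao_jaccard_dissimilarity,
    "morisita_horn": morisita_horn,
}


def pairwise_dissimilarity(matrix: AbundanceMatrix, index: str = "ruzicka",
                           ) -> DissimilarityMatrix:
    """All pairwise dissimilarities among the units of an abundance matrix."""
    try:
        fn = _INDEX_FUNCS[index]
    except KeyError:
        raise ValueError(f"unknown index {index!r}; choose from {sorted(_INDEX_FUNCS)}")
    counts = matrix.counts
    n = counts.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = fn(counts[i], counts[j])
    return DissimilarityMatrix(matrix.units, out, index)


def seedling_divergence(seedling_matrices: dict[str, AbundanceMatrix],
                        reference: AbundanceMatrix,
                        traits: pd.DataFrame,
                        min_dbhmax_mid_cm: float = 7.5,
                        ci: str = "normal",
                        n_boot: int = 1000,
                        seed: int | None = None) -> pd.DataFrame:
    """Similarity of seedling assemblages per class to a reference stem pool.

    For each class the seedling units are paired with every unit of the
    reference matrix (typically the >= 1 cm stems of the earliest
    basal-area class), each pair scored with the Chao-Jaccard abundance
    estimator on species that can reach the canopy size cut (maximum-DBH
    class mid-value >= ``min_dbhmax_mid_cm``), and the mean with 95%
    confidence limits over pairs is reported.
    """
    canopy = set(traits.loc[traits["dbhmax_mid_cm"] >= min_dbhmax_mid_cm,
                            "species_code"].astype(str))

    def _filter(m: AbundanceMatrix) -> pd.DataFrame:
        cols = [c for c in m.species if c in canopy]
        return m.df[cols]

    ref = _filter(reference)
    rng = np.random.default_rng(seed)
    rows = []
    for label, mat in seedling_matrices.items():
        sub = _filter(mat)
        if sub.shape[0] == 0:
            raise ValueError(f"class {label!r} has no seedling units")
        species = sorted(set(sub.columns) | set(ref.columns))
        a = sub.reindex(columns=species, fill_value=0).to_numpy()
        b = ref.reindex(columns=species, fill_value=0).to_numpy()
        sims = []
        for i in range(a.shape[0]):
            for j in range(b.shape[0]):
                if a[i].sum() == 0 or b[j].sum() == 0:
                    # a unit with no canopy-capable stems shares nothing
                    sims.append(0.0)
                else:
                    sims.append(chao_jaccard_abundance(a[i], b[j]))
        sims = np.asarray(sims)
        if sims.size == 0:
            raise ValueError(f"class {label!r}: no comparable unit pairs")
        mean = sims.mean()
        if ci == "normal":
            se = sims.std(ddof=1) / np.sqrt(sims.size) if sims.size > 1 else 0.0
            z = norm.ppf(0.975)
            lo, hi = mean - z * se, mean + z * se
        elif ci == "bootstrap":
            boots = np.array([rng.choice(sims, sims.size, replace=True).mean()
                              for _ in range(n_boot)])
            lo, hi = np.quantile(boots, [0.025, 0.975])
        else:
            raise ValueError("ci must be 'normal' or 'bootstrap'")
        rows.append({"class": label, "mean_similarity": float(mean),
                     "ci_low": float(lo), "ci_high": float(hi),
                     "n_pairs": int(sims.size)})
    return pd.DataFrame(rows)
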