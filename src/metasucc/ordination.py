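"""Non-metric multidimensional scaling (NMDS) and gradient diagnostics.

NMDS seeks a k-dimensional configuration whose inter-point distances are in
the same rank order as the input dissimilarities, minimizing Kruskal's
stress-1,

    stress = sqrt( sum (d_ij - dhat_ij)^2 / sum d_ij^2 ),

where ``dhat`` is the monotone (isotonic) regression of the configuration
distances on the dissimilarity ranks (primary treatment of ties: tied
dissimilarities impose no order among their fitted values).  The optimizer
is SMACOF-style majorization with the isotonic step re-solved each
iteration; the first start is the classical (metric) scaling solution, so
perfectly embeddable inputs converge immediately, and the remaining starts
are random.  The best configuration is centered and rotated to its
principal axes so axis 1 carries the dominant gradient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import procrustes
from scipy.spatial.distance import pdist, squareform
from sklearn.isotonic import IsotonicRegression

from .data import AbundanceMatrix
from .similarity import DissimilarityMatrix, pairwise_dissimilarity


@dataclass
class OrdinationResult:
    """Best NMDS configuration and its convergence diagnostics."""

    scores: pd.DataFrame          # unit x axis coordinates, PCA-rotated
    stress: float                 # Kruskal stress-1 of the best start
    k: int
    n_starts: int
    converged: bool               # two best starts agree (Procrustes)
    best_start_seed: int | None
    procrustes_rmse: float | None = None
    all_stress: tuple = ()

    @property
    def units(self) -> list[str]:
        return list(self.scores.index)

    def axis(self, i: int = 1) -> pd.Series:
        return self.scores[f"axis{i}"]


def kruskal_stress(d: np.ndarray, config: np.ndarray) -> float:
    """Stress-1 of a configuration against condensed dissimilarities ``d``.

    Depends on the dissimilarities only through their rank order, hence is
    invariant to monotone transformations of ``d``.
    """
    dist = pdist(config)
    dhat = _isotonic_disparities(d, dist)
    denom = (dist ** 2).sum()
    if denom == 0:
        return 0.0
    return float(np.sqrt(((dist - dhat) ** 2).sum() / denom))


def _isotonic_disparities(d: np.ndarray, dist: np.ndarray) -> np.ndarray:
    # primary tie treatment: order ties by current distance so they are free
    order = np.lexsort((dist, d))
    iso = IsotonicRegression()
    fitted = iso.fit_transform(np.arange(d.size), dist[order])
    dhat = np.empty_like(dist)
    dhat[order] = fitted
    return dhat


def _classical_mds(dmat: np.ndarray, k: int) -> np.ndarray:
    n = dmat.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (dmat ** 2) @ j
    w, v = np.linalg.eigh(b)
    idx = np.argsort(w)[::-1][:k]
    w = np.clip(w[idx], 0.0, None)
    return v[:, idx] * np.sqrt(w)


def _nmds_single(dmat: np.ndarray, d: np.ndarray, init: np.ndarray,
                 max_iter: int, tol: float) -> tuple[np.ndarray, float]:
    n = dmat.shape[0]
    x = init.copy()
    stress_prev = np.inf
    for _ in range(max_iter):
        dist = pdist(x)
        dhat = _isotonic_disparities(d, dist)
        # scale disparities to the distances' norm (stress-1 normalization)
        denom = (dist ** 2).sum()
        if denom == 0:
            return x, 0.0
        stress = np.sqrt(((dist - dhat) ** 2).sum() / denom)
        if stress_prev - stress < tol:
            stress_prev = min(stress, stress_prev)
            break
        stress_prev = stress
        # Guttman transform with the disparities as targets
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(dist > 0, dhat / dist, 0.0)
        b = -squareform(ratio)
        np.fill_diagonal(b, -b.sum(axis=1))
        x = b @ x / n
    return x, float(stress_prev if np.isfinite(stress_prev) else 0.0)


def _pca_rotate(x: np.ndarray) -> np.ndarray:
    x = x - x.mean(axis=0)
    _, _, vt = np.linalg.svd(x, full_matrices=False)
    rot = x @ vt.T
    # deterministic sign: largest-magnitude coordinate on each axis positive
    for j in range(rot.shape[1]):
        i = np.argmax(np.abs(rot[:, j]))
        if rot[i, j] < 0:
            rot[:, j] = -rot[:, j]
    return rot


def nmds(d: DissimilarityMatrix, k: int = 2, n_starts: int = 20,
         max_iter: int = 300, tol: float = 1e-7,
         seed: int | None = None) -> OrdinationResult:
    """Best-of-``n_starts`` NMDS of a dissimilarity matrix in ``k`` dimensions.

    Start 0 is the classical-scaling configuration, the rest are random.
    Convergence is declared when the two lowest-stress starts agree to
    Procrustes RMSE < 1e-4.
    """
    if k < 1 or n_starts < 1:
        raise ValueError("k and n_starts must be >= 1")
    dmat = d.values
    if dmat.shape[0] <= k:
        raise ValueError("need more units than dimensions")
    dcond = d.condensed()
    rng = np.random.default_rng(seed)
    solutions: list[tuple[float, np.ndarray, int | None]] = []
    scale = max(dcond.max(initial=1.0), 1e-12)
    for start in range(n_starts):
        if start == 0:
            init = _classical_mds(dmat, k)
            if np.allclose(init, 0):
                init = rng.normal(size=(dmat.shape[0], k)) * scale
        else:
            init = rng.normal(size=(dmat.shape[0], k)) * scale
        x, stress = _nmds_single(dmat, dcond, init, max_iter, tol)
        solutions.append((stress, x, start))
    solutions.sort(key=lambda t: t[0])
    best_stress, best_x, best_seed = solutions[0]
    rmse = None
    converged = len(solutions) == 1
    if len(solutions) > 1:
        try:
            _, _, disparity = procrustes(solutions[0][1], solutions[1][1])
            rmse = float(np.sqrt(disparity / dmat.shape[0]))
            converged = rmse < 1e-4
        except ValueError:  # degenerate (e.g. all-identical) configuration
            rmse = None
            converged = False
    rot = _pca_rotate(best_x)
    scores = pd.DataFrame(rot, index=d.units,
                          columns=[f"axis{i + 1}" for i in range(k)])
    return OrdinationResult(scores, best_stress, k, n_starts, converged,
                            best_seed, rmse, tuple(s for s, _, _ in solutions))


def choose_dimensions(d: DissimilarityMatrix, max_k: int = 4,
                      stress_target: float = 0.10, n_starts: int = 10,
                      seed: int | None = None) -> tuple[int, dict[int, float]]:
    """Scree rule: smallest k (up to ``max_k``) with stress below target."""
    stresses: dict[int, float] = {}
    for k in range(1, max_k + 1):
        res = nmds(d, k=k, n_starts=n_starts, seed=seed)
        stresses[k] = res.stress
        if res.stress < stress_target:
            return k, stresses
    return max_k, stresses


def orient_axis(result: OrdinationResult, covariate: pd.Series,
                axis: int = 1) -> OrdinationResult:
    """Flip an axis so its correlation with the covariate is non-negative."""
    col = f"axis{axis}"
    aligned = covariate.reindex(result.scores.index)
    if aligned.isna().any():
        missing = list(result.scores.index[aligned.isna()])
        raise ValueError(f"covariate missing for units {missing}")
    r = np.corrcoef(result.scores[col], aligned)[0, 1]
    if np.isfinite(r) and r < 0:
        result.scores[col] = -result.scores[col]
    return result


def axis_regression(result: OrdinationResult, sites: pd.DataFrame,
                    predictor: str, family: str | None = None,
                    axis: int = 1):
    """Regress an ordination axis on a site covariate (age, SBA, or light).

    Delegates to the succession regression machinery; with ``family=None``
    the best of the linear/power/exponential forms is selected.
    """
    from . import succession  # local import to avoid cycle at module load

    col = f"axis{axis}"
    aligned = sites.set_index(sites["site_id"].astype(str)) \
        if "site_id" in sites.columns else sites
    x = aligned[predictor].reindex(result.scores.index)
    if x.isna().any():
        raise ValueError("predictor missing for some ordination units")
    y = result.scores[col].to_numpy()
    if family is None:
        return succession.select_model(x.to_numpy(dtype=float), y)
    return succession.fit_model(x.to_numpy(dtype=float), y, family)


def frequency_threshold_sensitivity(matrix: AbundanceMatrix,
                                    thresholds=(0.10, 0.25, 0.50),
                                    index: str = "ruzicka", k: int = 2,
                                    n_starts: int = 10,
                                    seed: int | None = None) -> dict[float, float]:
    """Sensitivity of the main gradient to dropping infrequent species.

    Refits the NMDS keeping only species occurring in more than each given
    fraction of units and reports the absolute Pearson correlation between
    the refit and full-data axis-1 scores (axis sign is arbitrary).
    """
    full = nmds(pairwise_dissimilarity(matrix, index), k=k,
                n_starts=n_starts, seed=seed)
    occ_frac = (matrix.counts > 0).mean(axis=0)
    out: dict[float, float] = {}
    for thr in thresholds:
        if not 0 < thr < 1:
            raise ValueError("thresholds must lie in (0, 1)")
        keep = [sp for sp, f in zip(matrix.species, occ_frac) if f > thr]
        if len(keep) < 3:
            raise ValueError(f"fewer than 3 species exceed threshold {thr}")
        sub = AbundanceMatrix(matrix.df[keep].copy(), matrix.stratum,
                              matrix.unit_level, matrix.min_diameter_cm,
                              dict(matrix.sampled_area_m2), dict(matrix.unit_site))
        nonzero = sub.df.sum(axis=1) > 0
        sub.df = sub.df.loc[nonzero]
        red = nmds(pairwise_dissimilarity(sub, index), k=k,
                   n_starts=n_starts, seed=seed)
        joined = pd.concat([full.axis(1).rename("full"),
                            red.axis(1).rename("reduced")], axis=1).dropna()
        r = np.corrcoef(joined["full"], joined["reduced"])[0, 1]
        out[float(thr)] = float(abs(r))
    return out
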