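"""Synthetic metacommunity generator for chronosequence analyses.

The generator encodes the two processes the downstream statistics are meant
to detect — species-specific **dispersal limitation** (log-normally varying
colonization rates, so landscape frequency accumulates at very different
rates across species) and the **successional niche** (early high-light
specialists that colonize fast, grow fast, die young and fail to establish
under the low light of closed-canopy stands).

Mechanics, per site of age ``T`` years:

* colonization events per species ``i`` are Poisson(``rate_i * T``), with
  arrival times uniform on (0, T);
* stand basal area follows a saturating curve ``SBA(t) = sba_max * t/(t+h)``
  with site-level log-normal noise, and understory light declines as
  ``light% = 100 * exp(-k * SBA)``;
* an arrival establishes with probability ``s_i + (1 - s_i) * l^2`` where
  ``l`` is the light fraction at arrival time and ``s_i`` the species'
  shade tolerance — close to 1 under early high light for everyone,
  collapsing to the tolerance under closed canopy (the quadratic light
  term makes recruitment effectively gap-limited, which is what drives
  shade-intolerant pioneers out of older stands);
* established stems die with constant hazard ``1/longevity_i`` and grow as
  ``diameter = growth_i * residence`` capped at ``0.95 * DBH_max_i``;
* survivors are emitted as stems with the stratum implied by diameter and
  life form; saplings are thinned to the half-plot sampling area;
* seedlings (last-2-year establishments, no diameter) are drawn directly
  with a seed-rain multiplier representing the much denser recruit layer.

A structureless companion, :func:`generate_null`, emits i.i.d. Poisson
counts with no age, basal-area, or spatial dependence, for calibrating the
type-I error of the permutation tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .data import PLOT_AREA_M2

DBHMAX_CLASSES = ("1-5", "5-10", "10-20", "20-40", "40-80", ">80")
DBHMAX_MIDS = {"1-5": 3.0, "5-10": 7.5, "10-20": 15.0, "20-40": 30.0,
               "40-80": 60.0, ">80": 120.0}


@dataclass
class SpeciesPoolParams:
    """Parameters of the regional species pool.

    Rates are per-species expected colonization events per site-year; the
    pool mixes a pioneer guild (fast, intolerant, short-lived) with a
    residual guild spanning the full maximum-size spectrum.
    """

    n_species: int = 300
    pioneer_fraction: float = 0.15
    colonization_log_mean: float = np.log(0.06)  # median arrivals / site-year
    colonization_log_sd: float = 1.0
    pioneer_rate_multiplier: float = 6.0
    seedling_rain_factor: float = 50.0           # recruit layer vs established stems
    life_form_probs: dict = field(default_factory=lambda: {
        "tree": 0.55, "shrub": 0.20, "palm": 0.05, "liana": 0.20})

    def __post_init__(self) -> None:
        if self.n_species < 1:
            raise ValueError("n_species must be positive")
        if not 0 <= self.pioneer_fraction <= 1:
            raise ValueError("pioneer_fraction must be in [0, 1]")


@dataclass
class LandscapeParams:
    """Landscape layout and stand-development parameters."""

    n_sites: int = 45
    age_intervals: Sequence[tuple[int, int]] = ((2, 7), (8, 17), (18, 32))
    sba_max: float = 30.0            # asymptote, m^2/ha
    sba_half_sat_y: float = 8.0      # age at half saturation
    sba_noise_sd: float = 0.25       # log-normal sd of site deviation
    sba_range: tuple[float, float] = (0.5, 29.5)  # site-selection bounds, m^2/ha
    light_decay_k: float = 0.086     # light% = 100 exp(-k SBA); ~7.6% at SBA 30
    spatial_extent_m: float = 4000.0
    spatial_kernel: bool = False     # short-range colonization clustering
    spatial_range_m: float = 150.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_sites < 2:
            raise ValueError("need at least 2 sites")


def draw_species_pool(pool: SpeciesPoolParams, rng: np.random.Generator) -> pd.DataFrame:
    n = pool.n_species
    pioneer = rng.random(n) < pool.pioneer_fraction
    rate = rng.lognormal(pool.colonization_log_mean, pool.colonization_log_sd, n)
    rate[pioneer] *= pool.pioneer_rate_multiplier
    tol = np.where(pioneer, rng.beta(1.0, 14.0, n), rng.beta(2.5, 2.0, n))
    # pioneer flag promises below-median tolerance; enforce by capping
    med = np.median(tol)
    tol[pioneer] = np.minimum(tol[pioneer], med * 0.8)
    longevity = np.where(pioneer, rng.lognormal(np.log(12.0), 0.3, n),
                         rng.lognormal(np.log(60.0), 0.5, n))
    growth = np.where(pioneer, rng.lognormal(np.log(2.2), 0.3, n),
                      rng.lognormal(np.log(0.8), 0.4, n))
    lf_names = list(pool.life_form_probs)
    lf_p = np.array([pool.life_form_probs[k] for k in lf_names], dtype=float)
    lf_p = lf_p / lf_p.sum()
    life_form = rng.choice(lf_names, size=n, p=lf_p)
    dbh_class = np.empty(n, dtype=object)
    probs = {
        "pioneer": [0.10, 0.45, 0.35, 0.08, 0.02, 0.00],
        "tree": [0.05, 0.15, 0.20, 0.25, 0.22, 0.13],
        "shrub": [0.55, 0.40, 0.05, 0.00, 0.00, 0.00],
        "palm": [0.05, 0.25, 0.40, 0.30, 0.00, 0.00],
        "liana": [0.35, 0.40, 0.25, 0.00, 0.00, 0.00],
    }
    for i in range(n):
        key = "pioneer" if (pioneer[i] and life_form[i] in ("tree", "shrub", "palm")) \
            else life_form[i]
        dbh_class[i] = rng.choice(DBHMAX_CLASSES, p=probs[key])
    codes = [f"SP{i + 1:04d}" for i in range(n)]
    return pd.DataFrame({
        "species_code": codes, "life_form": life_form, "pioneer": pioneer,
        "colonization_rate": rate, "shade_tolerance": tol,
        "longevity_y": longevity, "growth_cm_y": growth,
        "dbhmax_class": dbh_class,
        "dbhmax_mid_cm": [DBHMAX_MIDS[c] for c in dbh_class],
    }).set_index("species_code", drop=False)


def _sba_at(t: np.ndarray | float, factor: float, lp: LandscapeParams) -> np.ndarray:
    return lp.sba_max * np.asarray(t, dtype=float) / (np.asarray(t) + lp.sba_half_sat_y) * factor


def _light_fraction(sba: np.ndarray | float, lp: LandscapeParams) -> np.ndarray:
    return np.exp(-lp.light_decay_k * np.asarray(sba, dtype=float))


def _draw_sites(lp: LandscapeParams, rng: np.random.Generator) -> pd.DataFrame:
    per_class = lp.n_sites // len(lp.age_intervals)
    rem = lp.n_sites - per_class * len(lp.age_intervals)
    ages = []
    for j, (lo, hi) in enumerate(lp.age_intervals):
        k = per_class + (1 if j < rem else 0)
        ages.append(rng.integers(lo, hi + 1, size=k))
    age = np.concatenate(ages)
    sba_factor = rng.lognormal(0.0, lp.sba_noise_sd, lp.n_sites)
    # sites are drawn from a landscape whose study design spans ~1-30 m^2/ha
    sba = np.clip(_sba_at(age, sba_factor, lp), *lp.sba_range)
    xy = rng.uniform(0, lp.spatial_extent_m, size=(lp.n_sites, 2))
    sites = pd.DataFrame({
        "site_id": [f"S{i + 1:03d}" for i in range(lp.n_sites)],
        "age_y": age.astype(int), "sba_m2ha": sba,
        "x_m": xy[:, 0], "y_m": xy[:, 1],
        "light_pct": 100.0 * _light_fraction(sba, lp),
        "_sba_factor": sba_factor,
    }).set_index("site_id", drop=False)
    return sites


def generate_metacommunity(pool: SpeciesPoolParams | None = None,
                           landscape: LandscapeParams | None = None,
                           seed: int | None = None,
                           traits: pd.DataFrame | None = None,
                           ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate a chronosequence inventory.

    Returns ``(stems, sites, traits)``: a long-format stem table, site
    metadata, and a species-trait table, in exactly the formats the loaders
    read.  ``seed`` overrides ``landscape.seed``; the full output is a
    deterministic function of the seed and parameters.  A pre-built trait
    table (as produced by :func:`draw_species_pool`) can be supplied to
    pin species properties across scenarios.
    """
    pool = pool or SpeciesPoolParams()
    landscape = landscape or LandscapeParams()
    if seed is not None:
        landscape = replace(landscape, seed=seed)
    ss = np.random.SeedSequence(landscape.seed)
    rng_sites, rng_pool, rng_stems, rng_seedl = (
        np.random.default_rng(s) for s in ss.spawn(4))

    if traits is not None:
        traits = traits.copy()
        if "species_code" not in traits.index.names or traits.index.name != "species_code":
            traits = traits.set_index(traits["species_code"].astype(str), drop=False)
        pool = replace(pool, n_species=len(traits))
    else:
        traits = draw_species_pool(pool, rng_pool)
    if float(traits["colonization_rate"].sum()) <= 0:
        raise ValueError("degenerate species pool: all colonization rates are zero")
    sites = _draw_sites(landscape, rng_sites)

    rate = traits["colonization_rate"].to_numpy()
    if landscape.spatial_kernel:
        src = rng_pool.uniform(0, landscape.spatial_extent_m, size=(pool.n_species, 2))

    tol = traits["shade_tolerance"].to_numpy()
    longevity = traits["longevity_y"].to_numpy()
    growth = traits["growth_cm_y"].to_numpy()
    dmax = traits["dbhmax_mid_cm"].to_numpy()
    life = traits["life_form"].to_numpy()
    codes = traits["species_code"].to_numpy()
    n_sp = pool.n_species

    rows: list[dict] = []
    for site_id, srow in sites.iterrows():
        T = float(srow["age_y"])
        site_rate = rate
        if landscape.spatial_kernel:
            d2src = np.hypot(src[:, 0] - srow["x_m"], src[:, 1] - srow["y_m"])
            w = np.exp(-d2src / landscape.spatial_range_m)
            # rescale so the landscape-average rate is unchanged
            site_rate = rate * w * n_sp / max(w.sum(), 1e-12)
        n_events = rng_stems.poisson(site_rate * T)
        sp_idx = np.repeat(np.arange(n_sp), n_events)
        m = sp_idx.size
        if m:
            t_arr = rng_stems.uniform(0.0, T, size=m)
            sba_t = _sba_at(t_arr, float(srow["_sba_factor"]), landscape)
            lfrac = _light_fraction(sba_t, landscape)
            p_est = tol[sp_idx] + (1.0 - tol[sp_idx]) * lfrac ** 2
            established = rng_stems.random(m) < p_est
            residence = T - t_arr
            surv = rng_stems.random(m) < np.exp(-residence / longevity[sp_idx])
            alive = established & surv
            sp_a = sp_idx[alive]
            res_a = residence[alive]
            size_noise = rng_stems.lognormal(0.0, 0.25, size=sp_a.size)
            diam = np.round(np.minimum(growth[sp_a] * res_a * size_noise,
                                       0.95 * dmax[sp_a]), 2)
            plot = np.where(rng_stems.random(sp_a.size) < 0.5, "upper", "lower")
            is_liana = life[sp_a] == "liana"
            for j in range(sp_a.size):
                d = float(diam[j])
                if is_liana[j]:
                    if d < 1.0:
                        continue
                    stratum = "liana"
                elif d >= 5.0:
                    stratum = "tree"
                elif d >= 1.0:
                    stratum = "sapling"
                    # saplings censused in half the plot
                    if rng_stems.random() >= 0.5:
                        continue
                else:
                    continue
                rows.append({"site_id": site_id, "plot_id": plot[j],
                             "species_code": codes[sp_a[j]], "stratum": stratum,
                             "life_form": life[sp_a[j]], "diameter_cm": d})
        # seedlings: recent (last-2-y) establishments scaled to the 20 m^2
        # subplot area through the seed-rain multiplier
        sba_now = float(srow["sba_m2ha"])
        l_now = float(_light_fraction(sba_now, landscape))
        p_now = tol + (1.0 - tol) * l_now ** 2
        lam = site_rate * 2.0 * p_now * pool.seedling_rain_factor \
            * (PLOT_AREA_M2["seedling"] / PLOT_AREA_M2["tree"])
        for plot_id in ("upper", "lower"):
            n_seedl = rng_seedl.poisson(lam)
            for i in np.nonzero(n_seedl)[0]:
                for _ in range(int(n_seedl[i])):
                    rows.append({"site_id": site_id, "plot_id": plot_id,
                                 "species_code": codes[i], "stratum": "seedling",
                                 "life_form": life[i], "diameter_cm": np.nan})

    stems = pd.DataFrame(rows, columns=["site_id", "plot_id", "species_code",
                                        "stratum", "life_form", "diameter_cm"])
    sites = sites.drop(columns=["_sba_factor"])
    return stems, sites, traits.drop(columns=["species_code"]).reset_index()


def generate_null(landscape: LandscapeParams | None = None, n_species: int = 100,
                  mean_abundance: float = 2.0, seed: int | None = None,
                  ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Structureless null data: counts i.i.d. across plots and species.

    Species means vary log-normally (so rank-abundance looks plausible) but
    carry no age, basal-area, or spatial signal whatsoever.
    """
    landscape = landscape or LandscapeParams()
    if seed is not None:
        landscape = replace(landscape, seed=seed)
    ss = np.random.SeedSequence(landscape.seed)
    rng_sites, rng_counts = (np.random.default_rng(s) for s in ss.spawn(2))
    if n_species < 1 or mean_abundance <= 0:
        raise ValueError("need n_species >= 1 and mean_abundance > 0")

    sites = _draw_sites(landscape, rng_sites).drop(columns=["_sba_factor"])
    mean_i = rng_counts.lognormal(0.0, 1.0, n_species)
    mean_i *= mean_abundance / mean_i.mean()
    codes = [f"SP{i + 1:04d}" for i in range(n_species)]
    rows = []
    for site_id in sites.index:
        for plot_id in ("upper", "lower"):
            counts = rng_counts.poisson(mean_i)
            for i in np.nonzero(counts)[0]:
                diam = np.round(rng_counts.uniform(1.0, 12.0, size=int(counts[i])), 2)
                for d in diam:
                    rows.append({"site_id": site_id, "plot_id": plot_id,
                                 "species_code": codes[i],
                                 "stratum": "tree" if d >= 5.0 else "sapling",
                                 "life_form": "tree", "diameter_cm": float(d)})
    stems = pd.DataFrame(rows, columns=["site_id", "plot_id", "species_code",
                                        "stratum", "life_form", "diameter_cm"])
    traits = pd.DataFrame({
        "species_code": codes, "life_form": "tree", "pioneer": False,
        "colonization_rate": mean_i, "shade_tolerance": 0.5,
        "longevity_y": 50.0, "growth_cm_y": 1.0,
        "dbhmax_class": "20-40", "dbhmax_mid_cm": 30.0})
    return stems, sites, traits


#: ready-made scenarios for the CLI and the test-bench
SCENARIOS = {
    "paper-like": lambda seed=None: generate_metacommunity(seed=seed),
    "paper-like-spatial": lambda seed=None: generate_metacommunity(
        landscape=LandscapeParams(spatial_kernel=True), seed=seed),
    "null": lambda seed=None: generate_null(seed=seed),
}
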