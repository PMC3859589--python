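"""End-to-end chronosequence analysis driven by one YAML-able config.

Stage order is fixed and deterministic: simulate (or load) -> classify ->
diversity -> similarity/divergence -> ordination + regressions -> spatial
-> landscape frequencies -> conservation.  Every stochastic stage draws its
seed from the config; outputs are write-once CSV/JSON files listed, with
content hashes, in ``manifest.json``, so a rerun with the same config and
seeds reproduces the hashes of all deterministic outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import (conservation, data, diversity, frequency, ordination,
               similarity, simulate, spatial, succession)

log = logging.getLogger("metasucc")

DEFAULT_CONFIG: dict[str, Any] = {
    "scenario": "paper-like",      # or null / paper-like-spatial; ignored if paths given
    "paths": None,                 # {"stems":..., "sites":..., "traits":...}
    "seeds": {"simulate": 1, "diversity": 2, "ordination": 3, "spatial": 4},
    "sba_edges": list(data.DEFAULT_SBA_EDGES),
    "age_intervals": [list(t) for t in data.DEFAULT_AGE_INTERVALS],
    "gamma_subsample": 12,
    "gamma_iterations": 200,
    "rarefaction_depth_site": 12,
    "rarefaction_depth_class": 1400,
    "hill_orders": [0, 1, 2],
    "dissimilarity_index": "ruzicka",
    "nmds_k": 2,
    "nmds_starts": 10,
    "permutations": 999,
    "rst_thresholds": [0.10, 0.30],
    "strata": ["seedling", "sapling", "tree", "liana"],
}


class ConfigError(ValueError):
    pass


def load_config(path: str | Path | None = None,
                overrides: dict | None = None) -> dict[str, Any]:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(user) - set(cfg)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg.update(user)
    if overrides:
        cfg.update(overrides)
    missing = [k for k in ("simulate", "diversity", "ordination", "spatial")
               if cfg["seeds"].get(k) is None]
    if cfg["paths"] is None and missing:
        raise ConfigError(f"stochastic stage(s) without a seed: {missing}")
    return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class _Bundle:
    """Write-once output directory with a hashed manifest."""

    def __init__(self, outdir: str | Path):
        self.outdir = Path(outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.files: dict[str, str] = {}

    def path(self, name: str) -> Path:
        p = self.outdir / name
        if name in self.files:
            raise RuntimeError(f"output {name} written twice")
        return p

    def register(self, name: str) -> None:
        self.files[name] = _sha256(self.outdir / name)

    def write_df(self, name: str, df: pd.DataFrame, **kw) -> None:
        df.to_csv(self.path(name), index=kw.pop("index", False), **kw)
        self.register(name)

    def write_json(self, name: str, obj) -> None:
        self.path(name).write_text(json.dumps(obj, indent=1, sort_keys=True,
                                              default=_jsonable))
        self.register(name)

    def finish(self) -> Path:
        manifest = self.outdir / "manifest.json"
        manifest.write_text(json.dumps(self.files, indent=1, sort_keys=True))
        return manifest


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if dataclasses.is_dataclass(o):
        return dataclasses.asdict(o)
    raise TypeError(f"not JSON-serializable: {type(o)}")


def run_pipeline(config: dict[str, Any], outdir: str | Path) -> Path:
    """Run every stage; returns the path of the manifest file."""
    cfg = dict(config)
    bundle = _Bundle(outdir)
    bundle.write_json("config.json", cfg)
    seeds = cfg["seeds"]

    # -- inputs ------------------------------------------------------------
    if cfg.get("paths"):
        stems, _rep = data.load_stem_table(cfg["paths"]["stems"])
        sites = data.load_site_table(cfg["paths"]["sites"])
        traits = conservation.load_trait_table(cfg["paths"]["traits"])
        log.info("loaded %d stems (%s)", len(stems), _rep)
    else:
        gen = simulate.SCENARIOS[cfg["scenario"]]
        stems, sites, traits = gen(seed=seeds["simulate"])
        log.info("simulated scenario %r: %d stems", cfg["scenario"], len(stems))
    data.write_stem_table(stems, bundle.path("stems.csv"))
    bundle.register("stems.csv")
    bundle.write_df("sites.csv", sites.reset_index(drop=True))
    bundle.write_df("traits.csv", traits)

    sba_scheme = data.assign_classes(sites, "sba", cfg["sba_edges"])
    age_scheme = data.assign_classes(sites, "age", cfg["age_intervals"])
    bundle.write_json("classes.json", {
        "sba": sba_scheme.membership, "age": age_scheme.membership,
        "sba_sizes": sba_scheme.class_sizes(), "age_sizes": age_scheme.class_sizes()})

    site_ids = list(sites.index.astype(str))
    mats = {
        "seedling": data.build_abundance_matrix(stems, "seedling", "site",
                                                all_units=site_ids),
        "sapling": data.build_abundance_matrix(stems, "sapling", "site",
                                               all_units=site_ids),
        "tree": data.build_abundance_matrix(stems, "tree", "site",
                                            all_units=site_ids),
        "liana": data.build_abundance_matrix(stems, "liana", "site",
                                             all_units=site_ids),
    }
    mats = {k: v for k, v in mats.items() if k in cfg["strata"]}

    # -- diversity ---------------------------------------------------------
    rows = []
    for stratum, mat in mats.items():
        for unit in mat.units:
            counts = mat.df.loc[unit].to_numpy()
            if counts.sum() == 0:
                continue
            for q in cfg["hill_orders"]:
                rows.append({"stratum": stratum, "unit": unit, "q": q,
                             "value": diversity.hill_number(counts, q)})
    bundle.write_df("alpha_diversity.csv", pd.DataFrame(rows))

    grows = []
    rng = np.random.default_rng(seeds["diversity"])
    for stratum, mat in mats.items():
        for scheme in (sba_scheme, age_scheme):
            for label in scheme.labels:
                units = [u for u in scheme.sites_in(label) if u in mat.df.index]
                sub = mat.subset_units(units)
                k = min(cfg["gamma_subsample"], len(units))
                for q in cfg["hill_orders"]:
                    g = diversity.resampled_gamma(
                        sub, subsample_size=k, iterations=cfg["gamma_iterations"],
                        q=q, seed=int(rng.integers(0, 2 ** 31 - 1)))
                    grows.append({"stratum": stratum, "scheme": scheme.kind,
                                  "class": label, "q": q, "mean": g.mean,
                                  "ci_low": g.ci_low, "ci_high": g.ci_high})
    bundle.write_df("gamma_diversity.csv", pd.DataFrame(grows))

    rrows = []
    d_site = cfg["rarefaction_depth_site"]
    d_class = cfg["rarefaction_depth_class"]
    for stratum, mat in mats.items():
        for unit in mat.units:
            counts = mat.df.loc[unit].to_numpy()
            if counts.sum() >= d_site:
                rrows.append({"stratum": stratum, "level": "site",
                              "unit": unit, "depth": d_site,
                              "value": diversity.rarefied_richness(counts, d_site)})
        for label in sba_scheme.labels:
            pooled = mat.pooled([u for u in sba_scheme.sites_in(label)
                                 if u in mat.df.index])
            if pooled.sum() >= d_class:
                rrows.append({"stratum": stratum, "level": "class",
                              "unit": label, "depth": d_class,
                              "value": diversity.rarefied_richness(pooled, d_class)})
    bundle.write_df("rarefied_richness.csv", pd.DataFrame(rrows))

    # -- similarity / seedling divergence ------------------------------------
    dmats = {s: similarity.pairwise_dissimilarity(m, cfg["dissimilarity_index"])
             for s, m in mats.items() if len(m.units) >= 4}
    sba1 = sba_scheme.labels[0]
    stems1 = data.build_abundance_matrix(
        stems, ("sapling", "tree", "liana"), "site", min_diameter_cm=1.0)
    ref_units = [u for u in sba_scheme.sites_in(sba1) if u in stems1.df.index]
    divergence = None
    if "seedling" in mats and ref_units:
        seedling_by_class = {}
        for label in sba_scheme.labels:
            units = [u for u in sba_scheme.sites_in(label)
                     if u in mats["seedling"].df.index]
            if units:
                seedling_by_class[label] = mats["seedling"].subset_units(units)
        divergence = similarity.seedling_divergence(
            seedling_by_class, stems1.subset_units(ref_units), traits)
        bundle.write_df("seedling_divergence.csv", divergence)

    # -- ordination + succession regressions ---------------------------------
    fit_rows = []
    ord_scores = []
    for stratum, dm in dmats.items():
        res = ordination.nmds(dm, k=cfg["nmds_k"], n_starts=cfg["nmds_starts"],
                              seed=seeds["ordination"])
        ordination.orient_axis(res, sites["age_y"])
        sc = res.scores.copy()
        sc.insert(0, "stratum", stratum)
        ord_scores.append(sc.reset_index(names="unit"))
        for predictor in ("age_y", "sba_m2ha"):
            sel = ordination.axis_regression(res, sites, predictor)
            fit_rows.append({"response": f"composition_{stratum}",
                             "predictor": predictor, "model": sel.code,
                             "r2": sel.r2, "significant": sel.is_significant})
    if ord_scores:
        bundle.write_df("nmds_scores.csv", pd.concat(ord_scores, ignore_index=True))

    for stratum, mat in mats.items():
        for q in cfg["hill_orders"]:
            vals, idx = [], []
            for unit in mat.units:
                c = mat.df.loc[unit].to_numpy()
                if c.sum() > 0:
                    idx.append(unit)
                    vals.append(diversity.hill_number(c, q))
            y = np.asarray(vals)
            for predictor in ("age_y", "sba_m2ha"):
                x = sites[predictor].reindex(idx).to_numpy(dtype=float)
                sel = succession.select_model(x, y)
                fit_rows.append({"response": f"{q}D_{stratum}",
                                 "predictor": predictor, "model": sel.code,
                                 "r2": sel.r2, "significant": sel.is_significant})
    bundle.write_df("succession_fits.csv", pd.DataFrame(fit_rows))

    # -- spatial -------------------------------------------------------------
    sp_rows = []
    rng_sp = np.random.default_rng(seeds["spatial"])
    coords_all = sites[["x_m", "y_m"]]
    for stratum, dm in dmats.items():
        for scheme in (sba_scheme, age_scheme):
            groups = [scheme.membership[u] for u in dm.units]
            pv = spatial.permanova(dm, groups, permutations=cfg["permutations"],
                                   seed=int(rng_sp.integers(0, 2 ** 31 - 1)))
            sp_rows.append({"test": "permanova", "stratum": stratum,
                            "scheme": scheme.kind, "class": "all",
                            "statistic": pv.pseudo_f, "r2": pv.r2,
                            "p": pv.test.p_value})
            first = scheme.labels[0]
            units = [u for u in scheme.sites_in(first) if u in dm.units]
            if len(units) >= 4:
                idx = [dm.units.index(u) for u in units]
                sub = similarity.DissimilarityMatrix(
                    units, dm.values[np.ix_(idx, idx)], dm.index_name)
                xy = coords_all.loc[units].to_numpy()
                geo = np.sqrt(((xy[:, None] - xy[None, :]) ** 2).sum(-1))
                mt = spatial.mantel(sub, geo, permutations=cfg["permutations"],
                                    seed=int(rng_sp.integers(0, 2 ** 31 - 1)))
                sp_rows.append({"test": "mantel", "stratum": stratum,
                                "scheme": scheme.kind, "class": first,
                                "statistic": mt.statistic, "r2": np.nan,
                                "p": mt.p_value})
    bundle.write_df("spatial_stats.csv", pd.DataFrame(sp_rows))

    # correlogram for the youngest age class of the pooled >= 1 cm stems
    young = [u for u in age_scheme.sites_in(age_scheme.labels[0])
             if u in stems1.df.index]
    if len(young) >= 5:
        dm_young = similarity.pairwise_dissimilarity(
            stems1.subset_units(young), cfg["dissimilarity_index"])
        corr = spatial.mantel_correlogram(
            dm_young, coords_all.loc[young].to_numpy(),
            permutations=cfg["permutations"],
            seed=int(rng_sp.integers(0, 2 ** 31 - 1)))
        bundle.write_df("mantel_correlogram.csv", corr)

    # -- landscape frequencies ------------------------------------------------
    plot_mat = data.build_abundance_matrix(stems, ("sapling", "tree", "liana"),
                                           "plot", min_diameter_cm=1.0)
    freq = frequency.occurrence_frequencies(plot_mat, sba_scheme)
    bundle.write_df("frequencies.csv", freq)
    turn_rows, slope_rows = [], []
    labs = sba_scheme.labels
    for a in labs:
        for b in labs:
            if a < b:
                ab, ba = frequency.class_turnover(freq, a, b)
                turn_rows.append({"class_a": a, "class_b": b,
                                  "pct_a_absent_b": ab, "pct_b_absent_a": ba})
        _, slope = frequency.rank_frequency_curve(freq, a)
        slope_rows.append({"class": a, "slope": slope})
    bundle.write_df("turnover.csv", pd.DataFrame(turn_rows))
    bundle.write_df("rank_frequency_slopes.csv", pd.DataFrame(slope_rows))

    # -- conservation ----------------------------------------------------------
    summaries = conservation.effective_gamma_summary(
        stems, traits, age_scheme, thresholds=tuple(cfg["rst_thresholds"]))
    bundle.write_df("conservation_summary.csv",
                    conservation.summary_frame(summaries))
    breakdown = []
    for label, s in summaries.items():
        d = s.per_dbhmax_species.copy()
        d.insert(0, "age_class", label)
        breakdown.append(d)
    bundle.write_df("conservation_breakdown.csv",
                    pd.concat(breakdown, ignore_index=True))

    summary = {
        "n_stems": int(len(stems)), "n_sites": int(len(sites)),
        "n_species_observed": int(stems["species_code"].nunique()),
        "config": cfg,
    }
    bundle.write_json("summary.json", summary)
    return bundle.finish()
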