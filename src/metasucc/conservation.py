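"""Effective diversity above relative size thresholds (RST).

A fallow can only act as a *source* for a tree species if individuals reach
reproductive size before the patch is cleared.  Lacking species-level data
on reproductive onset, each species is assigned a maximum-DBH class (1-5,
5-10, 10-20, 20-40, 40-80, >80 cm) whose mid-value serves as a conservative
DBH_max estimate, and a relative size threshold — 10% (optimistic) or 30%
(supported by field estimates of relative size at reproductive onset) of
DBH_max — stands in for the size at maturity.  The "effective
gamma-diversity" of an age class is then the number of tree and shrub
species with at least one individual above the threshold (optionally in
more than one plot, discounting the rarest species); comparing it with the
total species count measures how strongly ephemeral secondary forests
under-sample the reproductive species pool.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data import ClassScheme

DBHMAX_CLASSES = ("1-5", "5-10", "10-20", "20-40", "40-80", ">80")
#: class mid-values (cm); the open top class has no mid and defaults to
#: 1.5x its lower bound
DBHMAX_EDGES = (1.0, 5.0, 10.0, 20.0, 40.0, 80.0)
DEFAULT_OPEN_CLASS_MID = 120.0


def dbhmax_mid(dbh_class: str, open_class_mid: float = DEFAULT_OPEN_CLASS_MID) -> float:
    if dbh_class == ">80":
        return float(open_class_mid)
    i = DBHMAX_CLASSES.index(dbh_class)
    return (DBHMAX_EDGES[i] + DBHMAX_EDGES[i + 1]) / 2.0


@dataclass(frozen=True)
class SpeciesTrait:
    species_code: str
    life_form: str
    dbhmax_class: str
    dbhmax_mid_cm: float


def assign_dbhmax_class(observed_max_cm: float | None = None,
                        expert_class: str | None = None,
                        open_class_mid: float = DEFAULT_OPEN_CLASS_MID,
                        ) -> tuple[str, float]:
    """Maximum-DBH class and mid-value for one species.

    An expert label always wins; otherwise the class is the lower-inclusive
    interval containing the observed maximum diameter.
    """
    if expert_class is not None:
        if expert_class not in DBHMAX_CLASSES:
            raise ValueError(f"unknown DBH_max class {expert_class!r}")
        return expert_class, dbhmax_mid(expert_class, open_class_mid)
    if observed_max_cm is None or (isinstance(observed_max_cm, float)
                                   and np.isnan(observed_max_cm)):
        raise ValueError("need observed maximum diameter or expert class")
    d = float(observed_max_cm)
    if d >= 80.0:
        return ">80", float(open_class_mid)
    k = int(np.searchsorted(DBHMAX_EDGES, d, side="right") - 1)
    k = max(k, 0)
    cls = DBHMAX_CLASSES[k]
    return cls, dbhmax_mid(cls, open_class_mid)


def load_trait_table(path, dialect: Mapping[str, str] | None = None,
                     open_class_mid: float = DEFAULT_OPEN_CLASS_MID) -> pd.DataFrame:
    """Read a species-trait CSV (species_code, life_form, dbhmax_class or
    observed_max_cm) and attach class mid-values.  Species with neither a
    class nor an observed maximum are flagged unclassified."""
    df = pd.read_csv(path)
    if dialect:
        df = df.rename(columns={v: k for k, v in dialect.items()})
    for col in ("species_code", "life_form"):
        if col not in df.columns:
            raise ValueError(f"trait table missing column {col!r}")
    classes, mids = [], []
    for _, row in df.iterrows():
        expert = row.get("dbhmax_class")
        obs = row.get("observed_max_cm")
        try:
            cls, mid = assign_dbhmax_class(
                None if pd.isna(obs) else float(obs),
                None if (expert is None or pd.isna(expert)) else str(expert),
                open_class_mid)
        except ValueError:
            cls, mid = None, np.nan
        classes.append(cls)
        mids.append(mid)
    df["dbhmax_class"] = classes
    df["dbhmax_mid_cm"] = mids
    return df


@dataclass
class EffectiveDiversitySummary:
    """Species counts for one age class under the RST filters."""

    age_class: str
    n_species_total: int
    n_species_above: dict[float, int]            # threshold -> count
    n_species_above_multiplot: dict[float, int]  # threshold -> count (> 1 plot)
    per_dbhmax_species: pd.DataFrame = field(repr=False, default=None)
    per_dbhmax_stems: pd.DataFrame = field(repr=False, default=None)

    def reduction_pct(self, threshold: float) -> int:
        """Integer percentage by which the RST filter lowers the species count."""
        above = self.n_species_above[threshold]
        return int(round(100.0 * (1.0 - above / self.n_species_total)))


def _tree_shrub_stems(stems: pd.DataFrame, traits: pd.DataFrame) -> pd.DataFrame:
    traits = traits.set_index(traits["species_code"].astype(str))
    keep_sp = traits.index[traits["life_form"].isin(["tree", "shrub"])]
    sub = stems.loc[stems["species_code"].astype(str).isin(keep_sp)].copy()
    sub["dbhmax_mid_cm"] = sub["species_code"].astype(str).map(traits["dbhmax_mid_cm"])
    sub["dbhmax_class"] = sub["species_code"].astype(str).map(traits["dbhmax_class"])
    sub = sub.loc[sub["dbhmax_class"].notna()]
    return sub


def species_above_rst(stems: pd.DataFrame, traits: pd.DataFrame,
                      threshold: float, scheme: ClassScheme,
                      min_plots: int = 1) -> dict[str, set[str]]:
    """Species with a stem at or above ``threshold x DBH_max`` per age class.

    Only trees and shrubs count (lianas and palms excluded); a species
    qualifies in a class when it has a qualifying individual in at least
    ``min_plots`` distinct plots of that class (``min_plots=2`` is the
    rarity-discounted variant).  Seedlings carry no diameter and never
    qualify.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    sub = _tree_shrub_stems(stems, traits)
    sub = sub.loc[sub["diameter_cm"].notna()]
    qual = sub.loc[sub["diameter_cm"] >= threshold * sub["dbhmax_mid_cm"]].copy()
    qual["age_class"] = qual["site_id"].astype(str).map(scheme.membership)
    qual["plot"] = qual["site_id"].astype(str) + ":" + qual["plot_id"].astype(str)
    out: dict[str, set[str]] = {}
    for label in scheme.labels:
        cls = qual.loc[qual["age_class"] == label]
        nplots = cls.groupby("species_code")["plot"].nunique()
        out[label] = set(nplots.index[nplots >= min_plots].astype(str))
    return out


def effective_gamma_summary(stems: pd.DataFrame, traits: pd.DataFrame,
                            scheme: ClassScheme,
                            thresholds: Sequence[float] = (0.10, 0.30),
                            include_seedlings: bool = True,
                            ) -> dict[str, EffectiveDiversitySummary]:
    """Total vs effective species counts per age class, with DBH_max breakdown.

    Totals count every tree/shrub species present in the class (seedling-only
    occurrences included unless ``include_seedlings=False``); the RST columns
    apply :func:`species_above_rst`, and the multiplot variant additionally
    requires qualifying stems in more than one plot.
    """
    sub = _tree_shrub_stems(stems, traits)
    if not include_seedlings:
        sub = sub.loc[sub["stratum"] != "seedling"]
    sub = sub.copy()
    sub["age_class"] = sub["site_id"].astype(str).map(scheme.membership)
    above = {p: species_above_rst(stems, traits, p, scheme) for p in thresholds}
    above2 = {p: species_above_rst(stems, traits, p, scheme, min_plots=2)
              for p in thresholds}
    out: dict[str, EffectiveDiversitySummary] = {}
    for label in scheme.labels:
        cls = sub.loc[sub["age_class"] == label]
        if cls.empty:
            raise ValueError(f"age class {label!r} has no stems")
        total_sp = set(cls["species_code"].astype(str))
        sp_rows, stem_rows = [], []
        measured = cls.loc[cls["diameter_cm"].notna()]
        for dcls in DBHMAX_CLASSES:
            in_cls = cls.loc[cls["dbhmax_class"] == dcls]
            m_cls = measured.loc[measured["dbhmax_class"] == dcls]
            row_sp = {"dbhmax_class": dcls,
                      "n_species": in_cls["species_code"].nunique()}
            row_st = {"dbhmax_class": dcls, "n_stems": len(m_cls)}
            for p in thresholds:
                qualset = above[p][label]
                row_sp[f"n_species_rst{int(p * 100)}"] = len(
                    set(in_cls["species_code"].astype(str)) & qualset)
                row_st[f"n_stems_rst{int(p * 100)}"] = int(
                    (m_cls["diameter_cm"] >= p * m_cls["dbhmax_mid_cm"]).sum())
            sp_rows.append(row_sp)
            stem_rows.append(row_st)
        out[label] = EffectiveDiversitySummary(
            age_class=label,
            n_species_total=len(total_sp),
            n_species_above={p: len(above[p][label] & total_sp) for p in thresholds},
            n_species_above_multiplot={p: len(above2[p][label] & total_sp)
                                       for p in thresholds},
            per_dbhmax_species=pd.DataFrame(sp_rows),
            per_dbhmax_stems=pd.DataFrame(stem_rows),
        )
    return out


def summary_frame(summaries: Mapping[str, EffectiveDiversitySummary]) -> pd.DataFrame:
    rows = []
    for label, s in summaries.items():
        row = {"age_class": label, "n_species_total": s.n_species_total}
        for p, v in s.n_species_above.items():
            row[f"n_species_rst{int(p * 100)}"] = v
            row[f"reduction_rst{int(p * 100)}_pct"] = s.reduction_pct(p)
        for p, v in s.n_species_above_multiplot.items():
            row[f"n_species_rst{int(p * 100)}_multiplot"] = v
        rows.append(row)
    return pd.DataFrame(rows)
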