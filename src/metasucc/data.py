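"""Data model and I/O for chronosequence stem inventories.

The sampling design mirrors a replicated secondary-forest chronosequence:
each *site* is one slope carrying two 20 x 50 m plots (upper / lower), and
four strata are censused with different effort per plot:

======== ============================== ==================
stratum  definition                     sampled area (m^2)
======== ============================== ==================
seedling 20-80 cm tall, no DBH          20   (20 x 1 m^2)
sapling  1 <= DBH < 5 cm, non-climbing  500  (half plot)
tree     DBH >= 5 cm, non-climbing      1000 (full plot)
liana    climbing, diameter >= 1 cm     1000 (full plot)
======== ============================== ==================

Long-format stem tables (one row per individual) are the on-disk interchange
format; analyses consume unit x species :class:`AbundanceMatrix` objects.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

STRATA = ("seedling", "sapling", "tree", "liana")
LIFE_FORMS = ("tree", "shrub", "palm", "liana", "other")

#: sampled area per plot for each stratum, m^2
PLOT_AREA_M2 = {"seedling": 20.0, "sapling": 500.0, "tree": 1000.0, "liana": 1000.0}

STEM_COLUMNS = ("site_id", "plot_id", "species_code", "stratum", "life_form", "diameter_cm")
SITE_COLUMNS = ("site_id", "age_y", "sba_m2ha", "x_m", "y_m")


class ConfigurationError(ValueError):
    """A required column or configuration entry is missing."""


@dataclass(frozen=True)
class StemRecord:
    """One censused individual."""

    site_id: str
    plot_id: str
    species_code: str
    stratum: str
    life_form: str
    diameter_cm: float | None = None

    def validation_errors(self) -> list[str]:
        errs: list[str] = []
        if self.stratum not in STRATA:
            errs.append(f"unknown stratum {self.stratum!r}")
            return errs
        if self.life_form not in LIFE_FORMS:
            errs.append(f"unknown life form {self.life_form!r}")
        d = self.diameter_cm
        has_d = d is not None and not (isinstance(d, float) and np.isnan(d))
        if self.stratum == "seedling":
            if has_d and d >= 1.0:
                errs.append(f"seedling with diameter {d} cm (must be absent or < 1)")
        elif not has_d:
            errs.append(f"{self.stratum} stem without diameter")
        elif self.stratum == "sapling" and not (1.0 <= d < 5.0):
            errs.append(f"sapling diameter {d} cm outside [1, 5)")
        elif self.stratum == "tree" and d < 5.0:
            errs.append(f"tree diameter {d} cm below 5")
        elif self.stratum == "liana" and d < 1.0:
            errs.append(f"liana diameter {d} cm below 1")
        # climbing life form <-> liana stratum (seedlings may be of any life form)
        if self.stratum == "liana" and self.life_form != "liana":
            errs.append("liana stratum requires climbing (liana) life form")
        if self.life_form == "liana" and self.stratum in ("sapling", "tree"):
            errs.append("climbing life form cannot be in sapling/tree stratum")
        return errs


@dataclass
class ValidationReport:
    n_total: int
    n_valid: int
    rejected: list[tuple[int, str]] = field(default_factory=list)

    @property
    def n_rejected(self) -> int:
        return len(self.rejected)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.n_valid}/{self.n_total} rows valid, {self.n_rejected} rejected"


def _apply_dialect(df: pd.DataFrame, dialect: Mapping[str, str] | None,
                   required: Sequence[str]) -> pd.DataFrame:
    if dialect:
        df = df.rename(columns={v: k for k, v in dialect.items()})
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ConfigurationError(f"missing required column(s): {missing}")
    return df


def load_stem_table(path: str | Path, dialect: Mapping[str, str] | None = None,
                    drop_unknown_species: bool = False,
                    unknown_codes: Sequence[str] = ("UNKNOWN", "unknown", "?"),
                    ) -> tuple[pd.DataFrame, ValidationReport]:
    """Read a delimited stem table, validating every row.

    Returns the valid rows as a DataFrame with canonical columns and a
    :class:`ValidationReport` listing rejected rows (index, reason).
    """
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    raw = pd.read_csv(path, sep=sep, dtype={"site_id": str, "plot_id": str})
    required = [c for c in STEM_COLUMNS if c != "diameter_cm"]
    raw = _apply_dialect(raw, dialect, required)
    if "diameter_cm" not in raw.columns:
        raw["diameter_cm"] = np.nan
    return validate_stems(raw, drop_unknown_species=drop_unknown_species,
                          unknown_codes=unknown_codes)


def validate_stems(df: pd.DataFrame, drop_unknown_species: bool = False,
                   unknown_codes: Sequence[str] = ("UNKNOWN", "unknown", "?"),
                   ) -> tuple[pd.DataFrame, ValidationReport]:
    df = df.loc[:, list(STEM_COLUMNS)].copy()
    df["site_id"] = df["site_id"].astype(str)
    df["plot_id"] = df["plot_id"].astype(str)
    rejected: list[tuple[int, str]] = []
    keep = np.ones(len(df), dtype=bool)
    for pos, (idx, row) in enumerate(df.iterrows()):
        rec = StemRecord(row.site_id, row.plot_id, str(row.species_code),
                         str(row.stratum), str(row.life_form),
                         None if pd.isna(row.diameter_cm) else float(row.diameter_cm))
        errs = rec.validation_errors()
        if errs:
            keep[pos] = False
            rejected.append((int(idx) if isinstance(idx, (int, np.integer)) else pos,
                             "; ".join(errs)))
    if drop_unknown_species:
        unknown = df["species_code"].astype(str).isin(unknown_codes)
        keep &= ~unknown.to_numpy()
    valid = df.loc[keep].reset_index(drop=True)
    return valid, ValidationReport(n_total=len(df), n_valid=len(valid), rejected=rejected)


def write_stem_table(df: pd.DataFrame, path: str | Path) -> None:
    df.loc[:, list(STEM_COLUMNS)].to_csv(path, index=False)


def load_site_table(path: str | Path, dialect: Mapping[str, str] | None = None) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, dtype={"site_id": str})
    df = _apply_dialect(df, dialect, SITE_COLUMNS)
    if (df["age_y"] <= 0).any():
        bad = df.loc[df["age_y"] <= 0, "site_id"].tolist()
        raise ValueError(f"non-positive age for site(s) {bad}")
    if (df["sba_m2ha"] < 0).any():
        raise ValueError("negative stand basal area")
    return df.set_index("site_id", drop=False)


# ---------------------------------------------------------------------------
# Site classification

@dataclass
class ClassScheme:
    """Partition of sites into ordered classes (by stand basal area or age)."""

    kind: str                      # "sba" or "age"
    boundaries: tuple              # interval edges / (lo, hi) pairs
    labels: tuple[str, ...]
    membership: dict[str, str]     # site_id -> label

    def sites_in(self, label: str) -> list[str]:
        return [s for s, lab in self.membership.items() if lab == label]

    def class_sizes(self) -> dict[str, int]:
        return {lab: len(self.sites_in(lab)) for lab in self.labels}


#: default SBA class edges (m^2/ha), lower-inclusive / upper-exclusive
DEFAULT_SBA_EDGES = (0.0, 11.0, 20.0, 30.0)
DEFAULT_SBA_LABELS = ("SBA-1", "SBA-2", "SBA-3")
#: default age classes (years), integer labels with both ends inclusive
DEFAULT_AGE_INTERVALS = ((2, 7), (8, 17), (18, 32))
DEFAULT_AGE_LABELS = ("2-7 y", "8-17 y", "18-32 y")


def assign_classes(sites: pd.DataFrame, kind: str,
                   boundaries: Sequence | None = None,
                   labels: Sequence[str] | None = None) -> ClassScheme:
    """Assign every site to exactly one SBA or age class.

    SBA classes use half-open intervals [lo, hi); age classes use closed
    integer intervals (a 7-year-old site belongs to "2-7 y").  A site whose
    value falls outside all intervals raises a ValueError naming it.
    """
    if kind == "sba":
        edges = tuple(boundaries) if boundaries is not None else DEFAULT_SBA_EDGES
        labs = tuple(labels) if labels is not None else tuple(
            f"SBA-{i + 1}" for i in range(len(edges) - 1))
        if list(edges) != sorted(set(edges)):
            raise ValueError("boundaries must be strictly increasing")
        values = sites["sba_m2ha"]
        membership = {}
        for site_id, v in values.items():
            k = np.searchsorted(edges, v, side="right") - 1
            if k < 0 or k >= len(labs):
                raise ValueError(f"site {site_id}: SBA {v} outside class boundaries {edges}")
            membership[str(site_id)] = labs[k]
        return ClassScheme("sba", edges, labs, membership)
    if kind == "age":
        ivals = tuple(tuple(b) for b in boundaries) if boundaries is not None \
            else DEFAULT_AGE_INTERVALS
        labs = tuple(labels) if labels is not None else tuple(
            f"{lo}-{hi} y" for lo, hi in ivals)
        if any(ivals[i][1] >= ivals[i + 1][0] for i in range(len(ivals) - 1)):
            raise ValueError("age intervals must be ordered and non-overlapping")
        membership = {}
        for site_id, v in sites["age_y"].items():
            for (lo, hi), lab in zip(ivals, labs):
                if lo <= v <= hi:
                    membership[str(site_id)] = lab
                    break
            else:
                raise ValueError(f"site {site_id}: age {v} outside all intervals {ivals}")
        return ClassScheme("age", ivals, labs, membership)
    raise ValueError(f"unknown class kind {kind!r}")


# ---------------------------------------------------------------------------
# Abundance matrices

@dataclass
class AbundanceMatrix:
    """Sampling-unit x species count matrix for one stratum (or pooled strata).

    ``df`` has one row per unit (site, or "site:plot") and one integer column
    per species; all-zero species columns are dropped at construction.
    """

    df: pd.DataFrame
    stratum: tuple[str, ...]
    unit_level: str                      # "site" or "plot"
    min_diameter_cm: float | None = None
    sampled_area_m2: dict[str, float] = field(default_factory=dict)
    unit_site: dict[str, str] = field(default_factory=dict)  # unit -> site_id

    @property
    def units(self) -> list[str]:
        return list(self.df.index)

    @property
    def species(self) -> list[str]:
        return list(self.df.columns)

    @property
    def counts(self) -> np.ndarray:
        return self.df.to_numpy()

    def pooled(self, units: Iterable[str] | None = None) -> np.ndarray:
        """Column sums over the given units (all units by default)."""
        sub = self.df if units is None else self.df.loc[list(units)]
        return sub.to_numpy().sum(axis=0)

    def subset_units(self, units: Sequence[str]) -> "AbundanceMatrix":
        return AbundanceMatrix(self.df.loc[list(units)].copy(), self.stratum,
                               self.unit_level, self.min_diameter_cm,
                               dict(self.sampled_area_m2),
                               {u: self.unit_site.get(u, u) for u in units})

    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        self.df.to_csv(path, index_label="unit")
        meta = {"stratum": list(self.stratum), "unit_level": self.unit_level,
                "min_diameter_cm": self.min_diameter_cm,
                "sampled_area_m2": self.sampled_area_m2,
                "unit_site": self.unit_site}
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def from_csv(cls, path: str | Path) -> "AbundanceMatrix":
        path = Path(path)
        df = pd.read_csv(path, index_col="unit")
        df.index = df.index.astype(str)
        sidecar = path.with_suffix(path.suffix + ".json")
        meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
        return cls(df, tuple(meta.get("stratum", ())), meta.get("unit_level", "site"),
                   meta.get("min_diameter_cm"), meta.get("sampled_area_m2", {}),
                   meta.get("unit_site", {}))


def plot_unit(site_id: str, plot_id: str) -> str:
    return f"{site_id}:{plot_id}"


def build_abundance_matrix(stems: pd.DataFrame, stratum: str | Sequence[str],
                           unit_level: str = "site",
                           min_diameter_cm: float | None = None,
                           all_units: Sequence[str] | None = None) -> AbundanceMatrix:
    """Cross-tabulate stems into a unit x species count matrix.

    ``stratum`` may be one stratum or a collection (e.g. all stems >= 1 cm is
    ``("sapling", "tree", "liana")`` with ``min_diameter_cm=1``).  Site-level
    matrices pool the two plots of each site.  ``all_units`` forces rows for
    units with no qualifying stems (so units are comparable across strata).
    """
    if unit_level not in ("site", "plot"):
        raise ValueError("unit_level must be 'site' or 'plot'")
    strata = (stratum,) if isinstance(stratum, str) else tuple(stratum)
    bad = set(strata) - set(STRATA)
    if bad:
        raise ValueError(f"unknown strata {sorted(bad)}")
    sel = stems["stratum"].isin(strata)
    if min_diameter_cm is not None:
        sel &= stems["diameter_cm"] >= min_diameter_cm
    sub = stems.loc[sel]
    if unit_level == "site":
        units = sub["site_id"].astype(str)
    else:
        units = sub["site_id"].astype(str) + ":" + sub["plot_id"].astype(str)
    table = pd.crosstab(units, sub["species_code"]) if len(sub) else pd.DataFrame()
    table.index = table.index.astype(str)
    table.index.name = "unit"
    table.columns.name = None
    if all_units is not None:
        table = table.reindex(list(all_units), fill_value=0)
        table = table.fillna(0).astype(int)
    # drop species never observed
    if len(table.columns):
        table = table.loc[:, table.sum(axis=0) > 0]
    table = table.astype(int)
    table = table.sort_index()
    table = table[sorted(table.columns)] if len(table.columns) else table
    factor = 2.0 if unit_level == "site" else 1.0
    areas = {s: PLOT_AREA_M2[s] * factor for s in strata}
    unit_site = {u: u.split(":", 1)[0] for u in table.index}
    return AbundanceMatrix(table, strata, unit_level, min_diameter_cm, areas, unit_site)


def compute_sba(stems: pd.DataFrame, include_lianas: bool = True) -> pd.Series:
    """Stand basal area per site (m^2/ha) from stems >= 1 cm.

    Each stratum's basal-area sum is scaled by its own sampled area (saplings
    are censused in half the plot).  Lianas are included by default; pass
    ``include_lianas=False`` for a trees+saplings-only definition.
    """
    strata = ["sapling", "tree"] + (["liana"] if include_lianas else [])
    sel = stems["stratum"].isin(strata) & (stems["diameter_cm"] >= 1.0)
    sub = stems.loc[sel].copy()
    ba_m2 = np.pi * (sub["diameter_cm"] / 200.0) ** 2   # cm diameter -> m^2 area
    area = sub["stratum"].map(lambda s: 2 * PLOT_AREA_M2[s])  # per-site area
    per_ha = ba_m2 / area * 1e4
    out = per_ha.groupby(sub["site_id"].astype(str)).sum()
    out.name = "sba_m2ha"
    return out
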