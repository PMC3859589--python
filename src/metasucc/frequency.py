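"""Landscape-scale frequencies of occurrence and between-class turnover.

For every species (all woody life forms) and every site class, two
plot-level frequencies are computed from stems >= 1 cm diameter:

* **F1** — percentage of the class's plots holding at least one individual;
* **F5%** — percentage of the class's plots where the species makes up at
  least 5% of all such individuals (local dominance; boundary inclusive).

Rank-frequency curves (species sorted by descending F1) summarize how
evenly occupancy is spread across the species pool; their slope flattens
as succession spreads more species across more of the landscape.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .data import AbundanceMatrix, ClassScheme


def occurrence_frequencies(plot_matrix: AbundanceMatrix, scheme: ClassScheme,
                           dominance_threshold: float = 0.05) -> pd.DataFrame:
    """Per-class F1 and F5% for every species of a plot-level matrix.

    ``plot_matrix`` must be built at ``unit_level="plot"`` from all stems
    >= 1 cm (saplings + trees + lianas); the denominator of the dominance
    share is all such individuals in the plot.
    """
    if plot_matrix.unit_level != "plot":
        raise ValueError("frequencies are defined on plot-level matrices")
    df = plot_matrix.df
    plot_class = pd.Series({u: scheme.membership[plot_matrix.unit_site[u]]
                            for u in df.index})
    rows = []
    for label in scheme.labels:
        plots = plot_class.index[plot_class == label]
        if len(plots) == 0:
            raise ValueError(f"class {label!r} contains no plots")
        sub = df.loc[plots]
        totals = sub.sum(axis=1).to_numpy()[:, None]
        with np.errstate(invalid="ignore", divide="ignore"):
            share = np.where(totals > 0, sub.to_numpy() / totals, 0.0)
        f1 = 100.0 * (sub.to_numpy() > 0).mean(axis=0)
        f5 = 100.0 * (share >= dominance_threshold).mean(axis=0)
        for sp, a, b in zip(df.columns, f1, f5):
            rows.append({"species_code": sp, "class": label,
                         "f1_pct": float(a), "f5_pct": float(b)})
    out = pd.DataFrame(rows)
    bad = out["f5_pct"] > out["f1_pct"] + 1e-9
    assert not bad.any(), "dominance frequency exceeded occurrence frequency"
    return out


def class_turnover(freq_table: pd.DataFrame, class_a: str, class_b: str,
                   ) -> tuple[float, float]:
    """Directional species turnover between two classes, in percent.

    Returns ``(pct_of_A_absent_from_B, pct_of_B_absent_from_A)``, where
    presence in a class means F1 > 0 there.
    """
    def _present(label: str) -> set[str]:
        sub = freq_table.loc[freq_table["class"] == label]
        s = set(sub.loc[sub["f1_pct"] > 0, "species_code"])
        if not s:
            raise ValueError(f"class {label!r} has no species present")
        return s

    sa, sb = _present(class_a), _present(class_b)
    return (100.0 * len(sa - sb) / len(sa), 100.0 * len(sb - sa) / len(sb))


def rank_frequency_curve(freq_table: pd.DataFrame, class_label: str,
                         ) -> tuple[pd.DataFrame, float]:
    """Ordered (rank, F1) series for one class plus a tail-slope summary.

    Species are sorted by descending F1 with alphabetical tie-break.  The
    slope is the OLS slope of log10(F1) on rank — the standard decay-rate
    summary for rank curves — fitted from the end of the top decile of
    nonzero ranks through the last nonzero rank (the handful of ubiquitous
    head species is excluded so the slope describes how occupancy decays
    across the bulk of the pool).  A raw-F1 slope would *steepen* whenever
    occupancy rises across the whole pool and so cannot express the
    flattening of the curve that accompanies succession; the log-scale
    slope does.
    """
    sub = freq_table.loc[freq_table["class"] == class_label,
                         ["species_code", "f1_pct"]].copy()
    if sub.empty:
        raise ValueError(f"no rows for class {class_label!r}")
    sub = sub.sort_values(["f1_pct", "species_code"],
                          ascending=[False, True], ignore_index=True)
    sub["rank"] = np.arange(1, len(sub) + 1)
    nonzero = sub.loc[sub["f1_pct"] > 0]
    if nonzero.empty:
        return sub[["rank", "species_code", "f1_pct"]], 0.0
    last = int(nonzero["rank"].max())
    start = max(1, int(np.ceil(0.10 * last)))
    seg = sub.loc[(sub["rank"] >= start) & (sub["rank"] <= last)]
    seg = seg.loc[seg["f1_pct"] > 0]
    if len(seg) < 2 or seg["f1_pct"].nunique() == 1:
        slope = 0.0
    else:
        res = sm.OLS(np.log10(seg["f1_pct"].to_numpy()),
                     sm.add_constant(seg["rank"].to_numpy(dtype=float))).fit()
        slope = float(res.params[1])
    return sub[["rank", "species_code", "f1_pct"]], slope
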