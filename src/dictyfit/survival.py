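"""Survival-assay statistics: plating fractions, relative fitness, and
group-level rank comparisons.

The assay plates aliquots of a dormant-cell suspension clonally with food
bacteria; each viable spore or cyst founds one plaque, so the survival
fraction at a storage day is plaques counted over cells plated
(cells_per_ml x volume_ul / 1000).  Relative fitness F normalizes every
curve, spore and cyst alike, at each post-baseline time point to the mean
spore survival across all species and conditions at that time point, then
averages the normalized values over the six post-baseline days.  Group
comparisons pool per-species F values per major taxon group (spores) plus
one pool over all cysts, per storage condition, and test them with
Kruskal-Wallis followed by Dunn's pairwise matrix.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import stats as dstats

#: post-baseline storage days averaged into F; day 0 is a plating-efficiency QC
POST_BASELINE_DAYS = (1, 7, 30, 91, 182, 365)


def survival_fractions(observations: pd.DataFrame) -> pd.DataFrame:
    """Per-replicate survival fractions and their per-day mean and SD.

    Expects the plaque-count schema (species_id, taxon_group, form,
    condition, day, replicate, volume_ul, plaque_count, cells_per_ml).
    Returns one row per species x form x condition x day with columns
    mean_fraction, sd_fraction, n_replicates and an above_one flag
    (counting noise can push fractions past 1; they are kept, not clipped).
    """
    obs = observations.copy()
    cells = obs["cells_per_ml"] * obs["volume_ul"] / 1000.0
    if (cells <= 0).any():
        raise ValueError("zero or negative cells plated")
    key = ["species_id", "taxon_group", "form", "condition", "day", "replicate"]
    if obs.duplicated(subset=key).any():
        raise ValueError("duplicate replicate keys in observations")
    obs["fraction"] = obs["plaque_count"] / cells
    grouped = obs.groupby(["species_id", "taxon_group", "form",
                           "condition", "day"], sort=True)["fraction"]
    out = grouped.agg(mean_fraction="mean",
                      sd_fraction=lambda x: x.std(ddof=1) if len(x) > 1 else 0.0,
                      n_replicates="count").reset_index()
    out["above_one"] = out["mean_fraction"] > 1.0
    return out


def relative_fitness(curves: pd.DataFrame,
                     days: tuple[int, ...] = POST_BASELINE_DAYS) -> pd.DataFrame:
    """Relative fitness F per species x form x condition.

    The denominator at each time point is the mean survival fraction over
    all SPORE curves (every species, every condition); spore and cyst
    curves alike are divided by it.  F is the mean of the normalized values
    over ``days`` and SE = SD / sqrt(n) with n the number of time points
    with a defined normalized value.  Time points whose spore denominator
    is zero are dropped with a warning.

    By construction the mean of the normalized spore values at each time
    point is exactly 1.
    """
    sub = curves[curves["day"].isin(days)].copy()
    spores = sub[sub["form"] == "spore"]
    if spores.empty:
        raise ValueError("no spore curves to build the normalization denominator")
    denom = spores.groupby("day")["mean_fraction"].mean()
    missing = [d for d in days if d not in denom.index]
    if missing:
        raise ValueError(f"no spore curves at time points {missing}")
    zero_days = denom.index[denom == 0.0].tolist()
    if zero_days:
        warnings.warn(f"spore denominator is zero at days {zero_days}; "
                      "dropping those time points from the average")
        sub = sub[~sub["day"].isin(zero_days)]
        denom = denom.drop(zero_days)

    sub["normalized"] = sub["mean_fraction"] / sub["day"].map(denom)
    grouped = sub.groupby(["species_id", "taxon_group", "form", "condition"],
                          sort=True)["normalized"]
    out = grouped.agg(fitness="mean",
                      sd=lambda x: x.std(ddof=1) if len(x) > 1 else 0.0,
                      n_timepoints="count").reset_index()
    out["se"] = out["sd"] / np.sqrt(out["n_timepoints"])
    return out.drop(columns="sd")


@dataclass
class GroupComparison:
    """Per-condition pooled comparison of relative fitness values."""

    condition: str
    pool_stats: pd.DataFrame           # pool, n, mean, se
    kruskal: dstats.RankTestResult | None
    dunn_p: pd.DataFrame | None        # symmetric pairwise p-value matrix
    excluded_pools: list[str] = field(default_factory=list)
    degenerate: bool = False


def default_pooling(row) -> str | None:
    """Spores pool per major taxon group; all cysts pool together; species
    in minor groups are left out of the pools (but they still contributed to
    the all-spore normalization denominator upstream)."""
    if row["form"] == "cyst":
        return "cysts"
    if row["taxon_group"] in ("1", "2", "3", "4"):
        return f"grp{row['taxon_group']}"
    return None


def group_fitness_comparison(fitness: pd.DataFrame, pooling=default_pooling,
                             adjust: str = "none") -> dict[str, GroupComparison]:
    """Kruskal-Wallis + Dunn pairwise matrix over fitness pools, per condition.

    Pools with fewer than 2 values are excluded from the tests and listed in
    the result.  If all pooled values are identical the stats layer's
    degenerate-data signal is surfaced via the ``degenerate`` flag.
    """
    results: dict[str, GroupComparison] = {}
    for cond, sub in fitness.groupby("condition", sort=True):
        sub = sub.copy()
        sub["pool"] = sub.apply(pooling, axis=1)
        sub = sub[sub["pool"].notna()]
        stats_rows = []
        pools: dict[str, np.ndarray] = {}
        for pool, ps in sub.groupby("pool", sort=True):
            vals = ps["fitness"].to_numpy(dtype=float)
            pools[pool] = vals
            stats_rows.append({"pool": pool, "n": vals.size,
                               "mean": float(vals.mean()),
                               "se": float(vals.std(ddof=1) / math.sqrt(vals.size))
                               if vals.size > 1 else 0.0})
        pool_stats = pd.DataFrame(stats_rows)
        excluded = [p for p, v in pools.items() if v.size < 2]
        testable = {p: v for p, v in pools.items() if v.size >= 2}

        kw = None
        dunn = None
        degenerate = False
        if len(testable) >= 2:
            names = sorted(testable)
            try:
                kw = dstats.kruskal_wallis([testable[p] for p in names],
                                           method="approx")
                dmat = dstats.dunn_pairwise([testable[p] for p in names],
                                            adjust=adjust)
                dunn = pd.DataFrame(dmat, index=names, columns=names)
            except dstats.DegenerateDataError:
                degenerate = True
        results[cond] = GroupComparison(condition=cond, pool_stats=pool_stats,
                                        kruskal=kw, dunn_p=dunn,
                                        excluded_pools=excluded,
                                        degenerate=degenerate)
    return results


def plot_survival_curves(curves: pd.DataFrame, species_id: str, out_path: str) -> None:
    """Write a per-condition survival-curve figure for one species."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sub = curves[curves["species_id"] == species_id]
    if sub.empty:
        raise ValueError(f"no curves for species {species_id!r}")
    fig, ax = plt.subplots(figsize=(6, 4))
    for (form, cond), grp in sub.groupby(["form", "condition"]):
        grp = grp.sort_values("day")
        ax.errorbar(grp["day"], grp["mean_fraction"], yerr=grp["sd_fraction"],
                    label=f"{form} {cond}", marker="o", capsize=2)
    ax.set_xlabel("storage time (days)")
    ax.set_ylabel("survival fraction")
    ax.set_title(species_id)
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
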