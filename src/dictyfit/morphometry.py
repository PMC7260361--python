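"""Ultrastructure morphometry: per-species feature aggregation, area
fractions, trait-fitness correlations and group contrasts.

Per-cell TEM measurements (wall widths measured at 20 positions per cell,
organelle counts/areas, per-mitochondrion qualitative flags as fractions)
are averaged hierarchically to species means.  Granule cross-section area
assumes circular profiles (sum of pi d^2/4 over measured diameters); vesicle
area is measured directly.  Features are then correlated (Spearman by
default) with relative fitness at a chosen storage condition, and contrasted
per taxon group against all other groups with two-sided Mann-Whitney tests.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd

from . import stats as dstats

#: significance threshold used for heat-map signs and group flags
ALPHA = 0.05


def _parse_diameters(value) -> np.ndarray:
    if isinstance(value, (list, tuple, np.ndarray)):
        return np.asarray(value, dtype=float)
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return np.array([])
    return np.array([float(v) for v in str(value).split(";")])


def derive_area_fractions(record) -> tuple[float, float]:
    """Proportional contribution of granules and vesicles to the cell
    cross-section area (wall-exclusive) of one cell.

    ``record`` is a mapping/row with granule_diameters, vesicle_total_area
    and cell_cross_section_area.  Fractions above 1 are reported but capped
    with a warning (measurement error).
    """
    area = float(record["cell_cross_section_area"])
    if area <= 0:
        raise ValueError("cell cross-section area must be > 0")
    diam = _parse_diameters(record.get("granule_diameters", ""))
    if (diam < 0).any():
        raise ValueError("negative granule diameter")
    granule_area = float(np.sum(math.pi * diam**2 / 4.0))
    gf = granule_area / area
    vf = float(record["vesicle_total_area"]) / area
    for name, f in (("granule", gf), ("vesicle", vf)):
        if f > 1.0:
            warnings.warn(f"{name} area fraction {f:.3f} exceeds 1; capped")
    return min(gf, 1.0), min(vf, 1.0)


def species_feature_summary(records: pd.DataFrame,
                            min_cells: int = 10) -> pd.DataFrame:
    """Per-species mean of every numeric feature plus derived area fractions.

    Qualitative per-cell and per-mitochondrion flags are already fractions
    in the records, so their means are fractions of cells/mitochondria
    displaying the feature.  Species with fewer than ``min_cells`` cells
    trigger a warning; species with zero cells raise.
    """
    if records.empty:
        raise ValueError("no morphometry records")
    recs = records.copy()
    fracs = recs.apply(derive_area_fractions, axis=1, result_type="expand")
    recs["granule_area_fraction"] = fracs[0]
    recs["vesicle_area_fraction"] = fracs[1]

    feature_cols = [c for c in recs.columns
                    if c not in ("species_id", "taxon_group", "cell_index",
                                 "granule_diameters")
                    and pd.api.types.is_numeric_dtype(recs[c])]
    counts = recs.groupby("species_id")["cell_index"].count()
    low = counts[counts < min_cells]
    if not low.empty:
        warnings.warn(f"species with fewer than {min_cells} cells: "
                      f"{sorted(low.index)}")
    group_col = (recs.groupby("species_id")["taxon_group"].first()
                 if "taxon_group" in recs else None)
    out = recs.groupby("species_id", sort=True)[feature_cols].mean()
    out.insert(0, "n_cells", counts)
    if group_col is not None:
        out.insert(0, "taxon_group", group_col)
    return out.reset_index()


def feature_fitness_correlation(features: pd.DataFrame, fitness: pd.DataFrame,
                                condition: str = "m20C_wet",
                                method: str = "spearman",
                                fitness_mode: str = "spore") -> pd.DataFrame:
    """Correlate each species-level feature with relative fitness at one
    storage condition.

    ``fitness_mode='spore'`` uses spore fitness only; ``'pooled'`` averages a
    species' spore and cyst fitness.  Returns a table ordered by |rho| with
    per-feature rho, p, n and a sign flag for significant correlations.
    """
    fit = fitness[fitness["condition"] == condition]
    if fitness_mode == "spore":
        fit = fit[fit["form"] == "spore"]
    elif fitness_mode != "pooled":
        raise ValueError("fitness_mode must be 'spore' or 'pooled'")
    fit = fit.groupby("species_id")["fitness"].mean()

    merged = features.merge(fit.rename("fitness_value"), on="species_id")
    if len(merged) < 3:
        raise ValueError("fewer than 3 species shared between tables")
    feature_cols = [c for c in features.columns
                    if c not in ("species_id", "taxon_group", "n_cells")]
    rows = []
    for feat in feature_cols:
        x = merged[feat].to_numpy(dtype=float)
        y = merged["fitness_value"].to_numpy(dtype=float)
        try:
            if method == "spearman":
                res = dstats.spearman_rho(x, y, method="approx")
                rho, p = res.rho, res.p_value
            elif method == "pearson":
                rho = float(np.corrcoef(x, y)[0, 1])
                p = dstats._spearman_t_p(rho, x.size)
            else:
                raise ValueError("method must be 'spearman' or 'pearson'")
        except dstats.DegenerateDataError:
            rho, p = float("nan"), float("nan")
        sign = ""
        if p == p and p < ALPHA:
            sign = "positive" if rho > 0 else "negative"
        rows.append({"feature": feat, "rho": rho, "p_value": p,
                     "n": len(merged), "sign": sign})
    out = pd.DataFrame(rows)
    return out.reindex(out["rho"].abs().sort_values(ascending=False).index
                       ).reset_index(drop=True)


def group_feature_contrast(features: pd.DataFrame,
                           grouping: str = "taxon_group",
                           alpha: float = ALPHA) -> pd.DataFrame:
    """Group-vs-rest contrasts for every feature.

    Each group with >= 2 species is tested against all other species with a
    two-sided Mann-Whitney U; flags are 'higher'/'lower' when p < alpha and
    the group mean lies above/below the rest, 'untestable' for singleton
    groups.
    """
    if grouping not in features.columns:
        raise ValueError(f"grouping column {grouping!r} missing")
    feature_cols = [c for c in features.columns
                    if c not in ("species_id", grouping, "n_cells")]
    groups = sorted(features[grouping].unique())
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    rows = []
    for g in groups:
        mask = features[grouping] == g
        for feat in feature_cols:
            a = features.loc[mask, feat].to_numpy(dtype=float)
            b = features.loc[~mask, feat].to_numpy(dtype=float)
            if a.size < 2 or b.size < 2:
                rows.append({"group": g, "feature": feat,
                             "group_mean": float(a.mean()) if a.size else float("nan"),
                             "rest_mean": float(b.mean()) if b.size else float("nan"),
                             "p_value": float("nan"), "flag": "untestable"})
                continue
            try:
                res = dstats.mann_whitney_u(a, b, method="approx")
                p = res.p_value
            except dstats.DegenerateDataError:
                p = 1.0
            flag = ""
            if p < alpha:
                flag = "higher" if a.mean() > b.mean() else "lower"
            rows.append({"group": g, "feature": feat,
                         "group_mean": float(a.mean()),
                         "rest_mean": float(b.mean()),
                         "p_value": p, "flag": flag})
    return pd.DataFrame(rows)
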