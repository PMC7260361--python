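"""Climate-of-isolation analysis.

Climate zones are ranked on a 1-5 ordinal scale from tropical to
arctic/alpine; a species' range collapses to its coldest (max rank) and
warmest (min rank) zone.  The per-group percentage matrix over coldest
zones and the Spearman correlation of climate rank with spore relative
fitness follow.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from . import stats as dstats
from .synthetic import ZONES

ZONE_RANK = {zone: i + 1 for i, zone in enumerate(ZONES)}


def _zone_set(zones) -> list[str]:
    if isinstance(zones, str):
        items = [z.strip() for z in zones.split(";") if z.strip()]
    else:
        items = list(zones)
    if not items:
        raise ValueError("empty climate-zone set")
    unknown = [z for z in items if z not in ZONE_RANK]
    if unknown:
        raise ValueError(f"unknown climate zone labels: {unknown}")
    return items


def climate_ranks(record) -> tuple[int, int]:
    """(coldest_rank, warmest_rank) of one species record.

    tropical=1 ... arctic/alpine=5; coldest is the max rank of the zone set.
    """
    ranks = [ZONE_RANK[z] for z in _zone_set(record["zones"])]
    return max(ranks), min(ranks)


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def build_table1(records: pd.DataFrame, rounded: bool = True) -> pd.DataFrame:
    """Per-group percentage of species whose coldest zone is each of the
    five climate classes (columns cold -> warm, as printed).

    Percentages are rounded half away from zero, so rows can sum to
    98-102; ``rounded=False`` returns exact percentages summing to 100.
    Species without a recorded climate (empty zones) must be excluded by the
    caller; empty groups are omitted with a warning.
    """
    recs = records.copy()
    recs["coldest"] = recs.apply(lambda r: climate_ranks(r)[0], axis=1)
    cold_order = list(reversed(ZONES))  # printed coldest-first
    rows = {}
    for g, sub in recs.groupby("taxon_group", sort=True):
        n = len(sub)
        if n == 0:
            warnings.warn(f"empty group {g!r} omitted")
            continue
        counts = sub["coldest"].value_counts()
        pcts = []
        for zone in cold_order:
            pct = 100.0 * counts.get(ZONE_RANK[zone], 0) / n
            pcts.append(_round_half_away(pct) if rounded else pct)
        rows[g] = pcts
    return pd.DataFrame.from_dict(rows, orient="index", columns=cold_order)


def climate_fitness_correlation(records: pd.DataFrame, fitness: pd.DataFrame,
                                condition: str,
                                extreme: str = "coldest") -> dstats.CorrelationResult:
    """Spearman correlation of climate rank with spore relative fitness at
    one storage condition.

    ``extreme`` selects the coldest (max) or warmest (min) zone rank of each
    species' range.  Cysts are excluded: the comparison concerns spore
    survival.
    """
    if extreme not in ("coldest", "warmest"):
        raise ValueError("extreme must be 'coldest' or 'warmest'")
    recs = records.copy()
    idx = 0 if extreme == "coldest" else 1
    recs["rank"] = recs.apply(lambda r: climate_ranks(r)[idx], axis=1)

    fit = fitness[(fitness["condition"] == condition)
                  & (fitness["form"] == "spore")]
    merged = recs.merge(fit[["species_id", "fitness"]], on="species_id")
    if len(merged) < 3:
        raise ValueError("fewer than 3 species shared between tables")
    return dstats.spearman_rho(merged["rank"].to_numpy(dtype=float),
                               merged["fitness"].to_numpy(dtype=float),
                               method="approx")
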