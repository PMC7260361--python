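"""Synthetic data generators for every input the pipeline consumes.

Four generators emulate, with the statistical structure the analyses assume:

* plaque-count survival tables (binomial plating counts under per-group
  decay curves),
* per-cell ultrastructure (morphometry) tables,
* species climate-of-isolation rosters, and
* dated trees with independent log-normal branch rates plus noisy
  branch-length observations.

Defaults encode the study conditions: 22 species assayed for spore survival
(five per major taxon group, one per minor group), five cyst formers, four
storage regimes, sampling at days 0/1/7/30/91/182/365, triplicate 10 ul
aliquots of a 1e4 cells/ml suspension (100 cells) with larger aliquots at
late time points, and the qualitative group contrasts: group 4 spores most
frost resistant, groups 1 and 3 least; cysts die within days under dry
frost; group 2 thickest and group 3 thinnest spore walls; group 4 most
frequently isolated from arctic/alpine zones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chronology.tree import TimeTree

CONDITIONS = ("22C_wet", "4C_wet", "m20C_wet", "m20C_dry")
FORMS = ("spore", "cyst")
DEFAULT_SCHEDULE = (0, 1, 7, 30, 91, 182, 365)
#: aliquot volume (ul) plated at each storage day; larger late aliquots keep
#: plaque numbers countable as survival declines
DEFAULT_VOLUMES = {0: 10, 1: 10, 7: 10, 30: 10, 91: 20, 182: 30, 365: 40}

ZONES = ("tropical", "subtropical", "temperate",
         "subarctic/subalpine", "arctic/alpine")

MAJOR_GROUPS = ("1", "2", "3", "4")
MINOR_GROUP = "minor"


def default_species_roster() -> list[tuple[str, str]]:
    """(species_id, taxon_group) pairs: 5 per major group + 2 minor-group species."""
    roster = [(f"g{g}_s{i}", g) for g in MAJOR_GROUPS for i in range(1, 6)]
    roster += [("minA_s1", MINOR_GROUP), ("minB_s1", MINOR_GROUP)]
    return roster


#: species assayed for cyst survival (readily encysting, groups 1-3)
DEFAULT_CYST_FORMERS = ("g1_s1", "g1_s2", "g2_s1", "g3_s1", "g3_s2")


# ---------------------------------------------------------------------------
# Survival counts
# ---------------------------------------------------------------------------

# (tau [days], shape k, plateau s_inf) per (group, form, condition).
# Spores: best survival near/below 0 C, group 4 >> group 2 > minor > 1 ~ 3 at
# frost.  Cysts: comparable to spores at 22 C, worse when cold, dead within
# days of dry frost.
def _spore_params(g: str) -> dict[str, tuple[float, float, float]]:
    frost_tau = {"1": 90.0, "2": 280.0, "3": 75.0, "4": 520.0, MINOR_GROUP: 130.0}
    frost_pl = {"1": 0.04, "2": 0.20, "3": 0.03, "4": 0.42, MINOR_GROUP: 0.08}
    dry_tau = {"1": 45.0, "2": 150.0, "3": 38.0, "4": 400.0, MINOR_GROUP: 75.0}
    dry_pl = {"1": 0.02, "2": 0.10, "3": 0.015, "4": 0.30, MINOR_GROUP: 0.05}
    cold_tau = {"1": 140.0, "2": 320.0, "3": 120.0, "4": 460.0, MINOR_GROUP: 170.0}
    cold_pl = {"1": 0.06, "2": 0.22, "3": 0.05, "4": 0.38, MINOR_GROUP: 0.10}
    return {
        "22C_wet": (60.0, 0.8, 0.02),
        "4C_wet": (cold_tau[g], 0.9, cold_pl[g]),
        "m20C_wet": (frost_tau[g], 0.9, frost_pl[g]),
        "m20C_dry": (dry_tau[g], 0.9, dry_pl[g]),
    }


_CYST_PARAMS = {
    "22C_wet": (80.0, 0.8, 0.05),
    "4C_wet": (40.0, 0.9, 0.01),
    "m20C_wet": (22.0, 1.0, 0.005),
    "m20C_dry": (1.0, 1.0, 0.0),
}


def default_decay_parameters() -> dict[tuple[str, str, str], tuple[float, float, float]]:
    """(group, form, condition) -> (tau, k, s_inf) defaults."""
    params: dict[tuple[str, str, str], tuple[float, float, float]] = {}
    for g in MAJOR_GROUPS + (MINOR_GROUP,):
        for cond, p in _spore_params(g).items():
            params[(g, "spore", cond)] = p
        for cond, p in _CYST_PARAMS.items():
            params[(g, "cyst", cond)] = p
    return params


@dataclass
class SurvivalSimConfig:
    """Configuration of the survival-assay simulator."""

    species: list[tuple[str, str]] = field(default_factory=default_species_roster)
    cyst_formers: tuple[str, ...] = DEFAULT_CYST_FORMERS
    conditions: tuple[str, ...] = CONDITIONS
    schedule: tuple[int, ...] = DEFAULT_SCHEDULE
    volumes_ul: dict[int, int] = field(default_factory=lambda: dict(DEFAULT_VOLUMES))
    decay: dict[tuple[str, str, str], tuple[float, float, float]] = field(
        default_factory=default_decay_parameters)
    cells_per_ml: float = 1e4
    replicates: int = 3
    #: between-species log-normal jitter (CV) on tau and the plateau, within
    #: a taxon group; assays show sizable species-to-species variation
    species_tau_cv: float = 0.3
    species_plateau_cv: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not isinstance(self.replicates, (int, np.integer)) or isinstance(self.replicates, bool):
            raise ValueError("replicate count must be an integer")
        if self.replicates < 1:
            raise ValueError("need at least one replicate")
        days = list(self.schedule)
        if days != sorted(set(days)) or days[0] != 0:
            raise ValueError("schedule must be strictly increasing and include day 0")
        for cond in self.conditions:
            if cond not in CONDITIONS:
                raise ValueError(f"unknown condition label: {cond!r}")
        for (g, form, cond), (tau, k, s_inf) in self.decay.items():
            if form not in FORMS:
                raise ValueError(f"unknown form label: {form!r}")
            if not tau > 0:
                raise ValueError("half-life parameter tau must be > 0")
            if not k > 0:
                raise ValueError("shape k must be > 0")
            if not 0.0 <= s_inf <= 1.0:
                raise ValueError("plateau s_inf must lie in [0, 1]")


def survival_probability(day: float, tau: float, k: float, s_inf: float) -> float:
    """Weibull-with-plateau survival S(t) = s_inf + (1 - s_inf) exp(-(t/tau)^k)."""
    if day == 0:
        return 1.0
    if math.isinf(tau):
        return 1.0 if s_inf == 1.0 else s_inf + (1.0 - s_inf)
    return s_inf + (1.0 - s_inf) * math.exp(-((day / tau) ** k))


def gen_survival(config: SurvivalSimConfig | None = None) -> pd.DataFrame:
    """Simulate a plaque-count table.

    One row per species x available form x condition x day x replicate;
    plaque_count ~ Binomial(cells plated, S(day)).  Deterministic given
    (config, seed).
    """
    cfg = config if config is not None else SurvivalSimConfig()
    rng = np.random.default_rng(cfg.seed)
    rows = []
    for species_id, group in cfg.species:
        forms = ["spore"]
        if species_id in cfg.cyst_formers:
            forms.append("cyst")
        for form in forms:
            for cond in cfg.conditions:
                tau, k, s_inf = cfg.decay[(group, form, cond)]
                if cfg.species_tau_cv > 0 and math.isfinite(tau):
                    tau = float(_draw_lognormal(rng, tau, cfg.species_tau_cv, 1)[0])
                if cfg.species_plateau_cv > 0 and 0 < s_inf < 1:
                    s_inf = min(1.0, float(
                        _draw_lognormal(rng, s_inf, cfg.species_plateau_cv, 1)[0]))
                for day in cfg.schedule:
                    vol = cfg.volumes_ul.get(day, 10)
                    n_cells = int(round(cfg.cells_per_ml * vol / 1000.0))
                    p = survival_probability(day, tau, k, s_inf)
                    counts = rng.binomial(n_cells, p, size=cfg.replicates)
                    for rep, c in enumerate(counts, start=1):
                        rows.append((species_id, group, form, cond, day, rep,
                                     vol, int(c), cfg.cells_per_ml))
    return pd.DataFrame(rows, columns=[
        "species_id", "taxon_group", "form", "condition", "day",
        "replicate", "volume_ul", "plaque_count", "cells_per_ml"])


# ---------------------------------------------------------------------------
# Morphometry
# ---------------------------------------------------------------------------

#: the 20 per-cell ultrastructural features and their sampling family
FEATURES: dict[str, str] = {
    "wall_total_width": "lognormal",       # nm; derived as the sum of layers
    "wall_layer1_width": "lognormal",
    "wall_layer2_width": "lognormal",
    "wall_layer3_width": "lognormal",
    "wall_gray": "lognormal",              # electron density, 0-255 scale
    "granule_count": "lognormal",
    "granule_mean_diameter": "lognormal",  # um
    "vesicle_count": "lognormal",
    "vesicle_total_area": "lognormal",     # um^2
    "cell_cross_section_area": "lognormal",  # um^2, wall-exclusive
    "nucleus_area": "lognormal",           # um^2
    "mitochondria_count": "lognormal",
    "spore_elongation": "lognormal",       # length/width ratio
    "cytoplasm_gray": "lognormal",
    "mito_crenate_fraction": "beta",
    "mito_closed_cristae_fraction": "beta",
    "mito_ribosome_fringe_fraction": "beta",
    "granules_polar_fraction": "beta",
    "heterochromatin_condensed_fraction": "beta",
    "vesicles_clustered_fraction": "beta",
}


def default_morphometry_profiles() -> dict[str, dict[str, tuple[float, float]]]:
    """Per-group (mean, dispersion) for all 20 features.

    Group contrasts built in: group 2 thickest / group 3 thinnest walls;
    group 4 compacted (small, sparse granules and vesicles; crenate,
    closed-cristae, ribosome-fringed mitochondria); group 3 crenate
    mitochondria without the ribosome fringe.
    """
    # layer-width means (nm); total is generated as the sum of the layers
    layers = {"1": (35, 70, 35), "2": (55, 115, 55), "3": (22, 48, 22),
              "4": (45, 95, 45), MINOR_GROUP: (38, 76, 38)}
    granule_d = {"1": 0.26, "2": 0.24, "3": 0.27, "4": 0.13, MINOR_GROUP: 0.25}
    granule_n = {"1": 14, "2": 13, "3": 15, "4": 8, MINOR_GROUP: 13}
    vesicle_a = {"1": 0.9, "2": 0.7, "3": 1.0, "4": 0.18, MINOR_GROUP: 0.8}
    crenate = {"1": 0.15, "2": 0.15, "3": 0.70, "4": 0.85, MINOR_GROUP: 0.2}
    cristae = {"1": 0.15, "2": 0.20, "3": 0.35, "4": 0.80, MINOR_GROUP: 0.2}
    fringe = {"1": 0.10, "2": 0.10, "3": 0.12, "4": 0.75, MINOR_GROUP: 0.1}
    polar = {"1": 0.8, "2": 0.8, "3": 0.8, "4": 0.25, MINOR_GROUP: 0.75}

    cv = 0.15      # within-species coefficient of variation, quantitative
    bdisp = 0.04   # beta dispersion (inverse concentration)
    profiles: dict[str, dict[str, tuple[float, float]]] = {}
    for g in MAJOR_GROUPS + (MINOR_GROUP,):
        l1, l2, l3 = layers[g]
        prof = {
            "wall_total_width": (l1 + l2 + l3, cv),
            "wall_layer1_width": (l1, cv),
            "wall_layer2_width": (l2, cv),
            "wall_layer3_width": (l3, cv),
            "wall_gray": (120.0, cv),
            "granule_count": (granule_n[g], cv),
            "granule_mean_diameter": (granule_d[g], cv),
            "vesicle_count": (10.0, cv),
            "vesicle_total_area": (vesicle_a[g], cv),
            "cell_cross_section_area": (7.0 if g == "4" else 9.0, cv),
            "nucleus_area": (1.8, cv),
            "mitochondria_count": (9.0, cv),
            "spore_elongation": (1.8, 0.1),
            "cytoplasm_gray": (140.0, cv),
            "mito_crenate_fraction": (crenate[g], bdisp),
            "mito_closed_cristae_fraction": (cristae[g], bdisp),
            "mito_ribosome_fringe_fraction": (fringe[g], bdisp),
            "granules_polar_fraction": (polar[g], bdisp),
            "heterochromatin_condensed_fraction": (0.5, bdisp),
            "vesicles_clustered_fraction": (0.4, bdisp),
        }
        profiles[g] = prof
    return profiles


def _draw_lognormal(rng, mean: float, cv: float, size: int) -> np.ndarray:
    if cv == 0:
        return np.full(size, float(mean))
    sigma2 = math.log1p(cv * cv)
    mu = math.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, math.sqrt(sigma2), size=size)


def _draw_beta(rng, mean: float, dispersion: float, size: int) -> np.ndarray:
    if dispersion == 0:
        return np.full(size, float(mean))
    nu = 1.0 / dispersion
    return rng.beta(mean * nu, (1.0 - mean) * nu, size=size)


def gen_morphometry(group_profiles: dict | None = None,
                    n_cells_per_species: int = 10,
                    seed: int = 0,
                    species: list[tuple[str, str]] | None = None) -> pd.DataFrame:
    """Simulate a per-cell morphometry table.

    Widths, counts and areas are log-normal (strictly positive); per-cell
    mitochondrial and qualitative flags are beta fractions in [0, 1].  The
    per-cell wall total is the sum of the three layer draws, and individual
    granule diameters (semicolon-joined column ``granule_diameters``) are
    resampled around the per-cell mean diameter.
    """
    profiles = group_profiles if group_profiles is not None else default_morphometry_profiles()
    roster = species if species is not None else default_species_roster()
    for g, prof in profiles.items():
        missing = set(FEATURES) - set(prof)
        if missing:
            raise ValueError(f"profile for group {g!r} missing features: {sorted(missing)}")
        for feat, (mean, disp) in prof.items():
            if disp < 0:
                raise ValueError(f"dispersion must be >= 0 for {feat!r}")
    rng = np.random.default_rng(seed)
    rows = []
    for species_id, group in roster:
        prof = profiles[group]
        cells: dict[str, np.ndarray] = {}
        for feat, kind in FEATURES.items():
            mean, disp = prof[feat]
            if kind == "lognormal":
                cells[feat] = _draw_lognormal(rng, mean, disp, n_cells_per_species)
            else:
                cells[feat] = _draw_beta(rng, mean, disp, n_cells_per_species)
        cells["wall_total_width"] = (cells["wall_layer1_width"]
                                     + cells["wall_layer2_width"]
                                     + cells["wall_layer3_width"])
        for i in range(n_cells_per_species):
            n_gran = max(0, int(round(cells["granule_count"][i])))
            d_mean = cells["granule_mean_diameter"][i]
            diam = _draw_lognormal(rng, d_mean, 0.2, n_gran) if n_gran else np.array([])
            row = {"species_id": species_id, "taxon_group": group,
                   "cell_index": i + 1,
                   "granule_diameters": ";".join(f"{d:.6g}" for d in diam)}
            for feat in FEATURES:
                row[feat] = float(cells[feat][i])
            row["granule_count"] = float(n_gran)
            row["granule_mean_diameter"] = float(diam.mean()) if n_gran else 0.0
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Ecology
# ---------------------------------------------------------------------------

#: species per group: group 4 fixed at 27 by the survey; the remaining 58
#: split so every percentage row of the climate table is an exact
#: integer-count solution
DEFAULT_GROUP_SIZES = {"1": 17, "2": 27, "3": 13, "4": 27, MINOR_GROUP: 1}

#: coldest-zone counts per group, warm -> cold zone order
_DEFAULT_ZONE_COUNTS = {
    "1": (8, 0, 6, 3, 0),
    "2": (10, 6, 9, 1, 1),
    "3": (2, 6, 4, 1, 0),
    "4": (3, 1, 14, 4, 5),
    MINOR_GROUP: (0, 0, 1, 0, 0),
}


def default_zone_probabilities() -> dict[str, tuple[float, ...]]:
    """Per-group multinomial over coldest zones (warm -> cold order)."""
    return {g: tuple(c / sum(counts) for c in counts)
            for g, counts in _DEFAULT_ZONE_COUNTS.items()}


def _largest_remainder(n: int, probs: np.ndarray) -> np.ndarray:
    """Integer counts summing to n with expected proportions probs."""
    raw = n * probs
    base = np.floor(raw).astype(int)
    short = n - base.sum()
    order = np.argsort(-(raw - base))
    base[order[:short]] += 1
    return base


def gen_ecology(group_sizes: dict[str, int] | None = None,
                zone_probabilities: dict[str, tuple[float, ...]] | None = None,
                seed: int = 0,
                deterministic: bool = False,
                range_probability: float = 0.5) -> pd.DataFrame:
    """Simulate a species climate-of-isolation roster.

    Each species gets a coldest zone by a multinomial draw over the group's
    zone probabilities (or expected counts via largest remainder when
    ``deterministic``), plus, with probability ``range_probability``, a
    contiguous extension into warmer zones to form a range.  Columns:
    species_id, taxon_group, zones (semicolon-separated).
    """
    sizes = group_sizes if group_sizes is not None else dict(DEFAULT_GROUP_SIZES)
    probs = zone_probabilities if zone_probabilities is not None else default_zone_probabilities()
    for g, n in sizes.items():
        if n < 0:
            raise ValueError(f"negative group size for group {g!r}")
        p = np.asarray(probs[g], dtype=float)
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"zone probabilities for group {g!r} do not sum to 1")
    rng = np.random.default_rng(seed)
    rows = []
    for g in sorted(sizes):
        n = sizes[g]
        if n == 0:
            continue
        p = np.asarray(probs[g], dtype=float)
        if deterministic:
            counts = _largest_remainder(n, p)
            zone_idx = np.repeat(np.arange(len(ZONES)), counts)
        else:
            zone_idx = rng.choice(len(ZONES), size=n, p=p)
            zone_idx = np.sort(zone_idx)
        for i, z in enumerate(zone_idx, start=1):
            zones = [ZONES[z]]
            if not deterministic and z > 0 and rng.random() < range_probability:
                extent = rng.integers(1, z + 1)
                zones = [ZONES[j] for j in range(z - extent, z + 1)]
            rows.append((f"g{g}_e{i}", g, ";".join(zones)))
    return pd.DataFrame(rows, columns=["species_id", "taxon_group", "zones"])


def assign_zones_by_fitness(fitness: pd.DataFrame, condition: str = "m20C_wet",
                            seed: int = 0, noise_sd: float = 0.8,
                            range_probability: float = 0.9) -> pd.DataFrame:
    """Climate records for assayed species with coldest zone coupled to
    frost fitness.

    Emulates the observed association between cold-hardy spores and cold
    habitats of isolation: the coldest-zone rank is a noisy monotone
    function of the species' spore relative fitness at ``condition``;
    warmer range extensions are drawn independently.  Returns the ClimateRecord
    schema (species_id, taxon_group, zones).
    """
    rng = np.random.default_rng(seed)
    fit = fitness[(fitness["condition"] == condition)
                  & (fitness["form"] == "spore")]
    fit = fit.sort_values("species_id").reset_index(drop=True)
    pct = fit["fitness"].rank(pct=True).to_numpy()
    rows = []
    for i, r in fit.iterrows():
        z = 1.0 + 4.0 * pct[i] + rng.normal(0.0, noise_sd)
        zi = int(np.clip(round(z), 1, 5)) - 1
        zones = [ZONES[zi]]
        if zi > 0 and rng.random() < range_probability:
            # ranges reach a warm zone drawn independently of fitness: most
            # species occur in the (sub)tropics regardless of cold hardiness
            warm = min(int(rng.integers(0, 3)), zi)
            zones = [ZONES[j] for j in range(warm, zi + 1)]
        rows.append((r["species_id"], r["taxon_group"], ";".join(zones)))
    return pd.DataFrame(rows, columns=["species_id", "taxon_group", "zones"])


# ---------------------------------------------------------------------------
# Chronology simulation
# ---------------------------------------------------------------------------

@dataclass
class ChronoSimConfig:
    """Configuration of the dated-tree / branch-length simulator.

    Ages are in units of 100 My; rates in substitutions per site per 100 My.
    """

    n_tips: int = 8
    root_age: float = 5.0
    mu: float = 0.1
    sigma2: float = 0.1
    obs_variance: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tips < 2:
            raise ValueError("need at least 2 tips")
        if not self.root_age > 0:
            raise ValueError("root age must be > 0")
        if self.sigma2 < 0:
            raise ValueError("rate variance must be >= 0")
        if self.obs_variance < 0:
            raise ValueError("observation noise variance must be >= 0")


def sample_lognormal_rates(rng, mu: float, sigma2: float, size: int) -> np.ndarray:
    """Mean-preserving log-normal rates: log r ~ N(log mu - sigma2/2, sigma2)."""
    if sigma2 == 0:
        return np.full(size, float(mu))
    m = math.log(mu) - sigma2 / 2.0
    return rng.lognormal(m, math.sqrt(sigma2), size=size)


def gen_chronology(config: ChronoSimConfig | None = None,
                   truncate: bool = True
                   ) -> tuple[TimeTree, dict[str, float], pd.DataFrame]:
    """Simulate a dated tree, branch rates, and noisy branch-length data.

    Topology is a random coalescent-style merge; internal ages are ordered
    uniforms scaled so the root sits at ``root_age``.  Each branch gets an
    independent mean-preserving log-normal rate; the observed length is
    rate x duration plus Gaussian noise (truncated at zero unless
    ``truncate=False``).

    Returns (tree, rates keyed by child-node label, BranchData frame with
    columns branch_id / length / variance).
    """
    cfg = config if config is not None else ChronoSimConfig()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_tips
    ages = np.sort(rng.uniform(0.0, 1.0, size=n - 1))
    ages = ages * (cfg.root_age / ages[-1])

    lineages = [(f"t{i+1}", 0.0) for i in range(n)]
    children: dict[str, list[str]] = {}
    node_age: dict[str, float] = {lab: 0.0 for lab, _ in lineages}
    for j, age in enumerate(ages):
        i1, i2 = sorted(rng.choice(len(lineages), size=2, replace=False))
        (a_lab, _), (b_lab, _) = lineages[i1], lineages[i2]
        lab = f"n{j+1}"
        children[lab] = [a_lab, b_lab]
        node_age[lab] = float(age)
        lineages[i1] = (lab, float(age))
        del lineages[i2]
    root = lineages[0][0]
    tree = TimeTree.from_children(root, children, node_age)

    branch_ids = [lab for lab in tree.labels if lab != root]
    rates_arr = sample_lognormal_rates(rng, cfg.mu, cfg.sigma2, len(branch_ids))
    rates = dict(zip(branch_ids, rates_arr.tolist()))
    var = cfg.obs_variance if cfg.obs_variance > 0 else 1e-6
    rows = []
    for lab, r in rates.items():
        dur = tree.age(tree.parent_label(lab)) - tree.age(lab)
        obs = r * dur
        if cfg.obs_variance > 0:
            obs = obs + rng.normal(0.0, math.sqrt(cfg.obs_variance))
            if truncate:
                obs = max(0.0, obs)
        rows.append((lab, float(obs), var))
    data = pd.DataFrame(rows, columns=["branch_id", "length", "variance"])
    return tree, rates, data
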