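"""The generators: determinism, statistical structure, built-in contrasts."""

import math

import numpy as np
import pandas as pd
import pytest

from dictyfit import synthetic as syn


# ---------------------------------------------------------------------------
# determinism
# ---------------------------------------------------------------------------


def test_generators_deterministic_under_fixed_seed():
    a = syn.gen_survival(syn.SurvivalSimConfig(seed=1))
    b = syn.gen_survival(syn.SurvivalSimConfig(seed=1))
    pd.testing.assert_frame_equal(a, b)
    assert a.to_csv() == b.to_csv()

    pd.testing.assert_frame_equal(syn.gen_morphometry(seed=2),
                                  syn.gen_morphometry(seed=2))
    pd.testing.assert_frame_equal(syn.gen_ecology(seed=3),
                                  syn.gen_ecology(seed=3))
    t1, r1, d1 = syn.gen_chronology(syn.ChronoSimConfig(seed=4))
    t2, r2, d2 = syn.gen_chronology(syn.ChronoSimConfig(seed=4))
    assert t1.to_newick() == t2.to_newick()
    assert r1 == r2
    pd.testing.assert_frame_equal(d1, d2)


def test_different_seed_changes_counts():
    a = syn.gen_survival(syn.SurvivalSimConfig(seed=1))
    b = syn.gen_survival(syn.SurvivalSimConfig(seed=2))
    assert not a["plaque_count"].equals(b["plaque_count"])


# ---------------------------------------------------------------------------
# survival generator
# ---------------------------------------------------------------------------


def test_survival_probability_day_zero_is_one():
    for tau, k, s_inf in [(1.0, 1.0, 0.0), (500.0, 0.7, 0.4), (math.inf, 1.0, 1.0)]:
        assert syn.survival_probability(0, tau, k, s_inf) == 1.0


def test_counts_never_exceed_cells_plated(survival_table):
    plated = survival_table["cells_per_ml"] * survival_table["volume_ul"] / 1000
    assert (survival_table["plaque_count"] <= plated).all()


def test_cysts_dead_within_days_of_dry_frost(survival_table):
    sub = survival_table[(survival_table["form"] == "cyst")
                         & (survival_table["condition"] == "m20C_dry")
                         & (survival_table["day"] >= 7)]
    assert len(sub) > 0
    assert sub["plaque_count"].mean() < 1.0
    # the generating survival probability itself is < 1% from day 7 on
    tau, k, s_inf = syn._CYST_PARAMS["m20C_dry"]
    assert syn.survival_probability(7, tau, k, s_inf) < 0.01


def test_no_decay_full_plateau_yields_all_cells():
    decay = {(g, f, c): (math.inf, 1.0, 1.0)
             for g in ("1", "2", "3", "4", "minor")
             for f in ("spore", "cyst") for c in syn.CONDITIONS}
    cfg = syn.SurvivalSimConfig(species=[("sp1", "1")], cyst_formers=(),
                                conditions=("22C_wet",), schedule=(0, 1),
                                volumes_ul={0: 10, 1: 10}, decay=decay,
                                replicates=10000, seed=0,
                                species_tau_cv=0.0, species_plateau_cv=0.0)
    df = syn.gen_survival(cfg)
    # S(t)=1 with 100 cells plated: every count is exactly the binomial mean
    assert (df["plaque_count"] == 100).all()


def test_survival_group4_has_largest_frost_half_life():
    decay = syn.default_decay_parameters()
    for cond in ("m20C_wet", "m20C_dry"):
        taus = {g: decay[(g, "spore", cond)][0] for g in ("1", "2", "3", "4")}
        assert max(taus, key=taus.get) == "4"
        assert min(taus, key=taus.get) in ("1", "3")


def test_survival_config_validation():
    with pytest.raises(ValueError, match="condition"):
        syn.SurvivalSimConfig(conditions=("30C_wet",))
    with pytest.raises(ValueError, match="replicate"):
        syn.SurvivalSimConfig(replicates=2.5)
    with pytest.raises(ValueError, match="schedule"):
        syn.SurvivalSimConfig(schedule=(1, 7))
    bad = syn.default_decay_parameters()
    bad[("1", "spore", "22C_wet")] = (-1.0, 1.0, 0.0)
    with pytest.raises(ValueError, match="tau"):
        syn.SurvivalSimConfig(decay=bad)


# ---------------------------------------------------------------------------
# morphometry generator
# ---------------------------------------------------------------------------


def test_morphometry_group_wall_contrasts(morphometry_table):
    walls = morphometry_table.groupby("taxon_group")["wall_total_width"].mean()
    assert walls.idxmax() == "2"
    assert walls.idxmin() == "3"


def test_morphometry_zero_dispersion_is_degenerate():
    profiles = syn.default_morphometry_profiles()
    for g in profiles:
        profiles[g] = {f: (m, 0.0) for f, (m, d) in profiles[g].items()}
    df = syn.gen_morphometry(profiles, n_cells_per_species=5, seed=0,
                             species=[("sp1", "2")])
    prof = profiles["2"]
    for feat in ("wall_layer2_width", "mito_crenate_fraction"):
        assert np.allclose(df[feat], prof[feat][0])
    assert np.allclose(df["wall_total_width"],
                       prof["wall_layer1_width"][0]
                       + prof["wall_layer2_width"][0]
                       + prof["wall_layer3_width"][0])


def test_morphometry_missing_feature_rejected():
    profiles = syn.default_morphometry_profiles()
    del profiles["1"]["wall_gray"]
    with pytest.raises(ValueError, match="missing features"):
        syn.gen_morphometry(profiles)


def test_morphometry_fractions_in_unit_interval(morphometry_table):
    for col in ("mito_crenate_fraction", "mito_closed_cristae_fraction",
                "granules_polar_fraction"):
        assert morphometry_table[col].between(0, 1).all()


# ---------------------------------------------------------------------------
# ecology generator
# ---------------------------------------------------------------------------


def test_ecology_deterministic_group4_counts():
    recs = syn.gen_ecology(deterministic=True)
    g4 = recs[recs["taxon_group"] == "4"]
    assert len(g4) == 27
    coldest = g4["zones"].str.split(";").str[-1]
    assert (coldest == "arctic/alpine").sum() == 5
    assert len(recs) == 85


def test_ecology_zone_counts_sum_to_group_size():
    recs = syn.gen_ecology(deterministic=True)
    sizes = recs.groupby("taxon_group").size().to_dict()
    assert sizes == syn.DEFAULT_GROUP_SIZES


def test_ecology_empty_group_ok():
    recs = syn.gen_ecology(group_sizes={"1": 0, "4": 3}, deterministic=True,
                           zone_probabilities={"1": (1, 0, 0, 0, 0),
                                               "4": (0, 0, 1, 0, 0)})
    assert set(recs["taxon_group"]) == {"4"}


def test_ecology_validation():
    with pytest.raises(ValueError, match="negative"):
        syn.gen_ecology(group_sizes={"1": -1},
                        zone_probabilities={"1": (1, 0, 0, 0, 0)})
    with pytest.raises(ValueError, match="sum"):
        syn.gen_ecology(group_sizes={"1": 5},
                        zone_probabilities={"1": (0.5, 0.1, 0, 0, 0)})


def test_ecology_sampled_frequencies_match_probabilities():
    """Empirical coldest-zone frequencies over 10 000 draws lie within 3 SE."""
    p = (0.1, 0.2, 0.4, 0.2, 0.1)
    n = 10_000
    recs = syn.gen_ecology(group_sizes={"1": n}, zone_probabilities={"1": p},
                           seed=11, range_probability=0.0)
    coldest = recs["zones"].str.split(";").str[-1]
    for zone, prob in zip(syn.ZONES, p):
        freq = (coldest == zone).mean()
        se = math.sqrt(prob * (1 - prob) / n)
        assert abs(freq - prob) < 3 * se


# ---------------------------------------------------------------------------
# chronology generator
# ---------------------------------------------------------------------------


def test_strict_clock_limit_is_ultrametric():
    cfg = syn.ChronoSimConfig(n_tips=10, root_age=4.0, mu=0.1, sigma2=0.0,
                              obs_variance=0.0, seed=5)
    tree, rates, data = syn.gen_chronology(cfg)
    assert all(r == pytest.approx(0.1) for r in rates.values())
    # every root-to-tip path in expected substitutions = mu * root age
    lengths = dict(zip(data["branch_id"], data["length"]))
    for tip in tree.tip_labels():
        total, lab = 0.0, tip
        while lab != tree.root_label:
            total += lengths[lab]
            lab = tree.parent_label(lab)
        assert total == pytest.approx(0.1 * 4.0, rel=1e-9)


def test_tree_ages_valid():
    for seed in range(5):
        tree, _, _ = syn.gen_chronology(syn.ChronoSimConfig(n_tips=7, seed=seed))
        for b in tree.branch_labels():
            assert tree.age(tree.parent_label(b)) > tree.age(b)
        assert tree.age(tree.root_label) == pytest.approx(5.0)


def test_lognormal_rates_are_mean_preserving(rng):
    draws = syn.sample_lognormal_rates(rng, mu=0.1, sigma2=0.1, size=10_000)
    se = draws.std() / math.sqrt(draws.size)
    assert abs(draws.mean() - 0.1) < 3 * se


def test_chronology_config_validation():
    with pytest.raises(ValueError):
        syn.ChronoSimConfig(sigma2=-0.1)
    with pytest.raises(ValueError):
        syn.ChronoSimConfig(obs_variance=-1.0)
    with pytest.raises(ValueError):
        syn.ChronoSimConfig(root_age=0.0)


# ---------------------------------------------------------------------------
# fitness-coupled climate records
# ---------------------------------------------------------------------------


def test_assign_zones_by_fitness_schema(fitness_table):
    recs = syn.assign_zones_by_fitness(fitness_table, seed=0)
    assert list(recs.columns) == ["species_id", "taxon_group", "zones"]
    n_spore = fitness_table[(fitness_table["form"] == "spore")
                            & (fitness_table["condition"] == "m20C_wet")
                            ]["species_id"].nunique()
    assert len(recs) == n_spore
    for zones in recs["zones"]:
        assert all(z in syn.ZONES for z in zones.split(";"))
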