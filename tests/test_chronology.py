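"""The dating engine: priors, likelihood, sampler, summaries, trees."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import integrate
from scipy import stats as sps

from dictyfit import synthetic as syn
from dictyfit.chronology import (Calibration, ClockModel, McmcSettings,
                                 NodeDatingModel, TimeTree, approx_loglik,
                                 clock_prior_logdensity, expected_branch_lengths,
                                 gamma_logpdf, lognormal_rate_logpdf,
                                 run_dating_mcmc, summarize_chronogram)
from dictyfit.chronology.model import effective_sample_size


# ---------------------------------------------------------------------------
# soft-bound calibrations
# ---------------------------------------------------------------------------


def test_calibration_tail_masses_are_2p5_percent():
    cal = Calibration(node="r", t_min=5.8, t_max=12.3)
    below, _ = integrate.quad(cal.pdf, 1e-9, cal.t_min)
    above, _ = integrate.quad(cal.pdf, cal.t_max, np.inf)
    assert below == pytest.approx(0.025, abs=1e-6)
    assert above == pytest.approx(0.025, abs=1e-6)


def test_calibration_core_density_and_normalization():
    cal = Calibration(node="r", t_min=2.0, t_max=6.0)
    mid = 0.5 * (cal.t_min + cal.t_max)
    assert cal.pdf(mid) == pytest.approx(0.95 / (cal.t_max - cal.t_min))
    total, _ = integrate.quad(cal.pdf, 1e-9, np.inf, limit=200)
    assert total == pytest.approx(1.0, abs=1e-6)
    # continuous at the bounds
    assert cal.pdf(cal.t_min - 1e-9) == pytest.approx(cal.pdf(cal.t_min + 1e-9),
                                                      rel=1e-6)


def test_calibration_cdf_and_sampler_agree(rng):
    cal = Calibration(node="r", t_min=3.0, t_max=8.0)
    draws = cal.sample(rng, 20_000)
    assert (draws > 0).all()
    res = sps.kstest(draws, cal.cdf)
    assert res.statistic < 0.02
    assert (draws < cal.t_min).mean() == pytest.approx(0.025, abs=0.006)
    assert (draws > cal.t_max).mean() == pytest.approx(0.025, abs=0.006)


def test_calibration_validation():
    with pytest.raises(ValueError):
        Calibration(node="r", t_min=5.0, t_max=4.0)
    with pytest.raises(ValueError):
        Calibration(node="r", t_min=1.0, t_max=2.0, tail=0.6)
    cal = Calibration(node="r", t_min=1.0, t_max=2.0)
    with pytest.raises(ValueError):
        cal.logpdf(0.0)


# ---------------------------------------------------------------------------
# clock prior
# ---------------------------------------------------------------------------


def test_gamma_logpdf_matches_scipy():
    for x, shape, rate in [(0.1, 2.0, 20.0), (0.05, 1.0, 10.0), (1.7, 3.5, 0.8)]:
        expect = sps.gamma.logpdf(x, a=shape, scale=1.0 / rate)
        assert gamma_logpdf(x, shape, rate) == pytest.approx(expect, abs=1e-10)


def test_clock_prior_includes_hyperpriors_and_rates():
    model = ClockModel(mu=0.1, sigma2=0.2, rates={"a": 0.08, "b": 0.15})
    lp = clock_prior_logdensity(model)
    expect = (gamma_logpdf(0.1, 2.0, 20.0) + gamma_logpdf(0.2, 1.0, 10.0)
              + lognormal_rate_logpdf(np.array([0.08, 0.15]), 0.1, 0.2))
    assert lp == pytest.approx(expect, abs=1e-12)


def test_prior_rates_are_mean_preserving(rng):
    """Monte-Carlo mean of rates drawn from the prior equals mu."""
    mu, sigma2 = 0.1, 0.3
    m = math.log(mu) - sigma2 / 2.0
    draws = rng.lognormal(m, math.sqrt(sigma2), size=100_000)
    se = draws.std() / math.sqrt(draws.size)
    assert abs(draws.mean() - mu) < 3 * se


def test_sigma2_zero_is_degenerate():
    assert lognormal_rate_logpdf(np.array([0.1, 0.1]), 0.1, 0.0) == math.inf
    assert lognormal_rate_logpdf(np.array([0.1, 0.2]), 0.1, 0.0) == -math.inf


# ---------------------------------------------------------------------------
# expected branch lengths and approximate likelihood
# ---------------------------------------------------------------------------


@pytest.fixture()
def three_tip_tree() -> TimeTree:
    return TimeTree.from_children(
        "r", {"r": ["a", "t3"], "a": ["t1", "t2"]},
        {"r": 2.0, "a": 1.0, "t1": 0.0, "t2": 0.0, "t3": 0.0})


def test_expected_lengths_clock_identity(three_tip_tree):
    rates = {b: 0.1 for b in three_tip_tree.branch_labels()}
    model = ClockModel(mu=0.1, sigma2=0.0, rates=rates)
    lengths = expected_branch_lengths(three_tip_tree, model)
    assert lengths["a"] == pytest.approx(0.1)       # duration 1, rate 0.1
    assert lengths["t3"] == pytest.approx(0.2)
    # strict clock: root-to-tip sums equal mu * root age
    assert lengths["a"] + lengths["t1"] == pytest.approx(0.1 * 2.0)


def test_rate_time_confounding(three_tip_tree):
    rates = {b: 0.1 for b in three_tip_tree.branch_labels()}
    doubled = three_tip_tree.with_ages({"r": 4.0, "a": 2.0})
    halved = {b: 0.05 for b in rates}
    l1 = expected_branch_lengths(three_tip_tree,
                                 ClockModel(mu=0.1, sigma2=0.0, rates=rates))
    l2 = expected_branch_lengths(doubled,
                                 ClockModel(mu=0.05, sigma2=0.0, rates=halved))
    for b in l1:
        assert l1[b] == pytest.approx(l2[b])


def test_missing_rate_rejected(three_tip_tree):
    model = ClockModel(mu=0.1, sigma2=0.0, rates={"a": 0.1})
    with pytest.raises(ValueError, match="missing rates"):
        expected_branch_lengths(three_tip_tree, model)


def test_approx_loglik_values():
    v = {"b1": 0.01}
    assert approx_loglik({"b1": 0.1}, v, {"b1": 0.2}) == pytest.approx(
        -0.5 - 0.5 * math.log(2 * math.pi * 0.01))
    # expected == observed leaves only the normalization term
    assert approx_loglik({"b1": 0.1}, v, {"b1": 0.1}) == pytest.approx(
        -0.5 * math.log(2 * math.pi * 0.01))
    # monotone decrease moving a single expectation away from the observation
    lls = [approx_loglik({"b1": 0.1}, v, {"b1": 0.1 + d})
           for d in (0.0, 0.05, 0.1, 0.2)]
    assert all(a > b for a, b in zip(lls, lls[1:]))
    with pytest.raises(ValueError, match="variance"):
        approx_loglik({"b1": 0.1}, {"b1": 0.0}, {"b1": 0.1})


def test_loglik_variance_scaling_shift():
    """Scaling all variances by c shifts the optimum log-likelihood by
    -n/2 log c."""
    lengths = {"a": 0.1, "b": 0.3, "c": 0.2}
    var = {k: 0.01 for k in lengths}
    var_c = {k: 0.04 for k in lengths}
    l1 = approx_loglik(lengths, var, lengths)
    l2 = approx_loglik(lengths, var_c, lengths)
    assert l2 - l1 == pytest.approx(-0.5 * 3 * math.log(4.0))


# ---------------------------------------------------------------------------
# MCMC sampler
# ---------------------------------------------------------------------------


def test_prior_only_sampling_reproduces_calibration(three_tip_tree):
    cal = Calibration(node="r", t_min=2.0, t_max=6.0)
    chains = run_dating_mcmc(three_tip_tree, [cal], None,
                             McmcSettings(iterations=24_000, burn_in=4_000,
                                          sample_every=2, chains=1, seed=1))
    roots = chains[0].ages[:, chains[0].internal_labels.index("r")]
    assert roots.size == 10_000
    res = sps.kstest(roots, cal.cdf)
    assert res.statistic < 0.05


def test_sampler_refuses_uncalibrated_root(three_tip_tree):
    with pytest.raises(ValueError, match="root"):
        run_dating_mcmc(three_tip_tree,
                        [Calibration(node="a", t_min=0.5, t_max=1.5)],
                        None, McmcSettings())


def test_calibration_on_missing_node_rejected(three_tip_tree):
    with pytest.raises(ValueError, match="non-existent"):
        run_dating_mcmc(three_tip_tree,
                        [Calibration(node="zz", t_min=1, t_max=2)],
                        None, McmcSettings())


def test_strict_clock_root_recovery():
    cfg = syn.ChronoSimConfig(n_tips=8, root_age=5.0, mu=0.1, sigma2=0.0,
                              obs_variance=0.0, seed=3)
    tree, _, data = syn.gen_chronology(cfg)
    cal = Calibration(node=tree.root_label, t_min=3.0, t_max=7.0)
    model = NodeDatingModel(tree=tree, calibrations=[cal], branch_data=data)
    res = model.fit(McmcSettings(iterations=30_000, burn_in=6_000,
                                 sample_every=8, chains=1, seed=11))
    root_mean = res.posterior_mean_ages[tree.root_label]
    assert abs(root_mean - 5.0) / 5.0 < 0.10
    # the inferred overall rate ~ total length / total duration
    assert res.posterior_mu == pytest.approx(0.1, rel=0.25)


def test_two_chains_agree(three_tip_tree):
    cal = Calibration(node="r", t_min=2.0, t_max=6.0)
    rng = np.random.default_rng(2)
    data = pd.DataFrame({"branch_id": three_tip_tree.branch_labels()})
    data["length"] = [0.1 * (three_tip_tree.age(three_tip_tree.parent_label(b))
                             - three_tip_tree.age(b)) for b in data["branch_id"]]
    data["variance"] = 1e-4
    model = NodeDatingModel(tree=three_tip_tree, calibrations=[cal],
                            branch_data=data)
    res = model.fit(McmcSettings(iterations=16_000, burn_in=4_000,
                                 sample_every=4, chains=2, seed=5))
    assert res.convergence["converged"]
    assert res.convergence["relative_discrepancy"] < 0.02


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------


def test_identical_chains_converge_exactly(three_tip_tree):
    cal = Calibration(node="r", t_min=2.0, t_max=6.0)
    chain = run_dating_mcmc(three_tip_tree, [cal], None,
                            McmcSettings(iterations=4_000, burn_in=1_000,
                                         sample_every=4, chains=1, seed=9))[0]
    summary, report = summarize_chronogram([chain, chain])
    assert report["converged"]
    assert report["max_mean_discrepancy"] == 0.0
    assert set(summary.index) == {"r", "a"}


def test_hpd_of_uniform_marginal_close_to_central_interval(rng):
    u = rng.uniform(2.0, 6.0, size=5_000)
    from dictyfit.stats import hpd_interval
    lo, hi = hpd_interval(u, mass=0.95)
    assert lo == pytest.approx(np.quantile(u, 0.025), abs=0.15)
    assert hi == pytest.approx(np.quantile(u, 0.975), abs=0.15)


def test_ess_detects_correlation(rng):
    iid = rng.normal(size=2_000)
    assert effective_sample_size(iid) > 1_000
    walk = np.cumsum(rng.normal(size=2_000))
    assert effective_sample_size(walk) < 200


def test_unequal_chains_rejected(three_tip_tree):
    cal = Calibration(node="r", t_min=2.0, t_max=6.0)
    chain = run_dating_mcmc(three_tip_tree, [cal], None,
                            McmcSettings(iterations=3_000, burn_in=1_000,
                                         sample_every=4, chains=1, seed=9))[0]
    other = run_dating_mcmc(
        TimeTree.from_children("r", {"r": ["t1", "t2"]},
                               {"r": 3.0, "t1": 0.0, "t2": 0.0}),
        [cal], None,
        McmcSettings(iterations=3_000, burn_in=1_000, sample_every=4,
                     chains=1, seed=9))[0]
    with pytest.raises(ValueError, match="parameterization"):
        summarize_chronogram([chain, other])


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------


def test_annotated_chronogram_round_trips(three_tip_tree):
    cal = Calibration(node="r", t_min=1.5, t_max=4.0)
    model = NodeDatingModel(tree=three_tip_tree, calibrations=[cal])
    res = model.fit(McmcSettings(iterations=6_000, burn_in=2_000,
                                 sample_every=4, chains=2, seed=3))
    newick = res.annotated_tree()
    assert "|age=" in newick and "|hpd=" in newick
    back = TimeTree.from_newick(newick)
    for lab in ("r", "a"):
        assert back.age(lab) == pytest.approx(
            res.posterior_mean_ages[lab], rel=1e-4)


def test_newick_round_trip_plain(three_tip_tree):
    back = TimeTree.from_newick(three_tip_tree.to_newick())
    for lab in three_tip_tree.labels:
        assert back.age(lab) == pytest.approx(three_tip_tree.age(lab), abs=1e-9)


def test_time_tree_rejects_inverted_ages():
    with pytest.raises(ValueError, match="younger"):
        TimeTree.from_children("r", {"r": ["a", "t2"], "a": ["t1", "t3"]},
                               {"r": 1.0, "a": 2.0, "t1": 0, "t2": 0, "t3": 0})
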