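"""Metropolis-within-Gibbs sampler for node ages, branch rates and clock
hyperparameters.

Moves per sweep: a sliding-window proposal on each internal node age
(respecting parent > child ordering), an independent multiplier proposal on
every branch rate (valid as a parallel block because rates are conditionally
independent given ages and hyperparameters), and multiplier proposals on mu
and sigma2.  Step sizes are auto-tuned during burn-in toward 20-40%
acceptance.  With no branch data the sampler targets the prior alone.

The prior over node ages is the product of soft-bound calibration densities
with, for uncalibrated nodes, a flat density over the order polytope below
the root, normalized by root^-m (m = number of free non-root internal
ages).  The normalization makes the marginal prior of the root equal its
calibration density on any topology.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .priors import (MU_HYPERPRIOR, SIGMA2_HYPERPRIOR, Calibration,
                     gamma_logpdf)
from .tree import TimeTree


@dataclass
class McmcSettings:
    """Chain-length and proposal settings for the dating sampler."""

    iterations: int = 6000
    burn_in: int = 2000
    sample_every: int = 5
    chains: int = 2
    seed: int = 0
    age_step: float = 0.5
    rate_step: float = 0.4
    hyper_step: float = 0.4

    def __post_init__(self) -> None:
        if self.burn_in >= self.iterations:
            raise ValueError("burn-in must be smaller than iterations")
        if self.sample_every < 1:
            raise ValueError("sampling interval must be >= 1")
        if self.chains < 1:
            raise ValueError("need at least one chain")


@dataclass
class ChainSamples:
    """Thinned post-burn-in samples from one chain."""

    internal_labels: list[str]
    branch_labels: list[str]
    ages: np.ndarray      # (n_samples, n_internal)
    rates: np.ndarray     # (n_samples, n_branches)
    mu: np.ndarray
    sigma2: np.ndarray
    acceptance: dict = field(default_factory=dict)

    def ages_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.ages, columns=self.internal_labels)


def run_dating_mcmc(tree: TimeTree,
                    calibrations: list[Calibration],
                    branch_data: pd.DataFrame | None,
                    settings: McmcSettings,
                    mu_hyperprior=MU_HYPERPRIOR,
                    sigma2_hyperprior=SIGMA2_HYPERPRIOR) -> list[ChainSamples]:
    """Run ``settings.chains`` independent chains; per-chain seeds derive
    from the master seed.

    ``branch_data`` is a frame with columns branch_id / length / variance
    (branch_id = child-node label), or None for prior-only sampling.  The
    root must carry a calibration: without an age ceiling the node ages are
    unidentifiable and the run is refused.
    """
    cal_by_node = {c.node: c for c in calibrations}
    for c in calibrations:
        if c.node not in tree.index:
            raise ValueError(f"calibration on non-existent node {c.node!r}")
    if tree.root_label not in cal_by_node:
        raise ValueError("the root must be calibrated: no age ceiling, "
                         "node ages are unidentifiable")

    seeds = np.random.SeedSequence(settings.seed).spawn(settings.chains)
    return [_run_chain(tree, cal_by_node, branch_data, settings,
                       np.random.default_rng(s), mu_hyperprior,
                       sigma2_hyperprior)
            for s in seeds]


def _run_chain(tree, cal_by_node, branch_data, st, rng,
               mu_hyper, sigma2_hyper) -> ChainSamples:
    n = len(tree.labels)
    parent = tree.parent
    internal = [i for i in range(n) if tree.children[i]]
    root = tree.root
    free_internal = [i for i in internal if i != root]
    m_free = len(free_internal)

    branch_nodes = [i for i in range(n) if i != root]       # child node per branch
    branch_pos = {i: b for b, i in enumerate(branch_nodes)}
    bparent = np.array([parent[i] for i in branch_nodes])
    bchild = np.array(branch_nodes)

    if branch_data is not None:
        by_id = dict(zip(branch_data["branch_id"], zip(branch_data["length"],
                                                       branch_data["variance"])))
        missing = [tree.labels[i] for i in branch_nodes if tree.labels[i] not in by_id]
        if missing:
            raise ValueError(f"branch data missing for: {missing}")
        obs = np.array([by_id[tree.labels[i]][0] for i in branch_nodes])
        var = np.array([by_id[tree.labels[i]][1] for i in branch_nodes])
        if np.any(var <= 0):
            raise ValueError("branch-length variances must be > 0")
    else:
        obs = var = None

    cals = {tree.index[lab]: c for lab, c in cal_by_node.items()}

    # --- initial state ------------------------------------------------------
    root_cal = cals[root]
    ages = np.zeros(n)
    height = np.zeros(n, dtype=int)
    for i in reversed(range(n)):            # labels are preorder: reverse is postorder
        kids = tree.children[i]
        height[i] = 1 + max((height[k] for k in kids), default=-1)
    root_init = 0.5 * (root_cal.t_min + root_cal.t_max)
    if obs is not None:
        # align initial ages with the data under a rough clock: node depth in
        # substitutions scaled to the calibration midpoint
        sub_depth = np.zeros(n)
        for i in reversed(range(n)):
            kids = tree.children[i]
            if kids:
                sub_depth[i] = max(sub_depth[k] + max(obs[branch_pos[k]], 1e-4)
                                   for k in kids)
        for i in internal:
            ages[i] = root_init * sub_depth[i] / sub_depth[root]
    else:
        for i in internal:
            ages[i] = root_init * height[i] / height[root]

    durations = ages[bparent] - ages[bchild]
    if obs is not None:
        mu = max(1e-6, float(obs.sum() / durations.sum()))
        rates = np.maximum(obs / durations, mu * 1e-3)
    else:
        mu = mu_hyper[0] / mu_hyper[1]
        rates = np.full(len(branch_nodes), mu)
    sigma2 = 0.05

    # adjacency for incremental likelihood updates
    adj_branches = {i: [] for i in internal}
    for b, child in enumerate(branch_nodes):
        if child in adj_branches:
            adj_branches[child].append(b)
        p = parent[child]
        adj_branches[p].append(b)

    def branch_loglik(b, dur) -> float:
        if obs is None:
            return 0.0
        e = rates[b] * dur
        return -((obs[b] - e) ** 2) / (2.0 * var[b])

    def rate_logprior_terms(r, mu_, s2_):
        lr = np.log(r)
        mloc = math.log(mu_) - s2_ / 2.0
        return -lr - 0.5 * math.log(2.0 * math.pi * s2_) - (lr - mloc) ** 2 / (2.0 * s2_)

    age_step = np.full(n, st.age_step * root_init / max(1, height[root]))
    rate_step = st.rate_step
    mu_step = st.hyper_step
    s2_step = st.hyper_step

    scale_step = 0.2
    acc = {"age": np.zeros(n), "age_try": np.zeros(n),
           "rate": 0.0, "rate_try": 0.0,
           "mu": 0, "mu_try": 0, "s2": 0, "s2_try": 0,
           "scale": 0, "scale_try": 0}

    keep = (st.iterations - st.burn_in) // st.sample_every
    out_ages = np.empty((keep, len(internal)))
    out_rates = np.empty((keep, len(branch_nodes)))
    out_mu = np.empty(keep)
    out_s2 = np.empty(keep)
    k = 0

    children = tree.children
    for it in range(st.iterations):
        # --- node ages ------------------------------------------------------
        for i in internal:
            t_old = ages[i]
            t_new = t_old + rng.uniform(-age_step[i], age_step[i])
            lo = max((ages[c] for c in children[i]), default=0.0)
            hi = ages[parent[i]] if i != root else math.inf
            acc["age_try"][i] += 1
            if not lo < t_new < hi:
                continue
            delta = 0.0
            if i in cals:
                delta += cals[i].logpdf(t_new) - cals[i].logpdf(t_old)
            if i == root and m_free:
                delta += -m_free * (math.log(t_new) - math.log(t_old))
            if obs is not None:
                for b in adj_branches[i]:
                    d_old = ages[bparent[b]] - ages[bchild[b]]
                    # branch above i shortens as i ages; branches below lengthen
                    d_new = d_old + (t_new - t_old) * (-1 if bchild[b] == i else 1)
                    delta += branch_loglik(b, d_new) - branch_loglik(b, d_old)
            if delta >= 0 or rng.random() < math.exp(delta):
                ages[i] = t_new
                acc["age"][i] += 1

        # --- compensated age moves: shift one node age, rescale adjacent
        # branch rates to hold expected lengths (likelihood-invariant) -------
        for i in internal:
            t_old = ages[i]
            t_new = t_old + rng.uniform(-age_step[i], age_step[i])
            lo = max((ages[c] for c in children[i]), default=0.0)
            hi = ages[parent[i]] if i != root else math.inf
            if not lo < t_new < hi:
                continue
            adj = adj_branches[i]
            d_old_v = np.array([ages[bparent[b]] - ages[bchild[b]] for b in adj])
            sign = np.array([-1.0 if bchild[b] == i else 1.0 for b in adj])
            d_new_v = d_old_v + (t_new - t_old) * sign
            if np.any(d_new_v <= 0):
                continue
            factors = d_old_v / d_new_v
            r_old_v = rates[adj]
            r_new_v = r_old_v * factors
            delta = float(np.sum(rate_logprior_terms(r_new_v, mu, sigma2)
                                 - rate_logprior_terms(r_old_v, mu, sigma2)))
            delta += float(np.sum(np.log(factors)))  # Jacobian
            if i in cals:
                delta += cals[i].logpdf(t_new) - cals[i].logpdf(t_old)
            if i == root and m_free:
                delta += -m_free * (math.log(t_new) - math.log(t_old))
            if delta >= 0 or rng.random() < math.exp(delta):
                ages[i] = t_new
                rates[adj] = r_new_v

        # --- branch rates (parallel multiplier moves) -----------------------
        eps = rng.uniform(-rate_step, rate_step, size=rates.size)
        r_new = rates * np.exp(eps)
        dur = ages[bparent] - ages[bchild]
        delta = (rate_logprior_terms(r_new, mu, sigma2)
                 - rate_logprior_terms(rates, mu, sigma2) + eps)
        if obs is not None:
            delta += (-(obs - r_new * dur) ** 2 + (obs - rates * dur) ** 2) / (2.0 * var)
        accept = np.log(rng.uniform(size=rates.size)) < delta
        rates[accept] = r_new[accept]
        acc["rate"] += accept.mean()
        acc["rate_try"] += 1

        # --- joint scale move: ages * c, rates / c (likelihood-invariant) ---
        e = rng.uniform(-scale_step, scale_step)
        c = math.exp(e)
        acc["scale_try"] += 1
        r_new = rates / c
        delta = float(np.sum(rate_logprior_terms(r_new, mu, sigma2)
                             - rate_logprior_terms(rates, mu, sigma2)))
        for i, cal_i in cals.items():
            if tree.children[i]:
                delta += cal_i.logpdf(ages[i] * c) - cal_i.logpdf(ages[i])
        if m_free:
            delta += -m_free * e
        delta += (len(internal) - rates.size) * e  # multiplier Jacobians
        if delta >= 0 or rng.random() < math.exp(delta):
            ages[internal] *= c
            rates = r_new
            acc["scale"] += 1

        # --- extended scale move: ages * c, rates / c, mu / c ---------------
        # travels the full rate-time ridge (likelihood and, nearly, the rate
        # prior are invariant); only the calibrations and the mu hyperprior
        # resist, which is exactly the posterior's slow direction
        e = rng.uniform(-scale_step, scale_step)
        c = math.exp(e)
        acc["scale_try"] += 1
        r_new = rates / c
        mu_new = mu / c
        delta = float(np.sum(rate_logprior_terms(r_new, mu_new, sigma2)
                             - rate_logprior_terms(rates, mu, sigma2)))
        delta += gamma_logpdf(mu_new, *mu_hyper) - gamma_logpdf(mu, *mu_hyper)
        for i, cal_i in cals.items():
            if tree.children[i]:
                delta += cal_i.logpdf(ages[i] * c) - cal_i.logpdf(ages[i])
        if m_free:
            delta += -m_free * e
        delta += (len(internal) - rates.size - 1) * e  # multiplier Jacobians
        if delta >= 0 or rng.random() < math.exp(delta):
            ages[internal] *= c
            rates = r_new
            mu = mu_new
            acc["scale"] += 1

        # --- hyperparameters ------------------------------------------------
        for name in ("mu", "s2"):
            step = mu_step if name == "mu" else s2_step
            x_old = mu if name == "mu" else sigma2
            e = rng.uniform(-step, step)
            x_new = x_old * math.exp(e)
            hyper = mu_hyper if name == "mu" else sigma2_hyper
            delta = gamma_logpdf(x_new, *hyper) - gamma_logpdf(x_old, *hyper) + e
            if name == "mu":
                delta += float(np.sum(rate_logprior_terms(rates, x_new, sigma2)
                                      - rate_logprior_terms(rates, x_old, sigma2)))
            else:
                delta += float(np.sum(rate_logprior_terms(rates, mu, x_new)
                                      - rate_logprior_terms(rates, mu, x_old)))
            acc[f"{name}_try"] += 1
            if delta >= 0 or rng.random() < math.exp(delta):
                if name == "mu":
                    mu = x_new
                else:
                    sigma2 = x_new
                acc[name] += 1

        # --- burn-in step-size adaptation -----------------------------------
        if it < st.burn_in and (it + 1) % 100 == 0:
            for i in internal:
                if acc["age_try"][i]:
                    r = acc["age"][i] / acc["age_try"][i]
                    if r > 0.4:
                        age_step[i] *= 1.4
                    elif r < 0.2:
                        age_step[i] /= 1.4
            rr = acc["rate"] / max(1, acc["rate_try"])
            if rr > 0.4:
                rate_step *= 1.4
            elif rr < 0.2:
                rate_step /= 1.4
            if acc["mu_try"]:
                r = acc["mu"] / acc["mu_try"]
                mu_step *= 1.4 if r > 0.4 else (1 / 1.4 if r < 0.2 else 1.0)
                r = acc["s2"] / acc["s2_try"]
                s2_step *= 1.4 if r > 0.4 else (1 / 1.4 if r < 0.2 else 1.0)
                r = acc["scale"] / acc["scale_try"]
                scale_step *= 1.4 if r > 0.4 else (1 / 1.4 if r < 0.2 else 1.0)
            for key in ("rate", "mu", "s2", "scale"):
                acc[key] = 0
                acc[f"{key}_try"] = 0
            acc["age"][:] = 0
            acc["age_try"][:] = 0

        if it >= st.burn_in and (it - st.burn_in) % st.sample_every == 0 and k < keep:
            out_ages[k] = ages[internal]
            out_rates[k] = rates
            out_mu[k] = mu
            out_s2[k] = sigma2
            k += 1

    acceptance = {
        "age": float(np.mean(acc["age"][internal] / np.maximum(1, acc["age_try"][internal]))),
        "rate": acc["rate"] / max(1, acc["rate_try"]),
        "mu": acc["mu"] / max(1, acc["mu_try"]),
        "sigma2": acc["s2"] / max(1, acc["s2_try"]),
        "scale": acc["scale"] / max(1, acc["scale_try"]),
    }
    return ChainSamples(
        internal_labels=[tree.labels[i] for i in internal],
        branch_labels=[tree.labels[i] for i in branch_nodes],
        ages=out_ages[:k], rates=out_rates[:k],
        mu=out_mu[:k], sigma2=out_s2[:k], acceptance=acceptance)
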