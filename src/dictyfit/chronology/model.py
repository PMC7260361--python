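"""Model/Results interface for Bayesian node dating.

`NodeDatingModel` bundles a fixed rooted topology, soft-bound fossil
calibrations and (optionally) approximate branch-length data;
``fit()`` runs the MCMC and returns a `NodeDatingResults` carrying posterior
samples, per-node summaries (posterior mean age, 95% HPD), effective sample
sizes and a two-chain convergence report.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..stats import hpd_interval
from .mcmc import ChainSamples, McmcSettings, run_dating_mcmc
from .priors import MU_HYPERPRIOR, SIGMA2_HYPERPRIOR, Calibration
from .tree import TimeTree


def effective_sample_size(x: np.ndarray) -> float:
    """ESS from FFT autocovariance with a Geyer initial-positive-sequence cut."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 4 or np.ptp(x) == 0:
        return float(n)
    xc = x - x.mean()
    nfft = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(xc, nfft)
    acov = np.fft.irfft(f * np.conj(f), nfft)[:n].real / n
    rho = acov / acov[0]
    tau = 1.0
    for k in range(1, n // 2):
        pair = rho[2 * k - 1] + rho[2 * k]
        if pair < 0:
            break
        tau += 2.0 * pair
    return float(min(n, n / max(tau, 1.0)))


def summarize_chronogram(chains: list[ChainSamples], mass: float = 0.95,
                         rel_tol: float = 0.02) -> tuple[pd.DataFrame, dict]:
    """Pooled posterior means, HPD intervals and a convergence report.

    Convergence compares per-chain posterior mean ages; the run passes if
    every node's between-chain spread is below ``rel_tol`` of the pooled
    posterior mean root age (the model's time scale).
    """
    if len(chains) < 2:
        raise ValueError("need at least two chains for a convergence report")
    labels = chains[0].internal_labels
    for c in chains[1:]:
        if c.internal_labels != labels or c.branch_labels != chains[0].branch_labels:
            raise ValueError("chains have unequal parameterization")

    pooled = np.vstack([c.ages for c in chains])
    rows = []
    for j, lab in enumerate(labels):
        lo, hi = hpd_interval(pooled[:, j], mass=mass)
        ess = sum(effective_sample_size(c.ages[:, j]) for c in chains)
        rows.append({"node": lab, "mean_age": float(pooled[:, j].mean()),
                     "hpd_low": lo, "hpd_high": hi, "ess": ess})
    summary = pd.DataFrame(rows).set_index("node")

    chain_means = np.vstack([c.ages.mean(axis=0) for c in chains])
    spread = chain_means.max(axis=0) - chain_means.min(axis=0)
    scale = float(summary["mean_age"].max())  # root is the oldest node
    report = {
        "chain_mean_ages": pd.DataFrame(chain_means, columns=labels),
        "max_mean_discrepancy": float(spread.max()),
        "relative_discrepancy": float(spread.max() / scale) if scale > 0 else 0.0,
        "converged": bool(spread.max() <= rel_tol * scale),
    }
    return summary, report


@dataclass
class NodeDatingModel:
    """Relaxed-clock node-dating model on a fixed rooted topology."""

    tree: TimeTree
    calibrations: list[Calibration]
    branch_data: pd.DataFrame | None = None
    mu_hyperprior: tuple[float, float] = MU_HYPERPRIOR
    sigma2_hyperprior: tuple[float, float] = SIGMA2_HYPERPRIOR

    @classmethod
    def from_files(cls, newick_path: str, calibrations_path: str,
                   branch_data_path: str | None = None) -> "NodeDatingModel":
        """Build from a Newick topology, a calibration CSV
        (node_label, t_min, t_max[, tail]) and an optional branch-data CSV
        (branch_id, length, variance)."""
        with open(newick_path) as fh:
            tree = TimeTree.from_newick(fh.read())
        cal_df = pd.read_csv(calibrations_path)
        cals = [Calibration(node=str(r.node_label), t_min=float(r.t_min),
                            t_max=float(r.t_max),
                            tail=float(getattr(r, "tail", 0.025)))
                for r in cal_df.itertuples()]
        data = pd.read_csv(branch_data_path) if branch_data_path else None
        return cls(tree=tree, calibrations=cals, branch_data=data)

    def fit(self, settings: McmcSettings | None = None) -> "NodeDatingResults":
        st = settings if settings is not None else McmcSettings()
        chains = run_dating_mcmc(self.tree, self.calibrations,
                                 self.branch_data, st,
                                 mu_hyperprior=self.mu_hyperprior,
                                 sigma2_hyperprior=self.sigma2_hyperprior)
        return NodeDatingResults(model=self, settings=st, chains=chains)


@dataclass
class NodeDatingResults:
    """Posterior summaries of a node-dating run."""

    model: NodeDatingModel
    settings: McmcSettings
    chains: list[ChainSamples]

    def __post_init__(self) -> None:
        if len(self.chains) >= 2:
            self._summary, self.convergence = summarize_chronogram(self.chains)
        else:  # single-chain fits carry summaries without a convergence report
            c = self.chains[0]
            rows = []
            for j, lab in enumerate(c.internal_labels):
                lo, hi = hpd_interval(c.ages[:, j])
                rows.append({"node": lab, "mean_age": float(c.ages[:, j].mean()),
                             "hpd_low": lo, "hpd_high": hi,
                             "ess": effective_sample_size(c.ages[:, j])})
            self._summary = pd.DataFrame(rows).set_index("node")
            self.convergence = None

    @property
    def posterior_mean_ages(self) -> pd.Series:
        return self._summary["mean_age"]

    def hpd(self, node: str) -> tuple[float, float]:
        row = self._summary.loc[node]
        return float(row["hpd_low"]), float(row["hpd_high"])

    @property
    def posterior_mu(self) -> float:
        return float(np.concatenate([c.mu for c in self.chains]).mean())

    @property
    def posterior_sigma2(self) -> float:
        return float(np.concatenate([c.sigma2 for c in self.chains]).mean())

    def summary(self) -> pd.DataFrame:
        """Per-node posterior mean age (100 My), 95% HPD and ESS."""
        return self._summary.copy()

    def summary_text(self) -> str:
        lines = ["Node dating summary (ages in units of 100 My)",
                 f"chains: {len(self.chains)}, samples/chain: {self.chains[0].mu.size}",
                 f"posterior mean rate mu: {self.posterior_mu:.4g}, "
                 f"sigma2: {self.posterior_sigma2:.4g}"]
        if self.convergence is not None:
            lines.append("convergence: "
                         + ("PASS" if self.convergence["converged"] else "FAIL")
                         + f" (max chain-mean spread {self.convergence['max_mean_discrepancy']:.3g})")
        lines.append(self._summary.to_string(float_format=lambda v: f"{v:.3f}"))
        return "\n".join(lines)

    def annotated_tree(self) -> str:
        """Newick chronogram with posterior mean ages and HPD annotations."""
        new_ages = {lab: float(self._summary.loc[lab, "mean_age"])
                    for lab in self._summary.index}
        tree = _tree_with_consistent_ages(self.model.tree, new_ages)
        ann = {lab: self.hpd(lab) for lab in self._summary.index}
        return tree.to_newick(annotations=ann)


def _tree_with_consistent_ages(tree: TimeTree, ages: dict[str, float]) -> TimeTree:
    """Apply posterior mean ages; tiny parent/child inversions from pooling
    noise are nudged to keep the tree valid."""
    full = {lab: ages.get(lab, tree.age(lab)) for lab in tree.labels}
    for lab in reversed(tree.labels):      # postorder over the preorder list
        i = tree.index[lab]
        kids = tree.children[i]
        if kids:
            floor = max(full[tree.labels[c]] for c in kids)
            if full[lab] <= floor:
                full[lab] = floor + 1e-9
    return tree.with_ages(full)
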