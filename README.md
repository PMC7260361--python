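# dictyfit

Comparative fitness analysis of the two dormant cell forms of social amoebae
(Dictyostelia) — multicellular-fruiting-body **spores** versus unicellular
**cysts** — together with a desk-scale Bayesian relaxed-clock node-dating
engine.

Dictyostelia fall into four major molecular taxon groups; many species in
groups 1–3 retained encystment while group 4 lost it.  A long-term
plaque-assay measures survival of spores and cysts stored for up to a year
under climate-mimicking regimes (22 °C wet, 4 °C wet, −20 °C wet, −20 °C
dry).  The package turns such plaque-count tables into survival curves, a
relative-fitness statistic, rank-based group comparisons, trait–fitness and
climate–fitness correlations, and relates the timing of the spore/cyst
divergence to paleoclimate through fossil-calibrated node dating.  A
synthetic-data module emulates every input, so the full pipeline runs and is
tested without any downloads.

## The statistics at the core

**Relative fitness.**  A plated aliquot of `v` µl from a suspension of `c`
cells/ml contains `n = c·v/1000` cells; with plaque count `k` the survival
fraction is `S = k/n` (triplicate mean ± SD).  At each post-baseline storage
day `t` the normalizer is the mean spore survival over **all** species and
conditions, `D(t) = mean_spores S(t)`; every curve — spore or cyst — is
divided by `D(t)` and the relative fitness is the mean of the normalized
values over the six post-baseline days (`F`, with SE over days).  By
construction the spore-wide mean of normalized values at every day is
exactly 1.

**Group comparison.**  Per storage condition, species `F` values are pooled
per major taxon group (spores) plus one pool over all cysts and compared by
Kruskal–Wallis (ANOVA on ranks) with a Dunn pairwise P-matrix; trait and
climate associations use Spearman rank correlation.  All rank statistics are
implemented in `dictyfit.stats` with tie corrections and exact
small-sample p-values, and are cross-checked in the test suite against
enumeration oracles and independent library implementations.

**Node dating.**  On a fixed rooted topology with branch-length estimates
`b̂_i ± v_i` (substitutions/site), the model assumes independent log-normal
branch rates, `log r_i ~ N(log μ − σ²/2, σ²)` (so `E[r_i] = μ`), gamma
hyperpriors `μ ~ Γ(shape 2, rate 20)` and `σ² ~ Γ(shape 1, rate 10)`,
soft-bound uniform fossil calibrations (2.5% probability mass beyond each
bound), and an independent-Gaussian approximate likelihood
`b̂_i ~ N(r_i·Δt_i, v_i)`.  A Metropolis-within-Gibbs sampler with
rate–time ridge moves returns posterior mean node ages and 95% HPD
intervals (units of 100 My), with a two-chain convergence report.

## Worked example

```python
from dictyfit import synthetic as syn, survival as surv

table = syn.gen_survival(syn.SurvivalSimConfig(seed=1))
fit = surv.relative_fitness(surv.survival_fractions(table))
comp = surv.group_fitness_comparison(fit)["m20C_wet"]
print(comp.pool_stats)
print(f"Kruskal-Wallis H = {comp.kruskal.statistic:.2f}, "
      f"p = {comp.kruskal.p_value:.2e}")
```

prints

```
 pool  n  mean    se
cysts  5 0.372 0.026
 grp1  5 0.780 0.066
 grp2  5 1.514 0.039
 grp3  5 0.699 0.065
 grp4  5 1.822 0.045
Kruskal-Wallis H = 22.15, p = 1.87e-04
```

i.e. at wet frost, group 4 spores have the highest relative fitness, cysts
the lowest, and the pools differ significantly.  Dating a simulated 8-tip
tree (true root age 5.0, i.e. 500 My):

```python
from dictyfit.chronology import Calibration, McmcSettings, NodeDatingModel

tree, rates, data = syn.gen_chronology(syn.ChronoSimConfig(n_tips=8, root_age=5.0, seed=5))
cal = Calibration(node=tree.root_label, t_min=3.0, t_max=7.0)
res = NodeDatingModel(tree=tree, calibrations=[cal], branch_data=data).fit(
    McmcSettings(iterations=12000, burn_in=4000, sample_every=4, chains=2, seed=9))
print(res.summary_text())
```

```
Node dating summary (ages in units of 100 My)
chains: 2, samples/chain: 2000
posterior mean rate mu: 0.08522, sigma2: 0.07268
convergence: PASS (max chain-mean spread 0.0368)
      mean_age  hpd_low  hpd_high      ess
n7       4.935    2.934     6.877 2833.382
...
```

The posterior mean root age (4.94) recovers the generating value within the
rate–time uncertainty, and `res.annotated_tree()` serializes the chronogram
with age and HPD annotations.

The same steps are available from a shell:

```sh
dictyfit simulate --seed 1 --out-dir sim
dictyfit fitness --survival sim/survival.csv --out-dir fit
dictyfit date --tree sim/tree.nwk --calibrations sim/calibrations.csv \
    --branch-data sim/branch_data.csv --seed 4 --out-dir dated
```

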