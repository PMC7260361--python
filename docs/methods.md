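# Methods

This note records the models, the numerical choices, and what the synthetic
data do and do not establish.

## Survival assay and relative fitness

The assay plates aliquots of a washed dormant-cell suspension clonally with
food bacteria; each viable spore or cyst founds one countable plaque.  The
sampling schedule is days 0, 1, 7, 30, 91, 182 and 365; aliquots are 10 µl
of a 10⁴ cells/ml suspension (100 cells) with triplicate platings, enlarged
to 20/30/40 µl at late time points so that declining survival still yields
countable plaques.  Freeze-dried (dry frost) samples are reconstituted to
the same cells-per-aliquot before plating, so desiccation effects live
entirely in the survival dynamics, not in the plating arithmetic.

Survival fractions are plaques / cells plated, averaged over replicates
(mean ± SD, `ddof=1`).  Fractions can exceed 1 through counting noise; they
are kept and flagged rather than clipped — clipping would bias the
downstream average asymmetrically downward.

Relative fitness `F` normalizes each curve at each post-baseline day to the
mean spore survival across all species and conditions at that day, then
averages over the six post-baseline days.  Day 0 is treated as a
plating-efficiency control and excluded ("the six time points" is read as
days 1–365; the choice is configurable via the `days` argument).  Cysts are
normalized against the spore denominator, which makes spore and cyst values
directly comparable.  SE uses n = number of days with a defined normalized
value; days with a zero spore denominator are dropped with a warning.
Species of minor taxon groups contribute to the normalization denominator
but are not pooled in group comparisons (single-species pools are not
testable).

## Rank statistics

All rank procedures use average ranks for ties and tie-corrected variances.
"ANOVA on ranks" is implemented as Kruskal–Wallis with the chi-square
approximation (df = groups − 1) and an exact permutation p-value for total
N ≤ 10 (full enumeration of group assignments).  The pairwise follow-up is
Dunn's z test on pooled ranks; the P-matrix is reported raw by default with
Holm adjustment optional, since a raw matrix is the convention the pooled
comparison mirrors.  Group-versus-rest contrasts of morphometric features
use the two-sided Mann–Whitney U (exact for N ≤ 12, else normal
approximation with continuity and tie correction) at a configurable 0.05
threshold.  Spearman correlation is Pearson-on-average-ranks with a
t-approximation (n − 2 df) and exact permutation for n ≤ 8.  Degenerate
inputs (constant vectors, all-tied groups) raise `DegenerateDataError`
rather than returning a number.

HPD intervals are the narrowest contiguous window containing ⌈mass·n⌉
sorted samples, ties broken toward the smallest lower bound.

## Morphometry

Per-cell records carry the 20 ultrastructural features: total wall width and
up to three layer widths (spore walls have three layers, cyst walls at most
two), layer electron density, granule counts and diameters, vesicle counts
and total area, the wall-exclusive cell cross-section area, nucleus area,
mitochondrion count, elongation, and per-mitochondrion or per-cell
qualitative flags stored as fractions.  Granule cross-section area assumes
circular profiles (Σ π d²/4); fractions of the cross-section area above 1
are reported with a warning and capped.  Aggregation is hierarchical:
measurement positions → cell → species mean.

## Climate analysis

Zones are ranked 1–5 from tropical to arctic/alpine; a species' range
collapses to its coldest (max) and warmest (min) rank.  The per-group
percentage matrix over coldest zones rounds half away from zero, which is
why a row can sum to 101; unrounded rows sum to exactly 100.  The
climate–fitness correlation uses spore fitness only.

## Synthetic data: what it emulates

* **Survival counts** — plaque counts are Binomial(cells plated, S(t)) with
  a Weibull-with-plateau decay `S(t) = s∞ + (1 − s∞)·exp(−(t/τ)^k)`.  The
  published curves are empirical only, so this parametric family is a
  design choice: it captures both fast cyst death and long spore tails.
  Default parameters are calibrated to the qualitative orderings: group 4
  spores have the largest frost half-lives and plateaus, groups 1 and 3 the
  smallest; cysts match spores at 22 °C but lose viability within days of
  dry frost (S(7) < 0.01).  A log-normal between-species jitter on τ
  (CV 0.3) and on the plateau (CV 0.2) reproduces the sizable
  species-to-species variation within groups.  The roster is five species
  per major group plus two minor-group species; five species in groups 1–3
  also form cysts.
* **Morphometry** — widths, counts and areas are log-normal (CV 0.15),
  qualitative fractions beta-distributed; per-cell wall totals are the sum
  of the layer draws.  Group profiles encode the published contrasts:
  group 2 thickest and group 3 thinnest walls, group 4 compacted (small and
  sparse granules/vesicles, crenate ribosome-fringed mitochondria with
  closed cristae).
* **Climate roster** — 85 species with recorded climate: group 4 fixed at
  27, the remaining 58 split 17/27/13/1 over groups 1/2/3/minor.  These
  sizes are the package's choice: they make every printed percentage row an
  exact integer-count solution (e.g. group 4 counts 5/4/14/1/3 → 19/15/52/4/11%)
  with exactly five arctic/alpine group 4 species and one other.
  Deterministic mode assigns expected counts by largest remainder; sampled
  mode draws multinomially.  `assign_zones_by_fitness` additionally couples
  the coldest zone of the *assayed* species to their frost fitness (noisy
  monotone map), with warm range ends drawn independently — emulating the
  observed association between cold-hardy spores and cold habitats and the
  absence of one for warm range edges.
* **Dated trees** — random merge topologies with ordered-uniform node ages
  scaled to the root age, independent mean-preserving log-normal branch
  rates, Gaussian observation noise on branch lengths (truncated at zero by
  default; truncation can be disabled where exact Gaussian generative
  consistency is required, as in the coverage experiment).

Passing tests on these simulators show that the *analyses* recover the
structure the generators encode; they cannot show that real spore survival
follows a Weibull law, that real morphometric noise is log-normal, or that
real branch-length estimates have independent Gaussian errors.

## Node-dating model

Ages are in units of 100 My, leaves at age 0.  The clock is the
independent-rates model: branch rates i.i.d. log-normal with
`log r ~ N(log μ − σ²/2, σ²)` so that `E[r] = μ`.  The hyperpriors are
`μ ~ Γ(2, rate 20)` and `σ² ~ Γ(1, rate 10)` — the shape/"scale" wording of
the underlying dating convention is read as shape/rate (prior mean rate 0.1
per 100 My); both are configurable on `NodeDatingModel`.

Fossil calibrations are uniform with soft bounds: mass 1 − 2·tail uniform
on [t_min, t_max] and exponential tails matched for continuity at each
bound, each carrying exactly `tail` (default 2.5%) mass.  The exponential
tail shape is a documented choice; only the tail masses and continuity are
specified by the convention being followed.

The prior on uncalibrated node ages is flat over the order polytope below
the root, normalized by `root^−m` (m = free internal nodes).  The
normalization makes the marginal prior of the root equal its calibration
density exactly on any topology — a proper version of a uniform
order-statistics prior, chosen over a birth–death kernel because at desk
scale the calibrations dominate.  The root must be calibrated; without an
age ceiling the model is unidentifiable and `fit()` refuses to run.

The likelihood is the independent-Gaussian approximation on branch-length
estimates, `b̂_i ~ N(r_i Δt_i, v_i)` with per-branch variances supplied by
the user (a diagonal version of the curvature-based approximate likelihood
used by large-scale dating programs; a full-covariance extension would slot
into `approx_loglik`).

**Sampler.**  Metropolis-within-Gibbs with, per sweep: sliding-window moves
on each internal age (respecting parent > child), a *compensated* age move
that rescales the rates of adjacent branches to hold expected branch
lengths fixed, an independent multiplier move on every rate in parallel
(valid because rates are conditionally independent given ages and
hyperparameters), multiplier moves on μ and σ², and two likelihood-invariant
scale moves (ages × c with rates / c, optionally also μ / c) that travel the
rate–time confounding ridge.  Without the ridge moves the sampler mixes
poorly whenever the likelihood is tight.  Step sizes are tuned during
burn-in toward 20–40% acceptance; tuning stops at the end of burn-in so the
retained chain is a valid fixed-kernel MCMC.  Per-chain seeds derive from
the master seed via `SeedSequence.spawn`.

Summaries pool post-burn-in thinned samples across chains: posterior mean
age and 95% HPD per node, effective sample sizes (FFT autocovariance with a
Geyer-style initial-positive-sequence cutoff), and a convergence report
comparing per-chain posterior means (pass when the spread is below 2% of
the posterior root age).  Annotated chronograms serialize to Newick with
`name|age=..|hpd=lo,hi` labels and round-trip through the package reader.

**Validation.**  Three simulation checks exercise the engine end to end:
prior-only sampling reproduces the analytic calibration density including
its 2.5% tails (Kolmogorov–Smirnov distance < 0.05 at 10⁴ samples);
self-consistent simulation (all parameters drawn from the model's own
priors, Gaussian noise without truncation) gives 95% HPD coverage of true
node ages within Monte-Carlo error of nominal over 200 datasets; and on
noise-free strict-clock data the posterior mean root age lands within 10%
of truth — the residual scale uncertainty along the rate–time ridge is
genuine, set by the calibration width and the rate hyperprior.  The
sampler's marginals were additionally verified against exact numerical
quadrature on a two-tip model during development.

## Problem sizes and defaults

Test and example runs use 6–8-tip trees, chains of 3.5–40 k sweeps and
10³–10⁴ retained samples; the coverage experiment uses 200 datasets of
6 tips with observation SD 0.01 substitutions/site.  These sizes give
stable summaries for models of this dimension while keeping the full test
suite fast.  Dating a real 85-taxon phylogenomic dataset additionally
requires topology inference, alignment-level likelihood curvature and much
longer chains, all outside this package's scope — the package dates
desk-scale problems and demonstrates the statistical machinery.

## Known limitations

* No parametric survival-curve *fitting*: the pipeline reports empirical
  means, as the analysis it implements does.
* The Gaussian branch-length likelihood ignores covariance between sister
  branches; fine for simulated diagonal noise, an approximation for real
  estimates.
* The exact post-hoc procedure behind a published pairwise P-matrix is a
  convention choice (Dunn); Holm adjustment is available but off by
  default.
* Whether trait–fitness correlations should use spore-only or pooled
  spore+cyst fitness per species is exposed as `fitness_mode`; spore-only
  is the default.
* The climate analysis takes zone labels as given (literature compilation);
  there is no geocoding.
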