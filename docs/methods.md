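# Methods

This note documents the models implemented in `paleodiv`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical and design choices a maintainer should know
about. All ages are in Ma before present (larger = older), rates in events
per lineage-Myr, and age intervals are closed.

## Preservation likelihoods

A species with origination `ts` and extinction `te` leaves fossil finds
according to a Poisson process on [te, ts]; all likelihoods condition on the
species being found at all (≥ 1 occurrence), so a species observed k times
at ages t_1..t_k contributes

    Σ log r(t_i) − Λ − log(1 − e^{−Λ}),   Λ = ∫_{te}^{ts} r(t) dt.

Three intensity families are implemented:

* **HPP**: r(t) = q, constant.
* **NHPP** (lifespan-varying): r(t) = q·B(u; α, α) where u = (ts−t)/(ts−te)
  and B is the symmetric beta density. α > 1 makes fossils least likely to
  form just after origination and just before extinction, when population
  size is low; α = 1 reduces exactly to the HPP, and Λ = q(ts−te) for every
  α. The symmetric-beta shape is this package's choice for the hump; only
  its qualitative behaviour (depressed at the lifespan ends) is constrained
  by the biology, so α is estimated rather than fixed.
* **TPP** (time-varying): piecewise-constant rates on 1-Myr bins anchored at
  0 Ma (bin width configurable). Λ is the exact sum of per-bin overlaps. The
  bin grid extends 5 Myr beyond the oldest first find; proposals for ts
  beyond the grid are rejected, which effectively truncates the origination
  prior there.

**Across-lineage heterogeneity** uses the standard discretization of a
mean-one Gamma(ν, ν): the distribution is cut at equal-probability
quantiles and each category is represented by its conditional mean (so the
multipliers average to exactly 1); each species' conditioned likelihood is
averaged over the categories. Default 4 categories, the conventional
granularity; ν is estimated.

## Origination/extinction MCMC

A fixed-dimension Metropolis–Hastings sampler targets the joint posterior of
{ts_i, te_i}, the preservation parameters (q or the bin rates, α, ν) and
constant birth–death rates (λ, μ) that serve as the prior on lifespans:

    p(ts, te | λ, μ) ∝ λ^{S−1} μ^{E} e^{−(λ+μ) Σ(ts_i−te_i)},

with S species, E extinct species, and the oldest origination treated as the
process origin (no λ factor). Trans-dimensional averaging over
preservation-rate shift counts is deliberately out of scope: the downstream
covariate analyses consume only the times, so a configurable fixed-shift
model keeps the sampler simple and auditable.

Hard constraints: ts_i ≥ oldest find, 0 ≤ te_i ≤ youngest find; a species is
extant (te pinned at 0) when flagged explicitly or when its youngest find is
younger than 0.02 Ma. Proposals are sliding windows on times (width 0.4 Myr,
reflected at the constraints) and log-scale multipliers (half-width 0.6) on
all rates; these defaults give 20–60% acceptance on the synthetic fixture.
Priors: q and each bin rate ~ Gamma(1.5, 1.5); α ~ Gamma(2, 1);
ν ~ Gamma(2, 2); λ, μ ~ Exponential(1) — weakly informative with positive
support, all overridable in `McmcConfig`. λ and μ are estimated jointly with
the times. Default chain: 200,000 iterations sampled every 100 with 20%
burn-in — a desk-scale setting that passes the package's own recovery checks
(HPD coverage, grid-posterior agreement); real analyses should scale the
chain up by an order of magnitude. Dating uncertainty enters by resampling
each occurrence age uniformly in its interval (independently per record)
into replicate datasets; replicate posteriors are pooled by concatenation.

The sampler's q-marginal was validated against a dense grid evaluation of
prior × likelihood with times pinned (total variation < 0.02), and its
interval calibration against synthetic data with known truth (≈ 86–94%
coverage of true ts/te at nominal 95% on the standard fixture).

## Diversity-covariate birth–death model

The lineage-through-time trajectory D(t) = #{i : te_i < t ≤ ts_i} (extant
species counted at t = 0) is piecewise constant. Group g's rates are
λ_g(t) = λ0_g·e^{G_λg·D(t)} and μ_g(t) = μ0_g·e^{G_μg·D(t)}; the
log-likelihood sums log λ_g at each origination (except the clade origin),
log μ_g at each extinction, minus ∫ N_g(t)(λ_g(t)+μ_g(t)) dt evaluated in
closed form on the intervals where D and the group lineage count N_g are
both constant. Design choices:

* The predictor stays on its raw lineage-count scale (no standardization),
  so G is interpretable per coexisting species; a shifted predictor is
  exactly absorbed by rescaling λ0 (tested identity).
* The predictor is evaluated on the *older* side of each event: the standing
  diversity the event happened into, excluding the event's own ±1 step.
* In two-group analyses both groups' event terms are retained, each with its
  own parameters, and both groups share the clade-wide predictor; only the
  single oldest origination in the whole dataset is treated as the origin.
* Priors: Exponential(1) on baselines, Normal(0, 5²) on G — wide enough to
  cover any plausible per-species effect without being flat. Proposals:
  multipliers on baselines, sliding window (width 1.0) on G.
* Per-replicate pipeline: each age-resolution replicate's posterior-mean
  times build that replicate's D(t); the covariate model runs per replicate
  and the posteriors are pooled. Posterior means (rather than per-sample
  trajectories) keep the predictor fixed within a chain.

Summaries report the posterior mean of G, the 95% HPD (shortest contiguous
interval over sorted samples), and the sign fraction: the percentage of the
posterior on the mean's side of zero, flagged in tables when it exceeds 75%
(strict), with a second flag when the HPD excludes zero.

## Tree-based detector

Tip DR is the inverse of the equal-splits weighted path length (edge nearest
the tip weighted 1, halving toward the root). The diversity a tip
experienced is the number of branches crossing the time slice 0.5 Myr
(configurable) before the tip's height — a lineage crossing the slice is a
lineage, including the focal tip's own ancestor; a slice at or above the
root returns 1 (the stem) with a warning. The detector fits
DR ~ diversity by GLS with residual covariance V_ij = root-to-MRCA path
length (Brownian motion on the non-ultrametric tree, so residual variance
grows with each tip's root-to-tip depth — this is how non-contemporaneous
tips are weighted), two-sided t-tests at n − p degrees of freedom, and
classifies the slope's sign at p < 0.05. DR is used untransformed (a log-DR
option exists). Two-group analyses add a group main effect and a
diversity × group interaction; the interaction is the slope contrast.
Degenerate trees (constant diversity across tips, near-singular covariance)
classify as "none" with a warning so calibration sweeps never abort. The
GLS stage reproduces an independent R implementation
(`nlme::gls` with a Brownian correlation structure and depth-proportional
variance weights) to 1e-12 on simulated trees.

## Tree simulation

Gillespie forward simulation from a single lineage: with N lineages alive,
the next event arrives at rate N(λ+μ) and is a speciation with probability
λ/(λ+μ). Extinct lineages remain as tips with positive age; survivors are
closed at `max_height` (default 7 Myr) and the stem edge is dropped, so the
tree is rooted at the first split. Diversity dependence is the canonical
linear form λ(N) = max(0, λ0 − (λ0−μ0)·N/K), so λ(K) = μ0 at the carrying
capacity; the functional form is localized in one closure and easily
swapped. Trees with fewer than 4 tips (the detector's minimum) are redrawn,
up to 1,000 attempts. A `max_tips` cap (default 500) bounds runtime; trees
hitting it are closed at the cap time.

Batch distributions draw per-tree parameters from truncated normals
(redrawn until λ0 > μ0 > 0 and K > 1):

* diversity-dependent regime: λ0 ~ N(0.9, 0.2), μ0 ~ N(0.3, 0.1),
  K ~ N(17, 3) — rates sized for a small hominin-like clade with a
  carrying capacity near the study tree's 17 tips;
* constant-rate regime: λ0 ~ N(0.52, 0.11), μ0 ~ N(0.17, 0.06), calibrated
  (against tip counts only) so the median total tip count at height 7 is
  ≈ 17, comparable to the study phylogeny. Under the diversity-dependent
  defaults the median total count is ≈ 24, since extinct tips accumulate
  above K.

Perturbations: `drop_random_tips` removes a uniform number of tips up to 40%
(unifurcations suppressed with branch lengths merged, so surviving
root-to-tip distances are unchanged); `graft_random_tips` adds tips at
uniform points along branches within a group's subtree span, with tip ages
uniform between the attachment age and the present, leaving all existing
MRCA times untouched.

## Synthetic fossil generator

`generate_fossil_dataset` emulates the statistical structure the Bayesian
stages assume: birth–death lifespans (run length set so the expected species
count matches the target; realized counts outside ±30% are redrawn),
per-species gamma rate multipliers, occurrence times from the chosen
preservation intensity conditioned on ≥ 1 find (1,000 redraws per species,
then an error — bounding runtime), symmetric age-error intervals clipped at
0, and locality labels from a small pool. It does **not** emulate: taxonomic
error or synonymy, spatially structured sampling, correlated dating errors
within stratigraphic units (replicates resample ages independently per
record), preservation regimes that shift abruptly with facies, or anagenetic
ancestor–descendant relationships. Tests passing on this generator therefore
show the estimators are self-consistent under their assumed sampling model,
not that real occurrence databases satisfy those assumptions.

## Detector calibration: behaviour and limitations

The calibration loop (`run_calibration`) measures the detector's power on
diversity-dependent trees and its false-positive rate on constant-rate
trees, with and without random tip removal. Two findings matter for
interpretation:

* The detector is strongly anticonservative on constant-rate trees (the
  false-positive rate is an order of magnitude above the nominal 5%),
  because DR and sliced diversity are both functions of the same tree and
  share phylogenetic structure that the Brownian residual model only partly
  absorbs. Nearly all false positives are *negative* slopes; a significant
  positive slope on real data is therefore much stronger evidence than a
  negative one. The exact percentages depend visibly on the simulated trees'
  size and extinct-tip fraction, i.e. on the batch parameter distributions.
* Power does not increase monotonically as K decreases (stronger diversity
  dependence): smaller K compresses both the trees and the predictor's
  range, and at these tree sizes the data-size effect dominates the
  effect-size gain. Power and false-positive rates should always be read as
  a pair, at matched tree sizes.

Numerical notes: log(1 − e^{−x}) uses expm1/log1p branches for stability;
the q → 0 limit of the conditioned HPP likelihood is finite and tested;
beta log-densities at u ∈ {0, 1} return −inf for α > 1 (a proposal placing
an occurrence exactly at a lifespan endpoint is rejected); HPD intervals are
the shortest window of ⌈0.95·n⌉ sorted samples; paired comparisons of time
estimates with zero-variance differences report "no difference" with a
warning instead of propagating NaN; all randomness flows from a single seed
through `numpy.random.SeedSequence` spawning.
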