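# Methods

## Dispersal kernel

All dispersal — seed shadows, pollen clouds, scenario pedigrees, and the
wave-speed calculations — uses the one-parameter 2D-t kernel
`K(r) = u / (π (u + r²)²)` (the bivariate Student-t family with shape
fixed at 1). Its mean distance is `(π/2)√u`; its radial CDF
`F(r) = r²/(u + r²)` inverts in closed form, so random distances are
drawn by exact inverse-CDF (`R² = u·q/(1−q)`) rather than rejection.
The shape exponent is a frozen constant, not a configuration knob: the
one-parameter form is what makes the kernel identifiable from sparse
parentage data, and every reference (u, distance) pair the package
reproduces requires shape 1. Note the kernel's radial second moment is
infinite — sample means of distances converge, but slowly, and tests
that compare them to `(π/2)√u` use robust Monte-Carlo error bounds.

## Genotyping-error model

Observed microsatellite calls are modeled as true genotypes passed
through two channels, composed dropout-then-mistyping:

1. **Allelic dropout** (`e2` per locus): a heterozygote is recorded as a
   homozygote for one of its two alleles, equal split. Homozygotes
   cannot drop out (the event is undetectable and absorbed into the
   definition of the observed call).
2. **Mistyping** (`e1` per locus): each recorded allele independently
   shifts one motif unit up or down the locus's size ladder, equal
   split. The ladder spans min to max observed size in motif steps;
   edge rungs shift inward with the whole `e1` mass, which keeps the
   observation distribution exactly normalized.

"Adjacent fragment length" is the minimal reading of stutter-type
mistyping; a wider mistyping neighborhood would require evidence the
package's inputs do not carry. Half-called loci (one allele missing)
are treated as locus-missing, conservatively. The per-locus observation
matrix `W[a,b] = P(observed | true = {a,b})` is assembled analytically
from the tridiagonal single-allele mistype matrix, and the exact same
channel code corrupts simulated data, so forward simulation and
likelihood are consistent by construction.

Error-rate estimation from re-genotyped individuals compares a
reference (consensus) table to a re-typing: `e2` is the fraction of
reference heterozygotes re-typed as a self-allele homozygote; `e1` is
the fraction of allele comparisons shifted by exactly one motif.
Comparing two independently corrupted typings instead would estimate
roughly `2e`; the reference-vs-retype convention recovers the
per-typing rate (verified by simulation round-trip to ±0.03 at n=500).

## Parentage likelihood

For seedling *k* with candidate mother *i* and father *i′*:

```
w(k, i, i′) = f_i K(d_ik; u_s) · c_i′ K(d_i′i; u_p) · P(G°_k | G°_i, G°_i′, e1, e2)
```

with pollen output `c` proportional to seed fecundity `f`, and
`mother ≠ father` (red oaks are effectively self-incompatible). Both
orderings of each pair are enumerated separately — the model mixes over
maternity/paternity uncertainty rather than assuming the closer parent
is the mother. Parents' observed genotypes are taken at face value for
transmission; the error model applies to the offspring's observation
(errors in parental genotypes are second-order at the rates involved).
Unknown parents transmit alleles from pooled in-plot allele frequencies
(Hardy–Weinberg); a per-species mode restricts candidates and
frequencies to the seedling's species.

**Out-of-plot parents.** Either slot may be OUT. The exterior is tiled
with a regular grid of virtual parents between the plot boundary and a
cutoff (defaults 10 m spacing, 500 m cutoff; both configurable —
simulation studies in the tests use 30–40 m spacing, which changes
posterior means by well under a percent on those fixtures), each cell
carrying density × cell-area expected trees at the in-plot mean
fecundity. The OUT-mother × in-father term couples the seed kernel from
each cell to the seedling with the pollen kernel from the father to the
cell. For the out/out term, the pollen arriving at an exterior cell
from the (unbounded) exterior is computed by the complement rule
`ρ·c̄·(1 − ∫_plot K(·; u_p))` with the plot integral on an interior
midpoint grid — the same integral a cell-to-cell double sum targets,
without its quadratic cost and without truncating at the grid cutoff.

## Sampler

Each sweep: (1) per-tree fecundities are redrawn from zero-truncated
normals defined by their posterior mean/SD inputs, propagating
fecundity uncertainty; (2) every seedling's (mother, father) pair is
redrawn from its exact conditional — implemented by sampling the mother
from the marginal (father axis summed out) and then the father from its
conditional, which is algebraically identical to flattening the full
pair table; (3) `u_s` and `u_p` are updated by random-walk Metropolis
on log u (log-normal proposal with the Jacobian term), against the
kernel likelihood of the current pedigree times truncated-normal priors
(`u_s`: mean 253, SD 1000, bounds at mean distances 5 and 157 m; `u_p`:
mean 2000, SD 1500, bounds at 5 and 192 m; SDs are on the u scale).
Proposal scales adapt toward ~0.3 acceptance during burn-in only, so
the post-burn-in chain is a fixed-kernel Markov chain. The reference
schedule (50,000 steps, 30,000 burn-in, thin 20) retains exactly 1,000
draws. Posterior summaries report means, SDs, percentile 95% CIs, the
implied mean dispersal distances, per-seedling modal pairs, and modal
counts over the four parentage categories (in/in, in-mother/out-father,
in-father/out-mother, out/out).

Degenerate cases: a seedling whose genotype is incompatible with every
candidate (including OUT via frequencies) at the given error rates
raises an error naming the seedling rather than silently assigning OUT;
a seedling with no genotyped locus contributes a genotype term of 1
with a warning.

## Synthetic data

The generator emulates the stand structure the method targets:
26.5 adults/ha on a 7.5-ha square plot by default (Poisson count,
uniform locations), per-tree fecundity means Gamma(shape 2) scaled to a
948 seeds/yr mean (right-skewed, maxima ≈3× the mean at ~200 trees),
six loci with 14–35 alleles each at Dirichlet(0.5) frequencies, HWE
genotypes, per-locus mistyping 0.02–0.18 and dropout 0.02–0.08, and
dispersal defaults u_s = 92, u_p = 8600. Seedlings arise from
fecundity-weighted mothers, 2D-t displacements (discarded if landing
outside the plot), and pollen-kernel-weighted fathers. A 200 m buffer
strip of virtual exterior parents at the in-plot density supplies
immigrant seed and pollen; the width was chosen as several kernel means
so the generator approximates the continuous forest the likelihood
assumes — a thin buffer visibly starves immigration and biases seed
recovery upward.

What the generator does not emulate: masting time series, seedling
mortality, species-assortative mating, null alleles, or linkage.
Passing recovery tests therefore demonstrate correctness of the
inference under the model's own assumptions, not robustness to their
violation in field data.

## SGS scenario simulator

Three "generations" (stand cohorts: large adults, small adults,
seedlings; synthetic uniform maps by default, user maps accepted) are
assigned parents by kernel-weighted sampling from scenario-specific
sources: *distant* (4 pools of 10 trees ≥ 200 m beyond the boundary,
jitter SD 25 m — geometry is configurable since only "several outside
source populations" is specified), *scattered* (Poisson sources at a
chosen density over the plot plus a 100 m fringe; 1.5/ha default,
0.5/ha alternative), or *mixed* (pools plus k local trees). Generation
g draws candidates from sources plus all earlier generations.
Relatedness is the additive (numerator) relationship from the pedigree
recursion — full sibs 0.5, half sibs 0.25, higher under inbred matings
— with founders unrelated within and across pools. Profiles average
pair relatedness in 10 m classes (0–100 m) and report mean/min/max of
the per-replicate class means (100 replicates by default). Scenario
trees carry no simulated genotypes: comparison with the empirical
correlation r is qualitative by design.

## Empirical autocorrelation

The Smouse–Peakall (1999) multiallelic codominant estimator: per-locus
squared genotype distance = half the squared Euclidean distance between
allele-count vectors (AA–AB = 1, AA–BB = 4, AB–CD = 2, AA–BC = 3),
summed over loci with pairwise deletion of missing loci, Gower-centered
to a covariance matrix, and per distance class
`r = Σ 2c_ij / Σ (c_ii + c_jj)` over the class's pairs. Uncertainty is
a bootstrap over pairs within class (95% percentile CI); significance
is a permutation envelope from shuffling genotypes across locations
(999 by default). Adults split into large/small cohorts at the median
DBH, ties to the small cohort; a reference median may be supplied.

## Wave speed

`V = √((π/2)·u·R₀)/T` with `R₀` = seeds/yr × reproductive years ×
survival to adulthood; the speed ratio between two populations sharing
demography is `√(u₁/u₂)`. These are asymptotic, furthest-forward-
individual rates: large source populations spread faster, and
stochastic variation in R₀ can slow realized migration by orders of
magnitude (not modeled here).

## Numerical and testing choices

* Distances are Cartesian meters in a local plot frame; no geodesy.
* The prior log-density is evaluated analytically (the truncated-normal
  normalizer cached) rather than through generic distribution objects,
  which dominated runtime otherwise; `truncated_mean()` retains the
  scipy cross-check path used in tests.
* Weight-tensor computations are memoized per (u_s, u_p, fecundity)
  triple within a sweep.
* Simulation-study sizes in the test suite are chosen to finish on one
  CPU comfortably: the exact reference schedule runs on a ~50-adult,
  12-seedling stand; Gibbs-vs-enumeration uses 10⁵ sweeps of the
  4-adult toy with a 4-SE per-cell bound (~50 simultaneous cells);
  prior recovery retains 10⁴ draws and compares against the analytic
  truncated mean via an ESS-based Monte-Carlo SE; parameter recovery
  runs 10 replicates at the full 200-adult/200-seedling scale
  (u_s = 800, u_p = 5000, e1 = e2 = 0.02) with 2,000-step chains and
  requires ≥ 90% CI coverage across the 20 parameter checks; scenario
  contrasts use 100 replicates.
* Known limitations: the likelihood does not renormalize for the
  probability that a seed lands inside the plot (standard for this
  model family), which together with maternity/paternity mixing can
  bias u_s slightly upward at long dispersal on small stands; the
  exterior complement rule slightly overstates pollen available just
  outside a concave boundary; `estimate_error_rates` attributes
  het→hom discordances wholly to dropout and adjacent shifts wholly to
  mistyping, so the two estimates interact weakly at high rates.
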