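# Methods

This note records the models implemented in `helipop`, the numerical choices
behind them, and what the synthetic-data experiments do and do not
demonstrate.

## Scope and data flow

The package covers the desk-scale analysis chain for reduced-representation
SNP data from a crop and its wild progenitor: VCF-based dataset construction
(coverage/frequency filters, distance thinning, outgroup polarization),
population-genetic summaries for a spatially structured wild panel
(nucleotide diversity with bootstrap CIs, Weir–Cockerham F-statistics,
Mantel isolation-by-distance, clinal regression, hierarchical AMOVA),
construction and hypergeometric projection of the unfolded joint
site-frequency spectrum (SFS), and maximum-likelihood fitting of
two-population divergence models by the diffusion approximation, with AIC
model choice, Fisher-information uncertainties, and conversion to natural
units.

## SNP filtering

Filters apply in a fixed order: biallelic, per-site call-rate (fraction of
samples with a called genotype, `>=` threshold), minor-allele frequency
(strict `>`, computed over called genotypes only) or minor-allele count
(`>=`, so a count threshold of 2 keeps doubletons and excludes singletons),
then greedy left-to-right thinning per chromosome (keep the first site, then
every site at least `thin_bp` from the last kept site).  Polarization
assigns a site's ancestral state when at least one outgroup genotype is
called, all called outgroup genotypes are homozygous for one allele, and
that allele is carried by the ingroup; all other sites are dropped, which is
the conservative standard for building an unfolded SFS.

## Statistics

* **Per-site diversity.** For a biallelic site with allele counts `a, b`
  over `n = a + b` called haplotypes, `pi = a*b / C(n,2)`.  Reported means
  average over the variant sites present in the filtered dataset (the VCF
  carries no invariant sites); bootstrap CIs resample sites with
  replacement (percentile method, seeded).
* **F-statistics.** Weir & Cockerham (1984) variance components `a` (among
  populations), `b` (among individuals within populations), `c` (within
  individuals) per site, combined as ratios of sums over sites:
  `F_ST = sum a / sum(a+b+c)`, `F_IS = sum b / sum(b+c)`.  Pairwise `F_ST`
  re-estimates components from the two focal populations only.  Negative
  estimates are reported untruncated; they are legitimate outcomes of the
  unbiased estimator near zero differentiation.
* **Mantel test.** Pearson correlation of upper off-diagonal triangles;
  permutation p-value `(1 + #{r* >= r}) / (1 + n_perm)` with simultaneous
  row/column permutation, one-sided toward positive association (isolation
  by distance) by default, seeded.  Geographic distances are haversine on a
  sphere of radius 6,378,137 m.
* **Clinal regression.** OLS of a per-population statistic on one
  coordinate; `F = t^2` of the slope with `(1, n-2)` df.
* **AMOVA.** Four nested levels (clusters > populations > individuals >
  allele copies) on squared allele-difference distances over
  pairwise-complete shared sites.  Components solve the standard nested
  ANOVA expectation equations with unbalanced-design coefficients
  `A_l^m = sum_g sum_{h in g} n_h^2 / n_g`; percentages are computed over
  the raw (untruncated) total.  Permutation p-values shuffle labels at the
  tested level: populations among clusters, individuals among populations
  within clusters, individuals among populations.  Cluster labels are an
  input (the package does not infer genetic clusters).

## Divergence models and the diffusion solver

Three models share one history: an ancestral population at mutation–drift
equilibrium (the reference size `N_ref`) splits at scaled time `T` (units of
`2 N_ref` generations); the wild lineage takes relative size `nu_wild`
instantaneously at the split; the cultivated lineage is founded at
`nu_cult_founder` and changes exponentially to `nu_cult_current`
(`nu(tau) = nu_f (nu_c/nu_f)^(tau/T)`; the exponential form is the standard
growth parameterization and is isolated in `cult_size_trajectory` so a
two-epoch alternative could be swapped in).  Model A has no gene flow,
Model B one symmetric scaled rate, Model C two directional rates (scaled by
`2 N_ref`, receiving-population convention).  `theta = 4 N_ref mu L` enters
linearly and is profiled analytically in the likelihood.

The expected unfolded joint SFS solves the two-population Wright–Fisher
diffusion forward in time on a frequency grid crowded logistically near the
absorbing boundaries.  Numerics:

* Conservative finite-volume fluxes with exponential-fitting (Chang–Cooper
  style) advective weighting in the interior; alternating-direction
  implicit time stepping (pre-factorized Thomas solves; the
  exponential cultivated-size path is quantized into at most 48
  piecewise-constant epochs).
* Mutational influx `theta0/2` per axis injected at the first interior
  frequency, which maintains the stationary `theta/x` profile exactly.
* Boundary cells (where the diffusion coefficient vanishes) trap absorbed
  density: a site fixed or lost on one axis keeps evolving on the other,
  which is what the unmasked edge entries of the joint SFS measure.  The
  trap's exchange with the first interior node is calibrated so that the
  local zero-flux boundary-layer profile `y^(beta-1)` (with
  `beta = 2 M(0) nu`, `M(0)` the migration drift at the boundary) is a
  discrete equilibrium: the trap feeds back at rate `M(0)/2` when drift
  points into the domain and is a pure upwinded absorber when drift points
  at the boundary.  This keeps accumulated corner mass from leaking
  spuriously while preserving migration's re-seeding of lost alleles.
* Binomial sampling of the density to the requested haplotype sizes
  (trapezoid quadrature), computed on several grid sizes (default 40, 50,
  60 points) and extrapolated cell-wise to the infinite-grid limit by a
  quadratic Lagrange polynomial in the boundary grid spacing.  Small
  negative extrapolation artifacts are clipped to zero.
* Step control: the step count is `T * max(0.25/nu_min, m12+m21) / dt_fac`
  rounded **up to a geometric ladder** (12, 24, 48, ..., capped at 1200).
  Within a rung the count is constant, so the likelihood is a smooth
  function of the parameters there; without the ladder, integer step-count
  changes put small cliffs on the surface that stall simplex optimizers and
  can pin estimates against a cliff.  The cap bounds runtime at extreme
  parameter corners (tiny sizes with long times), where only accuracy — not
  stability — degrades.

Accuracy: with the default `dt_fac = 5e-3` the sampled equilibrium spectrum
matches the analytic `theta/i` form to 0.04% after extrapolation, and joint
spectra for divergence scenarios with bottlenecks and strong asymmetric
migration agree with coalescent (msprime branch-length) expectations to
~2% rms.  An exact finite-population Wright–Fisher Markov-chain oracle was
used during development to arbitrate boundary-treatment choices; the
coalescent comparison is kept as a regression test.

## Likelihood, optimization, uncertainty, units

* **Likelihood.** Poisson per unmasked cell with the analytically optimal
  scale `theta_hat = sum(data)/sum(model)` — equivalent to the multinomial
  form up to a data-only constant, and the exact sampling model for the
  synthetic spectra.  Model cells that are zero where data are positive are
  floored at a configurable epsilon (warned).
* **Optimization.** Multi-round Nelder–Mead on log parameters with a smooth
  quadratic penalty outside the bounds (defaults: `nu` in [1e-3, 100], `T`
  in [1e-3, 10], `m` in [1e-3, 20]; the migration lower bound is slightly
  positive because the search runs in log space — models with exactly zero
  migration are fitted as Model A).  Round 1 starts each replicate from a
  log-uniform random point; later rounds perturb the best parameters found
  so far (updated as replicates complete) by `2^(fold*u)`, `u` uniform in
  [-1, 1] per parameter.  The default schedule mirrors the full protocol
  (4 rounds; 50/50/50/100 replicates; 3/5/15/50 iterations; folds 3/2/2/1);
  the `reduced()` schedule used by the simulation studies is 2 rounds of 10
  replicates with 15 and 200 iterations and folds 2 and 1, with NM
  tolerances (`fatol = 1e-2`) matched to the residual smoothness of the
  extrapolated surface.
* **Uncertainty.** Observed Fisher information by central differences
  (relative step 1e-3, configurable); standard deviations from the inverse
  information diagonal; non-positive-definite information reports NaN per
  parameter rather than raising.
* **AIC.** `2k - 2 ll` with `k` the free demographic parameters (4, 5, 6
  for A, B, C); `theta` is profiled and not counted.
* **Units.** `N_ref = theta_hat/(4 mu L)`; sizes `nu_x N_ref`; time
  `T * 2 N_ref * gen_time` years.  Migration is reported as
  `migrants/year = m_scaled / 2 / gen_time`, i.e. the per-generation
  migrant count measured in units of `N_ref` individuals.  This convention
  is direction-independent, which is why a symmetric-migration model
  reports a single migrant number even when the two receiving populations
  differ in size; it is recorded in every fit's metadata and applied
  identically when converting natural rates into the simulator, so
  recovery experiments are convention-independent.  The default generation
  time is 1 year (annual plant).

## Reference recovery experiment

`helipop.recovery` encodes the published sunflower domestication estimates
under Model C (N_ref 4,230; wild 14,500; cultivated founded at 9,340
declining to 773; split 5,370 years ago; 3.81 and 0.353 migrants/year;
mu = 6.1e-9/site/generation; effective length 11.7 Mb) as the generating
truth.  Each replicate Poisson-samples a 30x24-haplotype unfolded joint SFS
from the model expectation (about 10,000 segregating sites, matching the
study scale) and refits Model C with the reduced schedule;
recovered parameters are converted back to natural units and summarized by
medians over seeds.  Generation and refitting share the same integration
settings (`dt_fac = 0.02`, grids 40/50/60), so the study is exactly
self-consistent; the likelihood surface has a soft ridge coupling the
founder size, migration and time parameters, which dominates the per-seed
scatter and is the main caveat when reading the per-parameter intervals.

## Synthetic phylogeography generator

`simulate_structured_genotypes` emulates the sampling design of a
16-population latitudinal transect panel (about a dozen diploid samples per
population, a few thousand unlinked SNPs, two outgroup samples from a
lineage ~2% diverged).  The history is a serial-founder expansion: each
population is founded from its southern neighbour every 400 generations
with sizes decaying by 0.85 per founding step from an ancestral 10,000
(lognormal jitter, sd 0.5, adds population-specific drift), plus
stepping-stone migration (5e-4 per neighbour per generation).  Coordinates
are evenly spaced latitudes with Gaussian jitter (sd 1.5 degrees) at fixed
longitude.  The backend is the msprime coalescent; a fixed seed gives
byte-identical output.

Under these defaults the panels show global Weir–Cockerham F_ST around
0.12–0.17, a strongly significant positive Mantel correlation, and a
monotone south-to-north decline in diversity.  Two honest deviations from
the empirical system: the simulated Mantel r (~0.8) is stronger than
typically observed in real two-dimensional landscapes (~0.3–0.5), because
a one-dimensional transect with cumulative founder divergence is cleaner
than real geography and sampling noise; and GBS artefacts (missing-data
structure, allele dropout, sequencing error) are not modelled, so passing
tests demonstrate correctness of the estimators and pipeline on idealized
panels, not robustness to genotyping artefacts.  Tests and the acceptance
experiments run scaled-down configurations (6–8 populations, ~5 samples,
400–800 sites) chosen to keep the full suite fast while preserving the
qualitative signatures.

## Known limitations

* Two populations only; no linkage beyond the coalescent simulator's
  recombination; folded spectra are out of scope.
* The diffusion solver's boundary treatment is accurate to a few percent at
  strong migration (validated against coalescent expectations); exact
  boundary-layer asymptotics are represented by a calibrated trap exchange,
  not resolved explicitly.
* FIM standard deviations are per-parameter (diagonal) quantities; along
  the founder-size/migration/time ridge they understate joint uncertainty.
* AMOVA assumes the distance-based and per-site sums-of-squares partitions
  agree, which is exact for complete data and approximate under
  pairwise-complete deletion with substantial missingness.
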