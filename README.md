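# helipop

Population-genetic statistics and joint-SFS demographic inference for crop
domestication and phylogeography studies, built around the sunflower
(*Helianthus annuus*) system: a wild progenitor sampled across a latitudinal
transect and a cultivated gene pool derived from it through a domestication
bottleneck.

The package implements the full desk-scale analysis chain for
reduced-representation SNP data:

* **SNP dataset construction** — biallelic/coverage/MAF/MAC filters,
  greedy ≥1 kb thinning, and outgroup polarization of ancestral states,
  from/to plain VCF.
* **Spatial population genetics** — per-site nucleotide diversity
  (π = a·b/C(n,2)) with bootstrap CIs, Weir–Cockerham F_ST/F_IS
  (ratio-of-sums), pairwise F_ST, Mantel isolation-by-distance with seeded
  permutations, haversine distances, clinal OLS regression, and four-level
  AMOVA.
* **Joint site-frequency spectra** — unfolded 2D SFS construction and
  hypergeometric projection to smaller sample sizes, with a plain-text
  serialization.
* **Demographic inference** — expected joint SFS under two-population
  divergence models (A: isolation; B: symmetric gene flow; C: asymmetric
  gene flow; bottleneck + exponential size change in the derived lineage)
  computed by a diffusion (Fokker–Planck) solver with 40/50/60-point grid
  extrapolation; Poisson/multinomial likelihood with profiled θ;
  multi-round Nelder–Mead search; AIC model choice; Fisher-information
  uncertainties; conversion to individuals/years via N_ref = θ̂/(4μL).
* **Synthetic data** — a coalescent (msprime) generator of serial-founder,
  stepping-stone structured panels with outgroups, emulating a postglacial
  range expansion, plus Poisson sampling of observed spectra from model
  expectations.

The core model: after an ancestral population of size N_ref at
mutation–drift equilibrium splits at time T, the density φ(x, y) of derived
allele frequencies in (wild, cultivated) evolves by

    ∂φ/∂t = Σ_axes [ −∂/∂x (m_in(x_other − x) φ) + ½ ∂²/∂x² (x(1−x)/ν · φ) ],

with time in 2·N_ref generations, relative sizes ν, migration scaled by
2·N_ref, and mutational influx θ/2 per axis.  Binomial sampling of φ gives
the expected unfolded joint SFS; observed spectra are fitted by maximum
likelihood.  See `docs/methods.md` for numerics and conventions.

## Worked example

Simulate a structured wild panel, filter and polarize it, and measure its
spatial structure:

```python
import numpy as np
from helipop import (SimConfig, simulate_structured_genotypes,
                     FilterSpec, filter_sites, polarize, PopulationMap)
from helipop.stats import (per_site_pi, weir_cockerham, mantel_test,
                           geographic_distance_matrix)

cfg = SimConfig(seed=1, n_pops=8, samples_per_pop=6, n_sites=800)
table, popmap = simulate_structured_genotypes(cfg)
table = filter_sites(table, FilterSpec(min_sample_coverage=0.8,
                                       mac_threshold=2, thin_bp=1000))
polarized = polarize(table, popmap.samples_for("outgroup"))

ingroup = PopulationMap({s: p for s, p in popmap.assignments.items()
                         if p != "outgroup"}, popmap.coords)
sub = polarized.take_samples(list(ingroup.assignments))
fs = weir_cockerham(sub, ingroup)
ibd = mantel_test(geographic_distance_matrix(ingroup), fs.fst_pairwise,
                  n_perm=9999, seed=1)
print(f"F_ST = {fs.fst_global:.3f}  Mantel r = {ibd.r:.3f} (p = {ibd.p:.4f})")
```

```
F_ST = 0.094  Mantel r = 0.613 (p = 0.0004)
```

The panel is moderately differentiated and genetic distance
increases significantly with geographic distance — the isolation-by-distance
signature the serial-founder expansion should leave.

Fit a divergence model to an observed joint SFS (statsmodels-style
Model/Results interface):

```python
from helipop import DemographicParams, DivergenceModel, OptimizerSchedule
from helipop.diffusion import expected_sfs
from helipop.simulate import sample_sfs_from_expectation

truth = DemographicParams(model="A", nu_wild_current=2.0,
                          nu_cult_founder=1.0, nu_cult_current=0.4,
                          T=0.3, theta=600.0)
data = sample_sfs_from_expectation(expected_sfs(truth, (8, 6)), seed=7)

model = DivergenceModel(data, model="A")
result = model.fit(schedule=OptimizerSchedule.reduced(), seed=1)
result.convert(mu=6.1e-9, L=11.7e6, gen_time=1.0)
print(result.summary())
```

```
Divergence model A fit
==================================
log-likelihood     -168.962
AIC (k=4)        345.924
theta-hat          612.5012
----------------------------------
parameter           estimate       sd
nu_wild_current       1.8702   0.1692
nu_cult_founder       0.7367   0.3873
nu_cult_current       0.4833   0.1579
T                     0.2833   0.0241
----------------------------------
N_ref                         2146
N_wild_current                4013
N_cult_founder                1581
N_cult_current                1037
T_years                       1216
mu                         6.1e-09
L                         1.17e+07
gen_time                         1
convention: migrants_per_year = m_scaled / 2 / gen_time (N_ref units)
```

The fitted parameters recover the generating values within their FIM
standard deviations (ν_wild 1.87 ± 0.17 vs 2.0, T 0.283 ± 0.024 vs 0.3, θ̂
612 vs 600 on roughly 600 segregating sites); AIC across models A/B/C ranks
competing gene-flow scenarios.

A `helipop` command-line tool exposes the same steps
(`simulate`, `filter`, `stats`, `sfs`, `fit`, `run`), with `run` driving the
whole pipeline from a YAML config.

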