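"""Synthetic data generation: SFS draws and spatially structured genotypes.

Two generators exercise the whole pipeline without external data:

* :func:`sample_sfs_from_expectation` draws an observed joint SFS from a
  model expectation (independent Poisson counts per unmasked cell), the
  sampling model under which the Poisson likelihood is exact.

* :func:`simulate_structured_genotypes` builds a coalescent (msprime) panel
  of populations on a south-to-north transect with serial-founder history
  (each population founded from its southern neighbour, with successively
  smaller sizes) and stepping-stone migration.  This produces the two
  signatures of a postglacial range expansion that the statistics layer is
  meant to detect: isolation by distance and a monotone decline of
  nucleotide diversity along the transect.  Outgroup samples from a deeply
  diverged lineage allow polarization; a configurable fraction of sites is
  made non-polarizable to exercise the drop path.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import msprime
import numpy as np

from .core import PopulationMap, VariantTable
from .sfs import JointSFS
from .vcfio import write_vcf  # noqa: F401  (re-exported: simulation output IO)


@dataclass
class SimConfig:
    """Configuration of the structured-genotype simulation.

    Defaults mirror the sampling design of the wild sunflower panel the
    package targets: 16 populations spanning a latitudinal transect with
    roughly a dozen diploid samples each, and a few thousand unlinked SNPs.
    ``migration_rate`` is the per-generation fraction of a population
    replaced by migrants from each neighbouring deme.
    """

    seed: int = 1
    n_pops: int = 16
    samples_per_pop: int = 12
    n_sites: int = 5000
    migration_scheme: str = "stepping_stone"   # island | stepping_stone | none
    migration_rate: float = 5e-4
    founder_series: tuple = ()                 # default: 0..n_pops-1
    outgroup_divergence: float = 0.02          # expected substitutions/site
    n_outgroup: int = 2
    nonpolarizable_fraction: float = 0.0
    # demographic scale knobs (ancestral size, founder decay, split spacing)
    n_anc: float = 10_000.0
    founder_decay: float = 0.85
    size_jitter: float = 0.5                   # lognormal sd of deme sizes
    lat_jitter: float = 1.5                    # sd (degrees) of latitude noise
    split_spacing: float = 400.0               # generations between foundings
    mu: float = 1e-8                           # per-bp per-generation
    site_spacing: int = 600                    # target genome bp per SNP

    def __post_init__(self):
        if self.n_sites <= 0:
            raise ValueError("n_sites must be positive")
        if not 0.0 <= self.migration_rate <= 1.0:
            raise ValueError("migration_rate must be in [0, 1]")
        if self.samples_per_pop < 2:
            raise ValueError("need >= 2 samples per population "
                             "(diversity undefined otherwise)")
        if self.migration_scheme not in ("island", "stepping_stone", "none"):
            raise ValueError("unknown migration scheme "
                             f"{self.migration_scheme!r}")
        if not self.founder_series:
            self.founder_series = tuple(range(self.n_pops))
        if sorted(self.founder_series) != list(range(self.n_pops)):
            raise ValueError("founder_series must be a permutation of "
                             "population indices")


def sample_sfs_from_expectation(expected: JointSFS, seed: int) -> JointSFS:
    """Poisson-sample an observed joint SFS from a model expectation."""
    exp = expected.data
    if not np.all(np.isfinite(exp)):
        raise ValueError("expectation contains non-finite entries")
    neg = np.argwhere((exp < 0) & ~expected.mask)
    if len(neg):
        i, j = neg[0]
        raise ValueError(f"negative expectation at cell ({i}, {j}): "
                         f"{exp[i, j]}")
    rng = np.random.default_rng(seed)
    data = np.where(expected.mask, 0.0, rng.poisson(np.abs(exp)))
    return JointSFS(data, mask=expected.mask.copy(), pop_ids=expected.pop_ids)


def _build_demography(cfg: SimConfig) -> msprime.Demography:
    dem = msprime.Demography()
    rank = {pop: r for r, pop in enumerate(cfg.founder_series)}
    jitter_rng = np.random.default_rng(cfg.seed + 7)
    jitter = np.exp(jitter_rng.normal(0.0, cfg.size_jitter, cfg.n_pops))
    sizes = [cfg.n_anc * cfg.founder_decay ** rank[i] * jitter[i]
             for i in range(cfg.n_pops)]
    for i in range(cfg.n_pops):
        dem.add_population(name=f"pop{i}", initial_size=sizes[i])
    dem.add_population(name="outgroup", initial_size=cfg.n_anc)
    dem.add_population(name="anc", initial_size=cfg.n_anc)

    if cfg.migration_scheme == "island":
        for i in range(cfg.n_pops):
            for j in range(cfg.n_pops):
                if i != j:
                    dem.set_migration_rate(source=f"pop{i}", dest=f"pop{j}",
                                           rate=cfg.migration_rate)
    elif cfg.migration_scheme == "stepping_stone":
        for i in range(cfg.n_pops - 1):
            dem.set_migration_rate(source=f"pop{i}", dest=f"pop{i + 1}",
                                   rate=cfg.migration_rate)
            dem.set_migration_rate(source=f"pop{i + 1}", dest=f"pop{i}",
                                   rate=cfg.migration_rate)

    def neighbours(q):
        if cfg.migration_scheme == "island":
            return [j for j in range(cfg.n_pops) if j != q]
        if cfg.migration_scheme == "stepping_stone":
            return [j for j in (q - 1, q + 1) if 0 <= j < cfg.n_pops]
        return []

    # serial founding along the founder series (most recent first backwards)
    series = list(cfg.founder_series)
    for r in range(len(series) - 1, 0, -1):
        t = cfg.split_spacing * (len(series) - r)
        q = series[r]
        # shut off migration involving the deme just before it deactivates
        for j in neighbours(q):
            dem.add_migration_rate_change(time=t - 1e-6, rate=0.0,
                                          source=f"pop{q}", dest=f"pop{j}")
            dem.add_migration_rate_change(time=t - 1e-6, rate=0.0,
                                          source=f"pop{j}", dest=f"pop{q}")
        dem.add_population_split(time=t, derived=[f"pop{q}"],
                                 ancestral=f"pop{series[r - 1]}")
        # the founding deme keeps existing (and being sampled) at time 0
        dem[f"pop{series[r - 1]}"].initially_active = True
    t_root = cfg.split_spacing * len(series) + 1
    dem.add_population_split(time=t_root, derived=[f"pop{series[0]}"],
                             ancestral="anc")
    # outgroup joins above the ingroup root
    t_og = max(cfg.outgroup_divergence / (2 * cfg.mu), t_root + 1)
    dem.add_population(name="root", initial_size=cfg.n_anc)
    dem.add_population_split(time=t_og, derived=["anc", "outgroup"],
                             ancestral="root")
    dem.sort_events()
    return dem


def transect_coordinates(n_pops: int, lat_south: float = 32.0,
                         lat_north: float = 51.0, lon: float = -100.0,
                         lat_jitter: float = 0.0, seed: int = 0):
    """South-to-north transect latitudes (fixed longitude).

    ``lat_jitter`` adds Gaussian noise to the evenly spaced latitudes,
    emulating sampling localities that deviate from an ideal transect.
    """
    lats = np.linspace(lat_south, lat_north, n_pops)
    if lat_jitter > 0:
        rng = np.random.default_rng(seed + 13)
        lats = lats + rng.normal(0.0, lat_jitter, n_pops)
    return {f"pop{i}": (float(lats[i]), lon) for i in range(n_pops)}


def simulate_structured_genotypes(cfg: SimConfig):
    """Simulate a diploid SNP panel with spatial structure and outgroups.

    Returns ``(VariantTable, PopulationMap)``.  The table contains
    ``cfg.n_sites`` biallelic SNPs (fewer, with a warning, if the simulated
    genome yields less variation); the map assigns samples to populations
    ``pop0..popN`` (south to north) plus ``outgroup``, with transect
    coordinates for the ingroup populations.
    """
    dem = _build_demography(cfg)
    seq_len = cfg.n_sites * cfg.site_spacing
    samples = {f"pop{i}": cfg.samples_per_pop for i in range(cfg.n_pops)}
    samples["outgroup"] = cfg.n_outgroup
    ts = msprime.sim_ancestry(
        samples=samples, demography=dem, sequence_length=seq_len,
        recombination_rate=1e-8, random_seed=cfg.seed, ploidy=2)
    ts = msprime.sim_mutations(ts, rate=cfg.mu, random_seed=cfg.seed + 1)

    rng = np.random.default_rng(cfg.seed + 2)
    pop_names = [f"pop{i}" for i in range(cfg.n_pops)] + ["outgroup"]
    sample_names, pop_of = [], {}
    counters = {p: 0 for p in pop_names}
    node_ind = []  # (individual diploid) -> column pair
    for ind in ts.individuals():
        pop = pop_names[ts.node(ind.nodes[0]).population] \
            if ts.node(ind.nodes[0]).population < len(pop_names) else None
        if pop is None:
            continue
        counters[pop] += 1
        name = f"{pop}_s{counters[pop]}"
        sample_names.append(name)
        pop_of[name] = pop
        node_ind.append(tuple(ind.nodes))

    ingroup_cols = [i for i, s in enumerate(sample_names)
                    if pop_of[s] != "outgroup"]
    chrom, pos, ref, alt, geno = [], [], [], [], []
    for var in ts.variants():
        if len(var.alleles) != 2:
            continue  # multi-allelic under the nucleotide model: drop
        g = var.genotypes
        site_geno = np.array([[g[a], g[b]] for a, b in node_ind],
                             dtype=np.int8)
        ing = site_geno[ingroup_cols]
        if ing.min() == ing.max():
            continue  # outgroup-branch substitution, not an ingroup SNP
        chrom.append("1")
        pos.append(int(var.site.position) + 1)
        ref.append(var.alleles[0])
        alt.append((var.alleles[1],))
        geno.append(site_geno)
        if len(pos) >= cfg.n_sites:
            break
    if len(pos) < cfg.n_sites:
        warnings.warn(f"simulation yielded {len(pos)} biallelic SNPs "
                      f"(< requested {cfg.n_sites})", stacklevel=2)
    if not pos:
        raise RuntimeError("simulation produced no biallelic SNPs")
    genotypes = np.stack(geno)

    # force a fraction of sites to be non-polarizable (outgroup heterozygous)
    if cfg.nonpolarizable_fraction > 0:
        out_cols = [i for i, s in enumerate(sample_names)
                    if pop_of[s] == "outgroup"]
        n_force = int(round(cfg.nonpolarizable_fraction * len(pos)))
        for site in rng.choice(len(pos), size=n_force, replace=False):
            genotypes[site, out_cols[0], :] = [0, 1]

    # deduplicate positions (finite-sites collisions) keeping the first
    seen, keep = set(), []
    for i, p in enumerate(pos):
        if p not in seen:
            seen.add(p)
            keep.append(i)
    table = VariantTable(
        chrom=np.array(chrom, dtype=object)[keep],
        pos=np.array(pos)[keep],
        ref=np.array(ref, dtype=object)[keep],
        alt=[alt[i] for i in keep],
        genotypes=genotypes[keep],
        samples=sample_names,
    )
    popmap = PopulationMap(assignments=dict(pop_of),
                           coords=transect_coordinates(
                               cfg.n_pops, lat_jitter=cfg.lat_jitter,
                               seed=cfg.seed))
    return table, popmap
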