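"""SNP dataset construction: coverage/frequency filters, distance thinning,
and outgroup polarization.

The filters mirror the standard VCFtools-style pipeline for reduced-
representation SNP data: keep biallelic sites, require a minimum fraction of
called samples, apply a minor-allele frequency (strict ``>``) or minor-allele
count (``>=``) threshold, and finally thin to a minimum inter-SNP distance
with a greedy left-to-right scan per chromosome.  Polarization assigns each
site's ancestral allele from outgroup samples that are fixed for one of the
site's ingroup alleles; unpolarizable sites are dropped.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .core import VariantTable

logger = logging.getLogger(__name__)


@dataclass
class FilterSpec:
    """Filtering thresholds.

    At most one of ``maf_threshold`` / ``mac_threshold`` may be set.  MAF is
    compared strictly (frequency must exceed the threshold); MAC is a minimum
    count (a site with minor-allele count equal to the threshold is kept).
    Frequencies are computed over called genotypes only.
    """

    min_sample_coverage: float = 0.0
    maf_threshold: float | None = None
    mac_threshold: int | None = None
    thin_bp: int | None = None
    biallelic_only: bool = True

    def __post_init__(self):
        if self.maf_threshold is not None and self.mac_threshold is not None:
            raise ValueError("set at most one of maf_threshold/mac_threshold")
        if self.thin_bp is not None and self.thin_bp <= 0:
            raise ValueError("thin_bp must be positive")
        if not 0.0 <= self.min_sample_coverage <= 1.0:
            raise ValueError("min_sample_coverage must be in [0, 1]")


def filter_sites(table: VariantTable, spec: FilterSpec) -> VariantTable:
    """Apply ``spec`` in order: biallelic, coverage, MAF/MAC, thinning."""
    keep = np.ones(table.n_sites, dtype=bool)

    if spec.biallelic_only:
        keep &= np.array([len(a) == 1 for a in table.alt])

    called = table.called_mask()  # (sites, samples)
    if spec.min_sample_coverage > 0:
        frac = called.mean(axis=1) if table.n_samples else np.zeros(table.n_sites)
        keep &= frac >= spec.min_sample_coverage

    if spec.maf_threshold is not None or spec.mac_threshold is not None:
        alt_count, n_called = table.allele_counts(allele=1)
        ref_count = n_called - alt_count
        minor = np.minimum(alt_count, ref_count)
        if spec.maf_threshold is not None:
            with np.errstate(invalid="ignore", divide="ignore"):
                maf = np.where(n_called > 0, minor / np.maximum(n_called, 1), 0.0)
            keep &= maf > spec.maf_threshold
        else:
            keep &= minor >= spec.mac_threshold

    out = table.take_sites(keep)
    if spec.thin_bp is not None:
        out = thin_by_distance(out, spec.thin_bp)
    if out.n_sites == 0:
        warnings.warn("all sites removed by filtering", stacklevel=2)
    logger.info("filter_sites: %d -> %d sites", table.n_sites, out.n_sites)
    return out


def thin_by_distance(table: VariantTable, thin_bp: int) -> VariantTable:
    """Greedy per-chromosome thinning to a minimum inter-SNP spacing.

    Keeps the first site on each chromosome, then each subsequent site whose
    distance from the last *kept* site is at least ``thin_bp``.
    """
    if thin_bp <= 0:
        raise ValueError("thin_bp must be positive")
    keep = np.zeros(table.n_sites, dtype=bool)
    last_chrom, last_pos = None, None
    for i in range(table.n_sites):
        c, p = table.chrom[i], table.pos[i]
        if c != last_chrom or p - last_pos >= thin_bp:
            keep[i] = True
            last_chrom, last_pos = c, p
    return table.take_sites(keep)


def polarize(table: VariantTable, outgroup_samples) -> VariantTable:
    """Assign ancestral alleles from outgroup samples; drop unpolarizable sites.

    A site is polarizable when at least one outgroup genotype is called, all
    called outgroup genotypes are homozygous for the same allele, and that
    allele is one of the site's two alleles.  Outgroup samples are removed
    from the returned (ingroup) table, which carries per-site ancestral
    allele indices.
    """
    outgroup_samples = list(outgroup_samples)
    if not outgroup_samples:
        raise ValueError("no outgroup samples supplied")
    lookup = {s: i for i, s in enumerate(table.samples)}
    try:
        out_idx = np.array([lookup[s] for s in outgroup_samples])
    except KeyError as e:
        raise KeyError(f"outgroup sample {e.args[0]!r} not in table") from None
    in_names = [s for s in table.samples if s not in set(outgroup_samples)]

    in_idx = np.array([lookup[s] for s in in_names])
    og = table.genotypes[:, out_idx, :]  # (sites, n_out, 2)
    ig = table.genotypes[:, in_idx, :]
    ancestral = np.full(table.n_sites, -1, dtype=np.int64)
    for i in range(table.n_sites):
        g = og[i]
        called = g[np.all(g >= 0, axis=1)]
        if len(called) == 0:
            continue  # no outgroup information
        alleles = np.unique(called)
        if len(alleles) != 1:
            continue  # outgroup polymorphic or heterozygous
        a = int(alleles[0])
        ing = ig[i][ig[i] >= 0]
        ing_alleles = np.unique(ing)
        if len(ing_alleles) > 2 or a not in ing_alleles:
            continue  # third allele, or ancestral state absent from ingroup
        ancestral[i] = a

    keep = ancestral >= 0
    dropped = int((~keep).sum())
    if dropped:
        logger.info("polarize: dropped %d unpolarizable sites", dropped)
    out = table.take_sites(keep).take_samples(in_names)
    out.ancestral = ancestral[keep]
    return out
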