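"""Unfolded joint (2D) site-frequency spectra.

The :class:`JointSFS` holds counts of segregating sites indexed by derived-
allele count in each of two populations, with the absorbing corners (fixed
ancestral [0,0] and fixed derived [n1,n2]) masked.  Spectra can be built from
polarized genotype tables, projected to smaller sample sizes by hypergeometric
downsampling, and serialized to a plain-text format with bit-exact round-trip.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
from scipy.special import gammaln

from .core import PopulationMap, VariantTable


class JointSFS:
    """Unfolded 2D SFS for (pop1, pop2) with haplotype sample sizes (n1, n2).

    ``data`` has shape (n1+1, n2+1); ``mask`` is boolean with the same shape,
    True marking cells excluded from likelihoods and summaries.  At minimum
    the two absorbing corners are masked.
    """

    def __init__(self, data, mask=None, pop_ids=("pop1", "pop2")):
        self.data = np.asarray(data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("joint SFS must be 2-dimensional")
        if mask is None:
            mask = corner_mask(self.data.shape)
        self.mask = np.asarray(mask, dtype=bool)
        if self.mask.shape != self.data.shape:
            raise ValueError("mask shape must match data shape")
        self.pop_ids = tuple(pop_ids)
        self.folded = False

    @property
    def sample_sizes(self):
        return (self.data.shape[0] - 1, self.data.shape[1] - 1)

    def unmasked_sum(self) -> float:
        return float(self.data[~self.mask].sum())

    def copy(self) -> "JointSFS":
        return JointSFS(self.data.copy(), self.mask.copy(), self.pop_ids)

    def __repr__(self):
        n1, n2 = self.sample_sizes
        return (f"JointSFS(n1={n1}, n2={n2}, pops={self.pop_ids}, "
                f"S={self.unmasked_sum():.1f})")

    # -- plain-text serialization ------------------------------------------
    def to_file(self, path):
        n1, n2 = self.data.shape
        with open(path, "w") as fh:
            fh.write(f"{n1} {n2} unfolded\n")
            for row in self.data:
                fh.write(" ".join(np.format_float_positional(
                    v, unique=True, trim="0") for v in row) + "\n")
            for row in self.mask:
                fh.write(" ".join("1" if m else "0" for m in row) + "\n")

    @classmethod
    def from_file(cls, path) -> "JointSFS":
        lines = Path(path).read_text().splitlines()
        header = lines[0].split()
        n1, n2 = int(header[0]), int(header[1])
        if header[2] != "unfolded":
            raise ValueError("only unfolded spectra are supported")
        data = np.array([[float(v) for v in lines[1 + i].split()]
                         for i in range(n1)])
        mask = np.array([[c == "1" for c in lines[1 + n1 + i].split()]
                         for i in range(n1)])
        return cls(data, mask)


def corner_mask(shape) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    mask[0, 0] = True
    mask[-1, -1] = True
    return mask


def site_derived_counts(table: VariantTable, popmap: PopulationMap, pops):
    """Per-site derived-allele and called-haplotype counts for two groups.

    Returns arrays (d1, n1, d2, n2) of length n_sites.  Requires a polarized
    table; the derived allele at a site is the biallelic allele that is not
    ancestral (heterozygotes contribute one derived copy).
    """
    if not table.is_polarized:
        raise ValueError("table must be polarized before SFS construction")
    out = []
    for pop in pops:
        idx = popmap.sample_indices(table, pop)
        if len(idx) == 0:
            raise ValueError(f"population {pop!r} has no samples in table")
        g = table.genotypes[:, idx, :]
        called = g >= 0
        n = called.sum(axis=(1, 2))
        anc = table.ancestral[:, None, None]
        d = ((g >= 0) & (g != anc)).sum(axis=(1, 2))
        out.extend([d, n])
    d1, n1, d2, n2 = out
    return d1, n1, d2, n2


def build_sfs(table: VariantTable, popmap: PopulationMap, pops) -> JointSFS:
    """Tally the unfolded joint SFS from sites fully called in both groups."""
    d1, n1, d2, n2 = site_derived_counts(table, popmap, pops)
    full1 = 2 * len(popmap.sample_indices(table, pops[0]))
    full2 = 2 * len(popmap.sample_indices(table, pops[1]))
    use = (n1 == full1) & (n2 == full2)
    data = np.zeros((full1 + 1, full2 + 1))
    np.add.at(data, (d1[use], d2[use]), 1.0)
    return JointSFS(data, pop_ids=tuple(pops))


def _projection_matrix(n_from: int, n_to: int) -> np.ndarray:
    """Hypergeometric projection weights W[d, k] = P(k derived in n_to | d of n_from)."""
    if n_to > n_from:
        raise ValueError("cannot project to a larger sample size")
    d = np.arange(n_from + 1)[:, None]
    k = np.arange(n_to + 1)[None, :]

    def logc(a, b):
        # log C(a, b), -inf outside support
        with np.errstate(invalid="ignore"):
            out = gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)
        return np.where((b >= 0) & (b <= a), out, -np.inf)

    logw = logc(d, k) + logc(n_from - d, n_to - k) - logc(n_from, n_to)
    return np.exp(logw)


def project_sfs(sfs_or_counts, target, pop_ids=("pop1", "pop2")) -> JointSFS:
    """Project to smaller sample sizes by hypergeometric downsampling.

    Accepts either a :class:`JointSFS` (projects the whole spectrum; this is
    exact when the original spectrum had no missing data) or per-site counts
    (d1, n1, d2, n2) as returned by :func:`site_derived_counts`, in which case
    each site is projected from its own called sample sizes and sites with
    fewer called haplotypes than the target are dropped.
    """
    t1, t2 = target
    if isinstance(sfs_or_counts, JointSFS):
        n1, n2 = sfs_or_counts.sample_sizes
        w1 = _projection_matrix(n1, t1)
        w2 = _projection_matrix(n2, t2)
        data = w1.T @ sfs_or_counts.data @ w2
        return JointSFS(data, pop_ids=sfs_or_counts.pop_ids)

    d1, n1, d2, n2 = (np.asarray(a) for a in sfs_or_counts)
    use = (n1 >= t1) & (n2 >= t2)
    data = np.zeros((t1 + 1, t2 + 1))
    cache = {}
    for dd1, nn1, dd2, nn2 in zip(d1[use], n1[use], d2[use], n2[use]):
        key1, key2 = (int(nn1), t1), (int(nn2), t2)
        if key1 not in cache:
            cache[key1] = _projection_matrix(*key1)
        if key2 not in cache:
            cache[key2] = _projection_matrix(*key2)
        data += np.outer(cache[key1][int(dd1)], cache[key2][int(dd2)])
    return JointSFS(data, pop_ids=tuple(pop_ids))


def build_projected_sfs(table, popmap, pops, target) -> JointSFS:
    """Build a projected joint SFS directly from a polarized table.

    Projection from per-site called sample sizes maximizes the number of
    usable sites under missing data (sites below the target are dropped).
    """
    counts = site_derived_counts(table, popmap, pops)
    return project_sfs(counts, target, pop_ids=tuple(pops))
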