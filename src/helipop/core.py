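"""Core in-memory containers: genotype tables and population maps.

A :class:`VariantTable` is a site x sample matrix of diploid genotypes with
per-site allele metadata, the common currency of the filtering, statistics and
SFS-building layers.  A :class:`PopulationMap` assigns samples to populations
and carries per-population geographic coordinates.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

MISSING = -1  # missing allele call in genotype arrays


@dataclass
class VariantTable:
    """Diploid genotypes at variant sites.

    Parameters
    ----------
    chrom : array of str, shape (n_sites,)
        Chromosome identifier per site.
    pos : array of int, shape (n_sites,)
        1-based position per site, strictly increasing within a chromosome.
    ref : array of str, shape (n_sites,)
        Reference allele.
    alt : list of tuple of str, length n_sites
        Alternate allele(s) per site.
    genotypes : int8 array, shape (n_sites, n_samples, 2)
        Allele indices (0 = ref, 1 = first alt, ...); ``MISSING`` (-1) marks
        an uncalled allele.  Both alleles of a genotype are either called or
        missing.
    samples : list of str
    ancestral : int array, shape (n_sites,), optional
        Allele index of the ancestral state (set by polarization); -1 where
        unknown.
    """

    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: list
    genotypes: np.ndarray
    samples: list
    ancestral: np.ndarray | None = None

    def __post_init__(self):
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=object)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.ndim != 3 or self.genotypes.shape[2] != 2:
            raise ValueError("genotypes must have shape (n_sites, n_samples, 2)")
        if self.ancestral is not None:
            self.ancestral = np.asarray(self.ancestral, dtype=np.int64)
        self.validate()

    # -- basic properties ---------------------------------------------------
    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[1]

    @property
    def is_polarized(self) -> bool:
        return self.ancestral is not None

    def validate(self):
        n = self.n_sites
        if not (len(self.chrom) == len(self.ref) == len(self.alt) == n
                and self.genotypes.shape[0] == n):
            raise ValueError("inconsistent per-site array lengths")
        if len(self.samples) != self.n_samples:
            raise ValueError("sample list does not match genotype matrix")
        for c in pd.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if len(p) > 1 and not np.all(np.diff(p) > 0):
                raise ValueError(
                    f"positions not strictly increasing on chromosome {c}")

    # -- selection helpers --------------------------------------------------
    def take_sites(self, idx) -> "VariantTable":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        else:
            idx = idx.astype(np.int64)
        return VariantTable(
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            ref=self.ref[idx],
            alt=[self.alt[i] for i in idx],
            genotypes=self.genotypes[idx],
            samples=list(self.samples),
            ancestral=None if self.ancestral is None else self.ancestral[idx],
        )

    def take_samples(self, names) -> "VariantTable":
        lookup = {s: i for i, s in enumerate(self.samples)}
        try:
            cols = [lookup[s] for s in names]
        except KeyError as e:
            raise KeyError(f"unknown sample {e.args[0]!r}") from None
        return VariantTable(
            chrom=self.chrom, pos=self.pos, ref=self.ref, alt=list(self.alt),
            genotypes=self.genotypes[:, cols, :], samples=list(names),
            ancestral=self.ancestral,
        )

    def called_mask(self) -> np.ndarray:
        """Boolean (n_sites, n_samples): genotype fully called."""
        return np.all(self.genotypes >= 0, axis=2)

    def allele_counts(self, allele: int = 1, sample_idx=None):
        """Per-site (count of `allele`, number of called haplotypes)."""
        g = self.genotypes if sample_idx is None else self.genotypes[:, sample_idx, :]
        called = g >= 0
        return (g == allele).sum(axis=(1, 2)), called.sum(axis=(1, 2))

    def equals(self, other: "VariantTable") -> bool:
        return (
            list(self.samples) == list(other.samples)
            and np.array_equal(self.chrom, other.chrom)
            and np.array_equal(self.pos, other.pos)
            and np.array_equal(self.ref, other.ref)
            and list(map(tuple, self.alt)) == list(map(tuple, other.alt))
            and np.array_equal(self.genotypes, other.genotypes)
        )


@dataclass
class PopulationMap:
    """Sample -> population assignment with per-population coordinates.

    ``coords`` maps population -> (latitude, longitude) in decimal degrees;
    it may be empty for analyses that do not need geography.
    """

    assignments: dict
    coords: dict = field(default_factory=dict)

    @property
    def populations(self) -> list:
        seen = {}
        for p in self.assignments.values():
            seen.setdefault(p, None)
        return list(seen)

    def samples_for(self, pop) -> list:
        return [s for s, p in self.assignments.items() if p == pop]

    def sample_indices(self, table: VariantTable, pop) -> np.ndarray:
        wanted = set(self.samples_for(pop))
        return np.array([i for i, s in enumerate(table.samples) if s in wanted],
                        dtype=np.int64)

    # -- plain-text serialization ------------------------------------------
    def write(self, popmap_path, coords_path=None):
        with open(popmap_path, "w") as fh:
            for s, p in self.assignments.items():
                fh.write(f"{s}\t{p}\n")
        if coords_path is not None:
            with open(coords_path, "w") as fh:
                fh.write("population\tlat\tlon\n")
                for p, (lat, lon) in self.coords.items():
                    fh.write(f"{p}\t{lat}\t{lon}\n")

    @classmethod
    def read(cls, popmap_path, coords_path=None) -> "PopulationMap":
        assignments = {}
        for line in Path(popmap_path).read_text().splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            sample, pop = line.split()[:2]
            assignments[sample] = pop
        coords = {}
        if coords_path is not None:
            df = pd.read_csv(coords_path, sep="\t")
            for _, row in df.iterrows():
                coords[str(row["population"])] = (float(row["lat"]),
                                                  float(row["lon"]))
        return cls(assignments=assignments, coords=coords)
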