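import numpy as np
import pytest

from helipop.core import PopulationMap, VariantTable


def make_table(genotypes, pos=None, chrom=None, samples=None, ancestral=None):
    """Build a VariantTable from an (n_sites, n_samples, 2) int array."""
    g = np.asarray(genotypes, dtype=np.int8)
    n_sites, n_samples, _ = g.shape
    return VariantTable(
        chrom=np.array(chrom if chrom is not None else ["1"] * n_sites,
                       dtype=object),
        pos=np.array(pos if pos is not None
                     else np.arange(1, n_sites + 1) * 10),
        ref=np.array(["A"] * n_sites, dtype=object),
        alt=[("G",)] * n_sites,
        genotypes=g,
        samples=samples or [f"s{i}" for i in range(n_samples)],
        ancestral=ancestral,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def two_pop_table(rng):
    """Random 12-site, 2x4-sample biallelic table with a PopulationMap."""
    g = rng.integers(0, 2, size=(12, 8, 2), dtype=np.int8)
    table = make_table(g)
    popmap = PopulationMap(
        {f"s{i}": ("p1" if i < 4 else "p2") for i in range(8)},
        coords={"p1": (35.0, -100.0), "p2": (45.0, -100.0)})
    return table, popmap
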