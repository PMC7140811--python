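"""Reading and writing VCF files.

Reading goes through cyvcf2 (handles plain and bgzipped VCF 4.x); writing
emits minimal, standards-conformant VCF 4.2 with diploid GT fields, which is
all the synthetic-data and pipeline layers need.  Genotypes round-trip
exactly, including missing calls ("./.").
"""
from __future__ import annotations

import numpy as np
from cyvcf2 import VCF

from .core import MISSING, VariantTable


def read_vcf(path, samples=None) -> VariantTable:
    """Load a VCF into a :class:`VariantTable`.

    Parameters
    ----------
    path : str or Path
        Plain or gzipped VCF.
    samples : list of str, optional
        Restrict to these samples (order preserved).
    """
    vcf = VCF(str(path), gts012=False)
    if samples is not None:
        vcf.set_samples(samples)
    names = list(vcf.samples)
    chrom, pos, ref, alt, gts, anc = [], [], [], [], [], []
    any_aa = False
    for var in vcf:
        chrom.append(var.CHROM)
        pos.append(var.POS)
        ref.append(var.REF)
        alleles = (var.REF,) + tuple(var.ALT)
        alt.append(tuple(var.ALT))
        aa = var.INFO.get("AA")
        if aa is not None and aa in alleles:
            anc.append(alleles.index(aa))
            any_aa = True
        else:
            anc.append(-1)
        # genotype.array(): columns [allele1, allele2, phased]; -1 = missing
        g = var.genotype.array()[:, :2]
        gts.append(g)
    vcf.close()
    if not chrom:
        geno = np.zeros((0, len(names), 2), dtype=np.int8)
    else:
        geno = np.asarray(gts, dtype=np.int8)
    geno[geno < 0] = MISSING
    return VariantTable(chrom=np.array(chrom, dtype=object),
                        pos=np.array(pos, dtype=np.int64),
                        ref=np.array(ref, dtype=object),
                        alt=alt, genotypes=geno, samples=names,
                        ancestral=np.array(anc) if any_aa else None)


def write_vcf(table: VariantTable, path, popmap=None):
    """Write a :class:`VariantTable` as plain-text VCF 4.2.

    ``popmap`` is unused for the record format but accepted so callers can
    pass the full simulation output through one call site.  Sites must be
    sorted (strictly increasing positions per chromosome); the table
    validates this on construction.
    """
    if table.n_sites == 0:
        raise ValueError("refusing to write an empty VariantTable")
    contigs = []
    for c in table.chrom:
        if c not in contigs:
            contigs.append(c)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=helipop\n")
        for c in contigs:
            length = int(table.pos[table.chrom == c].max()) + 1
            fh.write(f"##contig=<ID={c},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if table.is_polarized:
            fh.write('##INFO=<ID=AA,Number=1,Type=String,'
                     'Description="Ancestral allele">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(table.samples) + "\n")
        for i in range(table.n_sites):
            alleles = (table.ref[i],) + tuple(table.alt[i])
            if table.is_polarized and table.ancestral[i] >= 0:
                info = f"AA={alleles[table.ancestral[i]]}"
            else:
                info = "."
            cells = []
            for a1, a2 in table.genotypes[i]:
                if a1 < 0 or a2 < 0:
                    cells.append("./.")
                else:
                    cells.append(f"{a1}/{a2}")
            alt_field = ",".join(table.alt[i]) if table.alt[i] else "."
            fh.write(f"{table.chrom[i]}\t{table.pos[i]}\t.\t{table.ref[i]}\t"
                     f"{alt_field}\t.\tPASS\t{info}\tGT\t" + "\t".join(cells)
                     + "\n")
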