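import numpy as np
import pytest

from archintro.core_io import (
    ARCHAIC,
    HET,
    MISSING,
    MODERN_CARRIER,
    MODERN_NONCARRIER,
    GeneticMap,
    HaplotypePanel,
    RegionMask,
    VariantSite,
)


def make_site(pos, chrom="chr1", ref="A", alt="G", **kw):
    return VariantSite(chrom=chrom, pos=pos, id=f"s{pos}", ref_allele=ref, alt_allele=alt, **kw)


def make_panel(alleles, positions=None, groups=None, chrom="chr1", sites=None):
    """Convenience constructor for small hand-built panels."""
    alleles = np.asarray(alleles, dtype=np.int8)
    n_hap, n_sites = alleles.shape
    if sites is None:
        if positions is None:
            positions = [100 * (j + 1) for j in range(n_sites)]
        sites = [make_site(p, chrom=chrom) for p in positions]
    if groups is None:
        groups = [MODERN_NONCARRIER] * n_hap
    ids = []
    n_arch = 0
    for i, g in enumerate(groups):
        if g == ARCHAIC:
            ids.append(f"arch{n_arch}")
            n_arch += 1
        elif g == "ancestral":
            ids.append("ancestral")
        else:
            ids.append(f"h{i}")
    return HaplotypePanel(haplotype_ids=ids, alleles=alleles, sites=sites, group_labels=groups)


@pytest.fixture
def uniform_map():
    """1 cM/Mb over [1, 10 Mb]."""
    return GeneticMap(
        positions=np.array([1.0, 10_000_000.0]),
        cumulative_cM=np.array([0.0, (10_000_000 - 1) / 1e6]),
        chrom="chr1",
    )


@pytest.fixture
def full_mask():
    return RegionMask({"chr1": np.array([[0, 10_000_000]])})


def write_toy_vcf(path, records, samples=("S1", "S2"), archaic=(), header_extra=()):
    """records: list of (chrom,pos,id,ref,alt,info,genotype strings...)"""
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "##contig=<ID=chr1>",
        "##contig=<ID=chr8>",
    ]
    lines.extend(header_extra)
    if archaic:
        lines.append("##archaic_samples=" + ",".join(archaic))
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples)
    )
    for rec in records:
        chrom, pos, rid, ref, alt, info, *gts = rec
        lines.append(
            f"{chrom}\t{pos}\t{rid}\t{ref}\t{alt}\t.\tPASS\t{info}\tGT\t" + "\t".join(gts)
        )
    path.write_text("\n".join(lines) + "\n")
    return path
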