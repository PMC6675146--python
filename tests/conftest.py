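"""Shared fixtures: tiny hand-constructed genomic inputs, built at test time."""

from __future__ import annotations

import numpy as np
import pytest

from saltscan.io_filters import PopulationMap, VariantTable


def make_table(
    genotypes,
    chrom="chr1",
    pos=None,
    depth=20.0,
    samples=None,
    biallelic=None,
):
    """Build a VariantTable from a (n_sites, n_samples) dosage list."""
    g = np.asarray(genotypes, dtype=np.int8)
    n_sites, n_samples = g.shape
    if pos is None:
        pos = np.arange(n_sites) * 100 + 10
    pos = np.asarray(pos, dtype=np.int64)
    if samples is None:
        samples = [f"s{i}" for i in range(n_samples)]
    chrom_arr = (
        np.array(chrom, dtype=object)
        if not np.isscalar(chrom)
        else np.full(n_sites, chrom, dtype=object)
    )
    depth_arr = (
        np.asarray(depth, dtype=float)
        if not np.isscalar(depth)
        else np.full(n_sites, float(depth))
    )
    return VariantTable(
        chrom=chrom_arr,
        pos=pos,
        ref_allele=np.full(n_sites, "A", dtype=object),
        alt_allele=np.full(n_sites, "T", dtype=object),
        genotypes=g,
        site_mean_depth=depth_arr,
        samples=list(samples),
        is_biallelic=(
            np.ones(n_sites, dtype=bool) if biallelic is None
            else np.asarray(biallelic, dtype=bool)
        ),
    )


@pytest.fixture
def four_sample_popmap():
    return PopulationMap(
        {"s0": "upland", "s1": "upland", "s2": "saltmarsh", "s3": "saltmarsh"}
    )


TOY_VCF = """\
##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##contig=<ID=chr1,length=1000>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ta\tb\tc\td
chr1\t100\t.\tA\tT\t.\tPASS\t.\tGT:DP\t0/0:20\t0/1:18\t1/1:22\t0/0:20
chr1\t200\t.\tC\tG\t.\tPASS\t.\tGT:DP\t./.:0\t0/1:20\t0/0:20\t0/1:20
chr1\t300\t.\tG\tA\t.\tPASS\t.\tGT:DP\t1/1:25\t1/1:19\t0/1:21\t0/0:20
"""


@pytest.fixture
def toy_vcf(tmp_path):
    p = tmp_path / "toy.vcf"
    p.write_text(TOY_VCF)
    return p


@pytest.fixture
def toy_popmap_file(tmp_path):
    p = tmp_path / "popmap.tsv"
    p.write_text("a\tupland\nb\tupland\nc\tsaltmarsh\nd\tsaltmarsh\n")
    return p


@pytest.fixture
def toy_bed(tmp_path):
    p = tmp_path / "exons.bed"
    p.write_text("chr1\t100\t200\nchr1\t150\t250\nchr2\t0\t50\n")
    return p


@pytest.fixture
def toy_gff(tmp_path):
    p = tmp_path / "genes.gff3"
    p.write_text(
        "##gff-version 3\n"
        "chr1\ttest\tgene\t101\t200\t.\t+\t.\tID=geneA;Name=GENEA\n"
        "chr1\ttest\tgene\t151\t260\t.\t-\t.\tID=geneB\n"
        "chr2\ttest\tgene\t501\t900\t.\t+\t.\tID=geneC\n"
    )
    return p
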