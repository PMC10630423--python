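import numpy as np
import pandas as pd
import pytest

from euradmix import simdata
from euradmix.genio import GenotypeSet

# pairwise cluster F_ST targets used throughout: the subcontinental scale
PAIRWISE_FST = np.array(
    [[0.0, 0.033, 0.032], [0.033, 0.0, 0.028], [0.032, 0.028, 0.0]]
)


@pytest.fixture(scope="session")
def small_panel():
    """Two-cluster Balding–Nichols panel, moderate drift, 2,000 SNPs."""
    return simdata.draw_ancestral_frequencies(
        2000, np.array([[0.0, 0.05], [0.05, 0.0]]), seed=101
    )


@pytest.fixture(scope="session")
def three_way_panel():
    """Three-cluster panel at the subcontinental F_ST scale, 3,000 SNPs."""
    return simdata.draw_ancestral_frequencies(3000, PAIRWISE_FST, seed=102)


@pytest.fixture(scope="session")
def admixed_cohort(small_panel):
    """120 two-way admixed individuals with Dirichlet(1,1) proportions."""
    rng = np.random.default_rng(103)
    alpha = rng.dirichlet([1.0, 1.0], 120)
    gset, truth = simdata.simulate_admixed_cohort(
        small_panel, 120, alpha, generations=20, seed=104
    )
    return gset, truth


@pytest.fixture
def tiny_vcf(tmp_path):
    """Handcrafted 2-sample, 3-SNP phased VCF."""
    text = (
        "##fileformat=VCFv4.2\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        "##contig=<ID=1>\n"
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\n"
        "1\t100\trs1\tA\tG\t.\t.\t.\tGT\t0|0\t1|0\n"
        "1\t200\trs2\tC\tT\t.\t.\t.\tGT\t0|1\t1|1\n"
        "1\t300\trs3\tG\tA\t.\t.\t.\tGT\t1|1\t0|0\n"
    )
    path = tmp_path / "tiny.vcf"
    path.write_text(text)
    return path


def stack_cohorts(a: GenotypeSet, b: GenotypeSet) -> GenotypeSet:
    """Concatenate two cohorts that share a variant table."""
    haps = None
    if a.is_phased and b.is_phased:
        haps = np.vstack([a.haplotypes, b.haplotypes])
    return GenotypeSet(
        np.vstack([a.genotypes, b.genotypes]),
        a.variants,
        pd.concat([a.samples, b.samples], ignore_index=True),
        haplotypes=haps,
    )
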