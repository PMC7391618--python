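import numpy as np
import pytest

from herddiv import haploblocks as hb
from herddiv.datamodel import GenotypeMatrix, HaplotypeMatrix, MarkerMap
from herddiv.diversity import breed_allele_counts
from herddiv.simulate import simulate_hierarchical


@pytest.fixture(scope="session")
def small_cohort():
    """Three drifted breeds, 240 SNPs on a uniform 10 kb map."""
    h, breeds, truth = simulate_hierarchical(
        3, 10, 240, fst=[0.05, 0.1, 0.2], inbreeding=[0.0, 0.0, 0.3],
        snps_per_chrom=80, seed=11,
    )
    return h, breeds, truth


@pytest.fixture(scope="session")
def small_blocks(small_cohort):
    h, breeds, _ = small_cohort
    blocks = hb.build_blocks(h.markers)
    bg = hb.encode_block_alleles(h, blocks)
    table = breed_allele_counts(bg, breeds)
    return blocks, bg, table


def make_markers(positions, chrom="1", prefix="s"):
    positions = list(positions)
    return MarkerMap(
        np.array([f"{prefix}{i}" for i in range(len(positions))], object),
        np.array([chrom] * len(positions), object),
        np.array(positions, np.int64),
    )


@pytest.fixture
def markers_factory():
    return make_markers


def make_genotypes(dosage, chrom="1"):
    dosage = np.asarray(dosage, np.int8)
    markers = make_markers(range(1, dosage.shape[1] * 10_000, 10_000)[: dosage.shape[1]])
    # range slicing above yields exactly one position per SNP
    return GenotypeMatrix(
        [f"ind{i}" for i in range(dosage.shape[0])], markers, dosage
    )


@pytest.fixture
def genotypes_factory():
    return make_genotypes
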