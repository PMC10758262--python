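"""Shared fixtures: the six-haplotype worked example and small synthetic data.

The worked example has two regions on one chromosome: region A's rare
alleles are carried by haplotypes 1 and 4 (1-based), region B's by
haplotypes 3, 4 and 5 — so P(A) = 2/6, P(B) = 3/6, P(AB) = 1/6.
"""

from __future__ import annotations

import numpy as np
import pytest

from cld.haplotype_io import HaplotypeMatrix, Region, RegionSet, VariantRecord


def toy_matrix() -> tuple[HaplotypeMatrix, RegionSet]:
    """Six haplotypes, two regions; carriers A={1,4}, B={3,4,5} (1-based)."""
    # region A: [100, 200); region B: [300, 400)  (0-based half-open)
    # columns: two singleton variants in A, three in B
    values = np.zeros((6, 5), dtype=np.uint8)
    values[0, 0] = 1  # hap 1 carries A-variant at pos0 120
    values[3, 1] = 1  # hap 4 carries A-variant at pos0 150
    values[2, 2] = 1  # hap 3 carries B-variant at pos0 310
    values[3, 3] = 1  # hap 4 carries B-variant at pos0 350
    values[4, 4] = 1  # hap 5 carries B-variant at pos0 390
    variants = [
        VariantRecord("chr1", 121, "A>T", 1 / 6),
        VariantRecord("chr1", 151, "C>G", 1 / 6),
        VariantRecord("chr1", 311, "G>A", 1 / 6),
        VariantRecord("chr1", 351, "T>C", 1 / 6),
        VariantRecord("chr1", 391, "A>C", 1 / 6),
    ]
    sample_ids = [(f"S{i}", h) for i in range(3) for h in (0, 1)]
    H = HaplotypeMatrix(values, variants, sample_ids)
    regions = RegionSet(
        [Region("chr1", 100, 200, "A"), Region("chr1", 300, 400, "B")]
    )
    return H, regions


@pytest.fixture
def toy():
    return toy_matrix()


def write_toy_vcf(path) -> None:
    """The worked example as a phased VCF (3 diploid samples)."""
    from cld.haplotype_io import write_vcf

    H, _ = toy_matrix()
    write_vcf(H, path)


@pytest.fixture
def toy_files(tmp_path):
    """Toy VCF + BED on disk."""
    from cld.haplotype_io import write_bed

    vcf = tmp_path / "toy.vcf"
    bed = tmp_path / "toy.bed"
    write_toy_vcf(vcf)
    _, regions = toy_matrix()
    write_bed(regions, bed)
    return vcf, bed


@pytest.fixture
def rng():
    return np.random.default_rng(0)
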