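"""Phased-haplotype and region input.

Reads phased VCF genotypes into a binary haplotype × variant matrix
(two rows per diploid sample, 1 = minor allele in the loaded sample),
reads BED4+ region definitions, and applies the rare-variant MAF filter.

Conventions
-----------
* Alleles are re-oriented on load so that the stored allele is the minor
  one; at a frequency tie of exactly 0.5 the ALT allele is kept.
* Multi-allelic sites are expanded into one binary column per ALT allele.
* Missing alleles (``.``) are stored as 0 (non-carrier) and counted per
  variant; this is a documented convention, not imputation.
* Internal coordinates are 0-based half-open (BED convention); the
  ``pos`` field of a variant keeps the 1-based VCF position.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from cyvcf2 import VCF

logger = logging.getLogger("cld")

DEFAULT_MAF_CUTOFF = 0.005


class PhasingError(ValueError):
    """A genotype was not phased (``/`` separator)."""


@dataclass(frozen=True)
class VariantRecord:
    """One binary variant column.

    ``pos`` is the 1-based position as in the VCF source; ``pos0`` gives
    the 0-based coordinate used for region membership. ``maf`` is the
    minor-allele frequency computed from the loaded haplotypes only.
    """

    chrom: str
    pos: int
    ref_alt: str
    maf: float
    missing: int = 0

    @property
    def pos0(self) -> int:
        return self.pos - 1

    def __post_init__(self) -> None:
        if not (0.0 <= self.maf <= 0.5):
            raise ValueError(f"maf must be in [0, 0.5], got {self.maf}")


@dataclass
class HaplotypeMatrix:
    """Binary haplotypes (rows) × variants (columns).

    ``sample_ids`` maps each row to a ``(sample, haplotype_index)`` pair;
    diploid samples contribute two consecutive rows.
    """

    values: np.ndarray
    variants: list[VariantRecord]
    sample_ids: list[tuple[str, int]]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.uint8)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if self.values.shape[1] != len(self.variants):
            raise ValueError("column count must equal number of variants")
        if self.values.shape[0] != len(self.sample_ids):
            raise ValueError("row count must equal number of haplotype ids")
        if self.values.size and self.values.max() > 1:
            raise ValueError("haplotype matrix must be binary")

    @property
    def n_haplotypes(self) -> int:
        return self.values.shape[0]

    @property
    def n_variants(self) -> int:
        return self.values.shape[1]

    def mafs(self) -> np.ndarray:
        """Per-column allele frequency of the stored (minor) allele."""
        if self.n_haplotypes == 0:
            return np.zeros(self.n_variants)
        return self.values.mean(axis=0)

    def columns_in(self, region: "Region") -> np.ndarray:
        """Indices of variant columns inside ``region`` (0-based half-open)."""
        idx = [
            j
            for j, v in enumerate(self.variants)
            if v.chrom == region.chrom and region.start <= v.pos0 < region.end
        ]
        return np.asarray(idx, dtype=int)

    def subset_rows(self, rows: Sequence[int]) -> "HaplotypeMatrix":
        rows = list(rows)
        return HaplotypeMatrix(
            self.values[rows],
            list(self.variants),
            [self.sample_ids[i] for i in rows],
        )


@dataclass(frozen=True, order=True)
class Region:
    chrom: str
    start: int
    end: int
    name: str = field(compare=False, default="")

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"region {self.name!r}: start ({self.start}) must be < end ({self.end})"
            )

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)


@dataclass
class RegionSet:
    """Named genomic intervals, sorted by (chrom, start), unique names."""

    regions: list[Region]

    def __post_init__(self) -> None:
        names = [r.name for r in self.regions]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ValueError(f"duplicate region names: {sorted(dupes)}")
        self.regions = sorted(self.regions, key=lambda r: (r.chrom, r.start, r.end))

    def __iter__(self):
        return iter(self.regions)

    def __len__(self) -> int:
        return len(self.regions)

    def __getitem__(self, name: str) -> Region:
        for r in self.regions:
            if r.name == name:
                return r
        raise KeyError(name)


# ---------------------------------------------------------------------------
# loading


def load_haplotypes(
    vcf_path: str | Path,
    samples: Iterable[str] | None = None,
    chrom_filter: str | None = None,
) -> HaplotypeMatrix:
    """Load a phased VCF into a binary haplotype matrix.

    Parameters
    ----------
    vcf_path
        Path to a VCF (plain or bgzipped) with phased GT fields.
    samples
        Optional sample-ID subset; every ID must exist in the VCF.
    chrom_filter
        Optional chromosome name; records on other chromosomes are skipped.

    Raises
    ------
    PhasingError
        If any retained genotype uses the unphased ``/`` separator.
    KeyError
        If a requested sample is absent from the VCF.
    """
    vcf = VCF(str(vcf_path))
    if samples is not None:
        samples = list(samples)
        missing = [s for s in samples if s not in vcf.samples]
        if missing:
            raise KeyError(f"sample(s) not in VCF: {missing}")
        vcf.set_samples(samples)
    sample_names = list(vcf.samples)
    n_hap = 2 * len(sample_names)

    columns: list[np.ndarray] = []
    variants: list[VariantRecord] = []
    for rec in vcf:
        if chrom_filter is not None and rec.CHROM != chrom_filter:
            continue
        gts = rec.genotypes  # per sample: [allele0, allele1, phased]
        alleles = np.empty((len(sample_names), 2), dtype=np.int16)
        for i, g in enumerate(gts):
            if len(g) == 2:  # haploid call: duplicate it
                alleles[i] = (g[0], g[0])
                continue
            a0, a1, phased = g[0], g[1], g[-1]
            if not phased and not (a0 < 0 and a1 < 0):
                raise PhasingError(
                    f"unphased genotype for sample {sample_names[i]!r} at "
                    f"{rec.CHROM}:{rec.POS} ({rec.REF}>{','.join(rec.ALT)})"
                )
            alleles[i] = (a0, a1)
        flat = alleles.reshape(-1)  # haplotype order: (s0,h0),(s0,h1),(s1,h0)...
        n_missing = int((flat < 0).sum())
        if n_missing:
            logger.info(
                "%s:%d: %d missing allele(s) treated as major",
                rec.CHROM,
                rec.POS,
                n_missing,
            )
        for alt_index, alt in enumerate(rec.ALT, start=1):
            col = (flat == alt_index).astype(np.uint8)
            freq = col.mean() if n_hap else 0.0
            if freq > 0.5:  # re-orient: stored allele is the minor one
                col = np.where(flat < 0, 0, 1 - col).astype(np.uint8)
                freq = col.mean()
            variants.append(
                VariantRecord(
                    chrom=rec.CHROM,
                    pos=rec.POS,
                    ref_alt=f"{rec.REF}>{alt}",
                    maf=float(freq),
                    missing=n_missing,
                )
            )
            columns.append(col)

    values = (
        np.column_stack(columns) if columns else np.zeros((n_hap, 0), dtype=np.uint8)
    )
    sample_ids = [(s, h) for s in sample_names for h in (0, 1)]
    return HaplotypeMatrix(values, variants, sample_ids)


def load_regions(bed_path: str | Path) -> RegionSet:
    """Read a BED4+ file (chrom, start, end, name) into a RegionSet."""
    regions = []
    with open(bed_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise ValueError(
                    f"{bed_path}:{lineno}: BED4+ required (chrom, start, end, name)"
                )
            chrom, start, end, name = parts[0], int(parts[1]), int(parts[2]), parts[3]
            regions.append(Region(chrom=chrom, start=start, end=end, name=name))
    return RegionSet(regions)


def load_sample_list(path: str | Path) -> list[str]:
    """One sample ID per line; blank lines and ``#`` comments ignored."""
    with open(path) as fh:
        return [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]


# ---------------------------------------------------------------------------
# filtering


def filter_rare(
    H: HaplotypeMatrix, maf_cutoff: float = DEFAULT_MAF_CUTOFF
) -> HaplotypeMatrix:
    """Keep exactly the columns with 0 < MAF < ``maf_cutoff`` (strict).

    Monomorphic columns are dropped. An empty result is returned with a
    warning, never raised.
    """
    if not (0.0 < maf_cutoff <= 0.5):
        raise ValueError(f"maf_cutoff must be in (0, 0.5], got {maf_cutoff}")
    mafs = H.mafs()
    keep = np.flatnonzero((mafs > 0.0) & (mafs < maf_cutoff))
    if keep.size == 0:
        logger.warning("filter_rare: no variants below MAF %g", maf_cutoff)
    return HaplotypeMatrix(
        H.values[:, keep],
        [H.variants[j] for j in keep],
        list(H.sample_ids),
    )


# ---------------------------------------------------------------------------
# writers


def write_vcf(H: HaplotypeMatrix, path: str | Path) -> None:
    """Write the matrix as a minimal phased VCF (GT-only, one ALT per record).

    Stored (minor) alleles are written as ALT; the emitted file round-trips
    through :func:`load_haplotypes` to the identical binary matrix.
    """
    if H.n_haplotypes % 2:
        raise ValueError("matrix must have an even number of haplotype rows")
    sample_names = [s for s, h in H.sample_ids if h == 0]
    chroms = sorted({v.chrom for v in H.variants})
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=cld\n")
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(sample_names)
            + "\n"
        )
        order = sorted(
            range(H.n_variants), key=lambda j: (H.variants[j].chrom, H.variants[j].pos)
        )
        for j in order:
            v = H.variants[j]
            col = H.values[:, j]
            gts = "\t".join(
                f"{col[2 * i]}|{col[2 * i + 1]}" for i in range(len(sample_names))
            )
            ref, _, alt = v.ref_alt.partition(">")
            fh.write(
                f"{v.chrom}\t{v.pos}\t.\t{ref or 'A'}\t{alt or 'T'}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def write_bed(regions: RegionSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\n")


def variant_summary(H: HaplotypeMatrix) -> "pd.DataFrame":
    """Per-variant summary table (chrom, pos, ref_alt, maf, missing_count)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "chrom": [v.chrom for v in H.variants],
            "pos": [v.pos for v in H.variants],
            "ref_alt": [v.ref_alt for v in H.variants],
            "maf": [v.maf for v in H.variants],
            "missing_count": [v.missing for v in H.variants],
        }
    )
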