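"""Shared in-memory containers for the pipeline.

All genomic coordinates are 1-based base pairs. Marker order is the map
order and is never silently permuted by any operation. Genotype dosages
count copies of the alternate allele; ``MISSING`` (-1) is permitted only
in :class:`GenotypeMatrix` (pre-QC data) — phased haplotypes are complete
by contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1

__all__ = [
    "MISSING",
    "MarkerMap",
    "GenotypeMatrix",
    "HaplotypeMatrix",
    "BreedAssignment",
    "DataError",
    "FormatError",
    "PhasingError",
]


class DataError(ValueError):
    """Inconsistent or contract-violating data."""


class FormatError(DataError):
    """Unparseable input file."""


class PhasingError(FormatError):
    """Genotype record that is not phased where phase is required."""


@dataclass(frozen=True)
class MarkerMap:
    """Ordered SNP map: id, chromosome label and 1-based bp position.

    Positions must be strictly increasing within each chromosome and
    snp ids unique.
    """

    snp_id: np.ndarray
    chromosome: np.ndarray
    position_bp: np.ndarray

    def __post_init__(self) -> None:
        sid = np.asarray(self.snp_id, dtype=object)
        chrom = np.asarray(self.chromosome, dtype=object)
        pos = np.asarray(self.position_bp, dtype=np.int64)
        if not (len(sid) == len(chrom) == len(pos)):
            raise DataError("marker map columns differ in length")
        if len(sid) != len(set(sid)):
            raise DataError("duplicate snp ids in marker map")
        if len(pos) and pos.min() < 1:
            raise DataError("positions must be >= 1 (1-based bp)")
        same_chrom = chrom[1:] == chrom[:-1] if len(chrom) > 1 else np.array([], bool)
        if np.any(same_chrom & (pos[1:] <= pos[:-1])):
            raise DataError("positions not strictly increasing within chromosome")
        object.__setattr__(self, "snp_id", sid)
        object.__setattr__(self, "chromosome", chrom)
        object.__setattr__(self, "position_bp", pos)

    def __len__(self) -> int:
        return len(self.snp_id)

    def subset(self, index: np.ndarray) -> "MarkerMap":
        """Row subset preserving order (boolean mask or sorted indices)."""
        return MarkerMap(
            self.snp_id[index], self.chromosome[index], self.position_bp[index]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snp_id": self.snp_id,
                "chromosome": self.chromosome,
                "position_bp": self.position_bp,
            }
        )


@dataclass(frozen=True)
class GenotypeMatrix:
    """Diploid dosages (individuals x markers) in {0, 1, 2, MISSING}."""

    individuals: list[str]
    markers: MarkerMap
    dosage: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.dosage, dtype=np.int8)
        if d.shape != (len(self.individuals), len(self.markers)):
            raise DataError(
                f"dosage shape {d.shape} != "
                f"({len(self.individuals)}, {len(self.markers)})"
            )
        bad = ~np.isin(d, (0, 1, 2, MISSING))
        if bad.any():
            raise DataError("dosage values outside {0,1,2,missing}")
        object.__setattr__(self, "dosage", d)

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_snps(self) -> int:
        return len(self.markers)

    def subset_individuals(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        ids = [self.individuals[i] for i in np.flatnonzero(keep)] if keep.dtype == bool \
            else [self.individuals[i] for i in keep]
        return GenotypeMatrix(ids, self.markers, self.dosage[keep])

    def subset_snps(self, keep: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            list(self.individuals), self.markers.subset(keep), self.dosage[:, keep]
        )


@dataclass(frozen=True)
class HaplotypeMatrix:
    """Phased alleles, two rows per individual, values in {0, 1}.

    Row ``2*i`` and ``2*i + 1`` are the two haplotypes of individual
    ``individuals[i]``. No missing values are allowed: phasing and
    imputation happen upstream.
    """

    individuals: list[str]
    markers: MarkerMap
    alleles: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.alleles, dtype=np.uint8)
        if a.shape != (2 * len(self.individuals), len(self.markers)):
            raise DataError(
                f"allele table shape {a.shape} != "
                f"({2 * len(self.individuals)}, {len(self.markers)})"
            )
        if a.size and a.max() > 1:
            raise DataError("haplotype alleles must be 0/1")
        object.__setattr__(self, "alleles", a)

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_snps(self) -> int:
        return len(self.markers)

    def haplotype_rows(self, individual_index: int) -> tuple[int, int]:
        return 2 * individual_index, 2 * individual_index + 1

    def to_genotypes(self) -> GenotypeMatrix:
        """Collapse haplotype pairs by summation into dosages."""
        d = (self.alleles[0::2].astype(np.int8) + self.alleles[1::2]).astype(np.int8)
        return GenotypeMatrix(list(self.individuals), self.markers, d)

    def subset_individuals(self, keep_idx: np.ndarray) -> "HaplotypeMatrix":
        keep_idx = np.asarray(keep_idx)
        rows = np.empty(2 * len(keep_idx), dtype=np.int64)
        rows[0::2] = 2 * keep_idx
        rows[1::2] = 2 * keep_idx + 1
        return HaplotypeMatrix(
            [self.individuals[i] for i in keep_idx], self.markers, self.alleles[rows]
        )

    def subset_snps(self, keep: np.ndarray) -> "HaplotypeMatrix":
        return HaplotypeMatrix(
            list(self.individuals), self.markers.subset(keep), self.alleles[:, keep]
        )


@dataclass
class BreedAssignment:
    """Individual -> breed and breed -> geographic group assignment.

    Every individual maps to exactly one breed and every breed to exactly
    one group. ``nd`` (retained sample size) and display colors are
    optional metadata.
    """

    individual_breed: dict[str, str]
    breed_group: dict[str, str]
    nd: dict[str, int] = field(default_factory=dict)
    group_color: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = {b for b in self.individual_breed.values()} - set(self.breed_group)
        if unknown:
            raise DataError(f"breeds without group assignment: {sorted(unknown)}")

    @property
    def breeds(self) -> list[str]:
        return sorted(self.breed_group)

    @property
    def groups(self) -> list[str]:
        return sorted(set(self.breed_group.values()))

    def breed_of(self, individual: str) -> str:
        try:
            return self.individual_breed[individual]
        except KeyError:
            raise DataError(f"individual {individual!r} has no breed assignment")

    def members(self, breed: str, individuals: list[str]) -> np.ndarray:
        """Indices (into ``individuals``) of the members of ``breed``."""
        return np.array(
            [i for i, ind in enumerate(individuals)
             if self.individual_breed.get(ind) == breed],
            dtype=np.int64,
        )

    def unassigned(self, individuals: list[str]) -> list[str]:
        return [i for i in individuals if i not in self.individual_breed]
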