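"""Readers and writers for the pipeline's external formats.

Supported inputs: phased VCF (GT with ``|``), PLINK text PED/MAP, a
breed-assignment TSV and the packaged per-breed reference summary table.
Outputs are plain TSV with headers. Binary PLINK (BED) is deliberately
unsupported.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from importlib import resources
from pathlib import Path

import cyvcf2
import numpy as np
import pandas as pd

from .datamodel import (
    MISSING,
    BreedAssignment,
    DataError,
    FormatError,
    GenotypeMatrix,
    HaplotypeMatrix,
    MarkerMap,
    PhasingError,
)

__all__ = [
    "read_phased_vcf",
    "write_phased_vcf",
    "read_plink_text",
    "read_breed_map",
    "load_reference_table",
    "load_dataset_counts",
    "REFERENCE_TABLE_SHA256",
]

#: sha256 of the packaged reference summary table; guards silent edits.
REFERENCE_TABLE_SHA256 = (
    "48e32c78b7ad6f28bb76cedac03374531326fb01ef9d90a3223f980e11a936c9"
)


def read_phased_vcf(path: str | Path) -> HaplotypeMatrix:
    """Load a phased, diploid, biallelic-SNP VCF into a HaplotypeMatrix.

    Every GT must use the ``|`` separator; an unphased or multi-allelic
    record raises an error naming the offending site. Record order is
    preserved per chromosome.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        vcf = cyvcf2.VCF(str(path), gts012=False)
    except Exception as exc:  # htslib raises plain OSError/Exception
        raise FormatError(f"unreadable VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    if not samples:
        raise FormatError("VCF has no sample columns")
    chroms: list[str] = []
    poss: list[int] = []
    sids: list[str] = []
    rows: list[np.ndarray] = []
    for variant in vcf:
        site = f"{variant.CHROM}:{variant.POS}"
        if len(variant.ALT) != 1:
            raise FormatError(f"multi-allelic record at {site}")
        if len(variant.REF) != 1 or len(variant.ALT[0]) != 1:
            raise FormatError(f"non-SNP record at {site}")
        pair = np.empty(2 * len(samples), dtype=np.uint8)
        for j, (a, b, phased) in enumerate(variant.genotypes):
            if not phased:
                raise PhasingError(
                    f"unphased genotype for sample {samples[j]!r} at {site}"
                )
            if a not in (0, 1) or b not in (0, 1):
                raise PhasingError(f"missing allele for {samples[j]!r} at {site}")
            pair[2 * j] = a
            pair[2 * j + 1] = b
        chroms.append(variant.CHROM)
        poss.append(variant.POS)
        sids.append(variant.ID if variant.ID else site)
        rows.append(pair)
    vcf.close()
    if not rows:
        raise FormatError(f"no variant records in {path}")
    markers = MarkerMap(np.array(sids, object), np.array(chroms, object),
                        np.array(poss, np.int64))
    return HaplotypeMatrix(samples, markers, np.array(rows, np.uint8).T)


def write_phased_vcf(h: HaplotypeMatrix, path: str | Path) -> None:
    """Write a HaplotypeMatrix as a minimal phased VCF (REF=A, ALT=G)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in pd.unique(h.markers.chromosome):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(h.individuals) + "\n")
        a = h.alleles
        for k in range(h.n_snps):
            gts = "\t".join(
                f"{a[2 * i, k]}|{a[2 * i + 1, k]}" for i in range(h.n_individuals)
            )
            fh.write(
                f"{h.markers.chromosome[k]}\t{h.markers.position_bp[k]}\t"
                f"{h.markers.snp_id[k]}\tA\tG\t.\t.\t.\tGT\t{gts}\n"
            )


def read_plink_text(ped: str | Path, map_: str | Path) -> GenotypeMatrix:
    """Load whitespace-delimited PLINK text PED/MAP into a GenotypeMatrix.

    PED carries no ref/alt designation, so the alternate allele of each
    SNP is chosen deterministically as the lexicographically larger
    observed allele. ``0`` denotes a missing allele; a genotype with any
    missing allele is recorded as missing.
    """
    mp = pd.read_csv(map_, sep=r"\s+", header=None,
                     names=["chrom", "snp_id", "cm", "bp"], dtype=str)
    n_snps = len(mp)
    markers = MarkerMap(
        mp["snp_id"].to_numpy(object),
        mp["chrom"].to_numpy(object),
        mp["bp"].astype(np.int64).to_numpy(),
    )
    individuals: list[str] = []
    allele_rows: list[list[str]] = []
    with open(ped) as fh:
        for ln, line in enumerate(fh, 1):
            f = line.split()
            if not f:
                continue
            if len(f) != 6 + 2 * n_snps:
                raise FormatError(
                    f"PED line {ln}: {len(f) - 6} allele fields for {n_snps} MAP snps"
                )
            individuals.append(f[1])
            allele_rows.append(f[6:])
    al = np.array(allele_rows, dtype=object).reshape(len(individuals), n_snps, 2)
    dosage = np.full((len(individuals), n_snps), MISSING, dtype=np.int8)
    for k in range(n_snps):
        obs = al[:, k, :]
        present = obs != "0"
        seen = sorted(set(obs[present].tolist()))
        if len(seen) > 2:
            raise FormatError(f"more than two alleles at {markers.snp_id[k]}: {seen}")
        if not seen:
            continue
        alt = seen[-1]  # lexicographically larger observed allele
        full = present.all(axis=1)
        dosage[full, k] = (obs[full] == alt).sum(axis=1)
    return GenotypeMatrix(individuals, markers, dosage)


def read_breed_map(path: str | Path) -> BreedAssignment:
    """Load the individual/breed/group TSV (optional nd and color columns)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"individual", "breed", "group"}
    if not required <= set(df.columns):
        raise FormatError(f"breed map needs columns {sorted(required)}")
    dup = df["individual"][df["individual"].duplicated()]
    if len(dup):
        raise DataError(f"duplicated individuals in breed map: {sorted(set(dup))}")
    conflict = df.groupby("breed")["group"].nunique()
    if (conflict > 1).any():
        raise DataError(
            f"breeds mapped to multiple groups: {list(conflict[conflict > 1].index)}"
        )
    nd = {}
    if "nd" in df.columns:
        nd = {b: int(v) for b, v in zip(df["breed"], df["nd"]) if pd.notna(v)}
    colors = {}
    if "color" in df.columns:
        colors = dict(
            df.dropna(subset=["color"]).groupby("group")["color"].first()
        )
    return BreedAssignment(
        dict(zip(df["individual"], df["breed"])),
        dict(df.groupby("breed")["group"].first()),
        nd=nd,
        group_color=colors,
    )


def check_cohort_assignment(
    individuals: list[str], breeds: BreedAssignment
) -> list[str]:
    """Warn about genotyped individuals absent from the breed map.

    Returns the exclusion list (possibly empty).
    """
    missing = breeds.unassigned(individuals)
    if missing:
        warnings.warn(
            f"{len(missing)} genotyped individual(s) missing from the breed map; "
            "they will be excluded from breed-level analyses",
            stacklevel=2,
        )
    return missing


def _data_path(name: str):
    return resources.files("herddiv.data").joinpath(name)


def load_reference_table(check: bool = True) -> pd.DataFrame:
    """Load the packaged 115-breed reference diversity table.

    One row per breed with the columns Nd, nA, mA, Ho, He, Hdef, npA,
    nspA, fpA, F, AR, Ho_snp, He_snp and Ne5/Ne50/Ne2000 (NaN where the
    source prints no value). The file is a versioned transcription; its
    sha256 is verified unless ``check=False``.
    """
    ref = _data_path("reference_diversity_table.tsv")
    raw = ref.read_bytes()
    if check:
        digest = hashlib.sha256(raw).hexdigest()
        if digest != REFERENCE_TABLE_SHA256:
            raise DataError(
                "reference table checksum mismatch: "
                f"{digest} != {REFERENCE_TABLE_SHA256}"
            )
    with resources.as_file(ref) as p:
        df = pd.read_csv(p, sep="\t")
    if len(df) != 115:
        raise DataError(f"reference table has {len(df)} rows, expected 115")
    return df.set_index("breed", drop=False)


def load_dataset_counts() -> dict:
    """Dataset-level published counts accompanying the reference table."""
    return json.loads(_data_path("dataset_counts.json").read_text())


def write_square_matrix(
    m: np.ndarray, labels: list[str], path: str | Path
) -> None:
    """Write a labeled square matrix as TSV (row label in first column)."""
    pd.DataFrame(m, index=labels, columns=labels).to_csv(
        path, sep="\t", index_label="id"
    )


def read_square_matrix(path: str | Path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise FormatError("square matrix row/column labels differ")
    return df.to_numpy(float), list(df.index)
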