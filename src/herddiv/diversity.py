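"""Per-breed allelic diversity from multi-allelic haplotype blocks.

All estimators work on a :class:`BlockAlleleTable`: per breed and per
block, the counts of each block allele among the 2*Nd sampled gene
copies. Statistics mirror the standard multi-allelic toolkit:

* ``nA``  — total number of distinct alleles over all blocks,
* ``mA``  — mean number of alleles per block (nA / n_blocks),
* ``H_O`` — mean over blocks of the fraction of heterozygous animals,
* ``H_E`` — mean over blocks of Nei's unbiased gene diversity
  ``(2N/(2N-1)) (1 - sum p_u^2)`` (the small-sample factor matters at
  breed sizes down to 4),
* ``H_def`` — relative heterozygote deficit ``(H_E - H_O) / H_E``,
* ``AR``  — allelic richness by hypergeometric rarefaction to ``g`` gene
  copies,
* ``npA/nspA/ncA`` — private (one breed), semi-private (exactly two
  breeds) and common (all breeds) allele counts, where an allele's
  identity is the (block, word) pair,
* ``fpA`` — mean within-breed frequency of that breed's private alleles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .datamodel import MISSING, BreedAssignment, DataError, GenotypeMatrix
from .haploblocks import BlockGenotypes

__all__ = [
    "BlockAlleleTable",
    "breed_allele_counts",
    "diversity_summary",
    "allelic_richness",
    "private_allele_counts",
    "snp_heterozygosity",
    "group_weighted_summary",
    "correlate_f_private",
    "build_breed_summary",
]


@dataclass(frozen=True)
class BlockAlleleTable:
    """Block-allele counts per breed.

    ``counts[b, l, u]`` is the number of gene copies of allele ``u`` at
    block ``l`` in breed ``b``; each (b, l) slice sums to ``2 * nd[b]``.
    ``het[b, l]`` counts heterozygous individuals (needed for H_O, which
    is not a function of allele counts alone).
    """

    breeds: list[str]
    counts: np.ndarray  # (n_breeds, n_blocks, n_allele_codes) int32
    het: np.ndarray  # (n_breeds, n_blocks) int32
    nd: np.ndarray  # diploid sample size per breed

    def __post_init__(self) -> None:
        c = self.counts
        if c.ndim != 3 or c.shape[0] != len(self.breeds):
            raise DataError("counts array shape mismatch")
        if (c < 0).any():
            raise DataError("negative allele counts")
        sums = c.sum(axis=2)
        expected = (2 * np.asarray(self.nd))[:, None]
        if not (sums == expected).all():
            raise DataError("per-block counts do not sum to 2*Nd")

    @property
    def n_blocks(self) -> int:
        return self.counts.shape[1]

    @property
    def gene_copies(self) -> np.ndarray:
        return 2 * np.asarray(self.nd)

    def frequencies(self) -> np.ndarray:
        """Allele frequencies, counts / 2Nd, per breed per block."""
        return self.counts / self.gene_copies[:, None, None].astype(float)


def breed_allele_counts(
    bg: BlockGenotypes, breeds: BreedAssignment
) -> BlockAlleleTable:
    """Tally block-allele gene copies and heterozygote counts per breed."""
    present = [b for b in breeds.breeds
               if len(breeds.members(b, bg.individuals))]
    if not present:
        raise DataError("no breed has any genotyped member")
    n_codes = 1 << bg.block_size
    counts = np.zeros((len(present), bg.n_blocks, n_codes), dtype=np.int32)
    het = np.zeros((len(present), bg.n_blocks), dtype=np.int32)
    nd = np.zeros(len(present), dtype=np.int64)
    for b, breed in enumerate(present):
        idx = breeds.members(breed, bg.individuals)
        nd[b] = len(idx)
        sub = bg.alleles[idx]  # (n, L, 2)
        het[b] = (sub[:, :, 0] != sub[:, :, 1]).sum(axis=0)
        for l in range(bg.n_blocks):
            counts[b, l] = np.bincount(sub[:, l, :].ravel(),
                                       minlength=n_codes)
    return BlockAlleleTable(present, counts, het, nd)


def diversity_summary(t: BlockAlleleTable) -> pd.DataFrame:
    """nA, mA, H_O, H_E and H_def per breed (means over blocks)."""
    if t.n_blocks == 0:
        raise DataError("empty block table")
    copies = t.gene_copies.astype(float)
    n_dip = t.nd
    freq = t.frequencies()
    n_alleles_per_block = (t.counts > 0).sum(axis=2)  # (B, L)
    na = n_alleles_per_block.sum(axis=1)
    ho = (t.het / np.asarray(n_dip, float)[:, None]).mean(axis=1)
    gene_div = 1.0 - (freq**2).sum(axis=2)
    unbias = copies / (copies - 1.0)
    he = (unbias[:, None] * gene_div).mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        hdef = np.where(he > 0, (he - ho) / he, np.nan)
    return pd.DataFrame(
        {
            "breed": t.breeds,
            "Nd": n_dip,
            "nA": na,
            "mA": na / t.n_blocks,
            "Ho": ho,
            "He": he,
            "Hdef": hdef,
        }
    ).set_index("breed", drop=False)


def _log_comb(n: np.ndarray, k: float) -> np.ndarray:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def allelic_richness(t: BlockAlleleTable, g: int | None = None) -> pd.Series:
    """Rarefied allele counts: expected alleles in g gene copies.

    Per block, ``AR_g = sum_u (1 - C(N - N_u, g) / C(N, g))`` with N the
    copies sampled in that breed and N_u the copies of allele u; the
    breed value is the mean over blocks. ``g`` defaults to
    ``2 * min(Nd)`` so every breed can be rarefied to a common depth.
    """
    copies = t.gene_copies
    if g is None:
        g = int(copies.min())
    if g < 1 or g > copies.min():
        raise DataError(f"rarefaction depth g={g} exceeds smallest sample "
                        f"({copies.min()} copies)")
    ar = np.empty(len(t.breeds))
    for b in range(len(t.breeds)):
        n = float(copies[b])
        cnt = t.counts[b].astype(float)  # (L, U)
        # survival term C(N - N_u, g)/C(N, g); zero when N - N_u < g
        rem = n - cnt
        with np.errstate(invalid="ignore"):
            logratio = _log_comb(rem, g) - _log_comb(np.array(n), g)
        surv = np.where(rem >= g, np.exp(logratio), 0.0)
        ar[b] = ((cnt > 0) * (1.0 - surv)).sum(axis=1).mean()
    return pd.Series(ar, index=t.breeds, name="AR")


def private_allele_counts(t: BlockAlleleTable) -> tuple[pd.DataFrame, int]:
    """Private/semi-private/common allele counts and private frequencies.

    Returns a per-breed frame (npA, nspA, fpA) and the global count of
    common alleles ncA (alleles observed in every breed).
    """
    if len(t.breeds) < 2:
        raise DataError("private-allele analysis needs >= 2 breeds")
    present = t.counts > 0  # (B, L, U)
    occupancy = present.sum(axis=0)  # (L, U)
    exists = occupancy > 0
    npa = (present & (occupancy == 1)[None]).sum(axis=(1, 2))
    nspa = (present & (occupancy == 2)[None]).sum(axis=(1, 2))
    nca = int((occupancy == len(t.breeds)).sum())
    freq = t.frequencies()
    fpa = np.full(len(t.breeds), np.nan)
    for b in range(len(t.breeds)):
        mask = present[b] & (occupancy == 1)
        if mask.any():
            fpa[b] = freq[b][mask].mean()
    df = pd.DataFrame(
        {"breed": t.breeds, "npA": npa, "nspA": nspa, "fpA": fpa}
    ).set_index("breed", drop=False)
    # conservation invariants (cheap, always on)
    assert npa.sum() <= exists.sum()
    assert nspa.sum() == 2 * int((occupancy == 2).sum())
    return df, nca


def snp_heterozygosity(
    g: GenotypeMatrix, breeds: BreedAssignment
) -> pd.DataFrame:
    """Observed/expected heterozygosity per breed from bi-allelic SNPs.

    Same estimators as the block versions applied to single SNPs; SNPs
    with missing genotypes contribute their observed subsample.
    """
    rows = []
    for breed in breeds.breeds:
        idx = breeds.members(breed, g.individuals)
        if not len(idx):
            continue
        sub = g.dosage[idx].astype(float)
        obs = sub != MISSING
        n = obs.sum(axis=0)
        valid = n > 1
        het = ((sub == 1) & obs).sum(axis=0)
        alt = np.where(obs, sub, 0.0).sum(axis=0)
        p = alt[valid] / (2.0 * n[valid])
        ho = (het[valid] / n[valid]).mean()
        copies = 2.0 * n[valid]
        he = ((copies / (copies - 1.0)) * 2.0 * p * (1.0 - p)).mean()
        rows.append({"breed": breed, "Ho_snp": ho, "He_snp": he})
    return pd.DataFrame(rows).set_index("breed", drop=False)


def group_weighted_summary(
    table: pd.DataFrame,
    breeds: BreedAssignment,
    columns: tuple[str, ...] = (
        "nA", "mA", "Ho", "He", "npA", "nspA", "fpA", "F", "AR",
        "Ho_snp", "He_snp", "Ne5", "Ne50", "Ne2000",
    ),
) -> pd.DataFrame:
    """Nd-weighted group means of per-breed statistics.

    For every statistic the group value is ``sum(Nd_b * x_b) / sum(Nd_b)``
    over the group's breeds where the statistic is defined; breeds with a
    missing value (e.g. Ne for tiny samples) drop out of that statistic's
    weighting only.
    """
    if "Nd" not in table.columns:
        raise DataError("summary table lacks an Nd column")
    tab = table.copy()
    tab["group"] = [breeds.breed_group.get(b) for b in tab.index]
    if tab["group"].isna().any():
        missing = list(tab.index[tab["group"].isna()])
        raise DataError(f"breeds without group: {missing}")
    out = {}
    for grp, sub in tab.groupby("group"):
        row = {"Nd_total": int(sub["Nd"].sum()), "n_breeds": len(sub)}
        for col in columns:
            if col not in sub.columns:
                continue
            ok = sub[col].notna()
            if not ok.any():
                row[col] = np.nan
                continue
            w = sub.loc[ok, "Nd"].astype(float)
            row[col] = float((w * sub.loc[ok, col]).sum() / w.sum())
        out[grp] = row
    return pd.DataFrame(out).T


def correlate_f_private(
    table: pd.DataFrame, exclude_groups: tuple[str, ...] = ("Outgroup",),
    breeds: BreedAssignment | None = None,
) -> tuple[float, float]:
    """Pearson correlations of inbreeding with private-allele statistics.

    Returns ``(r(F, fpA), r(F, npA))`` across breeds. Outgroup taxa are
    excluded by default: a distant outgroup is an extreme outlier in both
    F and npA and swamps the within-species relationship.
    """
    tab = table
    if exclude_groups:
        if "group" in tab.columns:
            tab = tab[~tab["group"].isin(exclude_groups)]
        elif breeds is not None:
            keep = [b for b in tab.index
                    if breeds.breed_group.get(b) not in exclude_groups]
            tab = tab.loc[keep]
    tab = tab.dropna(subset=["F", "fpA", "npA"])
    if len(tab) < 3:
        raise DataError("need >= 3 breeds with F, fpA and npA")
    r_fpa = float(np.corrcoef(tab["F"], tab["fpA"])[0, 1])
    r_npa = float(np.corrcoef(tab["F"], tab["npA"])[0, 1])
    return r_fpa, r_npa


def build_breed_summary(
    t: BlockAlleleTable,
    g_snp: GenotypeMatrix | None = None,
    breeds: BreedAssignment | None = None,
    inbreeding: pd.Series | None = None,
    rarefaction_g: int | None = None,
) -> pd.DataFrame:
    """Assemble the per-breed summary table from the block-allele table.

    Optional ingredients add columns: SNP heterozygosities (needs the
    genotype matrix and breed map) and per-breed mean inbreeding.
    """
    out = diversity_summary(t)
    out["AR"] = allelic_richness(t, rarefaction_g)
    priv, _ = private_allele_counts(t)
    out = out.join(priv[["npA", "nspA", "fpA"]])
    if inbreeding is not None:
        out["F"] = inbreeding
    if g_snp is not None and breeds is not None:
        out = out.join(snp_heterozygosity(g_snp, breeds)[["Ho_snp", "He_snp"]])
    return out
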