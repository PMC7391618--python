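"""Marker and sample quality control.

The filter cascade is fixed: sample call rate -> SNP call rate -> MAF ->
within-breed Hardy-Weinberg. Re-running QC on its own output is a no-op.
Defaults mirror a standard SNP-array cattle workflow: samples kept only
with call rate strictly above 0.95, SNPs kept when genotyped in at least
90% of samples, pooled MAF >= 0.025, and removal when the exact HWE test
gives p <= 0.01 in any breed with at least ``min_n`` genotyped animals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .datamodel import MISSING, BreedAssignment, DataError, GenotypeMatrix

__all__ = [
    "QcReport",
    "filter_sample_call_rate",
    "filter_snp_call_rate",
    "filter_maf",
    "hwe_exact_test",
    "filter_hwe_within_breed",
    "run_qc",
    "NOT_TESTABLE",
]

#: sentinel p-value for untestable (empty) genotype configurations
NOT_TESTABLE = float("nan")


@dataclass
class QcReport:
    """Per-rule removal counts, echoed thresholds and surviving shape."""

    rule: str
    threshold: float
    n_individuals_removed: int = 0
    n_snps_removed: int = 0
    removed_individuals: list[str] = field(default_factory=list)
    removed_snps: list[str] = field(default_factory=list)
    surviving_shape: tuple[int, int] = (0, 0)

    def to_dict(self) -> dict:
        return {
            "rule": self.rule,
            "threshold": self.threshold,
            "n_individuals_removed": self.n_individuals_removed,
            "n_snps_removed": self.n_snps_removed,
            "surviving_individuals": self.surviving_shape[0],
            "surviving_snps": self.surviving_shape[1],
        }


def _check_nonempty(g: GenotypeMatrix, rule: str) -> None:
    if g.n_individuals == 0 or g.n_snps == 0:
        raise DataError(f"QC rule {rule!r} removed everything; check thresholds")


def filter_sample_call_rate(
    g: GenotypeMatrix, threshold: float = 0.95
) -> tuple[GenotypeMatrix, QcReport]:
    """Keep individuals whose non-missing fraction is strictly above threshold."""
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    called = (g.dosage != MISSING).mean(axis=1)
    keep = called > threshold
    out = g.subset_individuals(keep)
    report = QcReport(
        rule="sample_call_rate",
        threshold=threshold,
        n_individuals_removed=int((~keep).sum()),
        removed_individuals=[g.individuals[i] for i in np.flatnonzero(~keep)],
        surviving_shape=(out.n_individuals, out.n_snps),
    )
    _check_nonempty(out, report.rule)
    return out, report


def filter_snp_call_rate(
    g: GenotypeMatrix, threshold: float = 0.90
) -> tuple[GenotypeMatrix, QcReport]:
    """Remove SNPs genotyped in less than ``threshold`` of the samples.

    The rule is "less than": a SNP typed in exactly 90% of samples is
    retained at the default threshold.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    called = (g.dosage != MISSING).mean(axis=0)
    keep = called >= threshold
    out = g.subset_snps(keep)
    report = QcReport(
        rule="snp_call_rate",
        threshold=threshold,
        n_snps_removed=int((~keep).sum()),
        removed_snps=list(g.markers.snp_id[~keep]),
        surviving_shape=(out.n_individuals, out.n_snps),
    )
    _check_nonempty(out, report.rule)
    return out, report


def pooled_maf(g: GenotypeMatrix) -> np.ndarray:
    """Minor allele frequency per SNP over all non-missing genotypes pooled."""
    d = g.dosage.astype(float)
    obs = d != MISSING
    alt = np.where(obs, d, 0.0).sum(axis=0)
    n = 2.0 * obs.sum(axis=0)
    with np.errstate(invalid="ignore"):
        p = np.where(n > 0, alt / np.maximum(n, 1), 0.0)
    return np.minimum(p, 1.0 - p)


def filter_maf(
    g: GenotypeMatrix, threshold: float = 0.025
) -> tuple[GenotypeMatrix, QcReport]:
    """Remove SNPs with pooled MAF below threshold (monomorphic included)."""
    maf = pooled_maf(g)
    # an all-missing SNP has undefined MAF; treat as monomorphic -> removed
    keep = maf >= threshold
    out = g.subset_snps(keep)
    report = QcReport(
        rule="maf",
        threshold=threshold,
        n_snps_removed=int((~keep).sum()),
        removed_snps=list(g.markers.snp_id[~keep]),
        surviving_shape=(out.n_individuals, out.n_snps),
    )
    _check_nonempty(out, report.rule)
    return out, report


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided exact Hardy-Weinberg test for one biallelic SNP.

    Conditions on the observed allele counts and enumerates every
    possible heterozygote count, summing the probabilities of all
    configurations no more likely than the observed one
    (probability-ordering two-sided definition). Suitable for the very
    small within-breed samples this pipeline deals with, where the
    chi-square approximation breaks down.

    Returns NaN ("not testable") for an empty sample.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        return NOT_TESTABLE
    n_a = n_Aa + 2 * n_aa  # minor-or-not is irrelevant: test is symmetric
    rare = min(n_a, 2 * n - n_a)
    # heterozygote count shares the parity of the rare allele count
    hets = np.arange(rare % 2, rare + 1, 2)
    if len(hets) == 1:
        return 1.0
    # log P(n_Aa = h | n, allele counts) up to a shared constant:
    # multinomial coefficient x 2^h
    n_rr = (rare - hets) // 2
    n_cc = n - hets - n_rr
    logp = (
        hets * np.log(2.0)
        - gammaln(n_rr + 1)
        - gammaln(hets + 1)
        - gammaln(n_cc + 1)
    )
    logp -= logp.max()
    p = np.exp(logp)
    p /= p.sum()
    # n_Aa always indexes into hets because parity matches by construction
    p_obs = p[np.flatnonzero(hets == n_Aa)[0]]
    return float(min(1.0, p[p <= p_obs * (1 + 1e-12)].sum()))


def filter_hwe_within_breed(
    g: GenotypeMatrix,
    breeds: BreedAssignment,
    alpha: float = 0.01,
    min_n: int = 10,
) -> tuple[GenotypeMatrix, QcReport]:
    """Remove SNPs out of Hardy-Weinberg equilibrium within any breed.

    A SNP is dropped when the exact test gives p <= ``alpha`` in at least
    one breed with >= ``min_n`` genotyped individuals at that SNP; tiny
    breeds never trigger removals.
    """
    d = g.dosage
    fail = np.zeros(g.n_snps, dtype=bool)
    for breed in breeds.breeds:
        idx = breeds.members(breed, g.individuals)
        if len(idx) < min_n:
            continue
        sub = d[idx]
        obs = sub != MISSING
        n_obs = obs.sum(axis=0)
        n_aa = ((sub == 2) & obs).sum(axis=0)
        n_het = (sub == 1).sum(axis=0)
        n_AA = n_obs - n_aa - n_het
        testable = np.flatnonzero((n_obs >= min_n) & ~fail)
        for k in testable:
            p = hwe_exact_test(int(n_AA[k]), int(n_het[k]), int(n_aa[k]))
            if not np.isnan(p) and p <= alpha:
                fail[k] = True
    keep = ~fail
    out = g.subset_snps(keep)
    report = QcReport(
        rule="hwe_within_breed",
        threshold=alpha,
        n_snps_removed=int(fail.sum()),
        removed_snps=list(g.markers.snp_id[fail]),
        surviving_shape=(out.n_individuals, out.n_snps),
    )
    _check_nonempty(out, report.rule)
    return out, report


def run_qc(
    g: GenotypeMatrix,
    breeds: BreedAssignment | None = None,
    sample_cr: float = 0.95,
    snp_cr: float = 0.90,
    maf: float = 0.025,
    hwe_alpha: float = 0.01,
    hwe_min_n: int = 10,
) -> tuple[GenotypeMatrix, list[QcReport]]:
    """Run the full fixed-order QC cascade; HWE step skipped without breeds."""
    reports = []
    g, r = filter_sample_call_rate(g, sample_cr)
    reports.append(r)
    g, r = filter_snp_call_rate(g, snp_cr)
    reports.append(r)
    g, r = filter_maf(g, maf)
    reports.append(r)
    if breeds is not None:
        g, r = filter_hwe_within_breed(g, breeds, hwe_alpha, hwe_min_n)
        reports.append(r)
    return g, reports
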