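"""Genome-wide additive relationships, inbreeding and cohort pruning.

The unified additive relationship (UAR) matrix is the SNP-based
relationship estimator whose off-diagonal entry for individuals *i*, *j*
averages, over markers *k* with alternate-allele frequency ``p_k``,

    (x_ik - 2 p_k)(x_jk - 2 p_k) / (2 p_k (1 - p_k))

while the diagonal is

    1 + mean_k (x_ik^2 - (1 + 2 p_k) x_ik + 2 p_k^2) / (2 p_k (1 - p_k)).

The individual inbreeding coefficient is read off the diagonal as
``F_i = UAR[i, i] - 1``. Centering frequencies are computed once on the
full post-QC cohort so a single genome-wide matrix describes all breeds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2

from .datamodel import MISSING, BreedAssignment, DataError, GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "allele_frequencies",
    "uar_matrix",
    "inbreeding_from_uar",
    "detect_outliers",
    "prune_related",
    "PruneResult",
]


def allele_frequencies(g: GenotypeMatrix) -> np.ndarray:
    """Alternate-allele frequency per SNP over non-missing genotypes.

    Post-QC input is expected: a monomorphic SNP (p in {0, 1}) is an
    error because it would make the UAR denominator vanish.
    """
    d = g.dosage.astype(float)
    obs = d != MISSING
    n = 2.0 * obs.sum(axis=0)
    if (n == 0).any():
        raise DataError("SNP with no observed genotypes")
    p = np.where(obs, d, 0.0).sum(axis=0) / n
    if ((p <= 0) | (p >= 1)).any():
        bad = g.markers.snp_id[(p <= 0) | (p >= 1)]
        raise DataError(
            f"monomorphic SNPs present (should have been MAF-filtered): "
            f"{list(bad[:5])}..."
        )
    return p


def uar_matrix(g: GenotypeMatrix, p: np.ndarray | None = None) -> np.ndarray:
    """Unified additive relationship matrix over the cohort.

    Residual missing dosages are mean-imputed per SNP (2p) and logged;
    normally the matrix is computed on complete post-imputation data.
    """
    if p is None:
        p = allele_frequencies(g)
    p = np.asarray(p, float)
    if ((p <= 0) | (p >= 1)).any():
        raise DataError("centering frequencies must lie strictly inside (0, 1)")
    x = g.dosage.astype(float)
    miss = x == MISSING
    if miss.any():
        logger.info("mean-imputing %d residual missing dosages", int(miss.sum()))
        x = np.where(miss, 2 * p[None, :], x)
    m = len(p)
    denom = 2.0 * p * (1.0 - p)
    w = (x - 2.0 * p) / np.sqrt(denom)  # standardized dosages
    uar = (w @ w.T) / m
    # the diagonal uses its own estimator, not the squared standardized dosage
    diag_terms = (x * x - (1.0 + 2.0 * p) * x + 2.0 * p * p) / denom
    np.fill_diagonal(uar, 1.0 + diag_terms.mean(axis=1))
    return uar


def inbreeding_from_uar(uar: np.ndarray) -> np.ndarray:
    """Per-individual inbreeding coefficient F_i = UAR[i, i] - 1."""
    uar = np.asarray(uar, float)
    if uar.ndim != 2 or uar.shape[0] != uar.shape[1]:
        raise DataError("UAR matrix must be square")
    return np.diag(uar) - 1.0


def _principal_coordinates(sub: np.ndarray, k: int) -> np.ndarray:
    """Top-k principal coordinates of a relationship sub-matrix.

    The relationship matrix is itself an inner-product (kernel) matrix,
    so its double-centered eigendecomposition embeds the individuals.
    """
    n = sub.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = j @ ((sub + sub.T) / 2) @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals > max(vals.max(), 0) * 1e-10
    k_eff = min(k, int(pos.sum()))
    return vecs[:, :k_eff] * np.sqrt(vals[:k_eff])


def detect_outliers(
    uar: np.ndarray,
    individuals: list[str],
    breeds: BreedAssignment,
    k_dims: int = 5,
    alpha: float = 0.025,
) -> dict[str, bool]:
    """Flag within-breed multivariate outliers (mis-sampled/admixed animals).

    Per breed, members are embedded by principal coordinates of the
    within-breed UAR sub-matrix; each of the top ``k_dims`` coordinates is
    robustly standardized (median / scaled MAD) and the squared robust
    distance compared with the upper-``alpha`` chi-square quantile.
    Breeds with fewer than 5 members are skipped (logged), never flagged.
    """
    flags = {ind: False for ind in individuals}
    for breed in breeds.breeds:
        idx = breeds.members(breed, individuals)
        if len(idx) < 5:
            if len(idx):
                logger.info("breed %s too small for outlier test (n=%d)",
                            breed, len(idx))
            continue
        coords = _principal_coordinates(uar[np.ix_(idx, idx)], k_dims)
        med = np.median(coords, axis=0)
        mad = np.median(np.abs(coords - med), axis=0) * 1.4826
        # MAD collapses when most members coincide (near-clonal breeds);
        # fall back to the plain SD, then declare the axis uninformative
        sd = coords.std(axis=0)
        scale = np.where(mad > 0, mad, np.where(sd > 0, sd, np.inf))
        d2 = (((coords - med) / scale) ** 2).sum(axis=1)
        cut = chi2.ppf(1 - alpha, df=coords.shape[1])
        for local, i in enumerate(idx):
            if d2[local] > cut:
                flags[individuals[i]] = True
    return flags


@dataclass
class PruneResult:
    """Outcome of the greedy relatedness pruning."""

    kept: list[str]
    removed: dict[str, str]  # id -> reason ("outlier" | "related")
    threshold: float
    iterations: list[str] = field(default_factory=list)


def prune_related(
    uar: np.ndarray,
    individuals: list[str],
    breeds: BreedAssignment,
    threshold: float = 0.45,
    outlier_flags: dict[str, bool] | None = None,
) -> PruneResult:
    """Greedy successive exclusion of highly related animals within breed.

    While any within-breed off-diagonal relationship exceeds the
    threshold, the individual with the most above-threshold partners is
    removed (ties: larger mean relationship to its partners, then
    lexicographically smaller id). The default threshold 0.45 sits just
    below the first-degree-relative expectation of 0.5.
    """
    removed: dict[str, str] = {}
    log: list[str] = []
    active = set(range(len(individuals)))
    if outlier_flags:
        for i, ind in enumerate(individuals):
            if outlier_flags.get(ind, False):
                removed[ind] = "outlier"
                active.discard(i)
                log.append(f"outlier\t{ind}")

    breed_of = [breeds.individual_breed.get(ind) for ind in individuals]
    while True:
        act = sorted(active)
        partners: dict[int, list[int]] = {}
        for a_pos, i in enumerate(act):
            for j in act[a_pos + 1:]:
                if breed_of[i] is not None and breed_of[i] == breed_of[j] \
                        and uar[i, j] > threshold:
                    partners.setdefault(i, []).append(j)
                    partners.setdefault(j, []).append(i)
        if not partners:
            break

        def sort_key(i: int):
            mean_rel = float(np.mean([uar[i, j] for j in partners[i]]))
            return (-len(partners[i]), -mean_rel, individuals[i])

        worst = min(partners, key=sort_key)
        removed[individuals[worst]] = "related"
        active.discard(worst)
        log.append(
            f"related\t{individuals[worst]}\tpartners={len(partners[worst])}"
        )

    kept = [individuals[i] for i in sorted(active)]
    return PruneResult(kept=kept, removed=removed, threshold=threshold,
                       iterations=log)
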