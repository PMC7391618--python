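"""Patterson's D (ABBA-BABA) with weighted block jackknife.

For populations arranged as (((P1, P2), P3), O) and per-SNP
alternate-allele frequencies p1, p2, p3, pO, the population-level D is

    D = sum_k (p2 - p1)(p3 - pO) / sum_k (p1 + p2 - 2 p1 p2)(p3 + pO - 2 p3 pO)

whose numerator/denominator reduce to ABBA - BABA / ABBA + BABA pattern
counts when all frequencies are 0 or 1. Under treeness E[D] = 0; an
excess of ABBA (D > 0) indicates gene flow between P2 and P3, of BABA
(D < 0) between P1 and P3. Standard errors come from a delete-one
weighted block jackknife over genomic windows (default 5 Mb, beyond
cattle LD range) and |Z| > 3 flags significance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import MISSING, BreedAssignment, DataError, GenotypeMatrix, MarkerMap

__all__ = ["DStatResult", "d_statistic", "block_jackknife", "dstat_scan",
           "breed_frequencies"]

Z_SIGNIFICANT = 3.0


@dataclass(frozen=True)
class DStatResult:
    """One (((P1,P2),P3),O) test."""

    p1: str
    p2: str
    p3: str
    outgroup: str
    d: float
    se: float
    z: float
    n_sites: int
    n_blocks: int

    @property
    def significant(self) -> bool:
        return abs(self.z) > Z_SIGNIFICANT


def d_statistic(
    p1: np.ndarray, p2: np.ndarray, p3: np.ndarray, p_o: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """D plus the per-site numerator/denominator components.

    Sites where all four frequencies are equal carry no signal and are
    zero in both components. Returns NaN when the total denominator
    vanishes (no informative site).
    """
    arrays = [np.asarray(x, float) for x in (p1, p2, p3, p_o)]
    if len({a.shape for a in arrays}) != 1:
        raise DataError("frequency vectors must be aligned on one SNP set")
    a1, a2, a3, ao = arrays
    # sign convention: pure ABBA (p1=0, p2=1, p3=1, pO=0) -> D = +1,
    # so positive D flags P2-P3 sharing (ABBA excess)
    num = (a2 - a1) * (a3 - ao)
    den = (a1 + a2 - 2 * a1 * a2) * (a3 + ao - 2 * a3 * ao)
    total_den = den.sum()
    d = float(num.sum() / total_den) if total_den != 0 else float("nan")
    return d, num, den


def block_jackknife(
    num: np.ndarray,
    den: np.ndarray,
    block_index: np.ndarray,
    min_blocks: int = 20,
) -> tuple[float, float, int]:
    """Weighted delete-one-block jackknife SE and Z for a ratio statistic.

    ``block_index`` assigns every site to a genomic window; block weights
    are the site counts. Identical leave-one-out estimates give SE = 0,
    reported as Z = inf (sign of D).
    """
    block_index = np.asarray(block_index)
    blocks = np.unique(block_index)
    nonempty = [b for b in blocks if (block_index == b).sum() > 0]
    g = len(nonempty)
    if g < min_blocks:
        raise DataError(
            f"only {g} non-empty jackknife blocks (< {min_blocks}); "
            "use a larger input or smaller blocks"
        )
    total_num, total_den = num.sum(), den.sum()
    if total_den == 0:
        raise DataError("degenerate input: zero denominator")
    theta = total_num / total_den
    m = np.empty(g)
    theta_j = np.empty(g)
    for k, b in enumerate(nonempty):
        sel = block_index == b
        m[k] = sel.sum()
        den_j = total_den - den[sel].sum()
        theta_j[k] = (total_num - num[sel].sum()) / den_j if den_j != 0 else theta
    n_tot = m.sum()
    h = n_tot / m
    # weighted jackknife (Busing et al. 1999), reduces to the standard
    # delete-one formula for equal block sizes
    theta_dot = g * theta - ((1.0 - m / n_tot) * theta_j).sum()
    var = np.mean(
        (h * theta - (h - 1.0) * theta_j - theta_dot) ** 2 / (h - 1.0)
    )
    se = float(np.sqrt(max(var, 0.0)))
    if se <= 1e-12 * max(1.0, abs(theta)):  # numerically zero variance
        se = 0.0
    if se == 0:
        z = float("inf") if theta >= 0 else float("-inf")
    else:
        z = float(theta / se)
    return se, z, g


def breed_frequencies(
    g: GenotypeMatrix, breeds: BreedAssignment, breed: str
) -> np.ndarray:
    """Alternate-allele frequency per SNP within one breed (NaN if absent)."""
    idx = breeds.members(breed, g.individuals)
    if not len(idx):
        raise DataError(f"breed {breed!r} has no genotyped member")
    sub = g.dosage[idx].astype(float)
    obs = sub != MISSING
    n = 2.0 * obs.sum(axis=0)
    with np.errstate(invalid="ignore"):
        return np.where(n > 0, np.where(obs, sub, 0.0).sum(axis=0) / n, np.nan)


def _genomic_blocks(markers: MarkerMap, block_bp: int) -> np.ndarray:
    """Window index per SNP: block_bp tiles within each chromosome."""
    idx = np.empty(len(markers), dtype=np.int64)
    offset = 0
    for chrom in pd.unique(markers.chromosome):
        sel = markers.chromosome == chrom
        local = markers.position_bp[sel] // block_bp
        _, dense = np.unique(local, return_inverse=True)
        idx[sel] = dense + offset
        offset += dense.max() + 1
    return idx


def dstat_scan(
    g: GenotypeMatrix,
    breeds: BreedAssignment,
    outgroup: str,
    p3: str,
    p2: str,
    p1_list: list[str],
    jackknife_bp: int = 5_000_000,
    min_blocks: int = 20,
) -> pd.DataFrame:
    """One D-statistic per candidate P1 against fixed (P2, P3, O).

    Mirrors the introgression-scan design: a distant outgroup O, the
    introgressing source as P3, a reference breed assumed unadmixed as
    P2, and every other breed tested as P1. Sites with an undefined
    frequency in any population are dropped per test.
    """
    for b in [outgroup, p3, p2, *p1_list]:
        if b not in breeds.breed_group:
            raise DataError(f"breed {b!r} not in assignment")
    f_o = breed_frequencies(g, breeds, outgroup)
    f3 = breed_frequencies(g, breeds, p3)
    f2 = breed_frequencies(g, breeds, p2)
    blocks = _genomic_blocks(g.markers, jackknife_bp)
    rows = []
    for p1 in p1_list:
        f1 = breed_frequencies(g, breeds, p1)
        ok = ~(np.isnan(f1) | np.isnan(f2) | np.isnan(f3) | np.isnan(f_o))
        d, num, den = d_statistic(f1[ok], f2[ok], f3[ok], f_o[ok])
        se, z, n_blk = block_jackknife(num, den, blocks[ok],
                                       min_blocks=min_blocks)
        rows.append(
            {
                "P1": p1, "P2": p2, "P3": p3, "O": outgroup,
                "D": d, "SE": se, "Z": z,
                "n_sites": int(ok.sum()), "n_blocks": n_blk,
                "significant": abs(z) > Z_SIGNIFICANT,
            }
        )
    return pd.DataFrame(rows)
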