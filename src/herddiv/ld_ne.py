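"""Historical effective population size from LD decay.

Under drift-recombination equilibrium the expected squared correlation
between alleles at two loci with recombination fraction ``c`` reflects
the effective population size roughly ``t = 1/(2c)`` generations ago:

    Ne(t) = (4 f(c))^-1 (E[r2_adj]^-1 - alpha)

where ``f(c)`` maps physical distance to recombination fraction (linear
1 cM/Mb by default), ``alpha`` absorbs mutation (2 ignores it, 2.2
accounts for it), and ``r2_adj = r2 - 1/(beta * n)`` removes the finite
sample inflation (``beta = 2`` for phased haplotype data from ``n``
diploids). Pairs are restricted to 20 kb - 10 Mb so the curve spans
roughly 5 to 2500 generations; Ne_5, Ne_50 and Ne_2000 are read from the
distance bins whose ``t`` lands nearest 5, 50 and 2000 generations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import BreedAssignment, DataError, HaplotypeMatrix

logger = logging.getLogger(__name__)

__all__ = ["pairwise_r2", "distance_to_c", "ne_curve", "NeCurve",
           "estimate_ne", "group_ne_summary"]


def pairwise_r2(
    h: HaplotypeMatrix, d_min: int = 20_000, d_max: int = 10_000_000
) -> pd.DataFrame:
    """Squared allele-correlation for intra-chromosomal SNP pairs.

    Works on one breed's phased haplotypes (>= 2 individuals); r2 is the
    squared Pearson correlation of the 0/1 allele indicators across
    haplotype rows. Monomorphic SNPs in the breed are skipped.
    """
    if h.n_individuals < 2:
        raise DataError("need >= 2 individuals for LD")
    rows = []
    a = h.alleles.astype(float)
    for chrom in pd.unique(h.markers.chromosome):
        cols = np.flatnonzero(h.markers.chromosome == chrom)
        sub = a[:, cols]
        poly = sub.std(axis=0) > 0
        n_mono = int((~poly).sum())
        if n_mono:
            logger.debug("%d monomorphic SNPs skipped on %s", n_mono, chrom)
        cols = cols[poly]
        if len(cols) < 2:
            continue
        sub = sub[:, poly]
        pos = h.markers.position_bp[cols]
        r = np.corrcoef(sub.T)
        dist = np.abs(pos[:, None] - pos[None, :])
        iu = np.triu_indices(len(cols), k=1)
        d = dist[iu]
        keep = (d >= d_min) & (d <= d_max)
        r2 = r[iu][keep] ** 2
        for (pi, pj), dd, rr in zip(
            zip(cols[iu[0][keep]], cols[iu[1][keep]]), d[keep], r2
        ):
            rows.append((h.markers.snp_id[pi], h.markers.snp_id[pj],
                         int(dd), float(rr)))
    return pd.DataFrame(rows, columns=["snp_i", "snp_j", "distance_bp", "r2"])


def distance_to_c(
    d: np.ndarray | float, mapping: str = "linear", rate_cm_per_mb: float = 1.0
) -> np.ndarray:
    """Physical distance (bp) to recombination fraction.

    ``linear``: c = d * rate * 1e-8 (1 cM/Mb genome-wide average);
    ``haldane``: c = (1 - exp(-2 d rate 1e-8)) / 2. Values reaching 0.5
    are clamped just below with a warning.
    """
    d = np.asarray(d, float)
    if (d <= 0).any():
        raise DataError("distances must be positive")
    morgans = d * rate_cm_per_mb * 1e-8
    if mapping == "linear":
        c = morgans
    elif mapping == "haldane":
        c = 0.5 * (1.0 - np.exp(-2.0 * morgans))
    else:
        raise ValueError(f"unknown mapping {mapping!r}")
    if (c >= 0.5).any():
        logger.warning("recombination fractions >= 0.5 clamped")
        c = np.minimum(c, 0.5 - 1e-9)
    return c


@dataclass(frozen=True)
class NeCurve:
    """Binned Ne(t) trajectory plus the three standard extractions."""

    table: pd.DataFrame  # bin, c, t, mean_r2_adj, n_pairs, ne
    ne_5: float
    ne_50: float
    ne_2000: float

    def ne_at(self, generations: float) -> float:
        ok = self.table.dropna(subset=["ne"])
        if ok.empty:
            return float("nan")
        i = (ok["t"] - generations).abs().idxmin()
        return float(ok.loc[i, "ne"])


def ne_curve(
    records: pd.DataFrame,
    n: int,
    alpha: float = 2.0,
    beta: float = 2.0,
    bins: int = 30,
    mapping: str = "linear",
    rate_cm_per_mb: float = 1.0,
) -> NeCurve:
    """Bin LD records by distance and invert the drift-LD relation.

    Records are grouped into ``bins`` log-spaced distance bins; each bin
    uses the harmonic-mean recombination fraction of its pairs. Bins
    whose mean adjusted r2 is <= 0 (or <= 1/alpha, implying Ne <= 0)
    yield no estimate and are logged.
    """
    if records.empty:
        raise DataError("no LD records")
    if n < 2:
        raise DataError("sample size must be >= 2")
    d = records["distance_bp"].to_numpy(float)
    r2_adj = records["r2"].to_numpy(float) - 1.0 / (beta * n)
    edges = np.geomspace(d.min(), d.max() + 1, bins + 1)
    idx = np.clip(np.digitize(d, edges) - 1, 0, bins - 1)
    c_all = distance_to_c(d, mapping=mapping, rate_cm_per_mb=rate_cm_per_mb)
    rows = []
    for b in range(bins):
        sel = idx == b
        if not sel.any():
            continue
        c_bin = 1.0 / np.mean(1.0 / c_all[sel])  # harmonic mean
        t = 1.0 / (2.0 * c_bin)
        mean_r2 = float(r2_adj[sel].mean())
        if mean_r2 <= 0 or 1.0 / mean_r2 <= alpha:
            logger.info("bin %d: adjusted r2 %.4f yields no Ne", b, mean_r2)
            ne = np.nan
        else:
            ne = (1.0 / (4.0 * c_bin)) * (1.0 / mean_r2 - alpha)
        rows.append({"bin": b, "c": c_bin, "t": t, "mean_r2_adj": mean_r2,
                     "n_pairs": int(sel.sum()), "ne": ne})
    table = pd.DataFrame(rows)
    curve_ok = table.dropna(subset=["ne"])

    def extract(gen: float) -> float:
        if curve_ok.empty:
            return float("nan")
        i = (curve_ok["t"] - gen).abs().idxmin()
        return float(curve_ok.loc[i, "ne"])

    return NeCurve(table, extract(5), extract(50), extract(2000))


def estimate_ne(
    h: HaplotypeMatrix,
    d_min: int = 20_000,
    d_max: int = 10_000_000,
    **curve_kwargs,
) -> NeCurve:
    """Convenience: LD records then Ne curve for one breed's haplotypes."""
    rec = pairwise_r2(h, d_min=d_min, d_max=d_max)
    return ne_curve(rec, n=h.n_individuals, **curve_kwargs)


def group_ne_summary(
    table: pd.DataFrame, breeds: BreedAssignment, min_nd: int = 9
) -> pd.DataFrame:
    """Nd-weighted group means of Ne_5/Ne_50/Ne_2000.

    Only breeds with ``Nd >= min_nd`` and a defined estimate enter the
    weighting; a group with no eligible breed reports NaN.
    """
    cols = [c for c in ("Ne5", "Ne50", "Ne2000") if c in table.columns]
    if not cols:
        raise DataError("summary table has no Ne columns")
    tab = table.copy()
    tab["group"] = [breeds.breed_group.get(b) for b in tab.index]
    out = {}
    for grp, sub in tab.groupby("group"):
        row = {}
        for col in cols:
            ok = sub[col].notna() & (sub["Nd"] >= min_nd)
            if ok.any():
                w = sub.loc[ok, "Nd"].astype(float)
                row[col] = float((w * sub.loc[ok, col]).sum() / w.sum())
            else:
                row[col] = np.nan
        out[grp] = row
    return pd.DataFrame(out).T
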