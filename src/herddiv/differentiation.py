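"""Between-breed differentiation and low-dimensional projection.

Two complementary views:

* **Jost's D_EST** between breed pairs from multi-allelic block-allele
  frequencies. With ``n = 2`` demes of harmonic-mean size ``N~``,

      H_S^ = (2N~ / (2N~ - 1)) (1 - mean_deme sum p^2)
      H_T^ = 1 - sum (mean_deme p)^2 + H_S^ / (4 N~)
      D    = (H_T^ - H_S^) / (1 - H_S^) * n / (n - 1)

  aggregated over blocks via means of the H components (default) or as
  the mean of per-block D values (``per_locus_mean=True``). Unlike G_ST,
  D_EST stays informative when within-deme gene diversity is high, which
  is exactly the regime of multi-allelic haplotype blocks.

* **Allele-sharing distance D_PS** between individuals: one minus the
  mean proportion of block alleles shared by the two genotypes, projected
  to 2-D by classical (Torgerson) multidimensional scaling with breed
  centers and SD dispersion radii.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import BreedAssignment, DataError
from .diversity import BlockAlleleTable
from .haploblocks import BlockGenotypes

logger = logging.getLogger(__name__)

__all__ = [
    "dest_pairwise",
    "dest_matrix",
    "dest_summaries",
    "allele_sharing_distance",
    "mean_within_breed_dps",
    "classical_mds",
    "breed_dispersion",
    "MdsProjection",
]


def _dest_components(
    counts_a: np.ndarray, counts_b: np.ndarray, n_a: float, n_b: float
) -> tuple[np.ndarray, np.ndarray]:
    """Per-block (H_S^, H_T^) for two demes with sample-size correction."""
    p_a = counts_a / (2.0 * n_a)
    p_b = counts_b / (2.0 * n_b)
    n_tilde = 2.0 / (1.0 / n_a + 1.0 / n_b)  # harmonic mean deme size
    mean_sum_p2 = ((p_a**2).sum(axis=1) + (p_b**2).sum(axis=1)) / 2.0
    hs = (2.0 * n_tilde / (2.0 * n_tilde - 1.0)) * (1.0 - mean_sum_p2)
    p_bar = (p_a + p_b) / 2.0
    ht = 1.0 - (p_bar**2).sum(axis=1) + hs / (4.0 * n_tilde)
    return hs, ht


def dest_pairwise(
    counts_a: np.ndarray,
    counts_b: np.ndarray,
    n_a: int,
    n_b: int,
    per_locus_mean: bool = False,
) -> float:
    """Jost's D_EST between two breeds from block-allele count tables.

    ``counts_*`` are (n_blocks, n_alleles) gene-copy counts summing to
    ``2 * n_*`` per block. Small negative estimates are clamped to zero
    (and logged): the unbiased estimator can undershoot at low
    differentiation.
    """
    counts_a = np.asarray(counts_a, float)
    counts_b = np.asarray(counts_b, float)
    if counts_a.shape != counts_b.shape:
        raise DataError("breed count tables must share the block set")
    if min(n_a, n_b) < 1:
        raise DataError("each deme needs at least one diploid individual")
    hs, ht = _dest_components(counts_a, counts_b, float(n_a), float(n_b))
    if per_locus_mean:
        denom = 1.0 - hs
        ok = denom > 1e-12
        if not ok.any():
            logger.info("monomorphic-everywhere pair: D_EST = 0")
            return 0.0
        d_blocks = 2.0 * (ht[ok] - hs[ok]) / denom[ok]
        d = float(d_blocks.mean())
    else:
        hs_bar, ht_bar = hs.mean(), ht.mean()
        if 1.0 - hs_bar <= 1e-12:
            logger.info("saturated within-deme diversity: D_EST undefined -> 0")
            return 0.0
        d = float(2.0 * (ht_bar - hs_bar) / (1.0 - hs_bar))
    if d < 0:
        logger.debug("negative D_EST estimate %.3g clamped to 0", d)
        d = 0.0
    return min(d, 1.0)


def dest_matrix(t: BlockAlleleTable, per_locus_mean: bool = False) -> pd.DataFrame:
    """Symmetric breed x breed D_EST matrix (zero diagonal)."""
    b = len(t.breeds)
    m = np.zeros((b, b))
    for i in range(b):
        for j in range(i + 1, b):
            m[i, j] = m[j, i] = dest_pairwise(
                t.counts[i], t.counts[j], int(t.nd[i]), int(t.nd[j]),
                per_locus_mean=per_locus_mean,
            )
    return pd.DataFrame(m, index=t.breeds, columns=t.breeds)


def dest_summaries(
    m: pd.DataFrame, breeds: BreedAssignment
) -> tuple[pd.Series, pd.Series]:
    """Within-group mean D_EST and per-breed mean D_EST to all others.

    Within-group means are unweighted means over the distinct breed
    pairs of the group; a single-breed group has no within-group value.
    """
    labels = list(m.index)
    per_breed = pd.Series(
        {b: m.loc[b].drop(b).mean() for b in labels}, name="mean_dest"
    )
    vals = {}
    for grp in breeds.groups:
        members = [b for b in labels if breeds.breed_group.get(b) == grp]
        if len(members) < 2:
            vals[grp] = np.nan
            continue
        sub = m.loc[members, members].to_numpy()
        iu = np.triu_indices(len(members), k=1)
        vals[grp] = float(sub[iu].mean())
    return pd.Series(vals, name="within_group_dest"), per_breed


def allele_sharing_distance(bg: BlockGenotypes) -> pd.DataFrame:
    """Pairwise D_PS = 1 - mean over blocks of (shared alleles / 2).

    Sharing between two unordered block genotypes is the size of the
    multiset intersection of the two allele pairs (0, 1 or 2).
    """
    a = bg.alleles  # (n, L, 2)
    n = a.shape[0]
    d = np.zeros((n, n))
    for i in range(n - 1):
        gi = a[i]  # (L, 2)
        gj = a[i + 1:]  # (m, L, 2)
        s_direct = (gj[:, :, 0] == gi[:, 0]).astype(np.int8) + (
            gj[:, :, 1] == gi[:, 1]
        )
        s_cross = (gj[:, :, 0] == gi[:, 1]).astype(np.int8) + (
            gj[:, :, 1] == gi[:, 0]
        )
        shared = np.maximum(s_direct, s_cross)  # multiset intersection size
        dps = 1.0 - shared.mean(axis=1) / 2.0
        d[i, i + 1:] = dps
        d[i + 1:, i] = dps
    return pd.DataFrame(d, index=bg.individuals, columns=bg.individuals)


def mean_within_breed_dps(
    d: pd.DataFrame, breeds: BreedAssignment
) -> pd.Series:
    """Mean D_PS over distinct within-breed pairs (NaN for singletons)."""
    individuals = list(d.index)
    out = {}
    for breed in breeds.breeds:
        idx = breeds.members(breed, individuals)
        if len(idx) < 2:
            if len(idx) == 1:
                out[breed] = np.nan
            continue
        sub = d.to_numpy()[np.ix_(idx, idx)]
        iu = np.triu_indices(len(idx), k=1)
        out[breed] = float(sub[iu].mean())
    return pd.Series(out, name="mean_within_dps")


def classical_mds(d: np.ndarray, k: int = 2) -> np.ndarray:
    """Principal-coordinates (Torgerson) embedding of a distance matrix.

    Double-centers ``-D^2 / 2``, takes the top-k eigenpairs and scales
    eigenvectors by the square roots of their eigenvalues. The sign of
    each axis is fixed so its largest-magnitude loading is positive.
    Fewer than ``k`` positive eigenvalues reduce the dimensionality with
    a warning.
    """
    d = np.asarray(d, float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise DataError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-8) or not np.allclose(np.diag(d), 0):
        raise DataError("distance matrix must be symmetric with zero diagonal")
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    vals, vecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals > max(vals.max(), 0.0) * 1e-12
    k_eff = min(k, int(pos.sum()))
    if k_eff < k:
        logger.warning("only %d positive eigenvalues; returning %d axes",
                       int(pos.sum()), k_eff)
    coords = vecs[:, :k_eff] * np.sqrt(vals[:k_eff])
    for axis in range(k_eff):
        i_max = np.argmax(np.abs(coords[:, axis]))
        if coords[i_max, axis] < 0:
            coords[:, axis] = -coords[:, axis]
    return coords


@dataclass(frozen=True)
class MdsProjection:
    """Individual coordinates plus per-breed center and dispersion radius."""

    coordinates: pd.DataFrame  # individual, breed, x, y
    breed_summary: pd.DataFrame  # breed, cx, cy, radius, n


def breed_dispersion(
    coords: np.ndarray, individuals: list[str], breeds: BreedAssignment
) -> MdsProjection:
    """Breed centers (member means) and radii (SD of center distances)."""
    if coords.shape[1] < 2:
        raise DataError("need at least 2 MDS dimensions")
    xy = coords[:, :2]
    rows = []
    for breed in breeds.breeds:
        idx = breeds.members(breed, individuals)
        if not len(idx):
            continue
        center = xy[idx].mean(axis=0)
        dist = np.hypot(*(xy[idx] - center).T)
        rows.append(
            {"breed": breed, "cx": center[0], "cy": center[1],
             "radius": float(dist.std()), "n": len(idx)}
        )
    coord_df = pd.DataFrame(
        {
            "individual": individuals,
            "breed": [breeds.individual_breed.get(i) for i in individuals],
            "x": xy[:, 0],
            "y": xy[:, 1],
        }
    )
    return MdsProjection(coord_df, pd.DataFrame(rows).set_index("breed"))
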