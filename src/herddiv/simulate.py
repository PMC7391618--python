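"""Truth-known synthetic genotype generators.

The real multi-breed cattle genotypes this pipeline targets are
request-only, so every stage is exercised on synthetic substrates whose
generating parameters are returned alongside the data:

* :func:`simulate_hierarchical` — Balding-Nichols drift around shared
  ancestral frequencies: breed b's frequency at a SNP with ancestral
  frequency p is Beta(p (1-F)/F, (1-p)(1-F)/F) with F the breed's
  divergence parameter, optionally admixed (frequency-level mixture of
  source breeds) and with within-individual allele correlation equal to
  a per-breed inbreeding coefficient. Ancestral frequencies are
  Uniform(0.05, 0.95), mimicking array ascertainment against rare
  variants. Markers sit on a uniform map so haplotype blocks can form.
* :func:`simulate_wright_fisher` — discrete-generation forward simulator
  with Poisson recombination (Markov switch process along the
  chromosome, Haldane mapping), the LD substrate for Ne(t) recovery.
* :func:`simulate_dstat_graph` — frequency evolution along
  (((P1,P2),P3),O) with optional post-split P3->P2 introgression.

All randomness flows from the single seed; identical seeds give
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datamodel import BreedAssignment, DataError, HaplotypeMatrix, MarkerMap

__all__ = [
    "SimTruth",
    "STUDY_DESIGN",
    "simulate_hierarchical",
    "simulate_wright_fisher",
    "simulate_dstat_graph",
    "sample_genotypes_from_frequencies",
]

#: The sampling design the generators emulate at full scale: ~100 breeds
#: in ~10 geographic groups, 4-50 diploids per breed, tens of thousands
#: of mapped autosomal SNPs. Tests and the acceptance script run scaled-
#: down versions of the same structure.
STUDY_DESIGN = {
    "n_breeds": 100,
    "n_groups": 10,
    "n_per_breed_range": (4, 50),
    "n_snps": 46_678,
    "fst_range": (0.02, 0.25),
    "map_spacing_bp": 10_000,
}


@dataclass(frozen=True)
class SimTruth:
    """Generator parameters for parameter-recovery tests."""

    seed: int
    ancestral_freq: np.ndarray | None = None
    fst: np.ndarray | None = None
    admixture: np.ndarray | None = None
    inbreeding: np.ndarray | None = None
    ne_trajectory: tuple[int, ...] | None = None
    introgression_fraction: float | None = None
    extras: dict = field(default_factory=dict)


def _balding_nichols(
    rng: np.random.Generator, p: np.ndarray, fst: float
) -> np.ndarray:
    """Drifted frequencies around p at divergence fst (0 -> no drift)."""
    if not 0 <= fst < 1:
        raise DataError(f"fst must be in [0, 1), got {fst}")
    if fst == 0:
        return p.copy()
    a = p * (1.0 - fst) / fst
    b = (1.0 - p) * (1.0 - fst) / fst
    if (a <= 0).any() or (b <= 0).any():
        raise DataError("invalid Beta parameters (ancestral p on boundary?)")
    drift = rng.beta(a, b)
    # keep sites polymorphic-representable; exact 0/1 draws are measure-
    # zero in theory but occur in floating point
    return np.clip(drift, 1e-9, 1.0 - 1e-9)


def _uniform_map(n_snps: int, spacing: int, snps_per_chrom: int) -> MarkerMap:
    chroms = []
    poss = []
    for k in range(n_snps):
        chrom = k // snps_per_chrom + 1
        within = k % snps_per_chrom
        chroms.append(str(chrom))
        poss.append(1 + within * spacing)
    return MarkerMap(
        np.array([f"snp{k + 1}" for k in range(n_snps)], object),
        np.array(chroms, object),
        np.array(poss, np.int64),
    )


def simulate_hierarchical(
    n_pops: int,
    n_per_pop: int | list[int],
    n_snps: int,
    fst: float | list[float] = 0.1,
    admixture: np.ndarray | None = None,
    inbreeding: float | list[float] = 0.0,
    map_spacing: int = 10_000,
    snps_per_chrom: int = 1_000,
    groups: dict[str, str] | None = None,
    seed: int = 0,
) -> tuple[HaplotypeMatrix, BreedAssignment, SimTruth]:
    """Hierarchical-drift breeds with optional admixture and inbreeding.

    Breeds are named ``POP1..POPn``; ``groups`` maps breed name to group
    (default: all in group "SIM"). ``admixture`` is an
    (n_pops x n_pops) row-stochastic matrix mixing the drifted source
    frequencies; the identity (default) means no admixture.
    """
    rng = np.random.default_rng(seed)
    n_per = np.full(n_pops, n_per_pop) if np.isscalar(n_per_pop) \
        else np.asarray(n_per_pop)
    fst_arr = np.full(n_pops, fst, float) if np.isscalar(fst) \
        else np.asarray(fst, float)
    inb = np.full(n_pops, inbreeding, float) if np.isscalar(inbreeding) \
        else np.asarray(inbreeding, float)
    if len(n_per) != n_pops or len(fst_arr) != n_pops or len(inb) != n_pops:
        raise DataError("per-population parameter lengths must equal n_pops")
    if admixture is not None:
        admixture = np.asarray(admixture, float)
        if admixture.shape != (n_pops, n_pops):
            raise DataError("admixture matrix must be n_pops x n_pops")
        if not np.allclose(admixture.sum(axis=1), 1.0):
            raise DataError("admixture rows must sum to 1")

    p_anc = rng.uniform(0.05, 0.95, size=n_snps)
    pop_freq = np.stack(
        [_balding_nichols(rng, p_anc, float(f)) for f in fst_arr]
    )
    if admixture is not None:
        pop_freq = admixture @ pop_freq

    names = [f"POP{b + 1}" for b in range(n_pops)]
    individuals: list[str] = []
    ind_breed: dict[str, str] = {}
    hap_rows = []
    for b, name in enumerate(names):
        p = pop_freq[b]
        for i in range(int(n_per[b])):
            ind = f"{name}_{i + 1}"
            individuals.append(ind)
            ind_breed[ind] = name
            h1 = (rng.random(n_snps) < p).astype(np.uint8)
            fresh = (rng.random(n_snps) < p).astype(np.uint8)
            copy_mask = rng.random(n_snps) < inb[b]
            h2 = np.where(copy_mask, h1, fresh).astype(np.uint8)
            hap_rows.append(h1)
            hap_rows.append(h2)

    markers = _uniform_map(n_snps, map_spacing, snps_per_chrom)
    h = HaplotypeMatrix(individuals, markers, np.array(hap_rows, np.uint8))
    breed_group = groups if groups is not None else {n: "SIM" for n in names}
    assignment = BreedAssignment(ind_breed, breed_group,
                                 nd={n: int(k) for n, k in zip(names, n_per)})
    truth = SimTruth(
        seed=seed,
        ancestral_freq=p_anc,
        fst=fst_arr,
        admixture=admixture,
        inbreeding=inb,
    )
    return h, assignment, truth


def simulate_wright_fisher(
    ne: int,
    generations: int,
    n_snps: int,
    chrom_length: int = 50_000_000,
    recomb_rate_cm_per_mb: float = 1.0,
    n_sample: int = 25,
    seed: int = 0,
) -> tuple[HaplotypeMatrix, SimTruth]:
    """Forward Wright-Fisher population on one chromosome.

    2*ne haplotypes evolve for ``generations`` discrete generations; each
    offspring haplotype is a gamete of a randomly chosen diploid parent,
    built by a Markov crossover-switch process whose adjacent-site switch
    probabilities follow Haldane's mapping of the physical gaps. Initial
    site frequencies are Uniform(0.05, 0.95). Sites fixed in the final
    sample are dropped from the output (LD carries no information there);
    at least one site must remain.
    """
    if ne < 10:
        raise DataError("ne must be >= 10")
    if n_sample > ne:
        raise DataError("cannot sample more individuals than ne")
    rng = np.random.default_rng(seed)
    pos = np.sort(rng.choice(np.arange(1, chrom_length + 1), size=n_snps,
                             replace=False))
    gaps_morgan = np.diff(pos) * recomb_rate_cm_per_mb * 1e-8
    switch_p = 0.5 * (1.0 - np.exp(-2.0 * gaps_morgan))

    p0 = rng.uniform(0.05, 0.95, size=n_snps)
    haps = (rng.random((2 * ne, n_snps)) < p0).astype(np.uint8)

    n_gam = 2 * ne
    for _ in range(generations):
        parents = rng.integers(0, ne, size=n_gam)
        start = rng.integers(0, 2, size=n_gam)
        switches = rng.random((n_gam, n_snps - 1)) < switch_p
        chooser = np.empty((n_gam, n_snps), dtype=np.uint8)
        chooser[:, 0] = start
        chooser[:, 1:] = (start[:, None] + np.cumsum(switches, axis=1)) % 2
        rows = 2 * parents[:, None] + chooser
        haps = haps[rows, np.arange(n_snps)[None, :]]

    pick = rng.choice(ne, size=n_sample, replace=False)
    rows = np.empty(2 * n_sample, dtype=np.int64)
    rows[0::2] = 2 * pick
    rows[1::2] = 2 * pick + 1
    sample = haps[rows]
    seg = sample.std(axis=0) > 0
    if not seg.any():
        raise DataError("all sites fixed; simulate more SNPs or generations")
    sample = sample[:, seg]
    markers = MarkerMap(
        np.array([f"wf{k + 1}" for k in np.flatnonzero(seg)], object),
        np.array(["1"] * int(seg.sum()), object),
        pos[seg],
    )
    individuals = [f"WF_{i + 1}" for i in range(n_sample)]
    truth = SimTruth(seed=seed, ne_trajectory=tuple([ne] * generations),
                     extras={"n_snps_segregating": int(seg.sum())})
    return HaplotypeMatrix(individuals, markers, sample), truth


DEFAULT_DRIFT = {
    "o": 0.30, "p123": 0.05, "p3": 0.10, "p12": 0.05,
    "p1": 0.02, "p2": 0.02,
}


def simulate_dstat_graph(
    n_snps: int,
    drift_lengths: dict[str, float] | None = None,
    introgression_fraction: float = 0.0,
    seed: int = 0,
) -> tuple[tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray], SimTruth]:
    """Frequency vectors for (((P1,P2),P3),O) with optional P3->P2 flow.

    Each branch applies Balding-Nichols drift of the given length (an
    F-like parameter). With probability ``introgression_fraction`` a
    site's P2 frequency is replaced by its P3 value, emulating post-split
    introgression.
    """
    if not 0 <= introgression_fraction < 1:
        raise DataError("introgression fraction must be in [0, 1)")
    drift = dict(DEFAULT_DRIFT)
    if drift_lengths:
        drift.update(drift_lengths)
    rng = np.random.default_rng(seed)
    p_root = rng.uniform(0.05, 0.95, size=n_snps)
    p_o = _balding_nichols(rng, p_root, drift["o"])
    p_123 = _balding_nichols(rng, p_root, drift["p123"])
    p_3 = _balding_nichols(rng, p_123, drift["p3"])
    p_12 = _balding_nichols(rng, p_123, drift["p12"])
    p_1 = _balding_nichols(rng, p_12, drift["p1"])
    p_2 = _balding_nichols(rng, p_12, drift["p2"])
    if introgression_fraction > 0:
        mask = rng.random(n_snps) < introgression_fraction
        p_2 = np.where(mask, p_3, p_2)
    truth = SimTruth(seed=seed, introgression_fraction=introgression_fraction,
                     extras={"drift": drift})
    return (p_1, p_2, p_3, p_o), truth


def sample_genotypes_from_frequencies(
    freqs: dict[str, np.ndarray],
    n_per_pop: int,
    markers: MarkerMap,
    groups: dict[str, str] | None = None,
    seed: int = 0,
):
    """Draw Hardy-Weinberg diploid genotypes from per-breed frequencies.

    Returns a GenotypeMatrix plus BreedAssignment; convenience for
    feeding frequency-level simulations into genotype-level scans.
    """
    from .datamodel import GenotypeMatrix

    rng = np.random.default_rng(seed)
    individuals: list[str] = []
    ind_breed: dict[str, str] = {}
    rows = []
    for name, p in freqs.items():
        for i in range(n_per_pop):
            ind = f"{name}_{i + 1}"
            individuals.append(ind)
            ind_breed[ind] = name
            rows.append(
                (rng.random(len(p)) < p).astype(np.int8)
                + (rng.random(len(p)) < p).astype(np.int8)
            )
    group_map = groups if groups is not None else {n: "SIM" for n in freqs}
    return (
        GenotypeMatrix(individuals, markers, np.array(rows, np.int8)),
        BreedAssignment(ind_breed, group_map),
    )
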