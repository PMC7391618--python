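from collections import Counter

import numpy as np
import pandas as pd
import pytest

from conftest import make_markers
from herddiv.datamodel import BreedAssignment, DataError, GenotypeMatrix
from herddiv.diversity import (
    BlockAlleleTable,
    allelic_richness,
    breed_allele_counts,
    correlate_f_private,
    diversity_summary,
    group_weighted_summary,
    private_allele_counts,
    snp_heterozygosity,
)
from herddiv.haploblocks import BlockDefinition, BlockGenotypes
from herddiv.io import load_reference_table


def block_genotypes(allele_array, breed_of=None):
    """BlockGenotypes from an (n, L, 2) array of allele codes."""
    a = np.asarray(allele_array, np.int32)
    n, L, _ = a.shape
    blocks = [
        BlockDefinition(f"blk{l}", "1", (4 * l, 4 * l + 1, 4 * l + 2, 4 * l + 3),
                        1 + 40_000 * l, 30_001 + 40_000 * l)
        for l in range(L)
    ]
    inds = [f"i{k}" for k in range(n)]
    bg = BlockGenotypes(inds, blocks, a)
    breed_map = breed_of or {i: "B1" for i in inds}
    breeds = BreedAssignment(breed_map, {b: "G" for b in set(breed_map.values())})
    return bg, breeds


class TestBreedAlleleCounts:
    def test_exact_tally(self):
        bg, breeds = block_genotypes([[[0, 0]], [[0, 15]]])
        t = breed_allele_counts(bg, breeds)
        assert t.counts[0, 0, 0] == 3
        assert t.counts[0, 0, 15] == 1
        assert t.het[0, 0] == 1

    def test_counts_sum_to_2nd_everywhere(self, small_blocks):
        _, _, t = small_blocks
        np.testing.assert_array_equal(
            t.counts.sum(axis=2), np.repeat(t.gene_copies[:, None], t.n_blocks, 1)
        )

    def test_unknown_individuals_cause_error(self):
        bg, _ = block_genotypes([[[0, 0]]])
        orphan = BreedAssignment({}, {"B": "G"})
        with pytest.raises(DataError):
            breed_allele_counts(bg, orphan)


class TestDiversitySummary:
    def test_against_bruteforce_tally_oracle(self, small_blocks):
        _, bg, t = small_blocks
        s = diversity_summary(t)
        for b, breed in enumerate(t.breeds):
            members = [i for i, ind in enumerate(bg.individuals)
                       if ind.startswith(breed)]
            n = len(members)
            na = ho = he = 0.0
            for l in range(bg.n_blocks):
                pairs = [tuple(bg.alleles[i, l]) for i in members]
                copies = Counter(c for p in pairs for c in p)
                na += len(copies)
                ho += sum(1 for a, bb in pairs if a != bb) / n
                freqs = np.array(list(copies.values())) / (2 * n)
                he += (2 * n / (2 * n - 1)) * (1 - (freqs**2).sum())
            assert s.loc[breed, "nA"] == na
            assert s.loc[breed, "Ho"] == pytest.approx(ho / bg.n_blocks)
            assert s.loc[breed, "He"] == pytest.approx(he / bg.n_blocks)

    def test_all_heterozygote_limit(self):
        # one block, two equifrequent alleles, every individual heterozygous
        n = 50
        a = np.zeros((n, 1, 2), np.int32)
        a[:, 0, 1] = 1
        bg, breeds = block_genotypes(a)
        s = diversity_summary(breed_allele_counts(bg, breeds))
        assert s["Ho"].iloc[0] == 1.0
        assert s["He"].iloc[0] == pytest.approx(0.5 * (100 / 99))
        assert s["Hdef"].iloc[0] == pytest.approx(
            (0.5 * 100 / 99 - 1) / (0.5 * 100 / 99)
        )

    def test_reference_grb_hdef_consistency(self):
        t = load_reference_table()
        ho, he = t.loc["GRB", "Ho"], t.loc["GRB", "He"]
        assert (he - ho) / he == pytest.approx(t.loc["GRB", "Hdef"], abs=0.01)

    def test_relabeling_breeds_is_equivariant(self, small_blocks):
        _, _, t = small_blocks
        perm = [2, 0, 1]
        t2 = BlockAlleleTable(
            [t.breeds[i] for i in perm], t.counts[perm], t.het[perm], t.nd[perm]
        )
        s1 = diversity_summary(t).loc[[t.breeds[i] for i in perm]]
        s2 = diversity_summary(t2)
        pd.testing.assert_frame_equal(s1, s2)


class TestAllelicRichness:
    def table_for(self, counts):
        counts = np.asarray(counts)[None, None, :]
        nd = counts.sum() // 2
        return BlockAlleleTable(["B"], counts.astype(np.int32),
                                np.zeros((1, 1), np.int32), np.array([nd]))

    def test_full_depth_returns_observed_count(self):
        assert allelic_richness(self.table_for([4, 4]), g=8).iloc[0] == \
            pytest.approx(2.0)

    def test_hand_hypergeometric_value(self):
        # counts (7,1), g=2: 1 + (1 - C(7,2)/C(8,2)) = 1.25
        assert allelic_richness(self.table_for([7, 1]), g=2).iloc[0] == \
            pytest.approx(1.25)

    def test_monotone_in_depth(self, small_blocks):
        _, _, t = small_blocks
        depths = range(2, int(t.gene_copies.min()) + 1)
        curves = np.array([allelic_richness(t, g).to_numpy() for g in depths])
        assert (np.diff(curves, axis=0) >= -1e-12).all()

    def test_depth_beyond_sample_is_error(self, small_blocks):
        _, _, t = small_blocks
        with pytest.raises(DataError):
            allelic_richness(t, g=int(t.gene_copies.min()) + 1)


class TestPrivateAlleles:
    def test_fully_shared_alleles_are_all_common(self):
        a = np.zeros((4, 1, 2), np.int32)
        a[:, 0, 1] = 1  # both breeds carry alleles {0, 1}
        breed_of = {"i0": "A", "i1": "A", "i2": "B", "i3": "B"}
        bg, breeds = block_genotypes(a, breed_of)
        df, nca = private_allele_counts(breed_allele_counts(bg, breeds))
        assert (df["npA"] == 0).all()
        assert nca == 2

    def test_sole_private_allele_frequency(self):
        # breed A: allele 5 at frequency 0.3 (3 of 10 copies), private
        a = np.zeros((10, 1, 2), np.int32)
        a[0, 0] = [5, 5]
        a[1, 0, 0] = 5
        breed_of = {f"i{k}": ("A" if k < 5 else "B") for k in range(10)}
        bg, breeds = block_genotypes(a, breed_of)
        df, _ = private_allele_counts(breed_allele_counts(bg, breeds))
        assert df.loc["A", "npA"] == 1
        assert df.loc["A", "fpA"] == pytest.approx(0.3)

    def test_against_occupancy_oracle(self, small_blocks):
        _, bg, t = small_blocks
        df, nca = private_allele_counts(t)
        # brute force: map (block, word) -> set of carrying breeds
        carriers: dict[tuple[int, int], set] = {}
        for i, ind in enumerate(bg.individuals):
            breed = ind.split("_")[0]
            for l in range(bg.n_blocks):
                for code in bg.alleles[i, l]:
                    carriers.setdefault((l, int(code)), set()).add(breed)
        for breed in t.breeds:
            npa = sum(1 for s in carriers.values() if s == {breed})
            nspa = sum(1 for s in carriers.values()
                       if len(s) == 2 and breed in s)
            assert df.loc[breed, "npA"] == npa
            assert df.loc[breed, "nspA"] == nspa
        assert nca == sum(1 for s in carriers.values()
                          if len(s) == len(t.breeds))


class TestSnpHeterozygosity:
    def test_fixed_breed_is_zero(self):
        m = make_markers([1, 10_001])
        g = GenotypeMatrix(["a", "b"], m, np.array([[2, 0], [2, 0]], np.int8))
        breeds = BreedAssignment({"a": "X", "b": "X"}, {"X": "G"})
        s = snp_heterozygosity(g, breeds)
        assert s.loc["X", "Ho_snp"] == 0.0
        assert s.loc["X", "He_snp"] == 0.0

    def test_all_heterozygote_breed(self):
        m = make_markers([1])
        g = GenotypeMatrix(["a", "b"], m, np.array([[1], [1]], np.int8))
        breeds = BreedAssignment({"a": "X", "b": "X"}, {"X": "G"})
        assert snp_heterozygosity(g, breeds).loc["X", "Ho_snp"] == 1.0

    def test_equals_block_estimator_on_single_snp_blocks(self, small_cohort):
        h, breeds, _ = small_cohort
        g = h.to_genotypes()
        s = snp_heterozygosity(g, breeds)
        # 1-SNP "blocks": code = allele value, pair = the two haplotypes
        a = np.stack([h.alleles[0::2], h.alleles[1::2]], axis=2).astype(np.int32)
        blocks = [
            BlockDefinition(f"b{k}", "1", (k,), 1, 2) for k in range(h.n_snps)
        ]
        bg = BlockGenotypes(list(h.individuals), blocks, a, block_size=1)
        t = breed_allele_counts(bg, breeds)
        s_blk = diversity_summary(t)
        for breed in t.breeds:
            assert s.loc[breed, "Ho_snp"] == pytest.approx(s_blk.loc[breed, "Ho"])
            assert s.loc[breed, "He_snp"] == pytest.approx(s_blk.loc[breed, "He"])


class TestGroupSummary:
    def reference_setup(self):
        t = load_reference_table()
        breeds = BreedAssignment(
            {}, dict(zip(t["breed"], t["group"]))
        )
        return t, breeds

    def test_reference_group_means_reproduce(self):
        t, breeds = self.reference_setup()
        g = group_weighted_summary(t, breeds)
        assert g.loc["GreeceCyprus", "F"] == pytest.approx(0.178, abs=5e-3)
        assert g.loc["GreeceCyprus", "AR"] == pytest.approx(3.54, abs=5e-3)

    def test_single_breed_group_equals_breed_value(self):
        t, _ = self.reference_setup()
        solo = t.loc[["GRB"]].copy()
        breeds = BreedAssignment({}, {"GRB": "OnlyOne"})
        g = group_weighted_summary(solo, breeds)
        assert g.loc["OnlyOne", "F"] == pytest.approx(t.loc["GRB", "F"])

    def test_undefined_ne_excluded_from_weighting(self):
        t, breeds = self.reference_setup()
        g = group_weighted_summary(t, breeds)
        # Greece/Cyprus has Ne-less breeds; weighting the defined ones
        # still yields the printed value
        assert g.loc["GreeceCyprus", "Ne5"] == pytest.approx(40, abs=0.5)


class TestCorrelations:
    def test_reference_correlations(self):
        t = load_reference_table()
        r_fpa, r_npa = correlate_f_private(t)
        assert r_fpa == pytest.approx(0.72, abs=5e-3)
        assert r_npa == pytest.approx(-0.21, abs=5e-3)

    def test_perfect_correlation_case(self):
        df = pd.DataFrame(
            {"F": [0.1, 0.2, 0.3, 0.4], "fpA": [0.1, 0.2, 0.3, 0.4],
             "npA": [4, 3, 2, 1], "group": ["G"] * 4}
        )
        r_fpa, r_npa = correlate_f_private(df, exclude_groups=())
        assert r_fpa == pytest.approx(1.0)
        assert r_npa == pytest.approx(-1.0)

    def test_too_few_rows_is_error(self):
        df = pd.DataFrame({"F": [0.1], "fpA": [0.1], "npA": [1]})
        with pytest.raises(DataError):
            correlate_f_private(df, exclude_groups=())
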