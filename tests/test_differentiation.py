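import numpy as np
import pandas as pd
import pytest

from herddiv.datamodel import BreedAssignment
from herddiv.differentiation import (
    allele_sharing_distance,
    breed_dispersion,
    classical_mds,
    dest_matrix,
    dest_pairwise,
    dest_summaries,
    mean_within_breed_dps,
)
from herddiv.haploblocks import BlockDefinition, BlockGenotypes


def dest_oracle(counts_a, counts_b, n_a, n_b):
    """Independent direct-formula coding of the two-deme Jost D estimator.

    Written as explicit per-block scalar loops to stay structurally
    independent of the vectorized implementation.
    """
    hs_list, ht_list = [], []
    n_harm = 2.0 / (1.0 / n_a + 1.0 / n_b)
    for row_a, row_b in zip(counts_a, counts_b):
        pa = [c / (2 * n_a) for c in row_a]
        pb = [c / (2 * n_b) for c in row_b]
        sum_p2 = (sum(x * x for x in pa) + sum(x * x for x in pb)) / 2
        hs = (2 * n_harm / (2 * n_harm - 1)) * (1 - sum_p2)
        ht = 1 - sum(((x + y) / 2) ** 2 for x, y in zip(pa, pb)) + hs / (4 * n_harm)
        hs_list.append(hs)
        ht_list.append(ht)
    hs_bar = sum(hs_list) / len(hs_list)
    ht_bar = sum(ht_list) / len(ht_list)
    return max(0.0, 2.0 * (ht_bar - hs_bar) / (1.0 - hs_bar))


class TestDestPairwise:
    def test_identical_tables_give_zero(self):
        rng = np.random.default_rng(0)
        counts = rng.multinomial(40, [0.4, 0.3, 0.2, 0.1], size=30)
        d = dest_pairwise(counts, counts, 20, 20)
        assert d == pytest.approx(0.0, abs=1e-9)

    def test_disjoint_fixation_gives_one(self):
        a = np.zeros((10, 4))
        b = np.zeros((10, 4))
        a[:, 0] = 40
        b[:, 1] = 40
        assert dest_pairwise(a, b, 20, 20) == pytest.approx(1.0, abs=1e-9)

    def test_matches_independent_oracle(self):
        rng = np.random.default_rng(4)
        for trial in range(5):
            n_a, n_b = rng.integers(5, 30, size=2)
            pa = rng.dirichlet(np.ones(6), size=20)
            pb = rng.dirichlet(np.ones(6), size=20)
            ca = np.array([rng.multinomial(2 * n_a, p) for p in pa])
            cb = np.array([rng.multinomial(2 * n_b, p) for p in pb])
            got = dest_pairwise(ca, cb, int(n_a), int(n_b))
            want = dest_oracle(ca, cb, int(n_a), int(n_b))
            assert got == pytest.approx(want, abs=1e-12)

    def test_symmetric_and_label_invariant(self):
        rng = np.random.default_rng(5)
        ca = rng.multinomial(20, [0.5, 0.3, 0.2], size=10)
        cb = rng.multinomial(30, [0.2, 0.3, 0.5], size=10)
        d1 = dest_pairwise(ca, cb, 10, 15)
        d2 = dest_pairwise(cb, ca, 15, 10)
        assert d1 == pytest.approx(d2, abs=1e-12)
        perm = [2, 0, 1]
        d3 = dest_pairwise(ca[:, perm], cb[:, perm], 10, 15)
        assert d1 == pytest.approx(d3, abs=1e-12)


class TestDestSummaries:
    def test_hand_computed_three_breed_means(self):
        m = pd.DataFrame(
            [[0.0, 0.1, 0.3], [0.1, 0.0, 0.5], [0.3, 0.5, 0.0]],
            index=list("ABC"), columns=list("ABC"),
        )
        breeds = BreedAssignment({}, {"A": "G1", "B": "G1", "C": "G2"})
        within, per_breed = dest_summaries(m, breeds)
        assert within["G1"] == pytest.approx(0.1)
        assert np.isnan(within["G2"])  # singleton group
        assert per_breed["A"] == pytest.approx((0.1 + 0.3) / 2)

    def test_all_zero_matrix(self):
        m = pd.DataFrame(np.zeros((3, 3)), index=list("ABC"), columns=list("ABC"))
        breeds = BreedAssignment({}, {b: "G" for b in "ABC"})
        within, per_breed = dest_summaries(m, breeds)
        assert within["G"] == 0.0
        assert (per_breed == 0).all()


def simple_bg(allele_array, breed_of):
    a = np.asarray(allele_array, np.int32)
    blocks = [
        BlockDefinition(f"b{l}", "1", (0, 1, 2, 3), 1, 30_001)
        for l in range(a.shape[1])
    ]
    inds = [f"i{k}" for k in range(a.shape[0])]
    bg = BlockGenotypes(inds, blocks, a)
    breeds = BreedAssignment(
        breed_of, {b: "G" for b in set(breed_of.values())}
    )
    return bg, breeds


class TestAlleleSharing:
    def test_identical_homozygotes_share_everything(self):
        bg, _ = simple_bg([[[0, 0]], [[0, 0]]], {"i0": "A", "i1": "A"})
        d = allele_sharing_distance(bg)
        assert d.iloc[0, 1] == 0.0

    def test_disjoint_homozygotes_share_nothing(self):
        bg, _ = simple_bg([[[0, 0]], [[15, 15]]], {"i0": "A", "i1": "A"})
        assert allele_sharing_distance(bg).iloc[0, 1] == 1.0

    def test_half_shared_pair(self):
        # "0011/1100" vs "0011/0000": multiset intersection size 1
        bg, _ = simple_bg([[[3, 12]], [[3, 0]]], {"i0": "A", "i1": "A"})
        assert allele_sharing_distance(bg).iloc[0, 1] == pytest.approx(0.5)

    def test_swapped_pair_order_counts_as_shared(self):
        bg, _ = simple_bg([[[3, 12]], [[12, 3]]], {"i0": "A", "i1": "A"})
        assert allele_sharing_distance(bg).iloc[0, 1] == 0.0

    def test_within_breed_mean_matches_pair_enumeration(self, small_blocks):
        _, bg, _ = small_blocks
        breed_of = {ind: ind.split("_")[0] for ind in bg.individuals}
        breeds = BreedAssignment(
            breed_of, {b: "G" for b in set(breed_of.values())}
        )
        d = allele_sharing_distance(bg)
        means = mean_within_breed_dps(d, breeds)
        for breed in breeds.breeds:
            members = [i for i in bg.individuals if breed_of[i] == breed]
            vals = [
                d.loc[a, b]
                for k, a in enumerate(members) for b in members[k + 1:]
            ]
            assert means[breed] == pytest.approx(np.mean(vals))

    def test_breed_of_clones_has_zero_mean(self):
        a = np.tile(np.array([[3, 7]], np.int32), (4, 1, 1))
        bg, breeds = simple_bg(a, {f"i{k}": "C" for k in range(4)})
        d = allele_sharing_distance(bg)
        assert mean_within_breed_dps(d, breeds)["C"] == 0.0


class TestClassicalMds:
    def test_recovers_planar_triangle(self):
        pts = np.array([[0.0, 0.0], [3.0, 0.0], [0.0, 4.0]])
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        coords = classical_mds(d, k=2)
        d2 = np.linalg.norm(coords[:, None] - coords[None, :], axis=2)
        np.testing.assert_allclose(d2, d, atol=1e-8)

    def test_equilateral_configuration_from_equal_distances(self):
        d = np.ones((3, 3)) - np.eye(3)
        coords = classical_mds(d, k=2)
        d2 = np.linalg.norm(coords[:, None] - coords[None, :], axis=2)
        off = d2[~np.eye(3, dtype=bool)]
        np.testing.assert_allclose(off, 1.0, atol=1e-8)

    def test_duplicate_points_coincide(self):
        d = np.array(
            [[0.0, 0.0, 1.0], [0.0, 0.0, 1.0], [1.0, 1.0, 0.0]]
        )
        coords = classical_mds(d, k=2)
        np.testing.assert_allclose(coords[0], coords[1], atol=1e-10)

    def test_euclidean_reconstruction_property(self):
        rng = np.random.default_rng(8)
        pts = rng.normal(size=(12, 2))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        coords = classical_mds(d, k=2)
        d2 = np.linalg.norm(coords[:, None] - coords[None, :], axis=2)
        np.testing.assert_allclose(d2, d, atol=1e-8)

    def test_sign_convention_is_deterministic(self):
        rng = np.random.default_rng(9)
        pts = rng.normal(size=(6, 2))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        c1 = classical_mds(d, k=2)
        c2 = classical_mds(d.copy(), k=2)
        np.testing.assert_array_equal(c1, c2)
        for axis in range(2):
            assert c1[np.argmax(np.abs(c1[:, axis])), axis] > 0


class TestBreedDispersion:
    def test_unit_square_center_and_zero_sd(self):
        coords = np.array([[0, 0], [1, 0], [0, 1], [1, 1]], float)
        inds = [f"i{k}" for k in range(4)]
        breeds = BreedAssignment({i: "S" for i in inds}, {"S": "G"})
        proj = breed_dispersion(coords, inds, breeds)
        assert proj.breed_summary.loc["S", "cx"] == pytest.approx(0.5)
        assert proj.breed_summary.loc["S", "cy"] == pytest.approx(0.5)
        assert proj.breed_summary.loc["S", "radius"] == pytest.approx(0.0)

    def test_singleton_radius_zero(self):
        breeds = BreedAssignment({"i0": "S"}, {"S": "G"})
        proj = breed_dispersion(np.array([[2.0, 3.0]]), ["i0"], breeds)
        assert proj.breed_summary.loc["S", "radius"] == 0.0


class TestDestOnSimulation:
    def test_dest_matrix_symmetric_zero_diagonal(self, small_blocks):
        _, _, t = small_blocks
        m = dest_matrix(t)
        assert np.allclose(m, m.T)
        assert np.allclose(np.diag(m), 0.0)
        assert ((m.to_numpy() >= 0) & (m.to_numpy() <= 1)).all()
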