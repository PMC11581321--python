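"""Relationship matrices: A, A^-1, A22, genomic G, single-step H^-1."""

import numpy as np
import pytest

from canineqg import relmat, simpop
from canineqg.errors import IntegrityError, NumericalError
from canineqg.pedigree import Pedigree

from conftest import random_genotypes, random_pedigree


def kinship_oracle(pedigree: Pedigree) -> np.ndarray:
    """Brute-force A matrix straight from the recursive definition."""
    sire, dam = pedigree.parent_indices()
    n = len(pedigree)
    memo = {}

    def a(i, j):
        if i > j:
            i, j = j, i
        if (i, j) in memo:
            return memo[(i, j)]
        if i == j:
            s, d = sire[i], dam[i]
            val = 1.0 + (0.5 * a(s, d) if s >= 0 and d >= 0 else 0.0)
        else:
            # j is the younger animal (larger topological index)
            s, d = sire[j], dam[j]
            val = 0.0
            if s >= 0:
                val += 0.5 * a(i, s)
            if d >= 0:
                val += 0.5 * a(i, d)
        memo[(i, j)] = val
        return val

    return np.array([[a(i, j) for j in range(n)] for i in range(n)])


@pytest.fixture
def fullsib_incest_pedigree():
    """Parents -> full sibs -> inbred offspring of the full sibs."""
    return Pedigree.from_tuples(
        [
            ("p1", None, None, "M"),
            ("p2", None, None, "F"),
            ("c1", "p1", "p2", "M"),
            ("c2", "p1", "p2", "F"),
            ("inb", "c1", "c2", "M"),
        ],
        sort=False,
    )


class TestBuildA:
    def test_parent_offspring_textbook(self):
        ped = Pedigree.from_tuples(
            [("s", None, None, "M"), ("d", None, None, "F"),
             ("k", "s", "d", "M")], sort=False,
        )
        A = relmat.build_A(ped).values
        assert A[0, 2] == 0.5 and A[1, 2] == 0.5 and A[2, 2] == 1.0

    def test_full_sib_incest(self, fullsib_incest_pedigree):
        A = relmat.build_A(fullsib_incest_pedigree)
        i = A.ids.index
        assert A.values[i("c1"), i("c2")] == 0.5
        assert A.values[i("inb"), i("inb")] == 1.25  # F = 0.25
        assert A.metadata["inbreeding"][i("inb")] == 0.25

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_recursive_oracle(self, seed):
        ped = random_pedigree(np.random.default_rng(seed), 50)
        A = relmat.build_A(ped).values
        np.testing.assert_allclose(A, kinship_oracle(ped), atol=1e-12)

    def test_diagonal_and_psd(self):
        ped = random_pedigree(np.random.default_rng(77), 80)
        A = relmat.build_A(ped).values
        assert (np.diag(A) >= 1.0 - 1e-12).all()
        assert np.linalg.eigvalsh(A)[0] >= -1e-8


class TestBuildAInverse:
    def test_founders_only_identity(self):
        ped = Pedigree.from_tuples(
            [(f"f{i}", None, None, "M") for i in range(4)], sort=False
        )
        np.testing.assert_allclose(
            relmat.build_A_inverse(ped).values, np.eye(4), atol=1e-12
        )

    @pytest.mark.parametrize("seed", [3, 14, 159])
    def test_product_with_A_is_identity(self, seed):
        ped = random_pedigree(np.random.default_rng(seed), 50)
        A = relmat.build_A(ped).values
        Ainv = relmat.build_A_inverse(ped).values
        np.testing.assert_allclose(Ainv @ A, np.eye(50), atol=1e-8)

    def test_matches_dense_inversion(self):
        ped = random_pedigree(np.random.default_rng(21), 40)
        A = relmat.build_A(ped).values
        np.testing.assert_allclose(
            relmat.build_A_inverse(ped).values, np.linalg.inv(A), atol=1e-8
        )


class TestExtractA22:
    def test_all_ids_gives_A(self, fullsib_incest_pedigree):
        A = relmat.build_A(fullsib_incest_pedigree)
        A22 = relmat.extract_A22(A, A.ids)
        np.testing.assert_array_equal(A22.values, A.values)

    def test_singleton(self, fullsib_incest_pedigree):
        A = relmat.build_A(fullsib_incest_pedigree)
        A22 = relmat.extract_A22(A, ["inb"])
        assert A22.values.shape == (1, 1) and A22.values[0, 0] == 1.25

    def test_permutation_contract(self, fullsib_incest_pedigree):
        A = relmat.build_A(fullsib_incest_pedigree)
        fwd = relmat.extract_A22(A, ["c1", "c2", "inb"]).values
        rev = relmat.extract_A22(A, ["inb", "c2", "c1"]).values
        np.testing.assert_array_equal(rev, fwd[::-1, ::-1])

    def test_unknown_id_rejected(self, fullsib_incest_pedigree):
        A = relmat.build_A(fullsib_incest_pedigree)
        with pytest.raises(IntegrityError):
            relmat.extract_A22(A, ["nobody"])


class TestGenomicMatrices:
    def test_identical_rows_equal_entries(self):
        gm = random_genotypes(np.random.default_rng(1), 6, 40)
        gm.dosage[3] = gm.dosage[0]
        gm = gm.subset(snps=gm.dosage.std(axis=0) > 0)
        G = relmat.build_G_vanraden(gm).values
        assert G[0, 3] == pytest.approx(G[0, 0])

    def test_denominator_at_freq_half(self):
        rng = np.random.default_rng(2)
        m = 60
        gm = random_genotypes(rng, 8, m)
        # force every SNP to frequency exactly 0.5 over 8 animals
        for j in range(m):
            col = np.array([0, 0, 1, 1, 1, 1, 2, 2], dtype=float)
            rng.shuffle(col)
            gm.dosage[:, j] = col
        G = relmat.build_G_vanraden(gm)
        assert G.metadata["denominator"] == pytest.approx(m / 2)

    def test_mean_diagonal_near_one_unrelated(self):
        gm = random_genotypes(np.random.default_rng(3), 500, 2000)
        G = relmat.build_G_vanraden(gm).values
        assert 0.95 <= np.diag(G).mean() <= 1.05

    def test_centered_rows_sum_to_zero(self):
        gm = random_genotypes(np.random.default_rng(4), 10, 30)
        G = relmat.build_G_centered(gm).values
        assert np.max(np.abs(G @ np.ones(10))) < 1e-10

    def test_centered_single_snp_hand_value(self):
        gm = random_genotypes(np.random.default_rng(5), 3, 1)
        gm.dosage[:, 0] = [0.0, 1.0, 2.0]
        c = np.array([-1.0, 0.0, 1.0])
        np.testing.assert_allclose(
            relmat.build_G_centered(gm).values, np.outer(c, c), atol=1e-12
        )

    def test_centered_vs_vanraden_scalar_identity(self):
        gm = random_genotypes(np.random.default_rng(6), 12, 50)
        Gv = relmat.build_G_vanraden(gm)
        Gc = relmat.build_G_centered(gm).values
        p = Gv.metadata["allele_freq"]
        scale = (2.0 * np.sum(p * (1 - p))) / gm.n_snps
        np.testing.assert_allclose(Gc, Gv.values * scale, atol=1e-10)

    def test_monomorphic_rejected(self):
        gm = random_genotypes(np.random.default_rng(7), 5, 3)
        gm.dosage[:, 1] = 0.0
        with pytest.raises(NumericalError):
            relmat.build_G_vanraden(gm)

    def test_missing_rejected(self):
        gm = random_genotypes(np.random.default_rng(8), 5, 3, missing_rate=0.2)
        with pytest.raises(NumericalError):
            relmat.build_G_vanraden(gm)


class TestHInverse:
    def _parts(self, seed=30, n=30, n_geno=10):
        ped = random_pedigree(np.random.default_rng(seed), n)
        A = relmat.build_A(ped)
        Ainv = relmat.build_A_inverse(ped)
        geno_ids = ped.ids[-n_geno:]
        A22 = relmat.extract_A22(A, geno_ids)
        return ped, A, Ainv, A22, geno_ids

    def test_no_genotyped_animals_reduces_to_A_inverse(self):
        ped, A, Ainv, _, _ = self._parts()
        empty = relmat.RelationshipMatrix("G_VANRADEN", [], np.zeros((0, 0)))
        empty22 = relmat.RelationshipMatrix("A22", [], np.zeros((0, 0)))
        Hinv = relmat.build_H_inverse(Ainv, empty22, empty)
        np.testing.assert_allclose(Hinv.values, Ainv.values, atol=1e-12)

    def test_G_equal_A22_reduces_to_A_inverse(self):
        ped, A, Ainv, A22, geno_ids = self._parts()
        G = relmat.RelationshipMatrix("G_VANRADEN", A22.ids, A22.values.copy())
        Hinv = relmat.build_H_inverse(Ainv, A22, G)
        np.testing.assert_allclose(Hinv.values, Ainv.values, atol=1e-5)

    def test_matches_dense_joint_construction(self):
        # build H explicitly from A blocks and the blended G, invert, compare
        ped, A, Ainv, A22, geno_ids = self._parts(seed=31)
        gm = random_genotypes(np.random.default_rng(32), len(geno_ids), 200)
        gm.animal_ids = list(geno_ids)
        gm = gm.subset(snps=gm.dosage.std(axis=0) > 0)
        G = relmat.build_G_vanraden(gm)
        Hinv = relmat.build_H_inverse(Ainv, A22, G)

        n = len(ped)
        gidx = [ped.ids.index(a) for a in geno_ids]
        nidx = [i for i in range(n) if i not in gidx]
        Av = A.values
        A11 = Av[np.ix_(nidx, nidx)]
        A12 = Av[np.ix_(nidx, gidx)]
        A22v = Av[np.ix_(gidx, gidx)]
        Gb = 0.95 * (G.values + relmat.G_RIDGE * np.eye(len(gidx))) + 0.05 * A22v
        A22i = np.linalg.inv(A22v)
        H = np.zeros((n, n))
        H[np.ix_(nidx, nidx)] = A11 + A12 @ A22i @ (Gb - A22v) @ A22i @ A12.T
        H[np.ix_(nidx, gidx)] = A12 @ A22i @ Gb
        H[np.ix_(gidx, nidx)] = H[np.ix_(nidx, gidx)].T
        H[np.ix_(gidx, gidx)] = Gb
        np.testing.assert_allclose(np.linalg.inv(H), Hinv.values, atol=1e-6)

    def test_bad_blend_weights_rejected(self):
        ped, A, Ainv, A22, geno_ids = self._parts()
        G = relmat.RelationshipMatrix("G_VANRADEN", A22.ids, A22.values.copy())
        with pytest.raises(NumericalError):
            relmat.build_H_inverse(Ainv, A22, G, tau_g=0.9, tau_a=0.05)


class TestConsistencyWithSimulator:
    def test_G_approaches_A22_with_snp_count(self):
        # mean |G - A22| over genotyped pairs shrinks as markers grow
        devs = {}
        for m_per in (50, 250):
            cfg = simpop.SimConfig(
                seed=88, n_founders=30, n_generations=3,
                matings_per_generation=15, n_chromosomes=8,
                snps_per_chromosome=m_per, genotyped_fraction=0.5,
                missing_rate=0.0,
            )
            ped = simpop.simulate_pedigree(cfg)
            gm = simpop.simulate_genotypes(ped, cfg)
            poly = gm.dosage.std(axis=0) > 0
            G = relmat.build_G_vanraden(gm.subset(snps=poly))
            A22 = relmat.extract_A22(relmat.build_A(ped), G.ids)
            devs[m_per] = np.abs(G.values - A22.values).mean()
        assert devs[250] < devs[50]


class TestPedigreeSummary:
    def test_fullsib_family_counting(self):
        ped = Pedigree.from_tuples(
            [("s", None, None, "M"), ("d", None, None, "F")]
            + [(f"k{i}", "s", "d", "M") for i in range(3)],
            sort=False,
        )
        summ = relmat.pedigree_summary(ped, relmat.build_A(ped))
        assert summ.n_fullsib_families == 1
        assert summ.mean_fullsib_family_size == 3.0
        assert summ.n_sires == 1 and summ.n_dams == 1

    def test_founders_only_no_inbreeding(self):
        ped = Pedigree.from_tuples(
            [(f"f{i}", None, None, "F") for i in range(5)], sort=False
        )
        summ = relmat.pedigree_summary(ped, relmat.build_A(ped))
        assert summ.n_inbred == 0 and summ.max_F == 0.0

    def test_fullsib_incest_max_F(self, fullsib_incest_pedigree):
        summ = relmat.pedigree_summary(
            fullsib_incest_pedigree, relmat.build_A(fullsib_incest_pedigree)
        )
        assert summ.max_F == 0.25
        assert summ.mean_F_inbred >= summ.mean_F_all
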