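import numpy as np
import pytest

from rcgs.genotypes import MarkerMatrix
from rcgs.kinship import (
    Pedigree,
    PedigreeError,
    cop_matrix,
    distance_summary,
    gaussian_kernels,
    genomic_matrix,
    nei_distance,
    nei_distance_matrix,
    pca_scores,
    pedigree_matrix,
    read_pedigree,
    write_pedigree,
)


def _mm(dosages):
    d = np.asarray(dosages, dtype=float)
    return MarkerMatrix(
        [f"L{i}" for i in range(d.shape[0])],
        [f"m{j}" for j in range(d.shape[1])],
        d,
    )


class TestGenomicMatrix:
    def test_hand_computed_mmt_over_p(self):
        mm = _mm([[0, 1, 2], [1, 2, 0], [2, 0, 1], [1, 1, 1]])
        X = mm.dosages
        M = (X - X.mean(axis=0)) / X.std(axis=0)
        expected = M @ M.T / 3
        G = genomic_matrix(mm)
        assert np.allclose(G.values, expected, atol=1e-12)

    def test_identical_genotypes_have_identical_relationships(self):
        mm = _mm([[0, 1, 2, 1], [0, 1, 2, 1], [2, 1, 0, 0], [1, 0, 1, 2]])
        G = genomic_matrix(mm)
        assert np.allclose(G.values[0], G.values[1])
        assert G.values[0, 1] == pytest.approx(G.values[0, 0])

    def test_mean_diagonal_near_one_in_random_population(self):
        rng = np.random.default_rng(0)
        f = rng.uniform(0.1, 0.9, size=5000)
        dosages = rng.binomial(2, f, size=(500, 5000)).astype(float)
        G = genomic_matrix(_mm(dosages))
        assert 0.95 < G.values.diagonal().mean() < 1.05
        G.check_psd()

    def test_zero_variance_column_errors_toward_qc(self):
        mm = _mm([[0, 1], [0, 2], [0, 0]])
        with pytest.raises(ValueError, match="monomorphic"):
            genomic_matrix(mm)


def _gene_drop_oracle(ped: Pedigree, n_reps: int, seed: int):
    """Monte-Carlo IBD: drop unique founder alleles through the pedigree
    (including recorded extra selfing generations) and estimate the
    numerator relationship matrix. Returns (A_hat, SE)."""
    rng = np.random.default_rng(seed)
    order = ped.topological_records()
    alleles = {}
    next_allele = 0
    for rec in order:
        if rec.parent1 is None and rec.parent2 is None:
            geno = np.empty((n_reps, 2), dtype=np.int64)
            geno[:, 0] = next_allele
            geno[:, 1] = next_allele + 1
            next_allele += 2
        else:
            g1 = alleles[rec.parent1] if rec.parent1 else None
            g2 = alleles[rec.parent2] if rec.parent2 else None
            geno = np.empty((n_reps, 2), dtype=np.int64)
            for k, g in enumerate((g1, g2)):
                if g is None:
                    geno[:, k] = next_allele
                    next_allele += 1
                else:
                    pick = rng.integers(2, size=n_reps)
                    geno[:, k] = g[np.arange(n_reps), pick]
        for _ in range(rec.selfing_generations):
            pick = rng.integers(2, size=(n_reps, 2))
            geno = geno[np.arange(n_reps)[:, None], pick]
        alleles[rec.id] = geno
    ids = ped.ids
    n = len(ids)
    A_hat = np.zeros((n, n))
    SE = np.zeros((n, n))
    for i in range(n):
        gi = alleles[ids[i]]
        ibd_self = (gi[:, 0] == gi[:, 1]).astype(float)
        A_hat[i, i] = 1.0 + ibd_self.mean()
        SE[i, i] = ibd_self.std(ddof=1) / np.sqrt(n_reps)
        for j in range(i + 1, n):
            gj = alleles[ids[j]]
            # kinship averaged over all four allele pairings per replicate
            pairs = np.zeros(n_reps)
            for a in range(2):
                for b in range(2):
                    pairs += (gi[:, a] == gj[:, b]).astype(float)
            f_hat = pairs / 4.0
            A_hat[i, j] = A_hat[j, i] = 2.0 * f_hat.mean()
            SE[i, j] = SE[j, i] = 2.0 * f_hat.std(ddof=1) / np.sqrt(n_reps)
    return A_hat, SE


def _random_pedigree(n: int, seed: int) -> Pedigree:
    rng = np.random.default_rng(seed)
    tuples = []
    for k in range(n):
        if k < 6:
            tuples.append((f"I{k}", 0, 0, 0))
        else:
            p1, p2 = rng.choice(k, size=2, replace=False)
            g = int(rng.integers(0, 3))
            tuples.append((f"I{k}", f"I{p1}", f"I{p2}", g))
    return Pedigree.from_tuples(tuples)


class TestPedigreeMatrix:
    def test_full_sibs_of_unrelated_parents(self):
        ped = Pedigree.from_tuples(
            [("a", 0, 0), ("b", 0, 0), ("s1", "a", "b"), ("s2", "a", "b")]
        )
        A = pedigree_matrix(ped)
        df = A.to_frame()
        assert df.loc["s1", "s2"] == pytest.approx(0.5)
        assert df.loc["s1", "s1"] == pytest.approx(1.0)
        assert cop_matrix(A).to_frame().loc["s1", "s2"] == pytest.approx(0.25)

    def test_many_selfing_generations_drive_diagonal_to_two(self):
        ped = Pedigree.from_tuples(
            [("a", 0, 0), ("b", 0, 0), ("f1", "a", "b", 30)]
        )
        A = pedigree_matrix(ped)
        assert A.to_frame().loc["f1", "f1"] == pytest.approx(2.0, abs=1e-8)

    def test_cycle_detected(self):
        with pytest.raises(PedigreeError, match="cycle"):
            Pedigree.from_tuples([("a", "b", 0), ("b", "a", 0)])

    def test_matches_gene_dropping_on_random_pedigree(self):
        ped = _random_pedigree(30, seed=13)
        A = pedigree_matrix(ped).values
        A_hat, SE = _gene_drop_oracle(ped, n_reps=100_000, seed=99)
        iu = np.triu_indices(len(ped))
        z = np.abs(A - A_hat)[iu] / np.maximum(SE[iu], 1e-12)
        deterministic = SE[iu] == 0
        assert (np.abs(A - A_hat)[iu][deterministic] < 1e-12).all()
        z = z[~deterministic]
        # entrywise 3*SE band; with ~400 simultaneous entries ~1 excursion
        # is expected by chance even for an exact A, so allow the binomial
        # 99.9% count and cap the worst excursion
        n_outside = int((z > 3.0).sum())
        assert n_outside <= 5
        assert z.max() < 5.0

    def test_round_trip_pedigree_file(self, tmp_path):
        ped = _random_pedigree(12, seed=3)
        path = tmp_path / "ped.txt"
        write_pedigree(ped, path)
        back = read_pedigree(path)
        assert np.allclose(pedigree_matrix(back).values, pedigree_matrix(ped).values)


class TestDistanceAndKernels:
    def test_identical_rows_have_zero_distance(self):
        mm = _mm([[0, 1, 2], [0, 1, 2], [2, 0, 1]])
        ds = distance_summary(mm)
        assert ds.d2[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_median_from_hand_coordinates(self):
        mm = _mm([[0, 0], [2, 0], [0, 2], [2, 2]])
        ds = distance_summary(mm)
        M = (mm.dosages - 1.0) / 1.0  # columns have mean 1, sd 1 here
        d2 = ((M[:, None, :] - M[None, :, :]) ** 2).sum(-1)
        expected_m = np.median(d2[np.triu_indices(4, 1)])
        assert ds.m == pytest.approx(expected_m)

    def test_median_invariant_to_row_permutation(self, small_g):
        mm, _ = small_g
        ds = distance_summary(mm)
        perm = np.random.default_rng(1).permutation(mm.n_individuals)
        mm_perm = mm.subset_individuals(mm.individual_ids[perm])
        assert distance_summary(mm_perm).m == pytest.approx(ds.m)

    def test_kernel_entry_at_median_distance(self, small_g):
        mm, _ = small_g
        ds = distance_summary(mm)
        K1, K2, K3 = gaussian_kernels(ds)
        i, j = np.unravel_index(np.argmin(np.abs(ds.d2 - ds.m)), ds.d2.shape)
        # c = 1 kernel: entry exp(-d2/m); at d2 == m exactly, exp(-1)
        assert K2.values[i, j] == pytest.approx(np.exp(-ds.d2[i, j] / ds.m), abs=1e-12)
        exact = gaussian_kernels(
            type(ds)(np.array(["a", "b"], dtype=object),
                     np.array([[0.0, ds.m], [ds.m, 0.0]]), ds.m)
        )[1]
        assert exact.values[0, 1] == pytest.approx(np.exp(-1.0), abs=1e-12)

    def test_kernel_diagonals_exactly_one_and_monotone_in_bandwidth(self, small_g):
        mm, _ = small_g
        K1, K2, K3 = gaussian_kernels(distance_summary(mm))
        for K in (K1, K2, K3):
            assert (K.values.diagonal() == 1.0).all()
            assert ((K.values > 0) & (K.values <= 1)).all()
            K.check_psd()
        off = ~np.eye(K1.n, dtype=bool)
        assert (K1.values[off] >= K2.values[off]).all()
        assert (K2.values[off] >= K3.values[off]).all()

    def test_kernel_limits_identity_and_all_ones(self, small_g):
        mm, _ = small_g
        ds = distance_summary(mm)
        (K_tiny,) = gaussian_kernels(ds, multipliers=(1e-9,))
        assert np.allclose(K_tiny.values, 1.0, atol=1e-6)
        (K_huge,) = gaussian_kernels(ds, multipliers=(1e9,))
        assert np.allclose(K_huge.values, np.eye(K_huge.n), atol=1e-6)


class TestNeiDistance:
    def test_identical_profiles_give_zero(self):
        x = np.array([0.2, 0.7, 0.5])
        assert nei_distance(x, x) == pytest.approx(0.0)

    def test_disjoint_fixation_gives_infinity(self):
        assert nei_distance([1.0, 0.0], [0.0, 1.0]) == np.inf

    def test_hand_value_ln_sqrt_two(self):
        d = nei_distance([0.5, 0.5], [1.0, 0.0])
        assert d == pytest.approx(np.log(np.sqrt(2.0)))

    def test_symmetry_on_random_profiles(self):
        rng = np.random.default_rng(2)
        x, y = rng.random(50), rng.random(50)
        assert nei_distance(x, y) == pytest.approx(nei_distance(y, x))

    def test_matrix_variant_matches_pairwise_calls(self):
        rng = np.random.default_rng(4)
        F = rng.random((4, 30))
        D = nei_distance_matrix(F, ids=list("abcd"))
        assert D.loc["a", "c"] == pytest.approx(nei_distance(F[0], F[2]))
        assert (np.diag(D.values) == 0).all()


class TestPCA:
    def test_scores_shape_variance_and_sign_convention(self, small_g):
        mm, _ = small_g
        scores, explained = pca_scores(mm, n_components=3)
        assert scores.shape == (mm.n_individuals, 3)
        assert np.all(np.diff(explained) <= 1e-12) and explained.sum() <= 1.0 + 1e-9
        # two bi-parental families should separate on PC1
        fam = np.array([i.split("_")[0] for i in mm.individual_ids])
        pc1 = scores["PC1"].to_numpy()
        assert abs(pc1[fam == "F1"].mean() - pc1[fam == "F2"].mean()) > pc1.std()
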