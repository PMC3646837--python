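import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sgstools.sgs_core import (
    DistanceClassSpec,
    assign_distance_classes,
    autocorrelation,
    bootstrap_errorbars,
    gower_center,
    omega_multiclass,
    pairwise_genetic_distance,
    permutation_envelope,
    spatial_correlogram,
)

from conftest import make_dataset, random_dataset


class TestGeneticDistance:
    # the five codominant genotype-pair configurations and their squared
    # distances under half the squared dosage-vector difference
    @pytest.mark.parametrize(
        "g1,g2,expected",
        [
            ("AA", "AA", 0.0),
            ("AB", "AB", 0.0),
            ("AA", "AB", 1.0),
            ("AB", "AC", 1.0),
            ("AB", "CD", 2.0),
            ("AA", "BC", 3.0),
            ("AA", "BB", 4.0),
        ],
    )
    def test_single_locus_table(self, g1, g2, expected):
        ds = make_dataset([g1, g2], allele_codes=(1, 2, 3, 4))
        D = pairwise_genetic_distance(ds)
        assert D.d2[0, 1] == pytest.approx(expected)

    def test_table_matches_dosage_oracle_exhaustively(self):
        # every unordered genotype pair over a 3-allele locus
        genotypes = ["AA", "BB", "CC", "AB", "AC", "BC"]
        ds = make_dataset(genotypes, allele_codes=(1, 2, 3))
        D = pairwise_genetic_distance(ds)

        def dosage(g):
            v = np.zeros(3)
            for ch in g:
                v[ord(ch) - ord("A")] += 1
            return v

        for i, gi in enumerate(genotypes):
            for j, gj in enumerate(genotypes):
                expected = 0.5 * ((dosage(gi) - dosage(gj)) ** 2).sum()
                assert D.d2[i, j] == pytest.approx(expected)

    def test_missing_rescale_rule(self):
        # two loci; L2 missing in one individual; complete-locus d2 = 4
        ds = make_dataset(["AA AA", "BB .."], allele_codes=(1, 2))
        D = pairwise_genetic_distance(ds)
        assert D.d2[0, 1] == pytest.approx(8.0)
        assert D.n_complete[0, 1] == 1

    def test_pair_with_no_complete_locus_is_an_error(self):
        ds = make_dataset(["AA ..", ".. AA"])
        with pytest.raises(ValueError, match="i0.*i1|i1.*i0"):
            pairwise_genetic_distance(ds)


class TestGowerCenter:
    def test_zero_matrix_stays_zero(self):
        from sgstools.sgs_core import SquaredDistanceMatrix

        C = gower_center(np.zeros((4, 4)))
        assert np.allclose(C, 0)

    def test_rows_sum_to_zero(self, rng):
        ds = random_dataset(rng, n=9, L=4)
        C = gower_center(pairwise_genetic_distance(ds))
        scale = np.abs(C).max()
        assert np.abs(C.sum(axis=1)).max() <= 1e-9 * max(scale, 1.0)

    def test_matches_bruteforce_double_centering(self, rng):
        ds = random_dataset(rng, n=6, L=2)
        d2 = pairwise_genetic_distance(ds).d2
        n = 6
        brute = np.empty((n, n))
        for i in range(n):
            for j in range(n):
                brute[i, j] = -0.5 * (
                    d2[i, j] - d2[i, :].mean() - d2[j, :].mean() + d2.mean()
                )
        assert np.allclose(gower_center(d2), brute, atol=1e-12)


class TestDistanceClasses:
    def test_boundary_conventions(self):
        spec = DistanceClassSpec((50.0, 100.0))
        x = np.array([0.0, 0.0, 50.0, 50.0001])
        y = np.zeros(4)
        pc = assign_distance_classes(x, y, spec)
        lookup = {(i, j): c for i, j, c in zip(pc.ii, pc.jj, pc.cls)}
        assert lookup[(0, 1)] == 0      # co-located pair -> class 1
        assert lookup[(0, 2)] == 0      # exactly on the edge -> lower class
        assert lookup[(0, 3)] == 1      # just past the edge -> next class

    def test_pairs_beyond_last_edge_dropped(self):
        spec = DistanceClassSpec((50.0,))
        pc = assign_distance_classes(np.array([0.0, 200.0]), np.zeros(2), spec)
        assert pc.ii.size == 0

    def test_grid_counts_match_enumeration(self):
        # 5 points spaced 60 m on a line; enumerate all 10 pairs by hand
        x = np.arange(5) * 60.0
        spec = DistanceClassSpec((50.0, 100.0, 150.0, 200.0, 250.0))
        pc = assign_distance_classes(x, np.zeros(5), spec)
        counts = pc.n_pairs()
        expected = np.zeros(5, dtype=int)
        for i in range(5):
            for j in range(i + 1, 5):
                d = abs(x[i] - x[j])
                k = int(np.ceil(d / 50.0)) - 1
                expected[k] += 1
        assert np.array_equal(counts, expected)


class TestAutocorrelation:
    @pytest.mark.parametrize("N", range(3, 11))
    def test_single_class_all_pairs_identity(self, N):
        rng = np.random.default_rng(N)
        ds = random_dataset(rng, n=N, L=3, span=10)
        spec = DistanceClassSpec((1000.0,))
        C = gower_center(pairwise_genetic_distance(ds))
        pc = assign_distance_classes(ds.x, ds.y, spec)
        r = autocorrelation(C, pc)
        assert abs(r[0] + 1.0 / (N - 1)) <= 1e-9

    def test_two_individuals_r_is_minus_one(self):
        ds = make_dataset(["AA", "AB"], x=[0, 1], y=[0, 0])
        spec = DistanceClassSpec((10.0,))
        C = gower_center(pairwise_genetic_distance(ds))
        r = autocorrelation(C, assign_distance_classes(ds.x, ds.y, spec))
        assert r[0] == pytest.approx(-1.0)

    def test_clustered_clones_give_positive_short_range_r(self, rng):
        # identical genotypes co-located, different genotypes far away
        genos = ["AA BB", "AA BB", "CC DD", "CC DD", "AD AC", "AD AC"]
        x = [0, 1, 100, 101, 200, 201]
        ds = make_dataset(genos, x=x, y=np.zeros(6), allele_codes=(1, 2, 3, 4))
        spec = DistanceClassSpec((10.0, 300.0))
        C = gower_center(pairwise_genetic_distance(ds))
        r = autocorrelation(C, assign_distance_classes(ds.x, ds.y, spec))
        assert r[0] > 0 and r[0] > r[1]

    def test_no_genetic_variance_is_an_error(self):
        ds = make_dataset(["AA", "AA", "AA"], x=[0, 1, 2], y=[0, 0, 0],
                          allele_codes=(1, 2))
        C = gower_center(pairwise_genetic_distance(ds))
        pc = assign_distance_classes(ds.x, ds.y, DistanceClassSpec((10.0,)))
        with pytest.raises(ValueError, match="variance"):
            autocorrelation(C, pc)

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(st.integers(0, 2**16), st.permutations([0, 1, 2]))
    def test_invariant_to_allele_relabeling_and_locus_order(self, seed, locus_order):
        rng = np.random.default_rng(seed)
        ds = random_dataset(rng, n=10, L=3, n_alleles=4, span=150)
        spec = DistanceClassSpec((50.0, 100.0, 200.0))
        C = gower_center(pairwise_genetic_distance(ds))
        pc = assign_distance_classes(ds.x, ds.y, spec)
        r_base = autocorrelation(C, pc)

        relabel = {1: 7, 2: 3, 3: 9, 4: 5}
        ds2 = ds.subset(np.arange(10))
        calls = np.vectorize(lambda a: relabel.get(a, 0))(ds2.calls)
        from sgstools.io_tables import Locus

        ds2.calls = calls[:, locus_order, :]
        ds2.loci = [Locus(f"L{k}", (3, 5, 7, 9)) for k in range(3)]
        C2 = gower_center(pairwise_genetic_distance(ds2))
        r_perm = autocorrelation(C2, pc)
        np.testing.assert_allclose(r_perm, r_base, atol=1e-10)


class TestPermutation:
    def test_fixed_seed_is_reproducible(self, rng):
        ds = random_dataset(rng, n=20, L=3, span=200)
        spec = DistanceClassSpec((50.0, 100.0, 200.0))
        a = permutation_envelope(ds, spec, n_perm=99, seed=5)
        b = permutation_envelope(ds, spec, n_perm=99, seed=5)
        assert np.array_equal(a.p, b.p) and np.array_equal(a.lo, b.lo)
        c = permutation_envelope(ds, spec, n_perm=99, seed=6)
        assert not np.array_equal(a.null_r, c.null_r)

    def test_too_few_individuals_rejected(self):
        ds = make_dataset(["AA", "AB"], x=[0, 1], y=[0, 0])
        with pytest.raises(ValueError, match="at least 3"):
            permutation_envelope(ds, DistanceClassSpec((10.0,)), n_perm=9)

    def test_permuting_genotypes_equals_permuting_locations(self, rng):
        # applying a permutation to genotype rows or its inverse to the
        # coordinates must give the same correlogram
        ds = random_dataset(rng, n=12, L=3, span=150)
        spec = DistanceClassSpec((50.0, 100.0, 200.0))
        perm = rng.permutation(12)
        inv = np.argsort(perm)

        ds_g = ds.subset(np.arange(12))
        ds_g.calls = ds.calls[perm]
        C_g = gower_center(pairwise_genetic_distance(ds_g))
        r_g = autocorrelation(C_g, assign_distance_classes(ds.x, ds.y, spec))

        ds_l = ds.subset(np.arange(12))
        ds_l.x, ds_l.y = ds.x[inv], ds.y[inv]
        C_l = gower_center(pairwise_genetic_distance(ds_l))
        r_l = autocorrelation(C_l, assign_distance_classes(ds_l.x, ds_l.y, spec))
        np.testing.assert_allclose(r_g, r_l, atol=1e-12)

    def test_strong_sib_clustering_exceeds_envelope(self):
        from sgstools.simulate import SimulationConfig, simulate_population

        cfg = SimulationConfig(
            n_plots=2, n_adults=4, sigma=3.0,
            cohort_sizes={"FIRST_YEAR": 60, "YOUNG": 0, "SAPLING": 0},
            n_adults_sampled=0,
        )
        ds, _ = simulate_population(cfg, seed=7)
        spec = DistanceClassSpec.regular(50.0, 250.0)
        env = permutation_envelope(ds, spec, n_perm=199, seed=1)
        C, pc = gower_center(pairwise_genetic_distance(ds)), None
        from sgstools.sgs_core import _prepare

        C, pc = _prepare(ds, spec)
        r = autocorrelation(C, pc)
        assert r[0] > env.hi[0]


class TestBootstrap:
    def test_single_pair_class_is_blank(self):
        ds = make_dataset(
            ["AA", "AB", "BB"], x=[0.0, 1.0, 200.0], y=[0, 0, 0],
        )
        spec = DistanceClassSpec((10.0, 150.0, 300.0))
        lo, hi = bootstrap_errorbars(ds, spec, n_boot=99, seed=0)
        assert np.isnan(lo[0]) and np.isnan(hi[0])  # one pair only

    def test_reproducible_and_interval_ordered(self, rng):
        ds = random_dataset(rng, n=25, L=3, span=200)
        spec = DistanceClassSpec((100.0, 300.0))
        lo1, hi1 = bootstrap_errorbars(ds, spec, n_boot=199, seed=3)
        lo2, hi2 = bootstrap_errorbars(ds, spec, n_boot=199, seed=3)
        assert np.array_equal(lo1, lo2, equal_nan=True)
        assert (lo1 <= hi1)[~np.isnan(lo1)].all()

    def test_interval_width_shrinks_with_pair_count(self):
        from sgstools.simulate import SimulationConfig, simulate_population

        widths = []
        for n_off in (50, 800):
            cfg = SimulationConfig(
                n_plots=1, n_adults=30, sigma=np.inf,
                cohort_sizes={"FIRST_YEAR": n_off, "YOUNG": 0, "SAPLING": 0},
                n_adults_sampled=0,
            )
            ds, _ = simulate_population(cfg, seed=11)
            spec = DistanceClassSpec((260.0,))  # one class holds every pair
            lo, hi = bootstrap_errorbars(ds, spec, n_boot=199, seed=2)
            widths.append(hi[0] - lo[0])
        # pair count grows ~256x, so width should drop roughly 16x; allow slack
        assert widths[1] < widths[0] / 4


class TestOmega:
    def test_all_ones_gives_zero(self):
        omega, p = omega_multiclass(np.array([1.0, 1.0, 1.0]))
        assert omega == pytest.approx(0.0)

    def test_closed_form(self):
        omega, _ = omega_multiclass(np.array([0.05, 0.05]))
        assert omega == pytest.approx(-2 * 2 * np.log(0.05), rel=1e-12)
        assert omega == pytest.approx(11.98, abs=0.01)

    def test_zero_p_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            omega_multiclass(np.array([0.0, 0.5]))

    def test_chi2_fallback_uses_2k_dof(self):
        from scipy import stats

        p = np.array([0.2, 0.4, np.nan])
        omega, p_omega = omega_multiclass(p)
        assert p_omega == pytest.approx(stats.chi2.sf(omega, df=4))


def test_full_correlogram_determinism(rng):
    ds = random_dataset(rng, n=30, L=4, span=240)
    spec = DistanceClassSpec.regular(50.0, 250.0)
    a = spatial_correlogram(ds, spec, n_perm=99, n_boot=99, seed=9)
    b = spatial_correlogram(ds, spec, n_perm=99, n_boot=99, seed=9)
    assert a == b
    assert (a.n_pairs >= 0).all()
    defined = ~np.isnan(a.r)
    assert ((a.p[defined] > 0) & (a.p[defined] <= 1)).all()
    assert (a.perm_lo[defined] <= a.perm_hi[defined]).all()
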