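import numpy as np
import pytest

from sgstools.diversity import FrequencyTable, allele_frequencies
from sgstools.io_tables import Locus
from sgstools.kinship import kinship_correlogram, loiselle_fij
from sgstools.sgs_core import DistanceClassSpec
from sgstools.simulate import SimulationConfig, simulate_population

from conftest import make_dataset, random_dataset


def brute_force_fij(ds, ref, i, j):
    """Scalar reimplementation of the Loiselle estimator for one pair."""
    num = corr = den = 0.0
    for l, locus in enumerate(ds.loci):
        gi, gj = ds.calls[i, l], ds.calls[j, l]
        if 0 in gi or 0 in gj or not ref.available(l):
            continue
        p = dict(zip(locus.alleles, ref.freqs[l]))
        n_l = int(ref.n_copies[l])
        for a in locus.alleles:
            qi = (list(gi).count(a)) / 2.0
            qj = (list(gj).count(a)) / 2.0
            pa = p[a]
            num += (qi - pa) * (qj - pa)
            if n_l > 1:
                corr += pa * (1 - pa) / (n_l - 1)
            den += pa * (1 - pa)
    return (num + corr) / den


class TestLoiselleFij:
    def test_identical_homozygotes_with_known_reference(self):
        # one locus, alleles A/B at p = 0.5 each, huge reference sample:
        # numerator (1-.5)^2 + (0-.5)^2 = .5 over denominator .5 -> Fij = 1
        ds = make_dataset(["AA", "AA"], allele_codes=(1, 2))
        ref = FrequencyTable(
            loci=list(ds.loci),
            freqs=[np.array([0.5, 0.5])],
            n_copies=np.array([2_000_000_000]),
        )
        fij = loiselle_fij(ds, ref)
        assert fij[0, 1] == pytest.approx(1.0, abs=1e-8)

    def test_matches_bruteforce_on_random_data(self, rng):
        ds = random_dataset(rng, n=10, L=4, n_alleles=5)
        ds.calls[2, 1] = 0  # sprinkle missingness
        ds.calls[7, 3] = 0
        ref = allele_frequencies(ds)
        fij = loiselle_fij(ds, ref)
        for i in range(10):
            for j in range(i + 1, 10):
                assert fij[i, j] == pytest.approx(
                    brute_force_fij(ds, ref, i, j), abs=1e-10
                )

    def test_sample_reference_mean_matches_bruteforce(self, rng):
        ds = random_dataset(rng, n=12, L=5, n_alleles=6)
        fij = loiselle_fij(ds)  # reference = the sample itself
        vals = fij[np.triu_indices(12, k=1)]
        mean = np.nanmean(vals)
        brute = np.mean(
            [
                brute_force_fij(ds, allele_frequencies(ds), i, j)
                for i in range(12)
                for j in range(i + 1, 12)
            ]
        )
        assert mean == pytest.approx(brute, abs=1e-10)
        # with the finite-sample correction the all-pair mean sits near zero
        assert abs(mean) < 0.05

    def test_symmetry_and_invariances(self, rng):
        ds = random_dataset(rng, n=8, L=3, n_alleles=4)
        fij = loiselle_fij(ds)
        assert np.array_equal(fij, fij.T, equal_nan=True)

        # doubling every locus leaves Fij unchanged
        ds2 = ds.subset(np.arange(8))
        ds2.loci = ds.loci + [Locus(f"{l.name}b", l.alleles) for l in ds.loci]
        ds2.calls = np.concatenate([ds.calls, ds.calls], axis=1)
        fij2 = loiselle_fij(ds2)
        np.testing.assert_allclose(fij2, fij, atol=1e-12)

        # allele relabeling leaves Fij unchanged
        ds3 = ds.subset(np.arange(8))
        relabel = np.vectorize({0: 0, 1: 11, 2: 5, 3: 17, 4: 2}.get)
        ds3.calls = relabel(ds.calls)
        ds3.loci = [Locus(l.name, (2, 5, 11, 17)) for l in ds.loci]
        np.testing.assert_allclose(loiselle_fij(ds3), fij, atol=1e-12)

    def test_monomorphic_reference_rejected(self):
        ds = make_dataset(["AA", "AA", "AA"])
        with pytest.raises(ValueError, match="monomorphic"):
            loiselle_fij(ds)

    def test_parent_offspring_expectation(self):
        # kinship of a parent-offspring pair is 1/4 against the true
        # population frequencies
        cfg = SimulationConfig(
            n_plots=1, n_loci=100, alleles_per_locus=[6] * 100, n_adults=20,
            cohort_sizes={"FIRST_YEAR": 200, "YOUNG": 0, "SAPLING": 0},
            n_adults_sampled=20, sigma=np.inf,
        )
        ds, truth = simulate_population(cfg, seed=5)
        fij = loiselle_fij(ds, truth.reference_table())
        idx = {iid: k for k, iid in enumerate(ds.ids)}
        vals = np.array([fij[idx[o], idx[m]] for o, m in truth.mothers.items()])
        se = vals.std(ddof=1) / np.sqrt(vals.size)
        assert abs(vals.mean() - 0.25) <= 3 * se


class TestKinshipCorrelogram:
    def test_single_pair_within_mode(self):
        ds = make_dataset(
            ["AB", "AA", "BB", "AB"],
            x=[0, 10, 500, 500],
            y=[0, 0, 0, 0],
            meta={"size_class": ["YOUNG", "YOUNG", "ADULT_JUVENILE", "ADULT_JUVENILE"]},
        )
        spec = DistanceClassSpec((50.0,))
        curve = kinship_correlogram(ds, spec, "within:YOUNG")
        fij = loiselle_fij(ds)
        assert curve.n_pairs[0] == 1
        assert curve.mean_fij[0] == pytest.approx(fij[0, 1])
        assert curve.mean_r[0] == pytest.approx(2 * fij[0, 1])

    def test_relatedness_is_twice_kinship_everywhere(self, rng):
        ds = random_dataset(rng, n=20, L=3, span=200)
        ds.meta["size_class"] = "FIRST_YEAR"
        curve = kinship_correlogram(ds, DistanceClassSpec.regular(50, 250), "all")
        ok = ~np.isnan(curve.mean_fij)
        np.testing.assert_array_equal(curve.mean_r[ok], 2 * curve.mean_fij[ok])

    def test_all_mode_is_pair_weighted_combination(self, rng):
        ds = random_dataset(rng, n=16, L=3, span=200)
        classes = ["FIRST_YEAR"] * 8 + ["ADULT_JUVENILE"] * 8
        ds.meta["size_class"] = classes
        spec = DistanceClassSpec.regular(50, 250)
        curve_all = kinship_correlogram(ds, spec, "all")
        parts = [
            kinship_correlogram(ds, spec, "within:FIRST_YEAR"),
            kinship_correlogram(ds, spec, "within:ADULT_JUVENILE"),
            kinship_correlogram(ds, spec, "cross:FIRST_YEAR:ADULT_JUVENILE"),
        ]
        n_total = sum(p.n_pairs for p in parts)
        weighted = sum(
            np.where(p.n_pairs > 0, p.n_pairs * np.nan_to_num(p.mean_fij), 0.0)
            for p in parts
        )
        np.testing.assert_array_equal(curve_all.n_pairs, n_total)
        ok = n_total > 0
        np.testing.assert_allclose(
            curve_all.mean_fij[ok], weighted[ok] / n_total[ok], atol=1e-12
        )

    def test_seed_shadow_scenario_within_exceeds_between(self):
        # tight seed shadows with parents outside the sampled frame: sampled
        # seedling cohorts share parents, so within-cohort kinship at short
        # range exceeds seedling-adult kinship (the sampled adults are not
        # the parents)
        cfg = SimulationConfig(
            n_plots=3, n_adults=8, sigma=5.0,
            cohort_sizes={"FIRST_YEAR": 30, "YOUNG": 0, "SAPLING": 0},
            n_adults_sampled=0,
        )
        ds, truth = simulate_population(cfg, seed=17)
        # graft unrelated "adults" drawn from the founder law at the same
        # locations to stand for non-parental canopy trees
        cfg_adults = SimulationConfig(
            n_plots=3, n_adults=8, n_adults_sampled=8,
            cohort_sizes={"FIRST_YEAR": 0, "YOUNG": 0, "SAPLING": 0},
        )
        adults, _ = simulate_population(cfg_adults, seed=991)
        from sgstools.heterogeneity import pool_datasets

        pooled, _ = pool_datasets(ds, adults)
        spec = DistanceClassSpec((50.0, 250.0))
        within = kinship_correlogram(pooled, spec, "within:FIRST_YEAR")
        between = kinship_correlogram(pooled, spec, "between:FIRST_YEAR")
        assert within.mean_r[0] > between.mean_r[0]

    def test_empty_bin_is_blank_row(self, rng):
        ds = random_dataset(rng, n=8, L=3, span=10)
        ds.meta["size_class"] = "FIRST_YEAR"
        spec = DistanceClassSpec((50.0, 100.0))
        curve = kinship_correlogram(ds, spec, "all")
        assert curve.n_pairs[1] == 0 and np.isnan(curve.mean_fij[1])
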