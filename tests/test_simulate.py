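import dataclasses
import json

import numpy as np
import pytest

from sgstools.sgs_core import DistanceClassSpec, permutation_envelope
from sgstools.simulate import (
    SimulationConfig,
    parameter_recovery_suite,
    simulate_population,
)
from sgstools.io_tables import write_genotype_tables


class TestSimulationConfig:
    def test_defaults_mirror_the_study_design(self):
        cfg = SimulationConfig()
        assert cfg.n_plots == 14
        assert sum(cfg.cohort_sizes["FIRST_YEAR"]) == 142
        assert sum(cfg.cohort_sizes["YOUNG"]) == 130
        assert sum(cfg.cohort_sizes["SAPLING"]) == 57
        assert sum(cfg.n_adults_sampled) == 31
        assert np.mean(cfg.alleles_per_locus) == pytest.approx(7.71, abs=0.005)
        # 6 sandy plots below the 15% clay threshold, 8 clay plots above
        clay = np.asarray(cfg.clay_pct)
        assert (clay < 15).sum() == 6 and (clay > 15).sum() == 8

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(sigma=0.0)
        with pytest.raises(ValueError):
            SimulationConfig(n_loci=2, alleles_per_locus=(4,))
        with pytest.raises(ValueError):
            SimulationConfig(
                n_plots=1, cohort_sizes={"FIRST_YEAR": -1}
            )

    def test_offspring_require_two_breeding_adults(self):
        cfg = SimulationConfig(
            n_plots=1, n_adults=1,
            cohort_sizes={"FIRST_YEAR": 5, "YOUNG": 0, "SAPLING": 0},
        )
        with pytest.raises(ValueError, match="female and one male"):
            simulate_population(cfg, seed=0)

    def test_stratum_overrides_change_plot_params(self):
        cfg = SimulationConfig(
            stratum_overrides={"SANDY": {"sigma": 40.0}},
        )
        sandy_sigma, _ = cfg.plot_params(0)   # clay 2.68 -> SANDY
        clay_sigma, _ = cfg.plot_params(13)   # clay 83.3 -> CLAY
        assert sandy_sigma == 40.0 and clay_sigma == cfg.sigma


class TestSimulateOutput:
    def test_pedigree_consistency_exhaustive(self):
        cfg = SimulationConfig(n_plots=2, cohort_sizes={"FIRST_YEAR": 25, "YOUNG": 10, "SAPLING": 5})
        ds, truth = simulate_population(cfg, seed=13)
        for oid, mid in truth.mothers.items():
            fid = truth.fathers[oid]
            assert truth.sexes[mid] == "F" and truth.sexes[fid] == "M"
            assert mid != fid
            assert oid.split("_")[0] == mid.split("_")[0]  # mating within plot

    def test_offspring_alleles_come_from_parents(self):
        cfg = SimulationConfig(
            n_plots=1, n_adults=4, n_adults_sampled=4,
            cohort_sizes={"FIRST_YEAR": 40, "YOUNG": 0, "SAPLING": 0},
        )
        ds, truth = simulate_population(cfg, seed=21)
        idx = {iid: k for k, iid in enumerate(ds.ids)}
        for oid, mid in truth.mothers.items():
            fid = truth.fathers[oid]
            child = ds.calls[idx[oid]]
            mom = ds.calls[idx[mid]]
            dad = ds.calls[idx[fid]]
            for l in range(ds.n_loci):
                a, b = child[l]
                assert (a in mom[l] and b in dad[l]) or (
                    b in mom[l] and a in dad[l]
                )

    def test_fixed_seed_reproduces_files_byte_for_byte(self, tmp_path):
        cfg = SimulationConfig(n_plots=3, cohort_sizes={"FIRST_YEAR": 10, "YOUNG": 5, "SAPLING": 3})
        for tag in ("a", "b"):
            ds, truth = simulate_population(cfg, seed=99)
            write_genotype_tables(ds, tmp_path / f"g_{tag}.tsv", tmp_path / f"m_{tag}.tsv")
            truth.to_json(tmp_path / f"t_{tag}.json")
        assert (tmp_path / "g_a.tsv").read_bytes() == (tmp_path / "g_b.tsv").read_bytes()
        assert (tmp_path / "m_a.tsv").read_bytes() == (tmp_path / "m_b.tsv").read_bytes()
        assert (tmp_path / "t_a.json").read_bytes() == (tmp_path / "t_b.json").read_bytes()

    def test_truth_json_is_loadable(self, tmp_path):
        ds, truth = simulate_population(
            SimulationConfig(n_plots=1, cohort_sizes={"FIRST_YEAR": 5, "YOUNG": 0, "SAPLING": 0}),
            seed=1,
        )
        truth.to_json(tmp_path / "truth.json")
        payload = json.loads((tmp_path / "truth.json").read_text())
        assert set(payload["mothers"]) == {
            i for i in ds.ids if not i.split("_")[1].startswith("A")
        }

    def test_sigma_zero_limit_colocates_offspring_with_mother(self):
        cfg = SimulationConfig(
            n_plots=1, n_adults=6, sigma=1e-9,
            cohort_sizes={"FIRST_YEAR": 40, "YOUNG": 0, "SAPLING": 0},
            n_adults_sampled=0,
        )
        ds, truth = simulate_population(cfg, seed=31)
        pos = {a: xy for a, xy in truth.breeding_positions.items()}
        idx = {iid: k for k, iid in enumerate(ds.ids)}
        for oid, mid in truth.mothers.items():
            mx, my = pos[mid]
            k = idx[oid]
            assert abs(ds.x[k] - mx) < 1e-6 and abs(ds.y[k] - my) < 1e-6
        # co-located pairs are maternal sibs: short-range r strongly positive
        from sgstools.sgs_core import _prepare, autocorrelation

        r = autocorrelation(*_prepare(ds, DistanceClassSpec((5.0, 250.0))))
        assert r[0] > 0.1

    def test_realized_frequencies_converge_to_generator(self):
        cfg = SimulationConfig(
            n_plots=1, n_adults=2000, n_adults_sampled=2000,
            cohort_sizes={"FIRST_YEAR": 0, "YOUNG": 0, "SAPLING": 0},
        )
        ds, truth = simulate_population(cfg, seed=8)
        from sgstools.diversity import allele_frequencies

        ft = allele_frequencies(ds)
        for l, locus in enumerate(ds.loci):
            for a, p_hat in zip(locus.alleles, ft.freqs[l]):
                p = truth.true_freqs[l][a]
                se = max(np.sqrt(p * (1 - p) / ft.n_copies[l]), 1e-4)
                assert abs(p_hat - p) <= 3.5 * se


class TestRecoverySuite:
    def test_orderings_on_small_grid(self):
        report, checks = parameter_recovery_suite(
            sigma_grid=(5.0, 80.0), jc_lambdas=(0.0, 40.0), n_reps=6, seed=3,
            n_perm=49,
        )
        assert checks["r_decreasing_in_sigma"]
        assert checks["jc_erodes_sapling_sgs"]
        disp = report[report["cell"] == "dispersal"]
        assert disp["exceedance_rate"].iloc[0] >= disp["exceedance_rate"].iloc[-1]
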