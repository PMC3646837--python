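"""Monte-Carlo experiments over the generator-analysis loop.

These drive the statistical guarantees of the pipeline: type-I error of the
class-1 permutation test under a structureless generator, the dispersal
gradient and Janzen-Connell orderings of class-1 r, parent-offspring kinship
recovery, and size/power of the correlogram heterogeneity test. Each returns
plain dicts of numbers so callers (scripts, tests) can report them directly.
"""

from __future__ import annotations

import numpy as np

from .heterogeneity import correlogram_heterogeneity
from .kinship import loiselle_fij
from .sgs_core import (
    DistanceClassSpec,
    _prepare,
    autocorrelation,
    permutation_envelope,
)
from .simulate import SimulationConfig, simulate_population

COARSE = DistanceClassSpec.regular(50.0, 250.0)
FINE = DistanceClassSpec.regular(10.0, 250.0)


def _seed_for(master: int, stream: int, rep: int) -> int:
    return int((master * 1_000_003 + stream * 10_007 + rep) % (2**31))


def type_i_error_class1(
    n_datasets: int = 200,
    n: int = 120,
    n_loci: int = 7,
    n_perm: int = 999,
    alpha: float = 0.05,
    seed: int = 0,
    spec: DistanceClassSpec = COARSE,
) -> dict[str, float]:
    """Rejection rate of the class-1 permutation test under no structure.

    The generator places offspring uniformly in the plot (sigma = inf, JC
    off), so genotype and location are independent and the test should
    reject at its nominal level.
    """
    cfg = SimulationConfig(
        n_plots=1,
        n_adults=30,
        n_adults_sampled=0,
        n_loci=n_loci,
        alleles_per_locus=SimulationConfig().alleles_per_locus[:n_loci],
        cohort_sizes={"FIRST_YEAR": n, "YOUNG": 0, "SAPLING": 0},
        sigma=np.inf,
    )
    rejections = 0
    for rep in range(n_datasets):
        ds, _ = simulate_population(cfg, seed=_seed_for(seed, 1, rep))
        env = permutation_envelope(ds, spec, n_perm=n_perm, seed=_seed_for(seed, 2, rep))
        rejections += env.p[0] <= alpha
    return {"rate": rejections / n_datasets, "n_datasets": n_datasets, "alpha": alpha}


def dispersal_gradient(
    sigma_grid: tuple[float, ...] = (5.0, 20.0, 80.0),
    n_offspring: int = 200,
    n_reps: int = 50,
    seed: int = 0,
    spec: DistanceClassSpec = FINE,
) -> dict[float, float]:
    """Mean class-1 r per dispersal scale (should decrease with sigma).

    The grid cells share seeds per replicate (common random numbers): the
    same founders, pedigree and standard displacement draws are reused and
    only the kernel scale differs, so the across-sigma comparison is paired.
    """
    out: dict[float, float] = {}
    for sigma in sigma_grid:
        cfg = SimulationConfig(
            n_plots=2,
            n_adults=6,
            n_adults_sampled=0,
            cohort_sizes={"FIRST_YEAR": n_offspring // 2, "YOUNG": 0, "SAPLING": 0},
            sigma=sigma,
        )
        vals = []
        for rep in range(n_reps):
            ds, _ = simulate_population(cfg, seed=_seed_for(seed, 10, rep))
            vals.append(float(autocorrelation(*_prepare(ds, spec))[0]))
        out[float(sigma)] = float(np.mean(vals))
    return out


def jc_erosion(
    jc_lambda: float = 30.0,
    n_per_cohort: int = 100,
    n_reps: int = 50,
    seed: int = 0,
    spec: DistanceClassSpec = FINE,
) -> dict[str, float]:
    """Class-1 r gap (sapling minus first-year) with JC thinning off vs on.

    Saplings carry two thinning rounds, first-year seedlings none, so with
    thinning on the surviving sapling cohort should show weaker short-range
    structure than the newest cohort.
    """
    out = {}
    for tag, lam in (("off", 0.0), ("on", float(jc_lambda))):
        diffs = []
        cfg = SimulationConfig(
            n_plots=2,
            n_adults=6,
            n_adults_sampled=0,
            cohort_sizes={
                "FIRST_YEAR": n_per_cohort // 2,
                "YOUNG": 0,
                "SAPLING": n_per_cohort // 2,
            },
            jc_lambda=lam,
        )
        for rep in range(n_reps):
            ds, _ = simulate_population(cfg, seed=_seed_for(seed, 30, rep))
            r_first = float(autocorrelation(*_prepare(ds.select(size_class="FIRST_YEAR"), spec))[0])
            r_sap = float(autocorrelation(*_prepare(ds.select(size_class="SAPLING"), spec))[0])
            diffs.append(r_sap - r_first)
        out[tag] = float(np.mean(diffs))
    return out


def parent_offspring_kinship(
    n_loci: int = 100,
    n_pairs: int = 200,
    n_reps: int = 10,
    seed: int = 0,
) -> dict[str, float]:
    """Mean Loiselle Fij of simulated parent-offspring pairs against the
    generator's true allele frequencies (expectation 1/4).

    Pairs within one population share founders and allele-frequency draws,
    so the Monte-Carlo error is taken across ``n_reps`` independent
    populations (SE of the replicate means), not across pairs.
    """
    per_rep = max(n_pairs // n_reps, 1)
    cfg = SimulationConfig(
        n_plots=1,
        n_loci=n_loci,
        alleles_per_locus=[6] * n_loci,
        n_adults=20,
        n_adults_sampled=20,
        cohort_sizes={"FIRST_YEAR": per_rep, "YOUNG": 0, "SAPLING": 0},
        sigma=np.inf,
    )
    rep_means = []
    total = 0
    for rep in range(n_reps):
        ds, truth = simulate_population(cfg, seed=_seed_for(seed, 40, rep))
        fij = loiselle_fij(ds, truth.reference_table())
        idx = {iid: k for k, iid in enumerate(ds.ids)}
        vals = np.array([fij[idx[o], idx[m]] for o, m in truth.mothers.items()])
        rep_means.append(float(vals.mean()))
        total += vals.size
    rep_means = np.asarray(rep_means)
    return {
        "mean_fij": float(rep_means.mean()),
        "mc_se": float(rep_means.std(ddof=1) / np.sqrt(n_reps)),
        "n_pairs": int(total),
    }


def stratified_landscape(
    sigma_sandy: float,
    sigma_clay: float,
    n_per_plot: int = 30,
    n_plots: int = 10,
    seed: int = 0,
):
    """One landscape, one founder gene pool, soil-specific dispersal scales.

    Half the plots are sandy and half clay (via the default clay gradient);
    the stratum overrides set each soil's dispersal sigma. Returns the sandy
    and clay seedling groups, mirroring a sand-vs-clay comparison design.
    """
    cfg = SimulationConfig(
        n_plots=n_plots,
        n_adults=6,
        n_adults_sampled=0,
        cohort_sizes={"FIRST_YEAR": n_per_plot, "YOUNG": 0, "SAPLING": 0},
        stratum_overrides={
            "SANDY": {"sigma": float(sigma_sandy)},
            "CLAY": {"sigma": float(sigma_clay)},
        },
    )
    ds, _ = simulate_population(cfg, seed=seed)
    return ds.select(soil_class="SANDY"), ds.select(soil_class="CLAY")


def heterogeneity_power(
    sigma_sandy: float = 40.0,
    sigma_clay: float = 10.0,
    n_per_group: int = 150,
    n_reps: int = 100,
    n_perm: int = 999,
    alpha: float = 0.05,
    seed: int = 0,
    spec: DistanceClassSpec = COARSE,
) -> dict[str, float]:
    """Rejection rate of the whole-correlogram omega heterogeneity test for
    soil strata with contrasting dispersal scales (4x by default)."""
    rejections = 0
    for rep in range(n_reps):
        dsA, dsB = stratified_landscape(
            sigma_sandy, sigma_clay,
            n_per_plot=n_per_group // 5,
            seed=_seed_for(seed, 50, rep),
        )
        res = correlogram_heterogeneity(
            dsA, dsB, spec, n_perm=n_perm, seed=_seed_for(seed, 51, rep),
            labels=("SANDY", "CLAY"),
        )
        rejections += res.p_omega <= alpha
    return {"rate": rejections / n_reps, "n_reps": n_reps, "alpha": alpha}


def heterogeneity_null_size(
    n_per_group: int = 150,
    n_reps: int = 100,
    n_perm: int = 999,
    alpha: float = 0.05,
    seed: int = 0,
    spec: DistanceClassSpec = COARSE,
) -> dict[str, float]:
    """Size of the omega heterogeneity test on null pairs.

    Both groups come from one panmictic generator run (uniform placement,
    many breeding adults) split at random, so the group labels are
    exchangeable and rejections should occur at the nominal rate.
    """
    cfg = SimulationConfig(
        n_plots=10,
        n_adults=30,
        n_adults_sampled=0,
        cohort_sizes={"FIRST_YEAR": (2 * n_per_group) // 10, "YOUNG": 0, "SAPLING": 0},
        sigma=np.inf,
    )
    rejections = 0
    for rep in range(n_reps):
        ds, _ = simulate_population(cfg, seed=_seed_for(seed, 60, rep))
        rng = np.random.default_rng(_seed_for(seed, 61, rep))
        order = rng.permutation(ds.n_individuals)
        dsA = ds.subset(order[:n_per_group])
        dsB = ds.subset(order[n_per_group:])
        res = correlogram_heterogeneity(
            dsA, dsB, spec, n_perm=n_perm, seed=_seed_for(seed, 62, rep)
        )
        rejections += res.p_omega <= alpha
    return {"rate": rejections / n_reps, "n_reps": n_reps, "alpha": alpha}
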