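# sgstools

Fine-scale spatial genetic structure (SGS) analysis for codominant marker
data, built around the question of how relatedness among tropical-forest
plants changes with distance, ontogenetic stage and habitat. The package
implements the full analysis chain for microsatellite genotypes of mapped
individuals — seedling cohorts through adults, sampled in long transect
plots over a soil gradient — together with a spatially explicit forward
simulator of dispersal-limited recruitment that serves as its test bed.

## Who this is for

Population geneticists and plant ecologists who want a scripted, seeded,
reproducible equivalent of the usual GenAlEx/SPAGeDi desktop workflow:
multivariate spatial autocorrelation correlograms with permutation and
bootstrap inference, correlogram heterogeneity tests between groups,
Loiselle kinship curves within and between generations, and per-group
diversity summaries.

## The statistics

**Autocorrelation `r` (Smouse–Peakall).** Genotypes are encoded as
allele-dosage vectors; the per-locus squared genetic distance between two
individuals is `d² = ½‖y_i − y_j‖²`, which takes the values 0/1/2/3/4 over
the five possible codominant genotype-pair configurations. Distances are
summed over loci (with per-pair rescaling by total/complete loci when calls
are missing) and Gower-centered,

    c_ij = −½ (d²_ij − d̄²_i· − d̄²_·j + d̄²··),

and for each ground-distance class *h* (e.g. 0–50 m, 51–100 m, …)

    r_h = Σ_{i≠j} x_ij(h) c_ij / Σ_i w_i(h) c_ii ,

where `x_ij(h)` flags pairs in the class and `w_i(h)` counts how often
individual *i* is paired there. Under no structure `E[r] = −1/(N−1)`.
Inference: 999 permutations of genotypes among sampling locations give a
95% null envelope and two-sided p-values per class; bootstrap resampling of
each class's pair list gives error bars; Fisher's `ω = −2 Σ ln p_h` tests
the whole correlogram against a permutational reference.

**Heterogeneity between correlograms.** For two groups A and B, per class

    t²_h = ((r_Ah − b_Ah) − (r_Bh − b_Bh))² / (V_Ah + V_Bh),

with bias terms `b` and variances `V` taken from pooled-label permutations
(group membership shuffled, locations fixed) — the bias correction removes
the sample-size-dependent null expectation `≈ −1/(N_g−1)`. The
whole-correlogram comparison again combines per-class p-values into ω.

**Loiselle kinship.** With dosage fractions `q ∈ {0, ½, 1}` and reference
allele frequencies `p`,

    F_ij = [ Σ_l Σ_a (q_ila − p_la)(q_jla − p_la) + Σ_l Σ_a p_la(1−p_la)/(n_l−1) ]
           / Σ_l Σ_a p_la(1−p_la),

and relatedness `r = 2 F_ij` for non-inbred pairs (parent–offspring expects
`F = 0.25`). Kinship curves average `F_ij` per distance class either among
the members of one cohort (within-generation) or between a cohort and the
juvenile/adult class (between-generation).

**The simulator.** Dioecious adults are placed in 250 m plots a kilometre
apart; offspring draw a mother and father uniformly from the plot's females
and males, inherit one allele per parent per locus, and land at the mother
plus a Gaussian (or exponential) kernel displacement of scale σ. Optional
Janzen–Connell thinning applies survival `s(d) = 1 − exp(−d/λ)` per exposure
round, with older cohorts exposed more; soil strata can override σ and λ.
Defaults reproduce the study conditions: 14 plots, 360 individuals in four
size classes (142/130/57/31), two soil strata, 7 loci with 4–12 alleles.

## Worked example

```python
from sgstools import (SimulationConfig, simulate_population,
                      DistanceClassSpec, spatial_correlogram)

ds, truth = simulate_population(SimulationConfig(), seed=1)
first_year = ds.select(size_class="FIRST_YEAR")
cg = spatial_correlogram(first_year, DistanceClassSpec.regular(50, 250),
                         n_perm=999, n_boot=999, seed=2)
print(cg.to_frame()[["class_hi", "n_pairs", "r", "p"]].round(3))
print(f"omega = {cg.omega:.1f}, p = {cg.p_omega:.3f}")
```

prints

```
   class_hi  n_pairs      r      p
0      50.0      406  0.263  0.001
1     100.0      246  0.120  0.001
2     150.0      198  0.023  0.045
3     200.0       78  0.043  0.038
4     250.0       16  0.043  0.321
omega = 42.6, p = 0.001
```

First-year seedlings are far more related than random within 50 m
(r = 0.26 against a null expectation near −1/142) and the signal decays
with distance; the multiclass ω rejects "no autocorrelation at any
distance". Running the same analysis per size class shows the decline of
short-range structure from the youngest cohort to saplings that
distance-dependent thinning produces.

The numbered scripts under `analysis/` run the full study on a simulated
landscape: `01_simulate_landscape.py` writes the genotype/meta tables,
`02`–`05` produce the diversity, correlogram, heterogeneity and kinship
tables under `results/tables/`, and `06_calibration_experiments.py` measures
the pipeline's statistical operating characteristics.

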