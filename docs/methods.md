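# Methods

This note records the models, conventions and numerical choices behind
`sgstools`, and what the synthetic test bed does and does not establish.

## Data model

A `GenotypeDataset` holds diploid microsatellite calls (unordered allele
pairs, integer codes, 0 = no call), planar coordinates in metres, and
per-individual metadata (plot, height, clay fraction, size and soil class).
A genotype with only one called allele is treated as fully missing at that
locus: every statistic operates on diploid dosage vectors, which a single
allele cannot define. Coordinates supplied as lon/lat can be projected by a
local equirectangular projection about the centroid; over the few
kilometres such plot grids span, the distortion is orders of magnitude
below the narrowest (10 m) distance bin.

Size classes follow the field protocol: heights of 0–20 cm are first-year
seedlings, 20–40 cm young seedlings, 40–100 cm saplings, 100–200 cm are
excluded (too rare to pair), and anything taller is juvenile/adult. The
boundaries are closed on the right — "up to 20 cm" means 20.0 cm is still
first-year. Soils split at 15% clay; exactly 15% classifies as sandy, a
tie-break we fix explicitly because "less than 15" and "greater than 15"
leave the boundary undefined. Plots enter the analysis only if some size
class has at least two members (pairwise statistics need a pair).

## Spatial autocorrelation

Per locus, a genotype maps to its allele-dosage vector (entries 0/1/2
summing to 2) and the squared genetic distance of a pair is half the
squared Euclidean distance between dosages, giving the canonical 0/1/2/3/4
values over the five codominant pair configurations. Pairs missing a locus
drop it from the sum and the total is rescaled by (loci total)/(loci
complete) — unbiased in expectation under missing-at-random. A pair with
no complete locus is a hard error rather than a silent guess.

The squared-distance matrix is Gower double-centered; distance classes bin
ground distance with the convention [0, e₁], (e₁, e₂], …, so co-located
pairs land in class 1 and a distance exactly on an edge stays in the lower
class. The class statistic r is the ratio of ordered-pair covariance sums;
a class containing every pair yields r = −1/(N−1) exactly (an algebraic
consequence of zero row sums), which the tests verify to 1e-9.

Permutation inference shuffles genotype rows against locations. P-values
are two-sided with add-one smoothing, measured as absolute deviation from
the permutation-null mean — the null expectation of r is ≈ −1/(N−1), not
zero, and centering there keeps the test calibrated (measured type-I error
0.02–0.09 at α = 0.05 over 200 null landscapes). The printed 2.5%/97.5%
null envelope supports the conventional one-sided reading (r outside the
envelope) alongside the p-values. Bootstrap error bars resample each
class's unordered pair list with replacement and recompute r from the
resampled numerator/denominator contributions; classes with fewer than two
pairs stay blank.

The multiclass statistic is Fisher's ω = −2 Σ ln p over defined classes.
Its p-value uses a permutational reference by default: each null
replicate's per-class deviations are ranked against the whole null set to
form a pseudo-p vector and a null ω; the χ²₂ₖ upper tail is available as a
fallback. Randomness derives from one master seed with per-replicate
streams keyed by counter, so results are independent of evaluation order;
the study-scale default is 999 permutations and 999 bootstraps.

## Heterogeneity between groups

Two correlograms are compared with the pooled sample as the null reference:
group labels are permuted over the pooled individuals (coordinates fixed)
and both groups' correlograms recomputed per replicate, each group centered
within its own subset exactly as a standalone analysis would be. Per class,

t² = ((r_A − b_A) − (r_B − b_B))² / (V_A + V_B),

where b and V are the mean and variance of the label-permutation null for
that group — b is the sample-size-dependent bias correction (≈ −1/(N_g−1)).
When group sizes are equal the two null sets are exchangeable and are
pooled, which makes t² vanish exactly for identical inputs. Per-class
p-values rank the observed t² in the replicate t² distribution; the
whole-correlogram ω combines them with the same pseudo-p reference. Note
the per-class and whole-correlogram p-values are invariant to the choice of
V (it is a shared constant within a comparison); V matters only for the
reported magnitude of t².

Known limitation: when the two groups occupy disjoint plots and carry
strong family structure (a handful of maternal sib clusters per plot),
individuals are not exchangeable across groups and the label-permutation
test is anticonservative — we measured ~0.2 rejection at α = 0.05 with six
breeding adults per plot and no true difference. This is a property of the
individual-level permutation design itself (plot-level pseudoreplication),
not of the implementation; on exchangeable null groups (one panmictic
population split at random) the test is calibrated (0.07 at α = 0.05 over
100 replicates). Users comparing plot-level strata should read marginal
p-values with this in mind.

## Kinship

The Loiselle estimator is computed against a reference frequency table,
by default the pooled sample (all cohorts plus adults) so within- and
between-generation curves share a footing. The finite-sample term
Σ p(1−p)/(n_l − 1) uses the gene-copy count behind the reference
frequencies; with exact (generator) frequencies the term vanishes. Pairs
drop loci missing in either member from numerator and denominator alike.
Brute-force scalar summation reproduces the vectorized matrix to 1e-10,
and simulated parent–offspring pairs at 100 loci recover F ≈ 0.25 within
Monte-Carlo error — measured across independent replicate populations,
because pairs within one population share founders and frequency draws and
their naive SE would be too small.

Curve modes select pairs within one size class, between a class and the
juvenile/adult class, or all pairs; the all-pairs curve equals the
pair-count-weighted combination of its constituents, which the tests check
numerically. Bin edges are always an explicit input.

## The synthetic landscape

The generator emulates the sampling design the analysis assumes: long thin
plots (250 × 40 m defaults) spaced 1 km apart so cross-plot pairs fall
beyond every distance class; per-plot breeding pools of dioecious adults
(sex Bernoulli(½), redrawn until both sexes are present when offspring are
required — a plot with fewer than two adults and offspring requested is an
error); Mendelian inheritance; offspring placed at mother + kernel
displacement (Gaussian by default, exponential available, σ = ∞ meaning
uniform placement for null experiments). Janzen–Connell thinning applies
survival (1 − exp(−d/λ)) per exposure round with exposure 0/1/2 for the
first-year/young/sapling cohorts, so older cohorts have survived more
thinning; rejection redraws only the displacement, capped at 200 tries.
Soil strata can override σ and λ per stratum.

Defaults are the study conditions: 14 plots with the emulated design’s per-plot
cohort sizes (totals 142/130/57/31 over the four classes) and clay
percentages (6 sandy / 8 clay plots); 7 loci with allele counts
(8, 12, 9, 8, 4, 4, 9) — range 4–12, mean 7.71; founder frequencies from a
symmetric Dirichlet(0.5), giving nominal mean expected heterozygosity near
0.66; dispersal σ = 15 m, reflecting seed rain concentrated under the
maternal crown. The truth record (pedigree, true frequencies, breeding
positions) is written alongside every dataset so tests never re-derive
parentage from output.

What the generator does *not* emulate: multi-generation isolation by
distance (adults are unrelated founders, so long-range kinship plateaus at
zero rather than declining smoothly), mutation, selection, seed dormancy,
overlapping seed shadows from unsampled adults outside plots, and
genotyping artefacts (null alleles, allele dropout). Passing calibration
on this test bed therefore demonstrates correctness of the statistics and
the stated mechanisms, not that real data meet their assumptions.

## Experiment design choices

Calibration and mechanism experiments live in `sgstools.experiments`:

- Type-I error: 200 landscapes at σ = ∞ (thinning off), n = 120, 7 loci,
  999 permutations, class-1 two-sided test at α = 0.05.
- Dispersal gradient: mean class-1 r over 50 replicates at σ ∈ {5, 20, 80} m
  with n = 200 offspring. Distance classes are the study's fine 10 m bins —
  resolution below the smallest kernel scale, since a 50 m first bin cannot
  separate two kernels that both fit inside it. Grid cells share seeds per
  replicate (common random numbers), making the across-σ comparison paired.
- Thinning erosion: sapling-minus-first-year class-1 r with λ = 30 m on
  versus off, common seeds across the two arms.
- Heterogeneity size: one panmictic population (uniform placement, 30
  adults/plot) split at random into two groups of 150 — the exchangeable
  null. Power: one landscape, shared founder pool, soil strata with
  σ = 10 m (clay) versus 40 m (sand), 150 seedlings per stratum,
  999 permutations (measured 0.82 at α = 0.05 over 100 replicates).
- Parent–offspring kinship: 10 independent populations of 20 pairs each at
  100 six-allele loci; the SE is across replicate means.

Problem sizes throughout (replicate counts, 999 permutations, n per group)
are the package's study-scale conventions; the full test suite runs in
about five minutes on one core.

## Degenerate inputs and tie-breaks

Monomorphic loci contribute nothing to kinship denominators (all
monomorphic is an error); a dataset with identical genotypes has no genetic
variance and the autocorrelation errors out rather than returning 0/0;
empty distance classes propagate as blank rows, and classes empty in either
group make the heterogeneity t² blank for that class; ω sums over defined
classes only. Ties at distance-class edges go to the lower class; a clay
fraction exactly at the threshold classifies sandy; permutation p-values
are never zero by add-one smoothing.
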