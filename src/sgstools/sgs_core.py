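"""Multivariate spatial autocorrelation (Smouse-Peakall r) engine.

Pipeline: codominant genotypes -> per-locus squared genetic distances over
allele-dosage vectors -> Gower double-centering -> per-distance-class
autocorrelation r -> permutation null envelope and p-values -> bootstrap
error bars -> multiclass omega (Fisher combination of the per-class p's).

Under no spatial structure E[r] = -1/(N-1); a class containing every pair
attains that value exactly (row sums of the centered matrix are zero).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_tables import MISSING, GenotypeDataset


# ----------------------------------------------------------------------
# distance classes
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class DistanceClassSpec:
    """Ordered upper edges (m). Class 1 = [0, e1], class k = (e_{k-1}, e_k];
    pairs farther than the last edge are excluded."""

    edges: tuple[float, ...]

    def __post_init__(self) -> None:
        e = np.asarray(self.edges, dtype=float)
        if e.size == 0:
            raise ValueError("at least one distance-class edge required")
        if (e <= 0).any() or (np.diff(e) <= 0).any():
            raise ValueError("edges must be strictly increasing and positive")

    @classmethod
    def from_string(cls, text: str) -> "DistanceClassSpec":
        return cls(tuple(float(t) for t in text.split(",") if t.strip()))

    @classmethod
    def regular(cls, width: float, maximum: float) -> "DistanceClassSpec":
        n = int(round(maximum / width))
        return cls(tuple(width * (k + 1) for k in range(n)))

    @property
    def n_classes(self) -> int:
        return len(self.edges)

    def bounds(self) -> list[tuple[float, float]]:
        lo = (0.0,) + self.edges[:-1]
        return list(zip(lo, self.edges))


@dataclass
class PairClasses:
    """Unordered pairs within range and their distance-class indices."""

    ii: np.ndarray        # first index of each pair
    jj: np.ndarray        # second index
    cls: np.ndarray       # 0-based class index
    n_classes: int
    n_individuals: int

    def n_pairs(self) -> np.ndarray:
        return np.bincount(self.cls, minlength=self.n_classes).astype(np.int64)


def assign_distance_classes(
    x: np.ndarray, y: np.ndarray, spec: DistanceClassSpec
) -> PairClasses:
    """Bin all unordered pairs by planar ground distance.

    Boundary convention: a distance equal to an edge falls in the lower
    class; co-located pairs (distance 0) fall in class 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    ii, jj = np.triu_indices(n, k=1)
    d = np.hypot(x[ii] - x[jj], y[ii] - y[jj])
    edges = np.asarray(spec.edges)
    cls = np.searchsorted(edges, d, side="left")
    keep = cls < spec.n_classes
    return PairClasses(
        ii=ii[keep], jj=jj[keep], cls=cls[keep],
        n_classes=spec.n_classes, n_individuals=n,
    )


# ----------------------------------------------------------------------
# genetic distance and centering
# ----------------------------------------------------------------------

@dataclass
class SquaredDistanceMatrix:
    """Pairwise squared genetic distances with per-pair complete-locus counts."""

    d2: np.ndarray
    n_complete: np.ndarray  # loci with both genotypes called, per pair

    def __post_init__(self) -> None:
        if not np.allclose(self.d2, self.d2.T):
            raise ValueError("distance matrix must be symmetric")


def _dosage_matrix(dataset: GenotypeDataset, l: int) -> tuple[np.ndarray, np.ndarray]:
    """Allele-dosage matrix (n, A_l) and per-individual called mask for locus l."""
    alleles = np.asarray(dataset.loci[l].alleles)
    calls = dataset.calls[:, l, :]
    ok = (calls != MISSING).all(axis=1)
    dosage = (calls[:, :, None] == alleles[None, None, :]).sum(axis=1).astype(float)
    dosage[~ok] = 0.0
    return dosage, ok


def pairwise_genetic_distance(dataset: GenotypeDataset) -> SquaredDistanceMatrix:
    """Squared genetic distance: per locus half the squared Euclidean distance
    between allele-dosage vectors (0/1/2/3/4 over the five codominant
    genotype-pair configurations), summed over loci complete in both
    individuals and rescaled by total-loci/complete-loci per pair (the
    missing-data "interpolation" convention).
    """
    n, L = dataset.n_individuals, dataset.n_loci
    if n < 2 or L < 1:
        raise ValueError("need at least 2 individuals and 1 locus")
    d2 = np.zeros((n, n))
    complete = np.zeros((n, n), dtype=np.int64)
    for l in range(L):
        dosage, ok = _dosage_matrix(dataset, l)
        sq = (dosage**2).sum(axis=1)
        cross = dosage @ dosage.T
        dl = 0.5 * (sq[:, None] + sq[None, :] - 2.0 * cross)
        both = np.outer(ok, ok)
        d2 += np.where(both, dl, 0.0)
        complete += both
    np.fill_diagonal(complete, L)
    off = ~np.eye(n, dtype=bool)
    if (complete[off] == 0).any():
        i, j = np.argwhere((complete == 0) & off)[0]
        raise ValueError(
            f"individuals {dataset.ids[i]!r} and {dataset.ids[j]!r} share no "
            "complete locus"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        d2 = d2 * (L / complete)
    np.fill_diagonal(d2, 0.0)
    d2 = 0.5 * (d2 + d2.T)  # enforce exact symmetry against fp noise
    return SquaredDistanceMatrix(d2=d2, n_complete=complete)


def gower_center(D: SquaredDistanceMatrix | np.ndarray) -> np.ndarray:
    """Gower double-centering: c_ij = -1/2 (d2_ij - m_i - m_j + m)."""
    d2 = D.d2 if isinstance(D, SquaredDistanceMatrix) else np.asarray(D, dtype=float)
    row = d2.mean(axis=1)
    grand = row.mean()
    return -0.5 * (d2 - row[:, None] - row[None, :] + grand)


# ----------------------------------------------------------------------
# the r statistic
# ----------------------------------------------------------------------

def _class_sums(
    C: np.ndarray, pc: PairClasses, order: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Numerator (2*sum c_ij) and denominator (sum c_ii + c_jj) per class,
    optionally with genotype rows permuted by ``order``."""
    ii, jj = pc.ii, pc.jj
    if order is not None:
        ii, jj = order[ii], order[jj]
    diag = np.diagonal(C)
    num = 2.0 * np.bincount(pc.cls, weights=C[ii, jj], minlength=pc.n_classes)
    den = np.bincount(pc.cls, weights=diag[ii] + diag[jj], minlength=pc.n_classes)
    return num, den


def autocorrelation(C: np.ndarray, pc: PairClasses) -> np.ndarray:
    """Per-class autocorrelation r; NaN for classes without pairs."""
    if np.trace(C) <= 1e-12:
        raise ValueError("no genetic variance (all genotypes identical)")
    num, den = _class_sums(C, pc)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(den != 0, num / den, np.nan)
    r[pc.n_pairs() == 0] = np.nan
    return r


def _prepare(dataset: GenotypeDataset, spec: DistanceClassSpec):
    C = gower_center(pairwise_genetic_distance(dataset))
    pc = assign_distance_classes(dataset.x, dataset.y, spec)
    return C, pc


def _perm_rng(seed: int, tag: int, k: int) -> np.random.Generator:
    # one master seed; per-replicate streams derived by counter so results
    # do not depend on evaluation order
    return np.random.default_rng(np.random.SeedSequence([int(seed), tag, k]))


def _null_r_matrix(
    C: np.ndarray, pc: PairClasses, n_perm: int, seed: int, tag: int = 1
) -> np.ndarray:
    """(n_perm, K) matrix of r under random genotype-to-location permutation."""
    out = np.full((n_perm, pc.n_classes), np.nan)
    n = pc.n_individuals
    npairs = pc.n_pairs()
    for k in range(n_perm):
        order = _perm_rng(seed, tag, k).permutation(n)
        num, den = _class_sums(C, pc, order)
        with np.errstate(divide="ignore", invalid="ignore"):
            rk = np.where(den != 0, num / den, np.nan)
        rk[npairs == 0] = np.nan
        out[k] = rk
    return out


@dataclass
class PermutationResult:
    lo: np.ndarray
    hi: np.ndarray
    p: np.ndarray
    null_mean: np.ndarray
    null_r: np.ndarray


def _perm_pvalues(r_obs: np.ndarray, null_r: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided permutation p with add-one smoothing, measured as absolute
    deviation from the permutation-null mean (approx -1/(N-1), not 0)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN classes
        m = np.nanmean(null_r, axis=0)
    dev_null = np.abs(null_r - m)
    dev_obs = np.abs(r_obs - m)
    valid = (~np.isnan(null_r)).sum(axis=0)
    exceed = np.nansum(dev_null >= dev_obs[None, :], axis=0)
    with np.errstate(invalid="ignore"):
        p = (1.0 + exceed) / (1.0 + valid)
    p[np.isnan(r_obs)] = np.nan
    return p, m


def permutation_envelope(
    dataset: GenotypeDataset,
    spec: DistanceClassSpec,
    n_perm: int = 999,
    seed: int = 0,
) -> PermutationResult:
    """Null envelope (2.5/97.5% quantiles) and per-class p-values obtained by
    permuting genotypes among sampling locations."""
    if dataset.n_individuals < 3:
        raise ValueError("need at least 3 individuals for the permutation test")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    C, pc = _prepare(dataset, spec)
    r_obs = autocorrelation(C, pc)
    null_r = _null_r_matrix(C, pc, n_perm, seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN classes
        lo = np.nanpercentile(null_r, 2.5, axis=0)
        hi = np.nanpercentile(null_r, 97.5, axis=0)
    p, m = _perm_pvalues(r_obs, null_r)
    return PermutationResult(lo=lo, hi=hi, p=p, null_mean=m, null_r=null_r)


def bootstrap_errorbars(
    dataset: GenotypeDataset,
    spec: DistanceClassSpec,
    n_boot: int = 999,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """95% percentile interval on each class's r from resampling that class's
    unordered pair list with replacement. Classes with < 2 pairs are blank."""
    C, pc = _prepare(dataset, spec)
    lo = np.full(pc.n_classes, np.nan)
    hi = np.full(pc.n_classes, np.nan)
    diag = np.diagonal(C)
    for h in range(pc.n_classes):
        sel = pc.cls == h
        m = int(sel.sum())
        if m < 2:
            continue
        num_c = 2.0 * C[pc.ii[sel], pc.jj[sel]]
        den_c = diag[pc.ii[sel]] + diag[pc.jj[sel]]
        rng = _perm_rng(seed, 2, h)
        idx = rng.integers(0, m, size=(n_boot, m))
        num = num_c[idx].sum(axis=1)
        den = den_c[idx].sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            rb = num / den
        rb = rb[np.isfinite(rb)]
        if rb.size:
            lo[h] = np.percentile(rb, 2.5)
            hi[h] = np.percentile(rb, 97.5)
    return lo, hi


# ----------------------------------------------------------------------
# multiclass omega
# ----------------------------------------------------------------------

def _pseudo_p_matrix(dev_null: np.ndarray) -> np.ndarray:
    """Per-replicate pseudo-p's: each replicate's deviation ranked against the
    whole null set, column by column."""
    n_perm, K = dev_null.shape
    out = np.full_like(dev_null, np.nan)
    for k in range(K):
        col = dev_null[:, k]
        ok = ~np.isnan(col)
        if ok.sum() == 0:
            continue
        # number of replicates with deviation >= own deviation (ties counted)
        ranks = stats.rankdata(-col[ok], method="max")
        out[ok, k] = ranks / ok.sum()
    return out


def omega_multiclass(
    p_values: np.ndarray,
    null_p_replicates: np.ndarray | None = None,
) -> tuple[float, float]:
    """Fisher combination omega = -2 sum ln p over defined classes.

    ``null_p_replicates`` (n_perm, K) supplies the permutational reference for
    p_omega; without it the chi-square upper tail with 2K degrees of freedom
    is used as a documented fallback.
    """
    p = np.asarray(p_values, dtype=float)
    defined = ~np.isnan(p)
    if defined.sum() == 0:
        raise ValueError("no defined per-class p-values")
    if (p[defined] <= 0).any():
        raise ValueError("p-values must be positive (add-one smoothing)")
    omega = float(-2.0 * np.log(p[defined]).sum())
    if null_p_replicates is None:
        p_omega = float(stats.chi2.sf(omega, df=2 * int(defined.sum())))
        return omega, p_omega
    null_p = np.asarray(null_p_replicates, dtype=float)[:, defined]
    with np.errstate(divide="ignore", invalid="ignore"):
        omega_null = -2.0 * np.nansum(np.log(null_p), axis=1)
    n_valid = omega_null.size
    p_omega = float((1.0 + (omega_null >= omega).sum()) / (1.0 + n_valid))
    return omega, p_omega


# ----------------------------------------------------------------------
# the full correlogram
# ----------------------------------------------------------------------

@dataclass
class Correlogram:
    """Per-distance-class autocorrelation with its inference summaries."""

    edges: np.ndarray
    n_pairs: np.ndarray
    r: np.ndarray
    perm_lo: np.ndarray
    perm_hi: np.ndarray
    boot_lo: np.ndarray
    boot_hi: np.ndarray
    p: np.ndarray
    omega: float
    p_omega: float
    n_perm: int
    n_boot: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        edges = np.asarray(self.edges, dtype=float)
        lo = np.concatenate([[0.0], edges[:-1]]) if edges.size else edges
        return pd.DataFrame(
            {
                "class_lo": lo,
                "class_hi": edges,
                "n_pairs": np.asarray(self.n_pairs, dtype=np.int64),
                "r": self.r,
                "perm_lo": self.perm_lo,
                "perm_hi": self.perm_hi,
                "boot_lo": self.boot_lo,
                "boot_hi": self.boot_hi,
                "p": self.p,
            }
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Correlogram):
            return NotImplemented
        def eq(a, b):
            return np.array_equal(
                np.asarray(a, dtype=float), np.asarray(b, dtype=float), equal_nan=True
            )
        return (
            eq(self.edges, other.edges)
            and np.array_equal(self.n_pairs, other.n_pairs)
            and all(
                eq(getattr(self, f), getattr(other, f))
                for f in ("r", "perm_lo", "perm_hi", "boot_lo", "boot_hi", "p")
            )
            and eq([self.omega], [other.omega])
            and eq([self.p_omega], [other.p_omega])
            and (self.n_perm, self.n_boot, self.seed)
            == (other.n_perm, other.n_boot, other.seed)
        )


def spatial_correlogram(
    dataset: GenotypeDataset,
    spec: DistanceClassSpec,
    n_perm: int = 999,
    n_boot: int = 999,
    seed: int = 0,
    omega_reference: str = "permutation",
) -> Correlogram:
    """Full spatial autocorrelation analysis for one group of individuals.

    ``omega_reference`` is ``"permutation"`` (default; each replicate's
    pseudo-p vector scored against the null set) or ``"chi2"``.
    """
    C, pc = _prepare(dataset, spec)
    r_obs = autocorrelation(C, pc)
    perm = permutation_envelope(dataset, spec, n_perm=n_perm, seed=seed)
    boot_lo, boot_hi = bootstrap_errorbars(dataset, spec, n_boot=n_boot, seed=seed)
    if omega_reference == "permutation":
        dev_null = np.abs(perm.null_r - perm.null_mean)
        omega, p_omega = omega_multiclass(perm.p, _pseudo_p_matrix(dev_null))
    elif omega_reference == "chi2":
        omega, p_omega = omega_multiclass(perm.p)
    else:
        raise ValueError(f"unknown omega reference {omega_reference!r}")
    return Correlogram(
        edges=np.asarray(spec.edges, dtype=float),
        n_pairs=pc.n_pairs(),
        r=r_obs,
        perm_lo=perm.lo,
        perm_hi=perm.hi,
        boot_lo=boot_lo,
        boot_hi=boot_hi,
        p=perm.p,
        omega=omega,
        p_omega=p_omega,
        n_perm=n_perm,
        n_boot=n_boot,
        seed=seed,
    )
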