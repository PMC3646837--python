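"""Non-parametric comparison of two groups' correlograms.

The pooled sample is the null reference frame: group labels are permuted
over the pooled individuals (locations stay fixed) and both correlograms are
recomputed per replicate. For each distance class

    t2_k = ((r_Ak - b_Ak) - (r_Bk - b_Bk))^2 / (V_Ak + V_Bk)

where b_gk and V_gk are the mean and variance of group g's r over the label
permutations. Subtracting b_gk is the sample-size-dependent bias correction:
the null expectation of r is about -1/(N_g - 1) and differs between groups of
unequal size. The whole-correlogram test combines the per-class permutation
p-values into omega = -2 sum ln p, referenced against the same replicates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_tables import GenotypeDataset
from .sgs_core import (
    DistanceClassSpec,
    PairClasses,
    _class_sums,
    _perm_rng,
    _pseudo_p_matrix,
    assign_distance_classes,
    gower_center,
    omega_multiclass,
    pairwise_genetic_distance,
)


@dataclass
class HeterogeneityResult:
    """Per-class t2 statistics and the whole-correlogram omega test."""

    label_a: str
    label_b: str
    edges: np.ndarray
    t2: np.ndarray
    p: np.ndarray
    bias_a: np.ndarray   # permutation-null mean of r subtracted from group A
    bias_b: np.ndarray
    var_a: np.ndarray    # permutation-null variance of r per group
    var_b: np.ndarray
    omega: float
    p_omega: float
    n_perm: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        edges = np.asarray(self.edges, dtype=float)
        lo = np.concatenate([[0.0], edges[:-1]]) if edges.size else edges
        return pd.DataFrame(
            {
                "class_lo": lo,
                "class_hi": edges,
                "t2": self.t2,
                "p": self.p,
                "bias_a": self.bias_a,
                "bias_b": self.bias_b,
                "var_a": self.var_a,
                "var_b": self.var_b,
            }
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, HeterogeneityResult):
            return NotImplemented
        def eq(a, b):
            return np.array_equal(
                np.asarray(a, dtype=float), np.asarray(b, dtype=float), equal_nan=True
            )
        return (
            (self.label_a, self.label_b) == (other.label_a, other.label_b)
            and eq(self.edges, other.edges)
            and all(
                eq(getattr(self, f), getattr(other, f))
                for f in ("t2", "p", "bias_a", "bias_b", "var_a", "var_b")
            )
            and eq([self.omega, self.p_omega], [other.omega, other.p_omega])
            and (self.n_perm, self.seed) == (other.n_perm, other.seed)
        )


def pool_datasets(
    dsA: GenotypeDataset, dsB: GenotypeDataset
) -> tuple[GenotypeDataset, np.ndarray]:
    """Concatenate two datasets over identical locus panels.

    Returns the pooled dataset and the boolean group-A membership vector.
    Ids colliding between the groups are prefixed ``A:`` / ``B:``.
    """
    if dsA.locus_names != dsB.locus_names:
        raise ValueError("groups must share the same locus panel")
    from .io_tables import Locus

    ids_a, ids_b = list(dsA.ids), list(dsB.ids)
    if set(ids_a) & set(ids_b):
        ids_a = [f"A:{i}" for i in ids_a]
        ids_b = [f"B:{i}" for i in ids_b]
    loci = [
        Locus(la.name, tuple(sorted(set(la.alleles) | set(lb.alleles))))
        for la, lb in zip(dsA.loci, dsB.loci)
    ]
    meta = pd.concat([dsA.meta, dsB.meta], axis=0)
    pooled = GenotypeDataset(
        ids=ids_a + ids_b,
        loci=loci,
        calls=np.concatenate([dsA.calls, dsB.calls], axis=0),
        x=np.concatenate([dsA.x, dsB.x]),
        y=np.concatenate([dsA.y, dsB.y]),
        meta=meta,
    )
    in_a = np.zeros(pooled.n_individuals, dtype=bool)
    in_a[: dsA.n_individuals] = True
    return pooled, in_a


def _subset_r(
    D: np.ndarray, M: np.ndarray, idx: np.ndarray, K: int
) -> np.ndarray:
    """r per class for the individuals in ``idx``; centering is done within
    the subset, exactly as a standalone analysis of that group would."""
    Dk = D[np.ix_(idx, idx)]
    C = gower_center(Dk)
    Mk = M[np.ix_(idx, idx)]
    iu, ju = np.triu_indices(idx.size, k=1)
    cls = Mk[iu, ju]
    keep = cls >= 0
    iu, ju, cls = iu[keep], ju[keep], cls[keep]
    npairs = np.bincount(cls, minlength=K)
    diag = np.diagonal(C)
    num = 2.0 * np.bincount(cls, weights=C[iu, ju], minlength=K)
    den = np.bincount(cls, weights=diag[iu] + diag[ju], minlength=K)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(den != 0, num / den, np.nan)
    r[npairs == 0] = np.nan
    return r


def correlogram_heterogeneity(
    dsA: GenotypeDataset,
    dsB: GenotypeDataset,
    spec: DistanceClassSpec,
    n_perm: int = 999,
    seed: int = 0,
    labels: tuple[str, str] = ("A", "B"),
) -> HeterogeneityResult:
    """Single-class t2 and whole-correlogram omega heterogeneity tests."""
    pooled, in_a = pool_datasets(dsA, dsB)
    n, nA = pooled.n_individuals, int(in_a.sum())
    K = spec.n_classes

    D = pairwise_genetic_distance(pooled).d2
    # full pair-class matrix; -1 marks out-of-range pairs
    M = np.full((n, n), -1, dtype=np.int32)
    pc = assign_distance_classes(pooled.x, pooled.y, spec)
    M[pc.ii, pc.jj] = pc.cls
    M[pc.jj, pc.ii] = pc.cls

    all_idx = np.arange(n)
    rA_obs = _subset_r(D, M, all_idx[in_a], K)
    rB_obs = _subset_r(D, M, all_idx[~in_a], K)

    rA_null = np.full((n_perm, K), np.nan)
    rB_null = np.full((n_perm, K), np.nan)
    for m in range(n_perm):
        order = _perm_rng(seed, 3, m).permutation(n)
        rA_null[m] = _subset_r(D, M, order[:nA], K)
        rB_null[m] = _subset_r(D, M, order[nA:], K)

    with warnings.catch_warnings(), np.errstate(invalid="ignore"):
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN classes
        if nA == n - nA:
            # equal group sizes: the two null sets are exchangeable, so pool
            # them; identical input groups then give t2 exactly 0
            both = np.concatenate([rA_null, rB_null], axis=0)
            bias_a = bias_b = np.nanmean(both, axis=0)
            var_a = var_b = np.nanvar(both, axis=0, ddof=1)
        else:
            bias_a = np.nanmean(rA_null, axis=0)
            bias_b = np.nanmean(rB_null, axis=0)
            var_a = np.nanvar(rA_null, axis=0, ddof=1)
            var_b = np.nanvar(rB_null, axis=0, ddof=1)

    def t2_of(rA, rB):
        with np.errstate(divide="ignore", invalid="ignore"):
            return ((rA - bias_a) - (rB - bias_b)) ** 2 / (var_a + var_b)

    t2_obs = t2_of(rA_obs, rB_obs)
    t2_obs[np.isnan(rA_obs) | np.isnan(rB_obs)] = np.nan
    t2_null = t2_of(rA_null, rB_null)

    valid = (~np.isnan(t2_null)).sum(axis=0)
    exceed = np.nansum(t2_null >= t2_obs[None, :], axis=0)
    with np.errstate(invalid="ignore"):
        p = (1.0 + exceed) / (1.0 + valid)
    p[np.isnan(t2_obs)] = np.nan

    omega, p_omega = omega_multiclass(p, _pseudo_p_matrix(t2_null))
    return HeterogeneityResult(
        label_a=labels[0],
        label_b=labels[1],
        edges=np.asarray(spec.edges, dtype=float),
        t2=t2_obs,
        p=p,
        bias_a=bias_a,
        bias_b=bias_b,
        var_a=var_a,
        var_b=var_b,
        omega=omega,
        p_omega=p_omega,
        n_perm=n_perm,
        seed=seed,
    )


def tsq_single_class(
    dsA: GenotypeDataset,
    dsB: GenotypeDataset,
    spec: DistanceClassSpec,
    k: int,
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """t2 statistic and permutation p for one distance class (0-based ``k``)."""
    res = correlogram_heterogeneity(dsA, dsB, spec, n_perm=n_perm, seed=seed)
    return float(res.t2[k]), float(res.p[k])


def omega_heterogeneity(
    dsA: GenotypeDataset,
    dsB: GenotypeDataset,
    spec: DistanceClassSpec,
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """Whole-correlogram heterogeneity omega and its permutation p-value."""
    res = correlogram_heterogeneity(dsA, dsB, spec, n_perm=n_perm, seed=seed)
    return res.omega, res.p_omega
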