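"""Loiselle kinship coefficients and distance-binned kinship curves.

Fij estimates the coancestry of two individuals relative to reference allele
frequencies p. With dosage fractions q in {0, 1/2, 1}:

    Fij = [ sum_l sum_a (q_ila - p_la)(q_jla - p_la)
            + sum_l sum_a p_la (1 - p_la) / (n_l - 1) ]
          / [ sum_l sum_a p_la (1 - p_la) ]

where n_l is the number of gene copies behind the reference frequencies at
locus l (the small-sample correction term). Loci missing in either member of
a pair drop out of every sum for that pair. Relatedness of non-inbred
individuals is r = 2 Fij; parent-offspring and full-sib pairs expect
Fij = 0.25.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diversity import FrequencyTable, allele_frequencies
from .io_tables import MISSING, GenotypeDataset, SizeClass
from .sgs_core import DistanceClassSpec, assign_distance_classes


def loiselle_fij(
    dataset: GenotypeDataset, reference: FrequencyTable | None = None
) -> np.ndarray:
    """Pairwise Loiselle Fij matrix (diagonal NaN).

    ``reference`` defaults to the allele frequencies of the whole dataset
    (seedlings and adults pooled). Pairs sharing no polymorphic locus get NaN.
    """
    if reference is None:
        reference = allele_frequencies(dataset)
    if [l.name for l in reference.loci] != dataset.locus_names:
        raise ValueError("reference frequencies do not match the dataset loci")
    n, L = dataset.n_individuals, dataset.n_loci

    num = np.zeros((n, n))
    corr = np.zeros((n, n))
    den = np.zeros((n, n))
    total_den = 0.0
    for l in range(L):
        if not reference.available(l):
            continue
        ref_alleles = np.asarray(reference.loci[l].alleles)
        p = np.asarray(reference.freqs[l], dtype=float)
        den_l = float((p * (1.0 - p)).sum())
        total_den += den_l
        if den_l == 0.0:
            continue
        calls = dataset.calls[:, l, :]
        ok = (calls != MISSING).all(axis=1)
        q = 0.5 * (calls[:, :, None] == ref_alleles[None, None, :]).sum(axis=1)
        qc = q - p[None, :]
        qc[~ok] = 0.0
        num += qc @ qc.T
        n_l = int(reference.n_copies[l])
        corr_l = den_l / (n_l - 1) if n_l > 1 else 0.0
        both = np.outer(ok, ok)
        corr += corr_l * both
        den += den_l * both
    if total_den == 0.0:
        raise ValueError("all reference loci are monomorphic")
    with np.errstate(divide="ignore", invalid="ignore"):
        fij = (num + corr) / den
    np.fill_diagonal(fij, np.nan)
    return fij


@dataclass
class KinshipCurve:
    """Mean Loiselle Fij (and r = 2 Fij) per ground-distance class."""

    mode: str
    edges: np.ndarray
    n_pairs: np.ndarray
    mean_fij: np.ndarray
    mean_r: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        edges = np.asarray(self.edges, dtype=float)
        lo = np.concatenate([[0.0], edges[:-1]]) if edges.size else edges
        return pd.DataFrame(
            {
                "class_lo": lo,
                "class_hi": edges,
                "n_pairs": np.asarray(self.n_pairs, dtype=np.int64),
                "mean_fij": self.mean_fij,
                "mean_r": self.mean_r,
            }
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, KinshipCurve):
            return NotImplemented
        def eq(a, b):
            return np.array_equal(
                np.asarray(a, dtype=float), np.asarray(b, dtype=float), equal_nan=True
            )
        return (
            self.mode == other.mode
            and eq(self.edges, other.edges)
            and np.array_equal(self.n_pairs, other.n_pairs)
            and eq(self.mean_fij, other.mean_fij)
            and eq(self.mean_r, other.mean_r)
        )


def _pair_mask(dataset: GenotypeDataset, mode: str) -> np.ndarray:
    """Boolean (n, n) matrix of pairs selected by ``mode``.

    Modes: ``"all"``; ``"within:<CLASS>"`` both members in CLASS;
    ``"between:<CLASS>"`` one member in CLASS, the other ADULT_JUVENILE;
    ``"cross:<A>:<B>"`` one member in A, the other in B.
    """
    n = dataset.n_individuals
    sc = dataset.meta["size_class"].astype(str).to_numpy()
    if mode == "all":
        sel = np.ones((n, n), dtype=bool)
    else:
        parts = mode.split(":")
        if parts[0] == "within" and len(parts) == 2:
            m = sc == parts[1]
            sel = np.outer(m, m)
        elif parts[0] == "between" and len(parts) == 2:
            m = sc == parts[1]
            a = sc == SizeClass.ADULT_JUVENILE.value
            sel = np.outer(m, a) | np.outer(a, m)
        elif parts[0] == "cross" and len(parts) == 3:
            ma, mb = sc == parts[1], sc == parts[2]
            sel = np.outer(ma, mb) | np.outer(mb, ma)
        else:
            raise ValueError(f"unknown pair mode {mode!r}")
    np.fill_diagonal(sel, False)
    return sel


def kinship_correlogram(
    dataset: GenotypeDataset,
    spec: DistanceClassSpec,
    mode: str = "all",
    reference: FrequencyTable | None = None,
) -> KinshipCurve:
    """Distance-binned mean kinship for the pairs selected by ``mode``.

    Bin edges follow the same convention as the autocorrelation correlogram;
    empty bins are reported with n = 0 and blank means.
    """
    fij = loiselle_fij(dataset, reference)
    sel = _pair_mask(dataset, mode)
    pc = assign_distance_classes(dataset.x, dataset.y, spec)
    keep = sel[pc.ii, pc.jj]
    ii, jj, cls = pc.ii[keep], pc.jj[keep], pc.cls[keep]
    vals = fij[ii, jj]
    ok = ~np.isnan(vals)
    K = spec.n_classes
    n_pairs = np.bincount(cls[ok], minlength=K)
    sums = np.bincount(cls[ok], weights=vals[ok], minlength=K)
    with np.errstate(divide="ignore", invalid="ignore"):
        mean_fij = np.where(n_pairs > 0, sums / np.maximum(n_pairs, 1), np.nan)
    return KinshipCurve(
        mode=mode,
        edges=np.asarray(spec.edges, dtype=float),
        n_pairs=n_pairs.astype(np.int64),
        mean_fij=mean_fij,
        mean_r=2.0 * mean_fij,
    )
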