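"""Allele frequencies and per-group genetic diversity summaries.

The diversity table mirrors the usual microsatellite summary: per group the
sample size n, mean alleles per locus Na, mean effective alleles
Ne = 1/sum(p^2), private allele count Pa (with own-group frequencies),
observed and expected heterozygosity and the fixation index F = 1 - Ho/He,
each mean with its standard error across loci.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_tables import MISSING, GenotypeDataset, Locus


@dataclass
class FrequencyTable:
    """Reference allele frequencies per locus.

    ``freqs[l]`` is aligned with ``loci[l].alleles``; ``n_copies[l]`` is the
    number of gene copies (2 x non-missing individuals) behind those
    frequencies. A locus with no non-missing call in the reference group is
    UNAVAILABLE (``n_copies == 0``, empty frequency vector).
    """

    loci: list[Locus]
    freqs: list[np.ndarray]
    n_copies: np.ndarray

    def __post_init__(self) -> None:
        self.n_copies = np.asarray(self.n_copies, dtype=np.int64)
        for locus, f, n in zip(self.loci, self.freqs, self.n_copies):
            if n == 0:
                continue
            if n % 2 != 0:
                raise ValueError(f"{locus.name}: odd gene-copy count {n}")
            if abs(f.sum() - 1.0) > 1e-12:
                raise ValueError(f"{locus.name}: frequencies sum to {f.sum()}")

    def available(self, l: int) -> bool:
        return self.n_copies[l] > 0

    def as_dicts(self) -> list[dict[int, float]]:
        return [
            dict(zip(locus.alleles, f)) for locus, f in zip(self.loci, self.freqs)
        ]


@dataclass
class DiversityTable:
    """Per-group diversity summary; ``table`` has one row per group."""

    table: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        return self.table.copy()

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DiversityTable):
            return NotImplemented
        a, b = self.table, other.table
        if list(a.columns) != list(b.columns) or len(a) != len(b):
            return False

        def norm(v: object) -> object:
            # blanks and NaN are the same absence marker on disk; numeric
            # strings (e.g. a single private-allele frequency) compare as
            # numbers
            if v is None or (isinstance(v, float) and math.isnan(v)) or v == "":
                return None
            if isinstance(v, (int, float, np.integer, np.floating)):
                return (float(v),)
            s = str(v)
            try:
                return tuple(float(p) for p in s.split(";"))
            except ValueError:
                return s

        for col in a.columns:
            for x, y in zip(a[col], b[col]):
                if norm(x) != norm(y):
                    return False
        return True


def _group_mask(dataset: GenotypeDataset, group) -> np.ndarray:
    if group is None:
        return np.ones(dataset.n_individuals, dtype=bool)
    group = np.asarray(group)
    if group.dtype == bool:
        return group
    idx = {i: k for k, i in enumerate(dataset.ids)}
    mask = np.zeros(dataset.n_individuals, dtype=bool)
    for g in group:
        mask[idx[str(g)]] = True
    return mask


def allele_frequencies(dataset: GenotypeDataset, group=None) -> FrequencyTable:
    """Relative allele frequencies in a reference group.

    Each non-missing diploid call contributes 2 gene copies; a heterozygote
    contributes 1 copy to each of its alleles.
    """
    mask = _group_mask(dataset, group)
    if not mask.any():
        raise ValueError("reference group is empty")
    calls = dataset.calls[mask]
    freqs: list[np.ndarray] = []
    n_copies = np.zeros(dataset.n_loci, dtype=np.int64)
    for l, locus in enumerate(dataset.loci):
        flat = calls[:, l, :].ravel()
        flat = flat[flat != MISSING]
        n_copies[l] = flat.size
        if flat.size == 0:
            freqs.append(np.zeros(0))
            continue
        counts = np.array([(flat == a).sum() for a in locus.alleles], dtype=float)
        freqs.append(counts / flat.size)
    return FrequencyTable(loci=list(dataset.loci), freqs=freqs, n_copies=n_copies)


def _per_locus_stats(dataset: GenotypeDataset, mask: np.ndarray):
    """Arrays (over loci) of Na, Ne, Ho, He for one group; NaN where unavailable."""
    ft = allele_frequencies(dataset, mask)
    L = dataset.n_loci
    na = np.full(L, np.nan)
    ne = np.full(L, np.nan)
    ho = np.full(L, np.nan)
    he = np.full(L, np.nan)
    calls = dataset.calls[mask]
    for l in range(L):
        if not ft.available(l):
            continue
        f = ft.freqs[l]
        present = f > 0
        na[l] = int(present.sum())
        sum_p2 = float((f**2).sum())
        ne[l] = 1.0 / sum_p2
        he[l] = 1.0 - sum_p2
        cl = calls[:, l, :]
        ok = (cl != MISSING).all(axis=1)
        ho[l] = float((cl[ok, 0] != cl[ok, 1]).mean())
    return ft, na, ne, ho, he


def _mean_se(v: np.ndarray) -> tuple[float, float]:
    v = v[~np.isnan(v)]
    if v.size == 0:
        return math.nan, math.nan
    se = float(np.std(v, ddof=1) / math.sqrt(v.size)) if v.size > 1 else math.nan
    return float(v.mean()), se


def diversity_summary(
    dataset: GenotypeDataset,
    grouping: str | Mapping[str, str] | pd.Series,
    unbiased_he: bool = False,
) -> DiversityTable:
    """Per-group diversity summary over a partition of all individuals.

    ``grouping`` is a meta column name or an id -> label mapping; it must
    cover every individual. ``unbiased_he`` applies the 2n/(2n-1)
    small-sample factor to He (off by default: the plain gene diversity
    1 - sum(p^2) is reported).
    """
    if isinstance(grouping, str):
        labels = dataset.meta[grouping]
    else:
        labels = pd.Series(dict(grouping)).reindex(dataset.ids)
    labels = labels.astype(object)
    if labels.isna().any():
        bad = list(labels.index[labels.isna()])[:5]
        raise ValueError(f"grouping does not cover all individuals (e.g. {bad})")

    groups = list(dict.fromkeys(labels))
    # private alleles: which groups carry each (locus, allele)
    carrier: dict[tuple[int, int], set] = {}
    per_group_ft: dict[object, FrequencyTable] = {}
    rows = []
    for g in groups:
        mask = (labels == g).to_numpy()
        ft, na, ne, ho, he = _per_locus_stats(dataset, mask)
        per_group_ft[g] = ft
        if unbiased_he:
            with np.errstate(invalid="ignore"):
                corr = ft.n_copies / np.maximum(ft.n_copies - 1, 1)
                he = he * np.where(ft.n_copies > 1, corr, np.nan)
        with np.errstate(divide="ignore", invalid="ignore"):
            f_ix = np.where(he > 0, 1.0 - ho / he, np.nan)
        for l, locus in enumerate(dataset.loci):
            if not ft.available(l):
                continue
            for a, p in zip(locus.alleles, ft.freqs[l]):
                if p > 0:
                    carrier.setdefault((l, a), set()).add(g)
        na_m, na_se = _mean_se(na)
        ne_m, ne_se = _mean_se(ne)
        ho_m, ho_se = _mean_se(ho)
        he_m, he_se = _mean_se(he)
        f_m, f_se = _mean_se(f_ix)
        rows.append(
            {
                "group": str(g),
                "n": int(mask.sum()),
                "na": na_m, "na_se": na_se,
                "ne": ne_m, "ne_se": ne_se,
                "pa": 0, "pa_freqs": "",
                "ho": ho_m, "ho_se": ho_se,
                "he": he_m, "he_se": he_se,
                "f": f_m, "f_se": f_se,
            }
        )

    table = pd.DataFrame(rows)
    for gi, g in enumerate(groups):
        ft = per_group_ft[g]
        pa_freqs = []
        for (l, a), owners in carrier.items():
            # a private allele needs other groups to be absent from
            if len(groups) > 1 and owners == {g}:
                j = dataset.loci[l].alleles.index(a)
                pa_freqs.append(float(ft.freqs[l][j]))
        table.loc[gi, "pa"] = len(pa_freqs)
        table.loc[gi, "pa_freqs"] = ";".join(f"{p:.17g}" for p in sorted(pa_freqs))
    table["pa"] = table["pa"].astype(int)
    return DiversityTable(table=table)
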