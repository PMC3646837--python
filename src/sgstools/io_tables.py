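"""Genotype tables, metadata and result-table I/O.

The canonical on-disk dialect is plain TSV:

* genotype file — columns ``id, <locus>.a1, <locus>.a2, ...`` (two allele
  columns per microsatellite locus, integer allele codes, ``0`` or blank =
  missing);
* meta file — columns ``id, plot, x, y, height_cm, clay_pct`` and optional
  ``size_class`` / ``soil_class`` columns.

A GenAlEx-style codominant layout (three header rows, two columns per locus)
is accepted for the genotype block via ``dialect="GENALEX"``.

All result tables are TSV with ``#``-prefixed provenance/header lines and are
re-readable losslessly (floats serialised with 17 significant digits).
"""

from __future__ import annotations

import dataclasses
import io
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__

MISSING = 0  # allele code reserved for "no call"

META_COLUMNS = ("plot", "height_cm", "clay_pct", "size_class", "soil_class")

_EARTH_RADIUS_M = 6_371_000.0


class SizeClass(str, Enum):
    """Ontogenetic size classes used throughout the analysis."""

    FIRST_YEAR = "FIRST_YEAR"        # seedlings up to 20 cm
    YOUNG = "YOUNG"                  # seedlings 21-40 cm
    SAPLING = "SAPLING"              # seedlings 41-100 cm
    ADULT_JUVENILE = "ADULT_JUVENILE"  # trees taller than 200 cm
    EXCLUDED = "EXCLUDED"            # the sparse 100-200 cm band


class SoilClass(str, Enum):
    SANDY = "SANDY"
    CLAY = "CLAY"


@dataclass(frozen=True)
class Locus:
    """A codominant locus with its registry of observed allele codes."""

    name: str
    alleles: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.alleles) < 1:
            raise ValueError(f"locus {self.name!r} has no alleles")
        if len(set(self.alleles)) != len(self.alleles):
            raise ValueError(f"locus {self.name!r} has duplicate allele codes")
        if MISSING in self.alleles:
            raise ValueError(f"allele code {MISSING} is reserved for missing data")


@dataclass
class GenotypeDataset:
    """Individuals x loci diploid calls plus planar coordinates and metadata.

    ``calls`` has shape ``(n, L, 2)``; a missing genotype is ``(0, 0)``.
    Half-missing calls are normalised to fully missing on construction: every
    downstream statistic works on diploid dosage vectors and cannot use a
    single called allele.
    """

    ids: list[str]
    loci: list[Locus]
    calls: np.ndarray
    x: np.ndarray
    y: np.ndarray
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.ids = list(map(str, self.ids))
        n, L = len(self.ids), len(self.loci)
        self.calls = np.asarray(self.calls, dtype=np.int64)
        if self.calls.shape != (n, L, 2):
            raise ValueError(f"calls shape {self.calls.shape} != {(n, L, 2)}")
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != (n,) or self.y.shape != (n,):
            raise ValueError("coordinate arrays must match the number of individuals")
        if not (np.isfinite(self.x).all() and np.isfinite(self.y).all()):
            raise ValueError("coordinates must be finite")
        if len(set(self.ids)) != n:
            dup = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise ValueError(f"duplicated individual ids: {dup}")
        # normalise half-missing genotypes to fully missing
        half = (self.calls == MISSING).any(axis=2)
        self.calls[half] = MISSING
        for j, locus in enumerate(self.loci):
            observed = set(self.calls[:, j, :].ravel()) - {MISSING}
            extra = observed - set(locus.alleles)
            if extra:
                raise ValueError(
                    f"locus {locus.name!r}: allele codes {sorted(extra)} not in registry"
                )
        if not isinstance(self.meta, pd.DataFrame):
            raise TypeError("meta must be a DataFrame")
        self.meta = self.meta.copy()
        self.meta.index = pd.Index(self.ids, name="id")
        for col in META_COLUMNS:
            if col not in self.meta.columns:
                self.meta[col] = np.nan
        clay = pd.to_numeric(self.meta["clay_pct"], errors="coerce")
        bad = clay.dropna()
        if ((bad < 0) | (bad > 100)).any():
            raise ValueError("clay_pct outside [0, 100]")

    # ------------------------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def locus_names(self) -> list[str]:
        return [l.name for l in self.loci]

    def missing_mask(self) -> np.ndarray:
        """Boolean (n, L) mask, True where the genotype is missing."""
        return (self.calls == MISSING).all(axis=2)

    def subset(self, index: Sequence[int] | np.ndarray) -> "GenotypeDataset":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeDataset(
            ids=[self.ids[i] for i in index],
            loci=list(self.loci),
            calls=self.calls[index].copy(),
            x=self.x[index].copy(),
            y=self.y[index].copy(),
            meta=self.meta.iloc[index].copy(),
        )

    def select(self, **criteria: object) -> "GenotypeDataset":
        """Subset by meta-column equality, e.g. ``select(size_class="YOUNG")``.

        A tuple/list/set value keeps rows matching any of its members.
        """
        mask = np.ones(self.n_individuals, dtype=bool)
        for col, val in criteria.items():
            colvals = self.meta[col].to_numpy()
            if isinstance(val, (tuple, list, set, frozenset)):
                wanted = {getattr(v, "value", v) for v in val}
                mask &= np.array([v in wanted for v in colvals])
            else:
                mask &= colvals == getattr(val, "value", val)
        return self.subset(mask)

    def __eq__(self, other: object) -> bool:  # full-precision structural equality
        if not isinstance(other, GenotypeDataset):
            return NotImplemented
        meta_a = self.meta[list(META_COLUMNS)]
        meta_b = other.meta[list(META_COLUMNS)]
        return (
            self.ids == other.ids
            and self.loci == other.loci
            and np.array_equal(self.calls, other.calls)
            and np.array_equal(self.x, other.x)
            and np.array_equal(self.y, other.y)
            and _frames_equal(meta_a, meta_b)
        )


def _frames_equal(a: pd.DataFrame, b: pd.DataFrame) -> bool:
    if list(a.columns) != list(b.columns) or len(a) != len(b):
        return False
    for col in a.columns:
        va, vb = a[col].to_numpy(), b[col].to_numpy()
        na = pd.isna(va)
        if not np.array_equal(na, pd.isna(vb)):
            return False
        if va[~na].dtype.kind in "fc" or vb[~na].dtype.kind in "fc":
            if not np.array_equal(va[~na].astype(float), vb[~na].astype(float)):
                return False
        else:
            if not all(str(x) == str(y) for x, y in zip(va[~na], vb[~na])):
                return False
    return True


def lonlat_to_local_xy(
    lon: np.ndarray, lat: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Project lon/lat (degrees) to planar metres.

    Local equirectangular projection about the point-cloud centroid; adequate
    for extents of a few kilometres, far below the 10 m distance-bin width.
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    lon0, lat0 = lon.mean(), lat.mean()
    x = np.radians(lon - lon0) * _EARTH_RADIUS_M * math.cos(math.radians(lat0))
    y = np.radians(lat - lat0) * _EARTH_RADIUS_M
    return x, y


# ----------------------------------------------------------------------
# genotype/meta readers and writers
# ----------------------------------------------------------------------

def _parse_allele(v: object) -> int:
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return MISSING
    s = str(v).strip()
    if s == "" or s.lower() in {"na", "nan"}:
        return MISSING
    return int(float(s))


def _read_registry_header(path: Path) -> dict[str, tuple[int, ...]]:
    """Allele registries recorded as ``# alleles <locus>=c1,c2,...`` lines."""
    registries: dict[str, tuple[int, ...]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            text = line[1:].strip()
            if text.startswith("alleles ") and "=" in text:
                name, codes = text[len("alleles "):].split("=", 1)
                registries[name.strip()] = tuple(
                    int(c) for c in codes.split(",") if c.strip()
                )
    return registries


def _read_plain_genotypes(path: Path) -> tuple[list[str], list[str], np.ndarray]:
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if df.columns[0] != "id":
        raise ValueError(f"{path}: first genotype column must be 'id'")
    allele_cols = list(df.columns[1:])
    if len(allele_cols) % 2 != 0:
        raise ValueError(f"{path}: odd number of allele columns ({len(allele_cols)})")
    locus_names: list[str] = []
    for c1, c2 in zip(allele_cols[::2], allele_cols[1::2]):
        n1 = c1.rsplit(".", 1)[0]
        n2 = c2.rsplit(".", 1)[0]
        if n1 != n2:
            raise ValueError(f"{path}: allele columns {c1!r}/{c2!r} do not pair")
        locus_names.append(n1)
    ids = df["id"].astype(str).tolist()
    raw = df[allele_cols].map(_parse_allele).to_numpy(dtype=np.int64)
    calls = raw.reshape(len(ids), len(locus_names), 2)
    return ids, locus_names, calls


def _read_genalex_genotypes(path: Path) -> tuple[list[str], list[str], np.ndarray]:
    # GenAlEx codominant export: row 1 = counts, row 2 = title, row 3 = headers
    # (sample, pop, then one label per locus spanning two columns), data after.
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip() != ""]
    if len(lines) < 4:
        raise ValueError(f"{path}: not a GenAlEx codominant table")
    header = lines[2].split("\t")
    locus_names = [h for h in header[2:] if h.strip() != ""]
    ids, rows = [], []
    for ln in lines[3:]:
        parts = ln.split("\t")
        ids.append(parts[0].strip())
        alleles = parts[2 : 2 + 2 * len(locus_names)]
        if len(alleles) < 2 * len(locus_names):
            raise ValueError(f"{path}: truncated genotype row for {parts[0]!r}")
        rows.append([_parse_allele(a) for a in alleles])
    calls = np.asarray(rows, dtype=np.int64).reshape(len(ids), len(locus_names), 2)
    return ids, locus_names, calls


def read_genotype_table(
    genotype_path: str | Path,
    meta_path: str | Path,
    dialect: str = "PLAIN_TSV",
) -> GenotypeDataset:
    """Read a genotype table plus its metadata table into a dataset.

    Allele registries are built from the observed codes. A cell coded ``0``
    (or blank) on either allele maps to MISSING at that locus.
    """
    genotype_path, meta_path = Path(genotype_path), Path(meta_path)
    if dialect == "PLAIN_TSV":
        ids, locus_names, calls = _read_plain_genotypes(genotype_path)
    elif dialect == "GENALEX":
        ids, locus_names, calls = _read_genalex_genotypes(genotype_path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"{genotype_path}: duplicated individual ids {dup}")

    meta = pd.read_csv(
        meta_path, sep="\t", dtype={"id": str}, comment="#",
        float_precision="round_trip",
    )
    if "id" not in meta.columns:
        raise ValueError(f"{meta_path}: missing 'id' column")
    if meta["id"].duplicated().any():
        dup = sorted(meta.loc[meta["id"].duplicated(), "id"].unique())
        raise ValueError(f"{meta_path}: duplicated individual ids {dup}")
    meta = meta.set_index("id")
    only_geno = sorted(set(ids) - set(meta.index))
    only_meta = sorted(set(meta.index) - set(ids))
    if only_geno or only_meta:
        raise ValueError(
            "id mismatch between genotype and meta tables; "
            f"genotype-only={only_geno} meta-only={only_meta}"
        )
    meta = meta.loc[ids]  # meta row order is irrelevant on disk

    half = (calls == MISSING).any(axis=2)
    calls[half] = MISSING
    registries = _read_registry_header(genotype_path)
    loci = []
    for j, name in enumerate(locus_names):
        if name in registries:
            loci.append(Locus(name, registries[name]))
            continue
        observed = tuple(sorted(set(calls[:, j, :].ravel()) - {MISSING}))
        # an all-missing locus keeps a placeholder registry entry; it carries
        # no calls so it never contributes to any statistic
        loci.append(Locus(name, observed if observed else (999999,)))

    x = pd.to_numeric(meta["x"]).to_numpy(dtype=float)
    y = pd.to_numeric(meta["y"]).to_numpy(dtype=float)
    keep = meta.drop(columns=["x", "y"])
    return GenotypeDataset(ids=ids, loci=loci, calls=calls, x=x, y=y, meta=keep)


def write_genotype_tables(
    dataset: GenotypeDataset,
    genotype_path: str | Path,
    meta_path: str | Path,
) -> None:
    """Write the canonical PLAIN_TSV genotype + meta files.

    The allele registry of each locus is recorded in ``#`` header lines so a
    re-read restores registries exactly (including alleles unobserved in the
    written subset).
    """
    cols: dict[str, object] = {"id": dataset.ids}
    for j, locus in enumerate(dataset.loci):
        cols[f"{locus.name}.a1"] = dataset.calls[:, j, 0]
        cols[f"{locus.name}.a2"] = dataset.calls[:, j, 1]
    with open(genotype_path, "w") as fh:
        for locus in dataset.loci:
            fh.write(f"# alleles {locus.name}={','.join(map(str, locus.alleles))}\n")
        pd.DataFrame(cols).to_csv(fh, sep="\t", index=False)

    meta = dataset.meta.copy()
    meta.insert(0, "x", dataset.x)
    meta.insert(1, "y", dataset.y)
    meta = meta.reset_index()
    order = ["id", "plot", "x", "y", "height_cm", "clay_pct", "size_class", "soil_class"]
    extra = [c for c in meta.columns if c not in order]
    meta[order + extra].to_csv(
        meta_path, sep="\t", index=False, float_format="%.17g"
    )


# ----------------------------------------------------------------------
# result tables
# ----------------------------------------------------------------------

def _fmt(v: object) -> str:
    if v is None:
        return ""
    if isinstance(v, float):
        if math.isnan(v):
            return ""
        return f"{v:.17g}"
    return str(v)


def _provenance_lines(result_type: str, scalars: Mapping[str, object]) -> list[str]:
    lines = [f"# sgstools {__version__}", f"# type={result_type}"]
    for k, v in scalars.items():
        lines.append(f"# {k}={_fmt(v)}")
    return lines


def write_result_table(result: object, path: str | Path) -> None:
    """Write any finalized result object as a provenance-headed TSV."""
    from .sgs_core import Correlogram
    from .kinship import KinshipCurve
    from .heterogeneity import HeterogeneityResult
    from .diversity import DiversityTable

    path = Path(path)
    if isinstance(result, Correlogram):
        scalars = {
            "edges": ",".join(_fmt(float(e)) for e in result.edges),
            "omega": result.omega,
            "p_omega": result.p_omega,
            "n_perm": result.n_perm,
            "n_boot": result.n_boot,
            "seed": result.seed,
        }
        df = result.to_frame()
        _write_tsv(path, _provenance_lines("Correlogram", scalars), df)
    elif isinstance(result, KinshipCurve):
        scalars = {
            "mode": result.mode,
            "edges": ",".join(_fmt(float(e)) for e in result.edges),
        }
        _write_tsv(path, _provenance_lines("KinshipCurve", scalars), result.to_frame())
    elif isinstance(result, HeterogeneityResult):
        scalars = {
            "label_a": result.label_a,
            "label_b": result.label_b,
            "edges": ",".join(_fmt(float(e)) for e in result.edges),
            "omega": result.omega,
            "p_omega": result.p_omega,
            "n_perm": result.n_perm,
            "seed": result.seed,
        }
        _write_tsv(
            path, _provenance_lines("HeterogeneityResult", scalars), result.to_frame()
        )
    elif isinstance(result, DiversityTable):
        _write_tsv(path, _provenance_lines("DiversityTable", {}), result.to_frame())
    else:
        raise TypeError(f"cannot serialise result of type {type(result).__name__}")


def _write_tsv(path: Path, header: list[str], df: pd.DataFrame) -> None:
    buf = io.StringIO()
    for line in header:
        buf.write(line + "\n")
    df.to_csv(buf, sep="\t", index=False, float_format="%.17g", na_rep="")
    path.write_text(buf.getvalue())


def _read_tagged_tsv(path: str | Path) -> tuple[str, dict[str, str], pd.DataFrame]:
    path = Path(path)
    scalars: dict[str, str] = {}
    rtype = ""
    body: list[str] = []
    for line in path.read_text().splitlines():
        if line.startswith("#"):
            text = line[1:].strip()
            if "=" in text:
                k, v = text.split("=", 1)
                if k.strip() == "type":
                    rtype = v.strip()
                else:
                    scalars[k.strip()] = v.strip()
        else:
            body.append(line)
    df = (
        pd.read_csv(
            io.StringIO("\n".join(body)), sep="\t", float_precision="round_trip"
        )
        if body and body[0]
        else pd.DataFrame()
    )
    return rtype, scalars, df


def _scalar_float(scalars: Mapping[str, str], key: str) -> float:
    v = scalars.get(key, "")
    return float(v) if v != "" else math.nan


def read_result_table(path: str | Path) -> object:
    """Re-read a result TSV written by :func:`write_result_table`."""
    from .sgs_core import Correlogram
    from .kinship import KinshipCurve
    from .heterogeneity import HeterogeneityResult
    from .diversity import DiversityTable

    rtype, scalars, df = _read_tagged_tsv(path)
    edges = tuple(
        float(e) for e in scalars.get("edges", "").split(",") if e != ""
    )

    def col(name: str, dtype=float) -> np.ndarray:
        if name not in df.columns or len(df) == 0:
            return np.zeros(0, dtype=dtype)
        return pd.to_numeric(df[name], errors="coerce").to_numpy(dtype=dtype)

    if rtype == "Correlogram":
        n = len(df)
        return Correlogram(
            edges=np.asarray(edges[:n] if n else edges),
            n_pairs=col("n_pairs", float).astype(int),
            r=col("r"),
            perm_lo=col("perm_lo"),
            perm_hi=col("perm_hi"),
            boot_lo=col("boot_lo"),
            boot_hi=col("boot_hi"),
            p=col("p"),
            omega=_scalar_float(scalars, "omega"),
            p_omega=_scalar_float(scalars, "p_omega"),
            n_perm=int(scalars.get("n_perm", 0)),
            n_boot=int(scalars.get("n_boot", 0)),
            seed=int(scalars.get("seed", 0)),
        )
    if rtype == "KinshipCurve":
        return KinshipCurve(
            mode=scalars.get("mode", ""),
            edges=np.asarray(edges),
            n_pairs=col("n_pairs", float).astype(int),
            mean_fij=col("mean_fij"),
            mean_r=col("mean_r"),
        )
    if rtype == "HeterogeneityResult":
        return HeterogeneityResult(
            label_a=scalars.get("label_a", ""),
            label_b=scalars.get("label_b", ""),
            edges=np.asarray(edges),
            t2=col("t2"),
            p=col("p"),
            bias_a=col("bias_a"),
            bias_b=col("bias_b"),
            var_a=col("var_a"),
            var_b=col("var_b"),
            omega=_scalar_float(scalars, "omega"),
            p_omega=_scalar_float(scalars, "p_omega"),
            n_perm=int(scalars.get("n_perm", 0)),
            seed=int(scalars.get("seed", 0)),
        )
    if rtype == "DiversityTable":
        return DiversityTable(table=df)
    raise ValueError(f"{path}: unknown or missing result type tag {rtype!r}")
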