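"""Study orchestration: classification rules and the full analysis bundle.

Individuals are classified by height into ontogenetic classes (first-year
seedlings up to 20 cm, young seedlings to 40 cm, saplings to 100 cm, the
sparse 100-200 cm band excluded, juveniles/adults above 200 cm) and plots
into soil strata at 15% clay. ``run_study`` chains every analysis stage —
diversity tables, per-class and pooled correlograms, pairwise heterogeneity
tests, soil-stratified correlograms and within/between-generation kinship
curves — from one config, with per-stage seeds derived from the master seed.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .diversity import diversity_summary
from .heterogeneity import correlogram_heterogeneity
from .io_tables import (
    GenotypeDataset,
    SizeClass,
    SoilClass,
    read_genotype_table,
    write_result_table,
)
from .kinship import kinship_correlogram
from .sgs_core import DistanceClassSpec, spatial_correlogram

SEEDLING_CLASSES = ("FIRST_YEAR", "YOUNG", "SAPLING")
ANALYSIS_CLASSES = SEEDLING_CLASSES + ("ADULT_JUVENILE",)


def assign_size_class(
    height_cm: float, edges: Sequence[float] = (20.0, 40.0, 100.0, 200.0)
) -> SizeClass:
    """Map a height (cm) to its ontogenetic class.

    [0, 20] first-year; (20, 40] young; (40, 100] sapling; (100, 200]
    excluded (too few individuals in the field study); > 200 juvenile/adult.
    """
    if height_cm < 0:
        raise ValueError(f"negative height: {height_cm}")
    e1, e2, e3, e4 = edges
    if height_cm <= e1:
        return SizeClass.FIRST_YEAR
    if height_cm <= e2:
        return SizeClass.YOUNG
    if height_cm <= e3:
        return SizeClass.SAPLING
    if height_cm <= e4:
        return SizeClass.EXCLUDED
    return SizeClass.ADULT_JUVENILE


def classify_soil(clay_pct: float, threshold: float = 15.0) -> SoilClass:
    """Soil stratum from clay content; the exact-threshold tie goes to SANDY."""
    if not 0.0 <= clay_pct <= 100.0:
        raise ValueError(f"clay_pct outside [0, 100]: {clay_pct}")
    return SoilClass.CLAY if clay_pct > threshold else SoilClass.SANDY


def annotate(
    dataset: GenotypeDataset,
    height_edges: Sequence[float] = (20.0, 40.0, 100.0, 200.0),
    clay_threshold: float = 15.0,
) -> GenotypeDataset:
    """Fill missing size_class (from height) and soil_class (from clay).

    A size_class already present in the meta table wins over height — adults
    are recorded by class (measured by DBH), not by height.
    """
    ds = dataset.subset(np.arange(dataset.n_individuals))
    sc = ds.meta["size_class"].astype(object)
    for i, iid in enumerate(ds.ids):
        if pd.isna(sc.iloc[i]):
            h = ds.meta["height_cm"].iloc[i]
            if pd.isna(h):
                raise ValueError(f"{iid}: neither size_class nor height_cm present")
            sc.iloc[i] = assign_size_class(float(h), height_edges).value
    ds.meta["size_class"] = sc
    soil = ds.meta["soil_class"].astype(object)
    for i, iid in enumerate(ds.ids):
        if pd.isna(soil.iloc[i]):
            clay = ds.meta["clay_pct"].iloc[i]
            if not pd.isna(clay):
                soil.iloc[i] = classify_soil(float(clay), clay_threshold).value
    ds.meta["soil_class"] = soil
    return ds


def filter_analysis_plots(
    dataset: GenotypeDataset, min_per_class: int = 2
) -> GenotypeDataset:
    """Keep plots with at least ``min_per_class`` individuals in some size
    class (pairwise statistics need pairs within a plot)."""
    counts = (
        dataset.meta.groupby(["plot", "size_class"], observed=True)
        .size()
        .unstack(fill_value=0)
    )
    cols = [c for c in counts.columns if c in ANALYSIS_CLASSES]
    keep_plots = set(counts.index[(counts[cols] >= min_per_class).any(axis=1)])
    mask = dataset.meta["plot"].isin(keep_plots).to_numpy()
    return dataset.subset(mask)


# ----------------------------------------------------------------------

@dataclass
class StudyConfig:
    """One config for the whole analysis bundle."""

    genotypes: str | None = None
    meta: str | None = None
    out_dir: str | None = None
    coarse_edges: Sequence[float] = (50.0, 100.0, 150.0, 200.0, 250.0)
    fine_edges: Sequence[float] = tuple(10.0 * k for k in range(1, 26))
    height_edges: Sequence[float] = (20.0, 40.0, 100.0, 200.0)
    clay_threshold: float = 15.0
    min_per_class: int = 2
    soil_subset_classes: Sequence[str] = ("FIRST_YEAR", "YOUNG")
    n_perm: int = 999
    n_boot: int = 999
    seed: int = 0

    def __post_init__(self) -> None:
        DistanceClassSpec(tuple(self.coarse_edges))
        DistanceClassSpec(tuple(self.fine_edges))
        if self.clay_threshold <= 0:
            raise ValueError("clay_threshold must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**payload)


class StageError(RuntimeError):
    """An analysis stage failed; carries the stage name and partial bundle."""

    def __init__(self, stage: str, original: Exception, partial: dict):
        super().__init__(f"stage {stage!r} failed: {original}")
        self.stage = stage
        self.partial = partial


def stage_seed(master: int, name: str) -> int:
    """Deterministic per-stage seed below 2**31 derived from the master seed."""
    return int(
        np.random.SeedSequence([int(master), zlib.crc32(name.encode())])
        .generate_state(1)[0]
        % (2**31)
    )


def run_study(
    config: StudyConfig, dataset: GenotypeDataset | None = None
) -> dict[str, object]:
    """Run every stage of the study and return the result bundle.

    The orchestrator only composes module operations; rerunning any stage
    alone with ``stage_seed(config.seed, name)`` reproduces its entry.
    With ``config.out_dir`` set, every result is also written as TSV next to
    a provenance log.
    """
    bundle: dict[str, object] = {}
    coarse = DistanceClassSpec(tuple(config.coarse_edges))
    fine = DistanceClassSpec(tuple(config.fine_edges))

    def stage(name: str, fn):
        try:
            bundle[name] = fn()
        except Exception as exc:  # noqa: BLE001 - abort with stage context
            raise StageError(name, exc, dict(bundle)) from exc

    if dataset is None:
        if config.genotypes is None or config.meta is None:
            raise ValueError("either a dataset or genotype/meta paths are required")
        stage(
            "load",
            lambda: read_genotype_table(config.genotypes, config.meta),
        )
        dataset = bundle.pop("load")
    ds = annotate(dataset, config.height_edges, config.clay_threshold)
    ds = filter_analysis_plots(ds, config.min_per_class)
    bundle["n_individuals"] = ds.n_individuals
    bundle["n_plots"] = int(ds.meta["plot"].nunique())

    stage("diversity_size", lambda: diversity_summary(ds, "size_class"))
    stage("diversity_soil", lambda: diversity_summary(ds, "soil_class"))

    def correlogram_of(subset, spec, name):
        return spatial_correlogram(
            subset,
            spec,
            n_perm=config.n_perm,
            n_boot=config.n_boot,
            seed=stage_seed(config.seed, name),
        )

    for cls in ANALYSIS_CLASSES:
        name = f"correlogram_{cls}"
        stage(name, lambda c=cls, n=name: correlogram_of(ds.select(size_class=c), coarse, n))

    pooled_small = ds.select(size_class=("FIRST_YEAR", "YOUNG"))
    pooled_large = ds.select(size_class=("SAPLING", "ADULT_JUVENILE"))
    all_analysis = ds.select(size_class=ANALYSIS_CLASSES)
    stage(
        "correlogram_le40_fine",
        lambda: correlogram_of(pooled_small, fine, "correlogram_le40_fine"),
    )
    stage(
        "correlogram_gt40_fine",
        lambda: correlogram_of(pooled_large, fine, "correlogram_gt40_fine"),
    )
    stage(
        "correlogram_all_fine",
        lambda: correlogram_of(all_analysis, fine, "correlogram_all_fine"),
    )

    for a, b in itertools.combinations(ANALYSIS_CLASSES, 2):
        name = f"het_{a}_vs_{b}"
        stage(
            name,
            lambda a=a, b=b, n=name: correlogram_heterogeneity(
                ds.select(size_class=a),
                ds.select(size_class=b),
                coarse,
                n_perm=config.n_perm,
                seed=stage_seed(config.seed, n),
                labels=(a, b),
            ),
        )

    seedlings = ds.select(size_class=tuple(config.soil_subset_classes))
    clay_ds = seedlings.select(soil_class="CLAY")
    sand_ds = seedlings.select(soil_class="SANDY")
    stage(
        "correlogram_clay",
        lambda: correlogram_of(clay_ds, coarse, "correlogram_clay"),
    )
    stage(
        "correlogram_sand",
        lambda: correlogram_of(sand_ds, coarse, "correlogram_sand"),
    )
    stage(
        "het_soil",
        lambda: correlogram_heterogeneity(
            sand_ds,
            clay_ds,
            coarse,
            n_perm=config.n_perm,
            seed=stage_seed(config.seed, "het_soil"),
            labels=("SANDY", "CLAY"),
        ),
    )

    for cls in SEEDLING_CLASSES:
        stage(
            f"kinship_within_{cls}",
            lambda c=cls: kinship_correlogram(all_analysis, coarse, f"within:{c}"),
        )
        stage(
            f"kinship_between_{cls}",
            lambda c=cls: kinship_correlogram(all_analysis, coarse, f"between:{c}"),
        )
    stage("kinship_all", lambda: kinship_correlogram(all_analysis, coarse, "all"))

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, result in bundle.items():
            if isinstance(result, (int, float)):
                continue
            write_result_table(result, out / f"{name}.tsv")
        provenance = {
            "package": f"sgstools {__version__}",
            "seed": config.seed,
            "n_perm": config.n_perm,
            "n_boot": config.n_boot,
            "config": {
                k: (list(v) if isinstance(v, (tuple, list)) else v)
                for k, v in dataclasses.asdict(config).items()
            },
            "stages": [k for k in bundle],
        }
        (out / "provenance.json").write_text(json.dumps(provenance, indent=1))
    return bundle
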