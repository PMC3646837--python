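#!/usr/bin/env python
"""Within- versus between-generation kinship curves.

For each seedling size class, bins pairwise Loiselle kinship by ground
distance twice: among seedlings of that class (within-generation) and
between those seedlings and the juvenile/adult class (between-generation).
When within-generation kinship exceeds between-generation kinship at short
range, seedlings share parents that are not the sampled adults.
"""

import argparse
import importlib.util
from pathlib import Path

from sgstools.io_tables import write_result_table
from sgstools.kinship import kinship_correlogram
from sgstools.pipeline import SEEDLING_CLASSES
from sgstools.sgs_core import DistanceClassSpec

_loader = importlib.util.spec_from_file_location(
    "diversity_script", Path(__file__).parent / "02_genetic_diversity.py"
)
_mod = importlib.util.module_from_spec(_loader)
_loader.loader.exec_module(_mod)
load_dataset = _mod.load_dataset

COARSE = DistanceClassSpec.regular(50.0, 250.0)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data-dir", type=Path, default=Path("results/data"))
    ap.add_argument("--out-dir", type=Path, default=Path("results/tables"))
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    ds = load_dataset(args.data_dir)
    all_classes = ds.select(
        size_class=("FIRST_YEAR", "YOUNG", "SAPLING", "ADULT_JUVENILE")
    )
    for cls in SEEDLING_CLASSES:
        within = kinship_correlogram(all_classes, COARSE, f"within:{cls}")
        between = kinship_correlogram(all_classes, COARSE, f"between:{cls}")
        write_result_table(within, args.out_dir / f"kinship_within_{cls}.tsv")
        write_result_table(between, args.out_dir / f"kinship_between_{cls}.tsv")
        print(
            f"{cls}: class-1 mean r within={within.mean_r[0]:+.3f} "
            f"(n={within.n_pairs[0]}), vs adults={between.mean_r[0]:+.3f} "
            f"(n={between.n_pairs[0]})"
        )
    curve = kinship_correlogram(all_classes, COARSE, "all")
    write_result_table(curve, args.out_dir / "kinship_all.tsv")
    print(f"all pairs: class-1 mean r={curve.mean_r[0]:+.3f} (n={curve.n_pairs[0]})")
    print(f"wrote kinship curves to {args.out_dir}/")


if __name__ == "__main__":
    main()
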