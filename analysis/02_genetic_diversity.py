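#!/usr/bin/env python
"""Per-group genetic diversity summaries.

Computes sample size, mean alleles per locus (Na), effective alleles (Ne),
private alleles (Pa), observed/expected heterozygosity and the fixation
index per size class and per soil stratum, writing both tables under
results/tables/.
"""

import argparse
from pathlib import Path

from sgstools.diversity import diversity_summary
from sgstools.io_tables import read_genotype_table, write_result_table
from sgstools.pipeline import annotate, filter_analysis_plots


def load_dataset(data_dir: Path):
    geno, meta = data_dir / "genotypes.tsv", data_dir / "meta.tsv"
    if not geno.exists():
        raise SystemExit(f"{geno} not found - run analysis/01_simulate_landscape.py first")
    return filter_analysis_plots(annotate(read_genotype_table(geno, meta)))


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data-dir", type=Path, default=Path("results/data"))
    ap.add_argument("--out-dir", type=Path, default=Path("results/tables"))
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    ds = load_dataset(args.data_dir)
    for grouping, name in (("size_class", "diversity_size"), ("soil_class", "diversity_soil")):
        table = diversity_summary(ds, grouping)
        write_result_table(table, args.out_dir / f"{name}.tsv")
        print(f"-- by {grouping}:")
        cols = ["group", "n", "na", "ne", "pa", "ho", "he", "f"]
        print(table.table[cols].round(3).to_string(index=False))
    print(f"wrote diversity tables to {args.out_dir}/")


if __name__ == "__main__":
    main()
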