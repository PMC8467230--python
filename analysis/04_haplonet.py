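#!/usr/bin/env python
"""Summarise the per-species ITS haplotype networks.

Reads the haplotype tables and MSN edge lists the pipeline wrote and
reports, per species: haplotype count, main-haplotype composition
(whether the dominant consensus and its reference share a haplotype) and
the mutational-step range of the network edges.  Writes
results/tables/haplotype_summary.tsv.
"""

import argparse
import glob
import os

import pandas as pd

import rdnavar as rv


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--pipeline", default="results/pipeline")
    ap.add_argument("--outdir", default="results/tables")
    args = ap.parse_args()

    rows = []
    for path in sorted(glob.glob(f"{args.pipeline}/haplotypes_*.tsv")):
        species = os.path.basename(path)[len("haplotypes_"):-len(".tsv")]
        haps = pd.read_csv(path, sep="\t")
        edges = pd.read_csv(
            f"{args.pipeline}/network_edges_{species}.tsv", sep="\t")
        main = haps.iloc[0]
        rows.append({
            "species": species,
            "n_haplotypes": len(haps),
            "main_frequency": int(main["frequency"]),
            "main_includes_reference": main["source_class"] == "both",
            "n_edges": len(edges),
            "steps_min": int(edges["steps"].min()) if len(edges) else 0,
            "steps_max": int(edges["steps"].max()) if len(edges) else 0,
        })
    df = pd.DataFrame(rows)
    os.makedirs(args.outdir, exist_ok=True)
    rv.write_table(df, f"{args.outdir}/haplotype_summary.tsv")

    print(df.to_string(index=False))
    print(f"\nhaplotypes per species: {df['n_haplotypes'].min()}-"
          f"{df['n_haplotypes'].max()}; the main haplotype includes the "
          f"reference sequences in "
          f"{int(df['main_includes_reference'].sum())}/{len(df)} species")


if __name__ == "__main__":
    main()
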