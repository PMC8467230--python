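#!/usr/bin/env python
"""Species identification from the major variants, plus an NJ QC tree.

Summarises the pipeline's combined-region nearest-reference
classification of each strain's max-read consensuses, demonstrates how a
cross-species minor variant is flagged as an outlier, and writes a
neighbour-joining tree over the major ITS consensuses and references to
results/tables/nj_major_ITS.nwk.
"""

import argparse
import os

import numpy as np
import pandas as pd

import rdnavar as rv


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--sim", default="results/sim")
    ap.add_argument("--pipeline", default="results/pipeline")
    ap.add_argument("--outdir", default="results/tables")
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    cls = pd.read_csv(f"{args.pipeline}/classification.tsv", sep="\t")
    conc = (cls["flag"] == "concordant").mean()
    print(f"max-read consensus classification: {100 * conc:.0f}% of "
          f"{len(cls)} strains concordant "
          f"(min margin {cls['margin'].min():.3f})")

    refs = rv.read_references(f"{args.sim}/references.fasta")
    its_refs = [r for r in refs if r.region == "ITS"]

    # a minor variant drifted toward another species is flagged outlier
    rng = np.random.default_rng(args.seed)
    donor, origin = its_refs[0], its_refs[-1]
    minor = rv.mutate_haplotype(donor.seq, 0.02, rng)
    res = rv.classify("injected-minor", minor, "ITS", refs,
                      origin=origin.species)
    print(f"injected minor (origin {origin.species}, drifted to "
          f"{donor.species}): assigned {res.assigned}, flag={res.flag}")

    # NJ tree over major consensuses + references for visual QC
    labels, seqs = [], []
    for strain in sorted(cls["strain"]):
        cons = rv.read_fastx(f"{args.pipeline}/{strain}_ITS_consensus.fasta")
        major = next(c for c in cons if c.id.endswith("-C1"))  # largest
        labels.append(major.id)
        seqs.append(major.seq)
    for r in its_refs:
        labels.append(r.id)
        seqs.append(r.seq)
    tree = rv.nj_tree(rv.p_distance_matrix(labels, seqs))
    os.makedirs(args.outdir, exist_ok=True)
    with open(f"{args.outdir}/nj_major_ITS.nwk", "w") as fh:
        fh.write(tree + "\n")
    print(f"NJ tree over {len(labels)} sequences -> "
          f"{args.outdir}/nj_major_ITS.nwk")


if __name__ == "__main__":
    main()
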