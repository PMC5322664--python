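#!/usr/bin/env python
"""Coancestry painting and admixture flags on the simulated panel.

Paints every strain against all others with the copying-model HMM, writes
the chunk-count coancestry matrix, aggregates it by lineage (heat-map), and
flags admixture candidates. If the generator's truth table is present the
flags are scored against it.
"""

import argparse
from pathlib import Path

import pandas as pd

from andromix.chunk_painting import (
    PaintingParams,
    admixture_flags,
    aggregate_by_lineage,
    coancestry_matrix,
)
from andromix.genotypes_io import (
    attach_metadata,
    read_haplotypes,
    read_metadata,
)


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--vcf", type=Path, default=Path("results/panel.vcf"))
    parser.add_argument("--meta", type=Path,
                        default=Path("results/panel_meta.tsv"))
    parser.add_argument("--recomb-scale", type=float, default=1e-5)
    parser.add_argument("--theta", type=float, default=0.05)
    parser.add_argument("--threshold", type=float, default=0.25)
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    matrix = attach_metadata(read_haplotypes(args.vcf),
                             read_metadata(args.meta))
    params = PaintingParams(recomb_scale=args.recomb_scale,
                            miscopy_prob=args.theta)
    cm = coancestry_matrix(matrix, params)
    cm.to_frame().to_csv(args.out / "chunkcounts.tsv", sep="\t")

    agg = aggregate_by_lineage(cm, out_prefix=str(args.out) + "/")
    print("lineage-aggregated mean chunk counts:")
    print(agg.round(2).to_string())

    flags = admixture_flags(cm, threshold=args.threshold)
    flags.to_csv(args.out / "admixture_flags.tsv", sep="\t", index=False)
    candidates = flags[flags["admixture_candidate"]]
    print(f"\n{len(candidates)} admixture candidate(s) at threshold "
          f"{args.threshold}:")
    if len(candidates):
        print(candidates[["strain", "lineage", "top_foreign_lineage",
                          "top_foreign_fraction"]].to_string(index=False))

    truth_path = args.out / "admixed_truth.tsv"
    if truth_path.exists():
        truth = pd.read_csv(truth_path, sep="\t")
        merged = flags.merge(truth, left_on="strain", right_on="strain_id")
        tp = (merged.admixture_candidate & merged.true_admixed).sum()
        fn = (~merged.admixture_candidate & merged.true_admixed).sum()
        tn = (~merged.admixture_candidate & ~merged.true_admixed).sum()
        fp = (merged.admixture_candidate & ~merged.true_admixed).sum()
        print(f"\nvs truth: sensitivity {tp / max(tp + fn, 1):.2f}, "
              f"specificity {tn / max(tn + fp, 1):.2f}")
    print(f"written to {args.out}/chunkcounts.tsv, lineage_coancestry.tsv, "
          "coancestry_heatmap.png, admixture_flags.tsv")


if __name__ == "__main__":
    main()
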