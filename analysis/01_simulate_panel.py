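#!/usr/bin/env python
"""Simulate the study panel: four divergent lineages plus recent C x D
admixture.

Generates a partially selfing island population split into four lineages
(A-D, independent colonizations), samples isogenic strains from each, and
adds a small group of recently admixed C x D mosaic strains filed under
lineage D (as admixed strains present in nature would be). Writes the
haplotype panel as VCF, the strain metadata TSV, and the true per-strain
admixed status for later comparison.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from andromix.genotypes_io import write_haplotypes, write_metadata
from andromix.synthetic_data import (
    AdmixtureDesign,
    SimulationConfig,
    concat_strains,
    simulate_admixed_mosaic,
    simulate_divergent_lineages,
)

# one representative sampling locality per lineage (A: north-east lowland,
# B: montane plateau, C: south-west, D: north-east humid; admixed strains
# come from the C/D contact zone)
LINEAGE_LOCALITY = {"A": "SB", "B": "CC", "C": "TB", "D": "GE"}
LOCALITY_CLIMATE = {"SB": "warm", "CC": "cold", "TB": "mid-cold",
                    "GE": "mid-warm"}


def build_panel(seed: int):
    cfg = SimulationConfig(n_individuals=100, n_generations=800,
                           n_sampled_strains=15, seq_length=150_000,
                           n_contigs=6, selfing_rate=0.9, seed=seed)
    panel = simulate_divergent_lineages(cfg, n_lineages=4,
                                        split_generations=1500)
    src_c = panel.take_strains(
        [i for i, l in enumerate(panel.lineages) if l == "C"])
    src_d = panel.take_strains(
        [i for i, l in enumerate(panel.lineages) if l == "D"])
    design = AdmixtureDesign(src_c, src_d, n_admixed=5,
                             generations_since_cross=4, seed=seed + 1,
                             recomb_rate=1.0 / cfg.seq_length, label="D")
    admixed = simulate_admixed_mosaic(design)
    full = concat_strains([panel, admixed]).drop_monomorphic()
    truth = pd.DataFrame({
        "strain_id": full.strains,
        "true_admixed": [s.startswith("X") for s in full.strains],
    })
    return full, truth


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=2024)
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    panel, truth = build_panel(args.seed)
    write_haplotypes(panel, args.out / "panel.vcf")
    meta = pd.DataFrame({
        "strain_id": panel.strains,
        "lineage": panel.lineages,
        "locality": [LINEAGE_LOCALITY[l] for l in panel.lineages],
        "climate_group": [LOCALITY_CLIMATE[LINEAGE_LOCALITY[l]]
                          for l in panel.lineages],
    })
    write_metadata(meta, args.out / "panel_meta.tsv")
    truth.to_csv(args.out / "admixed_truth.tsv", sep="\t", index=False)

    counts = pd.Series(panel.lineages).value_counts().sort_index()
    print(f"panel: {panel.n_strains} strains, {panel.n_sites} sites on "
          f"{len(panel.contig_ids())} contigs")
    print("strains per lineage:", dict(counts))
    print(f"admixed strains: {int(truth['true_admixed'].sum())} "
          "(filed under lineage D)")
    print(f"written to {args.out}/panel.vcf, panel_meta.tsv, "
          "admixed_truth.tsv")


if __name__ == "__main__":
    main()
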