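#!/usr/bin/env python
"""Filter each synthetic species and compute the per-gene index tables.

Reads the FASTA panels written by 01_simulate_battery.py, applies the
structural CDS filter, and writes per-species gene_indices.tsv (ENC, SCUO,
MILC, CAI, GC fractions, skews, protein properties, ...) plus pooled
RSCU/RFSC tables and high-frequency codon calls, via the same library
entry points the pipeline CLI uses.  Prints a compact per-species summary.
"""

import argparse
from pathlib import Path

import pandas as pd

from cubkit.pipeline import analyse_species
from cubkit.sequence_io import filter_cds, read_cds


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--indir", type=Path, default=Path("results/synthetic"))
    parser.add_argument("--outdir", type=Path, default=Path("results/per_species"))
    args = parser.parse_args()

    fastas = sorted(args.indir.glob("*.fasta"))
    if not fastas:
        raise SystemExit(f"no FASTA inputs under {args.indir}; run 01 first")

    summaries = []
    for fasta in fastas:
        species = fasta.stem
        cds_set, report = filter_cds(read_cds(fasta, species=species))
        results = analyse_species(cds_set, args.outdir / species)
        df = results["index_table"]
        summaries.append(
            {
                "species": species,
                "n_genes": len(cds_set),
                "rejected": report.rejected,
                "mean_ENC": df["ENC"].mean(),
                "mean_SCUO": df["SCUO"].mean(),
                "mean_MILC": df["MILC"].mean(),
                "mean_GC3s": df["GC3s"].mean(),
                "n_hf_codons": len(results["hf"].codons),
                "n_optimal": len(results["optimal"]),
            }
        )
    summary = pd.DataFrame(summaries)
    args.outdir.mkdir(parents=True, exist_ok=True)
    summary.to_csv(args.outdir / "summary.tsv", sep="\t", index=False,
                   float_format="%.4f")
    print(summary.to_string(index=False, float_format=lambda x: f"{x:.3f}"))


if __name__ == "__main__":
    main()
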