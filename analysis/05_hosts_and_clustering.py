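#!/usr/bin/env python
"""Heterologous-host comparison and RSCU-based clustering of the panel.

Compares each synthetic species' per-thousand codon frequencies against
the packaged host tables (E. coli, S. cerevisiae, N. tabacum,
A. thaliana; synthetic snapshots), counts divergent codons (ratio <= 0.5
or >= 2), computes the shared high-frequency codon set of the AT-rich
species, and clusters all species by pooled RSCU (squared Euclidean,
between-groups average linkage).  Writes results/comparative/.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from cubkit.classes import high_frequency_codons, shared_hf
from cubkit.comparative import (
    HOST_NAMES,
    host_divergence,
    load_host_table,
    per_thousand_frequency,
    rscu_cluster,
)
from cubkit.composition import codon_counts
from cubkit.indices import rfsc, rscu
from cubkit.sequence_io import filter_cds, read_cds


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--indir", type=Path, default=Path("results/synthetic"))
    parser.add_argument("--outdir", type=Path, default=Path("results/comparative"))
    args = parser.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    sets = {}
    for fasta in sorted(args.indir.glob("*.fasta")):
        species = fasta.stem
        sets[species], _ = filter_cds(read_cds(fasta, species=species))

    rows = []
    for species, cds_set in sets.items():
        freq = per_thousand_frequency(codon_counts(cds_set), source=species)
        for host in HOST_NAMES:
            comp = host_divergence(freq, load_host_table(host))
            rows.append(
                {"species": species, "host": host,
                 "n_divergent": comp.n_divergent,
                 "pct_of_64": 100 * comp.n_divergent / 64}
            )
    hosts_df = pd.DataFrame(rows)
    hosts_df.to_csv(args.outdir / "host_divergence.tsv", sep="\t",
                    index=False, float_format="%.2f")
    pivot = hosts_df.pivot(index="species", columns="host", values="n_divergent")
    print("divergent codons (of 64) per species x host:")
    print(pivot.to_string())
    best = pivot.loc[["mut_gc35"]].idxmin(axis=1).iloc[0]
    print(f"\nfewest divergences for the AT-rich species: {best}")

    at_rich = [f"regimeA_{j}" for j in (1, 2, 3)]
    hf_sets = [
        high_frequency_codons(rfsc(codon_counts(sets[s])), species=s)
        for s in at_rich
    ]
    shared = shared_hf(hf_sets)
    (args.outdir / "shared_hf.tsv").write_text(
        "codon\n" + "".join(f"{c}\n" for c in sorted(shared))
    )
    print(f"\nshared HF codons across {at_rich}: {sorted(shared)}")

    matrix = pd.DataFrame.from_dict(
        {
            s: {c: (v if v is not None else np.nan)
                for c, v in rscu(codon_counts(cs)).values.items()}
            for s, cs in sets.items()
        },
        orient="index",
    )
    tree = rscu_cluster(matrix)
    (args.outdir / "rscu_cluster.nwk").write_text(tree.newick() + "\n")
    print(f"\nRSCU dendrogram ({len(tree.leaves)} leaves): {tree.newick()}")


if __name__ == "__main__":
    main()
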