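"""End-to-end orchestration of the codon-usage analysis.

``run_pipeline`` takes a :class:`PipelineConfig` naming one input file per
species and writes, per species: the filtered CDS set with its rejection
log, the master per-gene index table, pooled RSCU/RFSC tables, HF and
optimal codon tables, neutrality/ENC-plot/PR2 summaries, correspondence-
analysis coordinates, correlation tables and host-divergence reports —
plus, across species, the shared-HF codon set and the RSCU dendrogram.
All outputs are tab-separated with a commented header naming the stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .classes import (
    expression_datasets_by_enc,
    high_frequency_codons,
    optimal_codons,
    shared_hf,
)
from .comparative import (
    HOST_NAMES,
    host_divergence,
    load_host_table,
    per_thousand_frequency,
    read_frequency_table,
    rscu_cluster,
)
from .composition import codon_counts
from .indices import build_gene_index_table, enc, rfsc, rscu
from .selection import (
    AXIS1_CORRELATES,
    DEFAULT_CORRELATION_PAIRS,
    correlation_suite,
    correspondence_analysis,
    enc_plot,
    neutrality_regression,
    pr2_plot,
    rscu_matrix,
)
from .sequence_io import (
    filter_cds,
    read_cds,
    write_cds_fasta,
    write_filter_report,
)

log = logging.getLogger("cubkit")


class StageError(RuntimeError):
    def __init__(self, stage: str, species: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed for {species!r}: {cause}")
        self.stage = stage
        self.species = species


@dataclass
class SpeciesEntry:
    label: str
    path: str
    format: str | None = None  # inferred from extension when None


@dataclass
class PipelineConfig:
    species: list[SpeciesEntry]
    outdir: str = "results"
    min_len: int = 300
    dedupe: bool = True
    decile_fraction: float = 0.10
    correlation_method: str = "spearman"
    hosts: list[str] = field(default_factory=lambda: list(HOST_NAMES))
    host_table_paths: dict[str, str] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        labels = [s.label for s in self.species]
        if len(labels) != len(set(labels)):
            raise ValueError("species labels must be unique")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        species = [SpeciesEntry(**e) for e in raw.pop("species")]
        return cls(species=species, **raw)

    def digest(self) -> str:
        payload = json.dumps(
            {
                "species": [(s.label, s.path, s.format) for s in self.species],
                "min_len": self.min_len,
                "dedupe": self.dedupe,
                "decile_fraction": self.decile_fraction,
                "correlation_method": self.correlation_method,
                "hosts": sorted(self.hosts),
                "seed": self.seed,
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _write_tsv(df: pd.DataFrame, path: Path, stage: str, params: str = "") -> None:
    with open(path, "w") as fh:
        fh.write(f"# cubkit {__version__} stage={stage} {params}\n".rstrip() + "\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def analyse_species(
    cds_set,
    outdir: Path,
    decile_fraction: float = 0.10,
    correlation_method: str = "spearman",
) -> dict:
    """Run every per-species stage on an already-filtered CDS set."""
    outdir.mkdir(parents=True, exist_ok=True)
    label = cds_set.species
    results: dict = {"species": label, "n_genes": len(cds_set)}

    index_df = build_gene_index_table(cds_set, decile_fraction=decile_fraction)
    _write_tsv(index_df, outdir / "gene_indices.tsv", "indices")

    pooled = codon_counts(cds_set)
    rscu_t = rscu(pooled)
    rfsc_t = rfsc(pooled)
    pooled_df = pd.DataFrame(
        {
            "codon": list(rscu_t.values),
            "rscu": [rscu_t.values[c] for c in rscu_t.values],
            "rfsc": [rfsc_t.values[c] for c in rfsc_t.values],
        }
    )
    _write_tsv(pooled_df, outdir / "pooled_rscu.tsv", "rscu")

    hf = high_frequency_codons(rfsc_t, species=label)
    _write_tsv(
        pd.DataFrame(
            sorted((c, hf.rule_hit[c]) for c in hf.codons),
            columns=["codon", "rule"],
        ),
        outdir / "hf_codons.tsv",
        "hf",
    )
    results["hf"] = hf

    enc_by_gene = dict(zip(index_df["gene_id"], index_df["ENC"]))
    enc_by_gene = {k: (None if pd.isna(v) else v) for k, v in enc_by_gene.items()}
    try:
        high_set, low_set = expression_datasets_by_enc(
            cds_set, enc_by_gene, fraction=decile_fraction
        )
        optimal = optimal_codons(codon_counts(high_set), codon_counts(low_set))
    except ValueError as exc:
        log.warning("%s: optimal-codon stage skipped (%s)", label, exc)
        optimal = []
    _write_tsv(
        pd.DataFrame(
            [
                (r.codon, r.rscu_high, r.rscu_low, r.delta_rscu)
                for r in optimal
            ],
            columns=["codon", "rscu_high", "rscu_low", "delta_rscu"],
        ),
        outdir / "optimal_codons.tsv",
        "optimal",
    )
    results["optimal"] = optimal

    fit = neutrality_regression(index_df["GC12"], index_df["GC3"])
    _write_tsv(
        pd.DataFrame([vars(fit)]), outdir / "neutrality.tsv", "neutrality"
    )
    results["neutrality"] = fit

    ep = enc_plot(index_df)
    _write_tsv(ep.table, outdir / "enc_plot.tsv", "encplot")
    hist = pd.DataFrame(
        {
            "bin_left": ep.bin_edges[:-1],
            "bin_right": ep.bin_edges[1:],
            "count": ep.bin_counts,
        }
    )
    _write_tsv(
        hist,
        outdir / "enc_ratio_hist.tsv",
        "encplot",
        f"frac_in_band={ep.frac_in_band:.4f}",
    )
    results["enc_plot"] = ep

    points, quadrants = pr2_plot(cds_set)
    _write_tsv(
        pd.DataFrame([(p.gene_id, p.x, p.y) for p in points],
                     columns=["gene_id", "x", "y"]),
        outdir / "pr2.tsv",
        "pr2",
        " ".join(f"{k}={v}" for k, v in quadrants.items()),
    )
    results["pr2_quadrants"] = quadrants

    ca = correspondence_analysis(rscu_matrix(cds_set))
    _write_tsv(
        ca.row_coords.reset_index(names="gene_id"),
        outdir / "ca_gene_coords.tsv",
        "coa",
    )
    _write_tsv(
        ca.col_coords.reset_index(names="codon"),
        outdir / "ca_codon_coords.tsv",
        "coa",
    )
    _write_tsv(
        pd.DataFrame(
            {
                "axis": range(1, ca.n_axes + 1),
                "inertia_pct": ca.inertia_pct,
            }
        ),
        outdir / "ca_inertia.tsv",
        "coa",
    )
    results["ca"] = ca

    corr_table = index_df.copy()
    corr_table["axis1"] = corr_table["gene_id"].map(ca.row_coords["axis1"])
    pairs = list(DEFAULT_CORRELATION_PAIRS) + [
        ("axis1", v) for v in AXIS1_CORRELATES
    ]
    corr = correlation_suite(corr_table, pairs, method=correlation_method)
    corr["species"] = label
    _write_tsv(corr, outdir / "correlations.tsv", "correlate",
               f"method={correlation_method}")
    results["correlations"] = corr
    results["index_table"] = index_df
    results["pooled_rscu"] = rscu_t
    return results


def compare_hosts(cds_set, hosts, host_table_paths=None, outdir: Path | None = None):
    """Divergent-codon counts of one species against each host table."""
    host_table_paths = host_table_paths or {}
    freq = per_thousand_frequency(codon_counts(cds_set), source=cds_set.species)
    comparisons = {}
    rows = []
    for host in hosts:
        table = (
            read_frequency_table(host_table_paths[host], source=host)
            if host in host_table_paths
            else load_host_table(host)
        )
        comp = host_divergence(freq, table)
        comparisons[host] = comp
        for codon in sorted(freq.values):
            ratio = comp.ratios.get(codon)
            rows.append(
                {
                    "host": host,
                    "codon": codon,
                    "species_freq": freq.values[codon],
                    "host_freq": table.values[codon],
                    "ratio": ratio if ratio is not None else float("nan"),
                    "divergent": int(codon in comp.divergent),
                }
            )
    if outdir is not None:
        _write_tsv(pd.DataFrame(rows), outdir / "host_divergence.tsv", "hosts")
        summary = pd.DataFrame(
            [
                {
                    "host": h,
                    "n_divergent": c.n_divergent,
                    "pct_of_64": 100.0 * c.n_divergent / 64.0,
                }
                for h, c in comparisons.items()
            ]
        )
        _write_tsv(summary, outdir / "host_summary.tsv", "hosts")
    return comparisons


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis for every configured species.

    Returns a bundle dict keyed by species label plus ``shared_hf`` and
    ``cluster`` cross-species entries; writes everything under
    ``config.outdir`` along with a run manifest.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle: dict = {}
    hf_sets = []
    pooled_rscu_rows = {}

    for entry in config.species:
        sp_dir = outdir / entry.label
        sp_dir.mkdir(parents=True, exist_ok=True)
        try:
            candidates = read_cds(entry.path, format=entry.format,
                                  species=entry.label)
        except Exception as exc:  # noqa: BLE001 - stage-tagged rethrow
            raise StageError("read", entry.label, exc) from exc
        try:
            cds_set, report = filter_cds(
                candidates,
                min_len=config.min_len,
                dedupe=config.dedupe,
                provenance=(entry.path,),
            )
            write_filter_report(
                report, [g.id for g in cds_set], sp_dir / "filter_report.tsv"
            )
            if cds_set.members:
                write_cds_fasta(cds_set, sp_dir / "filtered.fasta")
            log.info(
                "%s: %d/%d CDS accepted", entry.label, report.accepted,
                report.accepted + report.rejected,
            )
        except StageError:
            raise
        except Exception as exc:
            raise StageError("filter", entry.label, exc) from exc
        try:
            results = analyse_species(
                cds_set,
                sp_dir,
                decile_fraction=config.decile_fraction,
                correlation_method=config.correlation_method,
            )
        except Exception as exc:
            raise StageError("analysis", entry.label, exc) from exc
        try:
            results["hosts"] = compare_hosts(
                cds_set, config.hosts, config.host_table_paths, sp_dir
            )
        except Exception as exc:
            raise StageError("hosts", entry.label, exc) from exc
        results["filter_report"] = report
        bundle[entry.label] = results
        hf_sets.append(results["hf"])
        pooled_rscu_rows[entry.label] = {
            c: v for c, v in results["pooled_rscu"].values.items()
        }

    shared = shared_hf(hf_sets)
    (outdir / "shared_hf.tsv").write_text(
        "# cubkit stage=shared_hf\ncodon\n"
        + "".join(f"{c}\n" for c in sorted(shared))
    )
    bundle["shared_hf"] = shared

    species_matrix = pd.DataFrame.from_dict(pooled_rscu_rows, orient="index")
    _write_tsv(
        species_matrix.T.rename_axis("codon").reset_index(),
        outdir / "species_rscu_matrix.tsv",
        "rscu",
    )
    if len(species_matrix) >= 2:
        tree = rscu_cluster(species_matrix)
        (outdir / "rscu_cluster.nwk").write_text(tree.newick() + "\n")
        bundle["cluster"] = tree

    manifest = {
        "cubkit_version": __version__,
        "config_digest": config.digest(),
        "seed": config.seed,
        "species": [s.label for s in config.species],
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return bundle
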