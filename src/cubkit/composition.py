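"""Nucleotide composition, positional GC content and nucleotide skews.

GC1/GC2/GC3 are the G+C fractions at the three codon positions; GC12 is
their mean over positions 1-2 and drives the neutrality plot, while GC3s
(synonymous third positions only: Met, Trp and stop codons excluded) drives
the ENC-plot.  The six skews are the pairwise asymmetries (X-Y)/(X+Y) for
AT, GC, purine (A,G), pyrimidine (C,T), keto (G,T) and amino (A,C),
computed on whole-gene nucleotide counts.
"""

from __future__ import annotations

import collections
from dataclasses import dataclass
from typing import Iterable, Mapping, Union

from .genetics import CODONS, CODON_TO_AA, SINGLE_CODON_AAS, STOP_CODONS
from .sequence_io import CdsSet, CodingSequence

GeneLike = Union[CodingSequence, CdsSet, Iterable[CodingSequence]]


@dataclass
class CodonCountTable:
    """Counts over the 64 codons, per gene or pooled per species."""

    counts: dict[str, int]
    total_codons: int
    scope: str = "gene"  # "gene" or "species_pooled"

    def __post_init__(self) -> None:
        full = {c: 0 for c in CODONS}
        full.update(self.counts)
        unknown = set(self.counts) - set(CODONS)
        if unknown:
            raise ValueError(f"unknown codons: {sorted(unknown)}")
        self.counts = full
        if sum(full.values()) != self.total_codons:
            raise ValueError("counts do not sum to total_codons")

    def __getitem__(self, codon: str) -> int:
        return self.counts[codon]

    def __add__(self, other: "CodonCountTable") -> "CodonCountTable":
        summed = {c: self.counts[c] + other.counts[c] for c in CODONS}
        return CodonCountTable(
            counts=summed,
            total_codons=self.total_codons + other.total_codons,
            scope="species_pooled",
        )


@dataclass
class CompositionProfile:
    frac_A: float
    frac_T: float
    frac_G: float
    frac_C: float
    A3: float
    T3: float
    G3: float
    C3: float
    GC1: float
    GC2: float
    GC3: float
    GC: float
    GC12: float
    GC3s: float

    FIELDS = (
        "frac_A",
        "frac_T",
        "frac_G",
        "frac_C",
        "A3",
        "T3",
        "G3",
        "C3",
        "GC1",
        "GC2",
        "GC3",
        "GC",
        "GC12",
        "GC3s",
    )


@dataclass
class SkewVector:
    """Pairwise nucleotide skews; None where the denominator is zero."""

    at_skew: float | None
    gc_skew: float | None
    purine_skew: float | None
    pyrimidine_skew: float | None
    keto_skew: float | None
    amino_skew: float | None

    FIELDS = (
        "at_skew",
        "gc_skew",
        "purine_skew",
        "pyrimidine_skew",
        "keto_skew",
        "amino_skew",
    )


def _iter_genes(genes: GeneLike) -> list[CodingSequence]:
    if isinstance(genes, CodingSequence):
        return [genes]
    return list(genes)


def _iter_codons(seq: str) -> Iterable[str]:
    return (seq[i : i + 3] for i in range(0, len(seq), 3))


def codon_counts(genes: GeneLike) -> CodonCountTable:
    """Count codons read in frame from position 1, pooling over all genes."""
    members = _iter_genes(genes)
    counter: collections.Counter[str] = collections.Counter()
    total_nt = 0
    for gene in members:
        if len(gene.seq) % 3 != 0:
            raise ValueError(f"gene {gene.id}: length not a multiple of 3")
        counter.update(_iter_codons(gene.seq))
        total_nt += len(gene.seq)
    scope = "gene" if len(members) == 1 else "species_pooled"
    return CodonCountTable(
        counts=dict(counter), total_codons=total_nt // 3, scope=scope
    )


def composition_profile(genes: GeneLike) -> CompositionProfile:
    """Positional nucleotide composition of one gene or a pooled set."""
    members = _iter_genes(genes)
    if not members or all(len(g.seq) == 0 for g in members):
        raise ValueError("zero-length input")
    pos = [collections.Counter() for _ in range(3)]  # per codon position
    syn3: collections.Counter[str] = collections.Counter()
    for gene in members:
        if len(gene.seq) % 3 != 0:
            raise ValueError(f"gene {gene.id}: length not a multiple of 3")
        for codon in _iter_codons(gene.seq):
            for k in range(3):
                pos[k][codon[k]] += 1
            aa = CODON_TO_AA.get(codon)
            if aa is not None and aa != "*" and aa not in SINGLE_CODON_AAS:
                syn3[codon[2]] += 1

    totals = {b: sum(p[b] for p in pos) for b in "ACGT"}
    n_all = sum(totals.values())
    n_codons = sum(pos[0].values())

    def gc(counter: collections.Counter, n: int) -> float:
        return (counter["G"] + counter["C"]) / n if n else float("nan")

    gc1, gc2, gc3 = (gc(pos[k], n_codons) for k in range(3))
    n_syn = sum(syn3.values())
    return CompositionProfile(
        frac_A=totals["A"] / n_all,
        frac_T=totals["T"] / n_all,
        frac_G=totals["G"] / n_all,
        frac_C=totals["C"] / n_all,
        A3=pos[2]["A"] / n_codons,
        T3=pos[2]["T"] / n_codons,
        G3=pos[2]["G"] / n_codons,
        C3=pos[2]["C"] / n_codons,
        GC1=gc1,
        GC2=gc2,
        GC3=gc3,
        GC=(gc1 + gc2 + gc3) / 3,
        GC12=(gc1 + gc2) / 2,
        GC3s=gc(syn3, n_syn) if n_syn else float("nan"),
    )


def nucleotide_counts(genes: GeneLike) -> dict[str, int]:
    counter: collections.Counter[str] = collections.Counter()
    for gene in _iter_genes(genes):
        counter.update(gene.seq)
    return {b: counter[b] for b in "ACGT"}


def nucleotide_skews(source: GeneLike | Mapping[str, int]) -> SkewVector:
    """The six pairwise skews on whole-gene nucleotide counts.

    Accepts gene(s) or a ready ``{A,C,G,T} -> count`` mapping.  A skew with
    a zero denominator is recorded as None (missing downstream).
    """
    if isinstance(source, Mapping):
        n = {b: int(source.get(b, 0)) for b in "ACGT"}
    else:
        n = nucleotide_counts(source)

    def skew(x: str, y: str) -> float | None:
        denom = n[x] + n[y]
        return (n[x] - n[y]) / denom if denom else None

    return SkewVector(
        at_skew=skew("A", "T"),
        gc_skew=skew("G", "C"),
        purine_skew=skew("A", "G"),
        pyrimidine_skew=skew("C", "T"),
        keto_skew=skew("G", "T"),
        amino_skew=skew("A", "C"),
    )
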