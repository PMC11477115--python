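"""High-frequency and optimal codon classification.

A codon is *high-frequency* (HF) for a species when its pooled RFSC exceeds
0.60, or exceeds 1.5x its family's mean RFSC (which is 1/n_i).  *Optimal*
codons are detected by contrasting the high-expression pool (the 10% of
genes with the lowest ENC) against the low-expression pool (highest ENC):
a codon qualifies when RSCU > 1 in the high pool, RSCU < 1 in the low pool
and the difference exceeds 0.08.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .composition import CodonCountTable
from .genetics import CODON_TO_AA, DEGENERACY
from .indices import RfscTable, rscu
from .sequence_io import CdsSet


@dataclass
class HFCodonSet:
    species: str
    codons: set[str]
    rule_hit: dict[str, str]  # codon -> "abs60" | "rel50"


@dataclass(frozen=True)
class OptimalCodonRecord:
    codon: str
    rscu_high: float
    rscu_low: float

    @property
    def delta_rscu(self) -> float:
        return self.rscu_high - self.rscu_low


def high_frequency_codons(
    rfsc_table: RfscTable, species: str = ""
) -> HFCodonSet:
    """Classify HF codons from a species-pooled RFSC table.

    ``abs60``: RFSC > 0.60.  ``rel50``: RFSC > 1.5 * (1/n_i), the family
    mean.  A codon satisfying both is recorded under ``abs60``.
    """
    codons: set[str] = set()
    rule_hit: dict[str, str] = {}
    for codon, value in rfsc_table.values.items():
        if value is None:
            continue
        n_i = DEGENERACY[CODON_TO_AA[codon]]
        if value > 0.60:
            codons.add(codon)
            rule_hit[codon] = "abs60"
        elif value > 1.5 / n_i:
            codons.add(codon)
            rule_hit[codon] = "rel50"
    return HFCodonSet(species=species, codons=codons, rule_hit=rule_hit)


def shared_hf(sets: Sequence[HFCodonSet]) -> set[str]:
    """Codons high-frequency in every species."""
    if not sets:
        raise ValueError("no HF sets supplied")
    shared = set(sets[0].codons)
    for s in sets[1:]:
        shared &= s.codons
    return shared


def expression_datasets_by_enc(
    cds_set: CdsSet,
    enc_by_gene: Mapping[str, float | None],
    fraction: float = 0.10,
) -> tuple[CdsSet, CdsSet]:
    """Split a species into high/low-expression pools by ENC deciles.

    The ``fraction`` of genes with the *lowest* ENC (strongest bias) is the
    high-expression pool; the same number with the highest ENC is the low-
    expression pool.  Pool size is ceil(fraction * n) over genes with a
    defined ENC; ties are broken by gene id.
    """
    usable = sorted(
        (
            (enc_by_gene[g.id], g.id, g)
            for g in cds_set
            if enc_by_gene.get(g.id) is not None
        ),
        key=lambda t: (t[0], t[1]),
    )
    if len(usable) < 10:
        raise ValueError(
            f"need >= 10 genes with defined ENC, have {len(usable)}"
        )
    k = math.ceil(fraction * len(usable))
    high = [t[2] for t in usable[:k]]
    low = [t[2] for t in usable[-k:]]
    return (
        CdsSet(species=cds_set.species, members=high),
        CdsSet(species=cds_set.species, members=low),
    )


def optimal_codons(
    high: CodonCountTable, low: CodonCountTable
) -> list[OptimalCodonRecord]:
    """Optimal codons: RSCU_high > 1, RSCU_low < 1 and dRSCU > 0.08."""
    rscu_high = rscu(high).values
    rscu_low = rscu(low).values
    records = []
    for codon in sorted(rscu_high):
        hi, lo = rscu_high[codon], rscu_low[codon]
        if hi is None or lo is None:
            continue
        if hi > 1.0 and lo < 1.0 and hi - lo > 0.08:
            records.append(
                OptimalCodonRecord(codon=codon, rscu_high=hi, rscu_low=lo)
            )
    return records


def mean_rscu_over_species(tables: Iterable) -> dict[str, float | None]:
    """Mean RSCU per codon across species tables (None where all undefined)."""
    tables = list(tables)
    out: dict[str, float | None] = {}
    for codon in tables[0].values:
        vals = [t.values[codon] for t in tables if t.values[codon] is not None]
        out[codon] = sum(vals) / len(vals) if vals else None
    return out
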