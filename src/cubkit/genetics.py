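"""Genetic-code tables and codon-family structure.

Chloroplast genes are translated with the bacterial/plastid code (NCBI
translation table 11), whose codon -> amino-acid map over the 64 codons is
identical to the standard code.  Everything downstream (RSCU, ENC, SCUO,
MILC, ...) is organised around *synonymous families*: the set of codons
encoding one amino acid, of degeneracy 1, 2, 3, 4 or 6.  The 59
"informative" codons are the 64 minus the two single-codon families
(ATG/Met, TGG/Trp) and the three stops.
"""

from __future__ import annotations

from Bio.Data import CodonTable
from Bio.Seq import Seq

TRANSLATION_TABLE_ID = 11

_table = CodonTable.unambiguous_dna_by_id[TRANSLATION_TABLE_ID]

BASES = ("T", "C", "A", "G")

#: All 64 codons, TCAG order (the order codon-usage tables are printed in).
CODONS: tuple[str, ...] = tuple(
    a + b + c for a in BASES for b in BASES for c in BASES
)

STOP_CODONS: frozenset[str] = frozenset(_table.stop_codons)

#: codon -> one-letter amino acid; stop codons map to "*".
CODON_TO_AA: dict[str, str] = {
    **{c: _table.forward_table[c] for c in CODONS if c not in STOP_CODONS},
    **{c: "*" for c in STOP_CODONS},
}

#: amino acid -> tuple of its codons (lexicographic), stops excluded.
FAMILIES: dict[str, tuple[str, ...]] = {}
for _codon in sorted(CODONS):
    _aa = CODON_TO_AA[_codon]
    if _aa == "*":
        continue
    FAMILIES.setdefault(_aa, ())
    FAMILIES[_aa] += (_codon,)

#: amino acid -> family size n_i.
DEGENERACY: dict[str, int] = {aa: len(cods) for aa, cods in FAMILIES.items()}

#: codon -> family size of its amino acid (stops excluded).
CODON_DEGENERACY: dict[str, int] = {
    c: DEGENERACY[CODON_TO_AA[c]] for c in CODONS if c not in STOP_CODONS
}

SINGLE_CODON_AAS: frozenset[str] = frozenset(
    aa for aa, n in DEGENERACY.items() if n == 1
)  # Met, Trp

#: The 59 codons informative for synonymous usage (64 - ATG - TGG - 3 stops).
INFORMATIVE_CODONS: tuple[str, ...] = tuple(
    c
    for c in sorted(CODONS)
    if c not in STOP_CODONS and DEGENERACY[CODON_TO_AA[c]] > 1
)

#: Degenerate amino acids grouped by degeneracy class, as used by Wright's
#: ENC estimator: 9 two-fold, 1 three-fold (Ile), 5 four-fold, 3 six-fold.
ENC_CLASSES: dict[int, tuple[str, ...]] = {}
for _aa, _n in sorted(DEGENERACY.items()):
    if _n > 1:
        ENC_CLASSES.setdefault(_n, ())
        ENC_CLASSES[_n] += (_aa,)


def translate(seq: str, *, keep_terminal_stop: bool = False) -> str:
    """Translate an in-frame CDS; the terminal stop is dropped by default."""
    if len(seq) % 3 != 0:
        raise ValueError("sequence length is not a multiple of 3")
    protein = str(Seq(seq).translate(table=TRANSLATION_TABLE_ID))
    if not keep_terminal_stop and protein.endswith("*"):
        protein = protein[:-1]
    return protein


def is_gc_ending(codon: str) -> bool:
    return codon[2] in ("G", "C")
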