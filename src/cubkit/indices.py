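"""Per-gene codon-usage indices.

The index suite:

* **RSCU** — observed codon count over its synonymous-family mean; 1 means
  no bias, > 1 a preferred codon.  **RFSC** — count over family total, so a
  family's values sum to 1 (RSCU = n_i * RFSC).
* **ENC** — Wright's effective number of codons, from per-amino-acid
  codon-homozygosity estimates F-hat = (n * sum p^2 - 1)/(n - 1) averaged
  within degeneracy classes: ENC = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6, capped at
  61.  ``expected_enc`` is the mutation-only reference curve
  2 + s + 29/(s^2 + (1-s)^2) in GC3s.
* **SCUO** — information-theoretic synonymous codon usage order: the
  usage-weighted mean, over degenerate amino acids, of the normalised
  entropy deficit (log2 n_i - H_i)/log2 n_i; 0 = uniform, 1 = one codon per
  family.
* **MILC** — Measure Independent of Length and Composition: a scaled
  likelihood-ratio distance between the gene's within-family codon
  fractions and a reference distribution, minus the correction
  C = sum_a (r_a - 1)/L.
* **CAI / CBI / Fop** — adaptation to a reference (high-expression) codon
  usage or to an optimal-codon set.
* Protein properties: length, Kyte-Doolittle GRAVY, aromaticity and the
  isoelectric point (bisection on the EMBOSS pKa set).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .composition import (
    CodonCountTable,
    CompositionProfile,
    SkewVector,
    codon_counts,
    composition_profile,
    nucleotide_skews,
)
from .genetics import (
    CODON_TO_AA,
    DEGENERACY,
    ENC_CLASSES,
    FAMILIES,
    INFORMATIVE_CODONS,
    translate,
)
from .sequence_io import CdsSet, CodingSequence

# ---------------------------------------------------------------------------
# RSCU / RFSC


@dataclass
class RscuTable:
    """RSCU over the 59 informative codons; unobserved families are None."""

    values: dict[str, float | None]
    scope: str = "gene"


@dataclass
class RfscTable:
    """Relative frequency of synonymous codons; family values sum to 1."""

    values: dict[str, float | None]
    scope: str = "gene"


def _family_totals(counts: CodonCountTable) -> dict[str, int]:
    return {
        aa: sum(counts[c] for c in codons) for aa, codons in FAMILIES.items()
    }


def rscu(counts: CodonCountTable) -> RscuTable:
    """RSCU = X_ij * n_i / sum_j X_ij; families with zero total -> None."""
    totals = _family_totals(counts)
    values: dict[str, float | None] = {}
    for codon in INFORMATIVE_CODONS:
        aa = CODON_TO_AA[codon]
        total = totals[aa]
        values[codon] = (
            counts[codon] * DEGENERACY[aa] / total if total > 0 else None
        )
    return RscuTable(values=values, scope=counts.scope)


def rfsc(counts: CodonCountTable) -> RfscTable:
    """RFSC = X_ij / sum_j X_ij; families with zero total -> None."""
    totals = _family_totals(counts)
    values: dict[str, float | None] = {}
    for codon in INFORMATIVE_CODONS:
        total = totals[CODON_TO_AA[codon]]
        values[codon] = counts[codon] / total if total > 0 else None
    return RfscTable(values=values, scope=counts.scope)


# ---------------------------------------------------------------------------
# ENC


def enc(counts: CodonCountTable) -> float | None:
    """Wright's per-gene effective number of codons, capped at 61.

    Amino acids observed fewer than twice, or with non-positive F-hat, do
    not contribute.  If the three-fold class (Ile) is empty it is imputed
    as (F2 + F4)/2; if any of the 2-, 4- or 6-fold classes is empty the
    estimate is undefined (None).
    """
    class_means: dict[int, float | None] = {}
    for size, aas in ENC_CLASSES.items():
        fhats = []
        for aa in aas:
            family = FAMILIES[aa]
            n = sum(counts[c] for c in family)
            if n < 2:
                continue
            p2 = sum((counts[c] / n) ** 2 for c in family)
            fhat = (n * p2 - 1) / (n - 1)
            if fhat > 0:
                fhats.append(fhat)
        class_means[size] = sum(fhats) / len(fhats) if fhats else None

    f2, f3, f4, f6 = (class_means.get(k) for k in (2, 3, 4, 6))
    if f2 is None or f4 is None or f6 is None:
        return None
    if f3 is None:
        f3 = (f2 + f4) / 2
    value = 2 + 9 / f2 + 1 / f3 + 5 / f4 + 3 / f6
    return min(value, 61.0)


def expected_enc(gc3s: float) -> float:
    """Mutation-only ENC reference curve: 2 + s + 29/(s^2 + (1-s)^2)."""
    if not 0.0 <= gc3s <= 1.0:
        raise ValueError(f"GC3s must lie in [0, 1], got {gc3s}")
    return 2.0 + gc3s + 29.0 / (gc3s**2 + (1.0 - gc3s) ** 2)


# ---------------------------------------------------------------------------
# SCUO


def scuo(counts: CodonCountTable) -> float | None:
    """Synonymous codon usage order in [0, 1]; None if nothing degenerate."""
    weights = []
    orders = []
    for aa, family in FAMILIES.items():
        n_i = DEGENERACY[aa]
        if n_i < 2:
            continue
        x = sum(counts[c] for c in family)
        if x == 0:
            continue
        h = 0.0
        for c in family:
            p = counts[c] / x
            if p > 0:
                h -= p * math.log2(p)
        h_max = math.log2(n_i)
        orders.append((h_max - h) / h_max)
        weights.append(x)
    if not weights:
        return None
    total = sum(weights)
    return sum(w * o for w, o in zip(weights, orders)) / total


# ---------------------------------------------------------------------------
# MILC


def milc(
    counts: CodonCountTable,
    reference: CodonCountTable,
    pseudocount: float = 0.5,
) -> float | None:
    """MILC of a gene against a reference codon-usage distribution.

    M_a = 2 * sum_c O_c ln(f_c / g_c) over the codons of amino acid a, with
    O_c the gene's codon counts, f_c its within-family fractions and g_c
    the reference's.  MILC = sum_a M_a / L - C with L the gene's codon
    count over contributing families and C = sum_a (r_a - 1)/L.  Reference
    families in which the gene observes a zero-frequency codon get a
    ``pseudocount`` added to every reference codon.
    """
    m_total = 0.0
    correction_terms = 0.0
    length = 0
    for aa, family in FAMILIES.items():
        if DEGENERACY[aa] < 2:
            continue
        obs = {c: counts[c] for c in family}
        x = sum(obs.values())
        if x == 0:
            continue
        ref = {c: float(reference[c]) for c in family}
        if any(ref[c] == 0 and obs[c] > 0 for c in family):
            ref = {c: ref[c] + pseudocount for c in family}
        g_total = sum(ref.values())
        if g_total == 0:
            continue
        m_a = 0.0
        for c in family:
            if obs[c] == 0:
                continue
            f_c = obs[c] / x
            g_c = ref[c] / g_total
            m_a += 2.0 * obs[c] * math.log(f_c / g_c)
        m_total += m_a
        length += x
        correction_terms += DEGENERACY[aa] - 1
    if length == 0:
        raise ValueError("gene has no degenerate-family codons")
    correction = correction_terms / length
    return m_total / length - correction


# ---------------------------------------------------------------------------
# CAI / CBI / Fop


def cai_weights(reference: CodonCountTable) -> dict[str, float]:
    """Relative adaptiveness w = RSCU / max RSCU per family, floored at 0.01."""
    if reference.total_codons == 0:
        raise ValueError("empty reference")
    ref_rscu = rscu(reference).values
    weights: dict[str, float] = {}
    for aa, family in FAMILIES.items():
        if DEGENERACY[aa] < 2:
            continue
        vals = {c: ref_rscu[c] for c in family}
        observed = {c: v for c, v in vals.items() if v is not None}
        if not observed:
            for c in family:
                weights[c] = 0.01
            continue
        vmax = max(observed.values())
        for c in family:
            v = observed.get(c)
            w = (v / vmax) if (v is not None and vmax > 0) else 0.0
            weights[c] = max(w, 0.01)
    return weights


def cai(counts: CodonCountTable, weights: Mapping[str, float]) -> float | None:
    """Geometric mean of weights over informative codon occurrences."""
    log_sum = 0.0
    n = 0
    for codon in INFORMATIVE_CODONS:
        x = counts[codon]
        if x == 0:
            continue
        log_sum += x * math.log(weights[codon])
        n += x
    if n == 0:
        return None
    return math.exp(log_sum / n)


def fop_cbi(
    counts: CodonCountTable, optimal: Iterable[str]
) -> tuple[float | None, float | None]:
    """Frequency of optimal codons and codon bias index.

    Over synonymous occurrences N_tot (degenerate families only):
    Fop = N_opt / N_tot; CBI = (N_opt - N_ran)/(N_tot - N_ran) with
    N_ran = sum_i x_i * k_i / n_i the random expectation.
    """
    optimal = set(optimal)
    n_tot = 0
    n_opt = 0
    n_ran = 0.0
    for aa, family in FAMILIES.items():
        n_i = DEGENERACY[aa]
        if n_i < 2:
            continue
        x = sum(counts[c] for c in family)
        if x == 0:
            continue
        k = sum(1 for c in family if c in optimal)
        n_tot += x
        n_opt += sum(counts[c] for c in family if c in optimal)
        n_ran += x * k / n_i
    if n_tot == 0:
        return None, None
    fop = n_opt / n_tot
    cbi = (n_opt - n_ran) / (n_tot - n_ran) if n_tot != n_ran else None
    return fop, cbi


# ---------------------------------------------------------------------------
# Protein properties

# Kyte-Doolittle hydropathy
_KD = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

# EMBOSS pKa values for the charge model behind the isoelectric point
_PKA_POSITIVE = {"Nterm": 8.6, "K": 10.8, "R": 12.5, "H": 6.5}
_PKA_NEGATIVE = {"Cterm": 3.6, "D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1}


def _net_charge(protein: str, ph: float) -> float:
    charge = 1.0 / (1.0 + 10 ** (ph - _PKA_POSITIVE["Nterm"]))
    charge -= 1.0 / (1.0 + 10 ** (_PKA_NEGATIVE["Cterm"] - ph))
    for aa in protein:
        if aa in _PKA_POSITIVE:
            charge += 1.0 / (1.0 + 10 ** (ph - _PKA_POSITIVE[aa]))
        elif aa in _PKA_NEGATIVE:
            charge -= 1.0 / (1.0 + 10 ** (_PKA_NEGATIVE[aa] - ph))
    return charge


def isoelectric_point(protein: str, tol: float = 1e-4) -> float:
    """pI by bisection of the net charge on [0, 14] (EMBOSS pKa set)."""
    lo, hi = 0.0, 14.0
    if _net_charge(protein, lo) < 0:
        return lo
    if _net_charge(protein, hi) > 0:
        return hi
    while True:
        mid = (lo + hi) / 2
        q = _net_charge(protein, mid)
        if abs(q) < tol:
            return mid
        if q > 0:
            lo = mid
        else:
            hi = mid


def protein_properties(gene: CodingSequence) -> tuple[int, float, float, float]:
    """(L_aa, GRAVY, aromaticity, pI) of the encoded protein (stop dropped)."""
    protein = translate(gene.seq)
    if "*" in protein:
        raise ValueError(f"gene {gene.id}: internal stop codon")
    l_aa = len(protein)
    gravy = sum(_KD[a] for a in protein) / l_aa
    aromaticity = sum(protein.count(a) for a in "FYW") / l_aa
    return l_aa, gravy, aromaticity, isoelectric_point(protein)


# ---------------------------------------------------------------------------
# Master per-gene table


@dataclass
class GeneIndexRecord:
    gene_id: str
    L_aa: int
    ENC: float | None
    ENC_expected: float | None
    ENC_ratio: float | None
    CAI: float | None
    CBI: float | None
    Fop: float | None
    SCUO: float | None
    MILC: float | None
    GRAVY: float
    aromaticity: float
    pI: float
    profile: CompositionProfile = field(repr=False, default=None)
    skews: SkewVector = field(repr=False, default=None)


def build_gene_index_table(
    cds_set: CdsSet,
    optimal: Iterable[str] | None = None,
    decile_fraction: float = 0.10,
):
    """Compute every per-gene index for a species and return a DataFrame.

    The CAI reference is the species' own high-expression pool (the
    lowest-ENC decile); the MILC reference is the species' pooled counts.
    ``optimal`` overrides the detected optimal-codon set for Fop/CBI.
    """
    import pandas as pd

    from .classes import expression_datasets_by_enc, optimal_codons

    per_gene_counts = {g.id: codon_counts(g) for g in cds_set}
    enc_by_gene = {gid: enc(c) for gid, c in per_gene_counts.items()}
    pooled = codon_counts(cds_set)

    # high/low expression pools by ENC decile; fall back to the pooled set
    # as CAI reference when too few genes have a defined ENC
    try:
        high_set, low_set = expression_datasets_by_enc(
            cds_set, enc_by_gene, fraction=decile_fraction
        )
        cai_ref = codon_counts(high_set)
        detected = optimal_codons(codon_counts(high_set), codon_counts(low_set))
        detected_set = {r.codon for r in detected}
    except ValueError:
        cai_ref = pooled
        detected_set = set()
    optimal_set = set(optimal) if optimal is not None else detected_set
    weights = cai_weights(cai_ref)

    rows = []
    for gene in cds_set:
        counts = per_gene_counts[gene.id]
        profile = composition_profile(gene)
        skews = nucleotide_skews(gene)
        l_aa, gravy, arom, pi = protein_properties(gene)
        e_obs = enc_by_gene[gene.id]
        gc3s = profile.GC3s
        e_exp = expected_enc(gc3s) if not math.isnan(gc3s) else None
        ratio = (
            (e_exp - e_obs) / e_exp
            if (e_obs is not None and e_exp is not None)
            else None
        )
        fop, cbi = fop_cbi(counts, optimal_set)
        record = {
            "gene_id": gene.id,
            "species": gene.species,
            "L_aa": l_aa,
            "ENC": e_obs,
            "ENC_expected": e_exp,
            "ENC_ratio": ratio,
            "CAI": cai(counts, weights),
            "CBI": cbi,
            "Fop": fop,
            "SCUO": scuo(counts),
            "MILC": milc(counts, pooled),
            "GRAVY": gravy,
            "aromaticity": arom,
            "pI": pi,
        }
        for name in CompositionProfile.FIELDS:
            record[name] = getattr(profile, name)
        for name in SkewVector.FIELDS:
            record[name] = getattr(skews, name)
        rows.append(record)
    df = pd.DataFrame(rows)
    return df.astype({c: float for c in df.columns if c not in ("gene_id", "species")})
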