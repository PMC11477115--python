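"""Synthetic CDS generator with known, controllable codon-usage structure.

Each simulated "species" is a set of independent in-frame genes: lengths
are drawn from a codon range, amino acids from a profile (first residue
Met, a uniform stop appended), and each synonymous codon from its family
with probability proportional to ``m(c) * exp(s * 1[c in preferred])``.
The mutational weight m(c) splits the target GC3 between a family's
G/C-ending codons (weight ``gc3_target``, shared equally) and its
A/T-ending codons (weight ``1 - gc3_target``), so the synonymous
third-position GC fraction (GC3s) is unbiased for the target.  Met and
Trp, whose single codons force a G at position 3, are emitted as-is —
which is why the target is defined on synonymous positions.

Regimes:

* ``mutation_only`` — s = 0; per-gene GC3 fixed or drawn from a range.
* ``selection`` — GC3 pinned at 0.5; every gene carries strength s.
* ``mixed`` — a fixed 25% subset of genes carries strength s (the
  "highly expressed" genes), the rest are neutral; this is what gives the
  ENC-decile optimal-codon procedure genuine high/low pools.
* ``gc_driven`` — a per-gene GC level tilts both the amino-acid profile
  (toward residues with G/C-rich first two codon positions) and the third
  position, coupling GC12 to GC3 as whole-genome mutation pressure would.

Defaults emulate an AT-rich chloroplast gene complement: 40 genes of
100-1,500 codons with GC3 around 0.37.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .genetics import (
    CODON_TO_AA,
    DEGENERACY,
    FAMILIES,
    STOP_CODONS,
    is_gc_ending,
)
from .sequence_io import CdsSet, CodingSequence

REGIMES = ("mutation_only", "selection", "mixed", "gc_driven")

AMINO_ACIDS = tuple(sorted(FAMILIES))
_MIXED_SELECTED_FRACTION = 0.25
_GC_DRIVEN_TILT = 4.0  # amino-acid log-weight per unit (g - 0.5) * GC12(aa)

#: Per degenerate family, the codon with the smallest mutational weight in
#: an AT-leaning genome (GC3 < 0.5), ties broken lexicographically: the
#: G/C-ending codon of each family except Ile, where ATA wins.  This is the
#: default planted preferred set.
def _default_preferred() -> frozenset[str]:
    chosen = []
    for aa, family in FAMILIES.items():
        if DEGENERACY[aa] < 2:
            continue
        gc = sorted(c for c in family if is_gc_ending(c))
        at = sorted(c for c in family if not is_gc_ending(c))
        # weight per codon at gc3 t<0.5: t/len(gc) vs (1-t)/len(at)
        t = 0.45
        best = min(
            family,
            key=lambda c: (
                (t / len(gc)) if is_gc_ending(c) else ((1 - t) / len(at)),
                c,
            ),
        )
        chosen.append(best)
    return frozenset(chosen)


DEFAULT_PREFERRED_SET: frozenset[str] = _default_preferred()


@dataclass
class SyntheticSpec:
    """Parameters of one simulated CDS set."""

    n_genes: int = 40
    length_codons: tuple[int, int] = (100, 1500)  # amino acids incl. Met
    aa_profile: dict[str, float] | None = None  # default uniform over 20
    gc3_target: float | tuple[float, float] = 0.37
    s: float = 0.0
    preferred_set: frozenset[str] = DEFAULT_PREFERRED_SET
    regime: str = "mutation_only"
    seed: int = 0
    species: str = "synthetic"

    def __post_init__(self) -> None:
        if self.regime not in REGIMES:
            raise ValueError(f"unknown regime {self.regime!r}")
        lo, hi = (
            (self.gc3_target, self.gc3_target)
            if np.isscalar(self.gc3_target)
            else self.gc3_target
        )
        if not (0.0 <= lo <= 1.0 and 0.0 <= hi <= 1.0):
            raise ValueError("gc3_target must lie in [0, 1]")
        if self.s < 0:
            raise ValueError("selection strength s must be >= 0")
        if self.regime in ("selection", "mixed") and self.s > 0 and not self.preferred_set:
            raise ValueError(f"regime {self.regime!r} needs a preferred_set")
        by_aa: dict[str, int] = {}
        for c in self.preferred_set:
            aa = CODON_TO_AA[c]
            by_aa[aa] = by_aa.get(aa, 0) + 1
        if any(v > 1 for v in by_aa.values()):
            raise ValueError("preferred_set has more than one codon per family")


@dataclass
class SyntheticTruth:
    """Per-gene ground truth of a simulated set."""

    gene_ids: list[str]
    gc3_target: list[float]  # per-gene target (synonymous positions)
    realized_gc3s: list[float]
    s: list[float]  # per-gene selection strength
    regime: str = "mutation_only"
    preferred_set: frozenset[str] = frozenset()


_FAMILY_SPLIT = {
    aa: (
        tuple(c for c in family if is_gc_ending(c)),
        tuple(c for c in family if not is_gc_ending(c)),
    )
    for aa, family in FAMILIES.items()
}


def _codon_probs(aa: str, gc3: float, s: float, preferred: frozenset[str]) -> tuple[tuple[str, ...], np.ndarray]:
    family = FAMILIES[aa]
    if len(family) == 1:
        return family, np.array([1.0])
    gc, at = _FAMILY_SPLIT[aa]
    weights = np.array(
        [
            (gc3 / len(gc) if is_gc_ending(c) else (1.0 - gc3) / len(at))
            * (np.exp(s) if c in preferred else 1.0)
            for c in family
        ]
    )
    return family, weights / weights.sum()


# GC fraction of codon positions 1-2, averaged over a family's codons;
# used only by the gc_driven regime's amino-acid tilt.
_AA_GC12 = {
    aa: float(
        np.mean(
            [(c[0] in "GC") + (c[1] in "GC") for c in family]
        )
        / 2.0
    )
    for aa, family in FAMILIES.items()
}


def _aa_probs(spec: SyntheticSpec, g: float) -> np.ndarray:
    if spec.aa_profile is not None:
        base = np.array([spec.aa_profile.get(a, 0.0) for a in AMINO_ACIDS])
        if base.sum() <= 0:
            raise ValueError("aa_profile has no mass")
    else:
        base = np.ones(len(AMINO_ACIDS))
    if spec.regime == "gc_driven":
        tilt = np.array(
            [np.exp(_GC_DRIVEN_TILT * (g - 0.5) * _AA_GC12[a]) for a in AMINO_ACIDS]
        )
        base = base * tilt
    return base / base.sum()


def simulate_cds_set(spec: SyntheticSpec) -> tuple[CdsSet, SyntheticTruth]:
    """Generate one CDS set plus its ground truth.

    Deterministic in ``spec.seed``; each gene uses an independent
    substream seeded by (seed, gene index), so adding genes never perturbs
    earlier ones.  Every emitted gene passes the structural CDS filter by
    construction.
    """
    lo_len, hi_len = spec.length_codons
    if lo_len < 100:
        raise ValueError("genes shorter than 100 codons fail the 300-nt filter")
    gc_lo, gc_hi = (
        (spec.gc3_target, spec.gc3_target)
        if np.isscalar(spec.gc3_target)
        else spec.gc3_target
    )

    if spec.regime == "mixed":
        rng0 = np.random.default_rng([int(spec.seed), 10**6])
        n_sel = max(1, round(_MIXED_SELECTED_FRACTION * spec.n_genes))
        selected = set(rng0.choice(spec.n_genes, size=n_sel, replace=False).tolist())
    else:
        selected = set(range(spec.n_genes))

    genes: list[CodingSequence] = []
    truth = SyntheticTruth(
        gene_ids=[],
        gc3_target=[],
        realized_gc3s=[],
        s=[],
        regime=spec.regime,
        preferred_set=spec.preferred_set,
    )
    stops = tuple(sorted(STOP_CODONS))
    for idx in range(spec.n_genes):
        rng = np.random.default_rng([int(spec.seed), idx])
        length = int(rng.integers(lo_len, hi_len + 1))
        if spec.regime == "selection":
            g = 0.5
        else:
            g = float(rng.uniform(gc_lo, gc_hi)) if gc_hi > gc_lo else gc_lo
        s_gene = spec.s if (spec.regime != "mutation_only" and idx in selected) else 0.0
        if spec.regime == "gc_driven":
            s_gene = 0.0

        aa_p = _aa_probs(spec, g)
        aa_seq = ["M"] + list(
            rng.choice(AMINO_ACIDS, size=length - 1, p=aa_p)
        )
        codons: list[str] = []
        syn_gc = 0
        syn_n = 0
        aa_arr = np.array(aa_seq)
        codon_arr = np.empty(len(aa_seq), dtype=object)
        # sorted: set order is hash-randomised per process, and the order
        # of rng.choice calls must not depend on it
        for aa in sorted(set(aa_seq)):
            positions = np.nonzero(aa_arr == aa)[0]
            family, probs = _codon_probs(aa, g, s_gene, spec.preferred_set)
            picks = rng.choice(family, size=positions.size, p=probs)
            codon_arr[positions] = picks
            if DEGENERACY[aa] > 1:
                syn_n += positions.size
                syn_gc += sum(1 for c in picks if is_gc_ending(c))
        codons = list(codon_arr)
        codons.append(stops[int(rng.integers(len(stops)))])
        gene_id = f"g{idx + 1:03d}"
        genes.append(
            CodingSequence(
                id=gene_id, species=spec.species, seq="".join(codons)
            )
        )
        truth.gene_ids.append(gene_id)
        truth.gc3_target.append(g)
        truth.realized_gc3s.append(syn_gc / syn_n if syn_n else float("nan"))
        truth.s.append(s_gene)
    return CdsSet(species=spec.species, members=genes), truth


#: the fixed scenario grid exercised by the acceptance checks
BATTERY_GC3_LEVELS = (0.2, 0.35, 0.5, 0.65, 0.8)
BATTERY_S_LEVELS = (0.0, 0.5, 1.0, 2.0, 5.0)


def regime_battery(seed: int = 0) -> dict[str, tuple[CdsSet, SyntheticTruth]]:
    """The fixed scenario grid used for end-to-end validation.

    * ``mut_gcXX`` — mutation-only at GC3 in {0.2, 0.35, 0.5, 0.65, 0.8}.
    * ``sel_sX`` — selection at s in {0, 0.5, 1, 2, 5} (GC3 = 0.5).
    * ``recovery`` — mixed regime (25% of genes at s = 3, GC3 = 0.35 as in
      an AT-rich chloroplast gene complement) for planted-codon recovery
      through the ENC-decile procedure.
    * ``neutral_range`` — mutation-only with per-gene GC3 in (0.2, 0.8),
      200 genes, for the neutrality-slope check.
    * ``regimeA_1..3`` / ``regimeB_1..3`` — two codon-usage regimes
      (GC3 0.3 vs 0.7), three "species" each, for clustering.

    Gene lengths are 300-1,000 codons so per-gene ENC estimates are stable.
    """
    out: dict[str, tuple[CdsSet, SyntheticTruth]] = {}

    def spec(**kw) -> SyntheticSpec:
        base = dict(
            n_genes=40, length_codons=(300, 1000), seed=seed, s=0.0
        )
        base.update(kw)
        return SyntheticSpec(**base)

    for i, g in enumerate(BATTERY_GC3_LEVELS):
        name = f"mut_gc{int(round(100 * g))}"
        out[name] = simulate_cds_set(
            spec(regime="mutation_only", gc3_target=g, seed=seed * 1000 + i,
                 species=name)
        )
    for i, s in enumerate(BATTERY_S_LEVELS):
        name = f"sel_s{s:g}"
        out[name] = simulate_cds_set(
            spec(regime="selection", gc3_target=0.5, s=s,
                 seed=seed * 1000 + 100 + i, species=name)
        )
    out["recovery"] = simulate_cds_set(
        spec(regime="mixed", gc3_target=0.35, s=3.0,
             seed=seed * 1000 + 200, species="recovery")
    )
    out["neutral_range"] = simulate_cds_set(
        spec(regime="mutation_only", gc3_target=(0.2, 0.8), n_genes=200,
             seed=seed * 1000 + 300, species="neutral_range")
    )
    for j, g in ((1, 0.3), (2, 0.3), (3, 0.3)):
        name = f"regimeA_{j}"
        out[name] = simulate_cds_set(
            spec(regime="mutation_only", gc3_target=g,
                 seed=seed * 1000 + 400 + j, species=name)
        )
    for j, g in ((1, 0.7), (2, 0.7), (3, 0.7)):
        name = f"regimeB_{j}"
        out[name] = simulate_cds_set(
            spec(regime="mutation_only", gc3_target=g,
                 seed=seed * 1000 + 500 + j, species=name)
        )
    return out


def write_truth_table(truth: SyntheticTruth, path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tgc3_target\trealized_gc3s\ts\tregime\n")
        for gid, t, r, s in zip(
            truth.gene_ids, truth.gc3_target, truth.realized_gc3s, truth.s
        ):
            fh.write(f"{gid}\t{t:.4f}\t{r:.4f}\t{s:g}\t{truth.regime}\n")
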