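# Methods

## Scope and model

`cubkit` quantifies codon usage bias (CUB) in sets of protein-coding
sequences, one set per species, and attributes it to mutation pressure
versus natural selection.  The working model is the standard one for
organellar genomes: mutation pressure acts on base composition and is
most visible at synonymous third codon positions, while translational
selection concentrates usage on a preferred codon per family in highly
expressed genes.  Every statistic operates on codon counts read in frame
from filtered CDSs under the bacterial/plastid genetic code (NCBI table
11, identical to the standard code over the 64 codons).

## CDS filtering

A candidate CDS is retained iff it (1) starts with ATG (alternative
starts GTG/TTG are rejected — the filter demands a literal ATG), (2) ends
with TAA, TAG or TGA, (3) has no internal in-frame stop, (4) has length a
multiple of 3 and (5) ≥ `min_len` (default 300 nt), and (6) contains only
A/C/G/T — ambiguity codes reject the whole gene rather than being
partially counted.  Duplicate gene names (inverted-repeat copies,
trans-spliced fragments annotated twice) are collapsed to the first
occurrence; the flag `dedupe=False` disables this, renaming later copies
to keep identifiers unique.  Each rejection is logged with a single
reason code, assigned in the order the checks are listed.  Filtering is
idempotent, and every retained gene translates to a protein with a
terminal stop and no internal stop.

## Indices

* **RSCU** = X·n/ΣX within each synonymous family (n = family size);
  **RFSC** = X/ΣX, so RSCU = n·RFSC.  Families with zero occurrences are
  *undefined* (not 0), and undefined values are excluded pairwise from
  every downstream correlation.
* **ENC** (Wright): per amino acid observed n ≥ 2 times, the codon
  homozygosity is estimated as F̂ = (nΣp² − 1)/(n − 1); F̂ is averaged
  inside the degeneracy classes {2, 3, 4, 6}, amino acids with F̂ ≤ 0 are
  dropped from their class average; ENC = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ +
  3/F̄₆, capped at 61.  If the 3-fold class (Ile) is empty it is imputed
  as (F̄₂ + F̄₄)/2; if the 2-, 4- or 6-fold class is empty, ENC is
  undefined for that gene.  The mutation-only reference curve is
  ENC*(s) = 2 + s + 29/(s² + (1 − s)²) in GC3s, and the per-gene **ENC
  ratio** is (ENC* − ENC)/ENC*, signed so genes *below* the curve
  (selection-limited) are positive.  Its histogram uses left-closed
  0.05-wide bins aligned to multiples of 0.05, spanning at least
  [−0.25, 0.30), and the summary reports the fraction inside the closed
  band [−0.05, 0.10].
* **GC3s** is the G/C fraction at third positions of synonymous codons
  only (Met, Trp and stops excluded); plain GC3 counts every codon.  The
  ENC-plot uses GC3s, the neutrality plot GC12 vs GC3.
* **SCUO**: for each degenerate amino acid, the normalised entropy
  deficit O = (log₂n − H)/log₂n of its within-family distribution,
  usage-weighted across amino acids; 0 = uniform usage, 1 = one codon per
  family.
* **MILC**: Σₐ Mₐ/L − C with Mₐ = 2Σ O_c ln(f_c/g_c) (observed counts O,
  gene fractions f, reference fractions g), L the codon count over
  contributing families and C = Σₐ(rₐ − 1)/L.  The reference is the
  species' pooled codon usage; if the gene uses a codon the reference
  never does, 0.5 is added to every reference codon of that family.
  A gene matching the reference exactly scores −C.
* **CAI**: geometric mean of relative adaptiveness w = RSCU/maxRSCU,
  computed from a reference set and floored at 0.01 for unobserved
  codons.  With no external high-expression catalogue for these genomes,
  the reference is the species' own low-ENC decile (the same pool the
  optimal-codon detection uses); single-codon families and stops never
  score.
* **Fop / CBI**: over occurrences in degenerate families, Fop is the
  optimal-codon fraction; CBI = (N_opt − N_ran)/(N_tot − N_ran) with
  N_ran the random expectation Σ xᵢkᵢ/nᵢ.  The optimal set is the
  species' detected optimal codons unless an explicit set is supplied.
* **Protein properties**: translation without the terminal stop, GRAVY as
  the mean Kyte–Doolittle hydropathy, aromaticity as the Phe/Tyr/Trp
  fraction, and pI by bisecting the net-charge curve on [0, 14] to
  |charge| < 10⁻⁴ with the EMBOSS pKa set (N-term 8.6, C-term 3.6,
  C 8.5, D 3.9, E 4.1, H 6.5, K 10.8, R 12.5, Y 10.1).

## Codon classification

High-frequency codons satisfy RFSC > 0.60 or RFSC > 1.5 × (1/n), the
parameter-free reading of "50% above the family mean" (the mean RFSC of a
family including the codon itself is 1/n).  Expression pools are the
⌈0.10·n⌉ genes with the lowest ENC (high expression) and highest ENC (low
expression), ties broken by gene id; RSCU for optimal-codon detection is
computed from each pool's *pooled* counts, not averaged per-gene RSCU.
A codon is optimal when RSCU_high > 1, RSCU_low < 1 and ΔRSCU > 0.08.

Two properties of this procedure are worth knowing.  First, with ~40
genes a decile pool holds only 4 genes, so pool RSCU carries sampling
noise of order ±0.1; when a codon's neutral baseline RSCU is close to 1
the RSCU_low < 1 condition loses power (this is why the synthetic
recovery scenario is AT-rich — planted G/C-ending codons have baseline
0.7 there).  Second, in data with *no* selection at all, the same noise
produces spurious detections: the ENC ranking then orders genes by
chance, and a handful of codons will pass all three rules.  Detection
counts alone therefore do not demonstrate selection.

## Selection diagnostics

The neutrality plot regresses GC12 on GC3 by OLS (slope ≈ 1: mutation
drives all positions; ≈ 0: selection decouples them).  The PR2-plot
places each gene at (G3/(G3+C3), A3/(A3+T3)); (0.5, 0.5) is the
mutation-only parity point, and quadrant counts use ≥ 0.5 as the
right/top rule.  Correspondence analysis runs per species on the
gene × 59 RSCU matrix (undefined entries as 0, all-zero columns dropped):
P = N/total, standardized residuals Dr^(−1/2)(P − rcᵀ)Dc^(−1/2) are
decomposed by SVD, principal coordinates are Dr^(−1/2)UΣ and Dc^(−1/2)VΣ,
and per-axis inertia percentages come from squared singular values
(total inertia equals χ²/total — an identity the tests exploit).
Correlations are Spearman by default (Pearson by flag), two-sided,
pairwise-complete with n ≥ 4; no multiple-testing correction is applied
by default since the convention in this literature is to report raw
p-values.

## Comparative layer

Host comparison works on frequencies per thousand codons over all 64
codons (the 64-codon denominator matches how divergence percentages are
conventionally quoted).  The ratio is species/host; a codon is divergent
when the ratio ≤ 0.5 or ≥ 2 (boundaries count as divergent), a zero host
frequency with nonzero species frequency is divergent with undefined
ratio, and codons absent from both are excluded.  The orientation is
fixed and the relation is deliberately asymmetric.  The packaged host
tables for E. coli, S. cerevisiae, N. tabacum and A. thaliana are
**synthetic snapshots** — approximate per-thousand values written from
general knowledge of those organisms' published usage and renormalised to
sum 1000 — adequate for exercising the machinery and for coarse
divergence patterns, not for publication-grade host choice; users should
supply real tables via `host_table_paths`.

Species clustering uses squared Euclidean distances between pooled
59-codon RSCU profiles and between-groups average linkage (the "intergroup
linkage" of SPSS-style packages), implemented directly (Lance–Williams
update) so that ties break deterministically on the lexicographic pair of
cluster labels; scipy's linkage serves as an independent cross-check in
the tests.  Trees serialise to newick with branch lengths taken as
differences of merge heights.

## Synthetic data generator

Each simulated gene draws a length (default 100–1,500 codons), an amino
acid sequence (first residue Met, uniform profile over the 20 residues by
default, a uniform stop appended), and synonymous codons with probability
∝ m(c)·exp(s·1[c ∈ preferred]).  The mutational weight m(c) gives a
family's G/C-ending codons total weight t (the GC3 target, split equally)
and its A/T-ending codons 1 − t, so the *synonymous* third-position GC
(GC3s) is unbiased for t.  Met and Trp are emitted as-is; because their
forced G third positions (and the stop codons) shift whole-gene GC3 away
from t mechanically (≈ +4 points at t = 0.5 under a uniform amino-acid
profile), the generator's target is defined — and verified — on GC3s.
Within-class equal splitting also makes the expected GC12 independent of
t (each family's first-two-position prefixes are represented equally in
both ending classes), which is what makes the mutation-only neutrality
slope ≈ 0 by construction rather than by accident.

Regimes: `mutation_only` (s = 0, per-gene GC3 fixed or drawn from a
range); `selection` (GC3 pinned at 0.5, all genes at strength s);
`mixed` (a fixed 25% of genes carry s, the rest are neutral — the
structure the ENC-decile procedure presumes); and `gc_driven`, where a
per-gene GC level tilts the amino-acid profile toward residues with
G/C-rich first-two positions (log-weight 4·(g − 0.5)·GC12(aa)) as well as
the third position, coupling GC12 to GC3 the way whole-genome mutation
pressure would.  The default planted preferred set contains, per
degenerate family, the codon with the smallest mutational weight in an
AT-leaning genome (the lexicographically first G/C-ending codon; ATA for
Ile) — codons genuinely dispreferred under neutrality, so selection on
them is detectable.  Randomness uses one root seed with per-gene
substreams keyed by (seed, gene index): adding genes never perturbs
earlier ones, and identical seeds give byte-identical FASTA.

What the generator does *not* emulate: phylogenetic correlation between
species (genes are i.i.d., there is no shared tree), real gene families
or length/composition covariance, amino-acid composition of actual
chloroplast proteins, and within-gene spatial structure.  Passing tests
therefore validate the *statistics*, not claims about any particular
genome.

## Fixed evaluation panel and problem sizes

The regime battery (`cubkit.synthetic.regime_battery`) is the standard
evaluation panel: mutation-only at GC3 ∈ {0.20, 0.35, 0.50, 0.65, 0.80},
selection at s ∈ {0, 0.5, 1, 2, 5} (GC3 0.5), a mixed recovery species
(GC3 0.35, s = 3, 25% of genes selected), a 200-gene GC3 ∈ (0.2, 0.8)
gradient for the neutrality slope, and two three-species clustering
regimes (GC3 0.3 vs 0.7) — 40 genes of 300–1,000 codons per set unless
noted.  These sizes mirror a chloroplast gene complement (37–41 genes)
while keeping per-gene ENC estimates stable and the whole panel cheap to
regenerate (a few seconds).  The correlation-calibration check uses 1,000
null replicates at n = 40.

## Numerical choices and degenerate inputs

Undefined statistics propagate as missing (`None`/NaN) rather than 0.
Zero skew denominators, zero PR2 denominators, unobserved RSCU families,
ENC with a missing required class, CAI with no scorable codon and CBI at
N_tot = N_ran are all undefined.  The CA drops all-zero codon columns and
reports them; identical rows give zero inertia and no axes.  Histogram
bins are left-closed; the ENC-ratio band is closed on both ends.  pI
bisection is deterministic; CA axis signs are whatever the SVD returns
(tests compare up to sign).

## Known limitations

The host tables are reconstructions (see above).  The ENC-decile
expression proxy is circular by construction (expression is *defined* by
bias), which is faithful to practice in this literature but means CAI and
the optimal-codon set are internally referenced, not anchored to measured
expression.  MILC aggregation to species level is a plain mean over
genes.  Correspondence analysis is performed on RSCU values, not raw
counts; both conventions exist in the literature and give similar but not
identical axes.
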