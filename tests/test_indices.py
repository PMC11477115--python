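"""RSCU/RFSC, ENC, SCUO, MILC, CAI, Fop/CBI and protein properties."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cubkit.composition import CodonCountTable, codon_counts
from cubkit.genetics import CODONS, DEGENERACY, FAMILIES, INFORMATIVE_CODONS, CODON_TO_AA
from cubkit.indices import (
    build_gene_index_table,
    cai,
    cai_weights,
    enc,
    expected_enc,
    fop_cbi,
    isoelectric_point,
    milc,
    protein_properties,
    rfsc,
    rscu,
    scuo,
)

from conftest import make_counts, make_gene


@st.composite
def count_tables(draw):
    n_entries = draw(st.integers(1, 20))
    codons = draw(
        st.lists(st.sampled_from(INFORMATIVE_CODONS), min_size=n_entries,
                 max_size=n_entries, unique=True)
    )
    counts = {c: draw(st.integers(1, 50)) for c in codons}
    return make_counts(**counts)


class TestRscuRfsc:
    def test_uniform_family(self):
        t = rscu(make_counts(AAA=5, AAG=5))
        assert t.values["AAA"] == t.values["AAG"] == pytest.approx(1.0)

    def test_hand_evaluation(self):
        t = rscu(make_counts(AAA=3, AAG=1))
        assert t.values["AAA"] == pytest.approx(1.5)
        assert t.values["AAG"] == pytest.approx(0.5)
        f = rfsc(make_counts(AAA=3, AAG=1))
        assert f.values["AAA"] == pytest.approx(0.75)
        assert f.values["AAG"] == pytest.approx(0.25)

    def test_single_codon_limit_six_fold(self):
        t = rscu(make_counts(TTA=7))
        assert t.values["TTA"] == pytest.approx(6.0)

    def test_unobserved_family_is_undefined(self):
        t = rscu(make_counts(AAA=1))
        assert t.values["GGG"] is None

    def test_uniform_four_fold_rfsc(self):
        f = rfsc(make_counts(GTT=2, GTC=2, GTA=2, GTG=2))
        assert all(f.values[c] == pytest.approx(0.25) for c in ("GTT", "GTC", "GTA", "GTG"))

    @given(count_tables())
    @settings(max_examples=50, deadline=None)
    def test_family_sum_identities(self, counts):
        r = rscu(counts).values
        f = rfsc(counts).values
        for aa, family in FAMILIES.items():
            if DEGENERACY[aa] < 2:
                continue
            observed = [c for c in family if r[c] is not None]
            if not observed:
                continue
            assert sum(r[c] for c in family) == pytest.approx(DEGENERACY[aa])
            assert sum(f[c] for c in family) == pytest.approx(1.0)
            for c in family:
                assert r[c] == pytest.approx(DEGENERACY[aa] * f[c])


class TestEnc:
    def test_one_codon_per_family_gives_twenty(self):
        counts = {family[0]: 5 for family in FAMILIES.values()}
        assert enc(make_counts(**counts)) == pytest.approx(20.0)

    def test_uniform_long_gene_approaches_61(self, rng):
        codons = rng.choice(INFORMATIVE_CODONS, size=3000)
        seq = "".join(codons)
        value = enc(codon_counts(make_gene("ATG" + seq + "TAA")))
        assert value == pytest.approx(61.0, abs=0.5)

    def test_concentration_never_increases_enc(self):
        # one amino acid per degeneracy class; sweep Lys usage from uniform
        # to fully concentrated and compare against a step-by-step evaluator
        base = dict(ATT=20, ATC=20, ATA=20, GTT=15, GTC=15, GTA=15, GTG=15,
                    TTA=10, TTG=10, CTT=10, CTC=10, CTA=10, CTG=10)
        previous = None
        for k in range(31):  # AAA = 30 + k, AAG = 30 - k
            value = enc(make_counts(AAA=30 + k, AAG=30 - k, **base))
            if previous is not None:
                assert value <= previous + 1e-9
            previous = value

    def test_undefined_when_required_class_missing(self):
        assert enc(make_counts(AAA=5, AAG=5)) is None  # no 4- or 6-fold aa

    def test_ile_fallback_used(self):
        counts = dict(AAA=6, AAG=2, GTT=5, GTC=3, TTA=6, TTG=2, CTT=1)
        assert enc(make_counts(**counts)) is not None  # Ile absent, imputed


class TestExpectedEnc:
    @pytest.mark.parametrize("s,value", [(0.0, 31.0), (1.0, 32.0), (0.5, 60.5)])
    def test_curve_values(self, s, value):
        assert expected_enc(s) == pytest.approx(value)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            expected_enc(1.2)

    @given(st.floats(0.0, 1.0))
    @settings(max_examples=50, deadline=None)
    def test_symmetry_up_to_linear_term(self, s):
        assert expected_enc(s) - s == pytest.approx(expected_enc(1 - s) - (1 - s))


class TestScuo:
    def test_uniform_usage_is_zero(self):
        counts = {c: 10 for c in INFORMATIVE_CODONS}
        assert scuo(make_counts(**counts)) == pytest.approx(0.0)

    def test_one_codon_per_family_is_one(self):
        counts = {family[0]: 5 for aa, family in FAMILIES.items() if DEGENERACY[aa] > 1}
        assert scuo(make_counts(**counts)) == pytest.approx(1.0)

    def test_hand_entropy_value(self):
        # Lys only: O = 1 - H(0.75, 0.25) = 0.188722
        value = scuo(make_counts(AAA=3, AAG=1))
        expected = 1 - (-(0.75 * math.log2(0.75) + 0.25 * math.log2(0.25)))
        assert value == pytest.approx(expected)
        assert value == pytest.approx(0.18872, abs=1e-5)

    def test_no_degenerate_amino_acid_is_undefined(self):
        assert scuo(make_counts(ATG=3, TGG=2)) is None

    @given(count_tables())
    @settings(max_examples=50, deadline=None)
    def test_bounded_in_unit_interval(self, counts):
        value = scuo(counts)
        assert value is None or 0.0 <= value <= 1.0 + 1e-12


class TestMilc:
    def test_null_equals_minus_correction(self):
        # gene fractions identical to reference -> sum M_a = 0, MILC = -C
        gene = make_counts(AAA=6, AAG=2, GTT=4, GTC=4)
        ref = make_counts(AAA=30, AAG=10, GTT=20, GTC=20)
        length = 16
        correction = ((2 - 1) + (4 - 1)) / length
        assert milc(gene, ref) == pytest.approx(-correction)

    def test_moving_away_from_reference_increases_milc(self):
        ref = make_counts(AAA=50, AAG=50, GTT=25, GTC=25, GTA=25, GTG=25)
        values = []
        for shift in range(0, 11, 2):  # keep L fixed at 40
            gene = make_counts(AAA=10 + shift, AAG=10 - shift,
                               GTT=5, GTC=5, GTA=5, GTG=5)
            values.append(milc(gene, ref))
        assert all(b > a for a, b in zip(values, values[1:]))

    def test_zero_reference_codon_pseudocounted(self):
        gene = make_counts(AAA=3, AAG=1)
        ref = make_counts(AAA=10)  # AAG unseen in reference
        assert math.isfinite(milc(gene, ref))


class TestCai:
    def test_weights_basics(self):
        ref = make_counts(AAA=30, AAG=10, GTT=40, GTC=20, GTA=20, GTG=20)
        w = cai_weights(ref)
        assert w["AAA"] == 1.0 and w["GTT"] == 1.0
        assert w["AAG"] == pytest.approx(10 / 30)
        scaled = cai_weights(make_counts(AAA=300, AAG=100, GTT=400, GTC=200,
                                         GTA=200, GTG=200))
        assert scaled == pytest.approx(w)

    def test_unobserved_codon_floored(self):
        w = cai_weights(make_counts(AAA=10))
        assert w["AAG"] == 0.01

    def test_geometric_mean(self):
        ref = make_counts(AAA=40, AAG=10)
        w = cai_weights(ref)
        gene = make_counts(AAA=1, AAG=1)
        assert cai(gene, w) == pytest.approx(math.sqrt(1.0 * 0.25))

    def test_only_top_codons_give_one(self):
        ref = make_counts(AAA=40, AAG=10, GAA=7, GAG=3)
        gene = make_counts(AAA=5, GAA=2)
        assert cai(gene, cai_weights(ref)) == pytest.approx(1.0)

    @given(count_tables())
    @settings(max_examples=30, deadline=None)
    def test_bounded(self, counts):
        ref = make_counts(**{c: 10 for c in INFORMATIVE_CODONS})
        value = cai(counts, cai_weights(ref))
        assert value is None or 0.0 < value <= 1.0 + 1e-12


class TestFopCbi:
    def test_all_optimal(self):
        fop, cbi = fop_cbi(make_counts(AAA=10, GTT=5), {"AAA", "GTT"})
        assert fop == 1.0 and cbi == pytest.approx(1.0)

    def test_uniform_usage_gives_cbi_zero(self):
        counts = make_counts(AAA=10, AAG=10, GTT=5, GTC=5, GTA=5, GTG=5)
        fop, cbi = fop_cbi(counts, {"AAA", "GTT"})
        assert cbi == pytest.approx(0.0)
        assert fop == pytest.approx((10 + 5) / 40)

    def test_empty_optimal_set(self):
        fop, cbi = fop_cbi(make_counts(AAA=10, AAG=2), set())
        assert fop == 0.0


class TestProteinProperties:
    def test_poly_ile_gravy(self):
        gene = make_gene("ATG" + "ATT" * 99 + "TAA")
        l_aa, gravy, arom, _ = protein_properties(gene)
        assert l_aa == 100
        assert gravy == pytest.approx((1.9 + 99 * 4.5) / 100)  # Met + 99 Ile
        assert arom == 0.0

    def test_hand_translation(self):
        l_aa, _, _, _ = protein_properties(make_gene("ATGAAATAA"))
        assert l_aa == 2  # Met-Lys

    def test_aromaticity_counts_fyw(self):
        gene = make_gene("ATG" + "TTT" + "TAT" + "TGG" + "AAA" * 4 + "TAA")
        _, _, arom, _ = protein_properties(gene)
        assert arom == pytest.approx(3 / 8)

    def test_pi_ordering_acidic_vs_basic(self):
        acidic = "".join("GAA" for _ in range(20))  # poly-Glu
        basic = "".join("AAA" for _ in range(20))  # poly-Lys
        pi_acid = protein_properties(make_gene("ATG" + acidic + "TAA"))[3]
        pi_base = protein_properties(make_gene("ATG" + basic + "TAA"))[3]
        assert pi_acid < 5 < 9 < pi_base

    def test_pi_neutral_charge_at_solution(self):
        protein = "MKDEHRYC"
        pi = isoelectric_point(protein)
        from cubkit.indices import _net_charge

        assert abs(_net_charge(protein, pi)) < 1e-4


class TestMasterTable:
    def test_columns_and_laa_invariant(self, battery):
        cds_set, _ = battery["mut_gc35"]
        df = build_gene_index_table(cds_set)
        assert len(df) == len(cds_set)
        for col in ("ENC", "SCUO", "MILC", "CAI", "Fop", "GC3s", "at_skew", "pI"):
            assert col in df.columns
        lengths = {g.id: len(g.seq) // 3 - 1 for g in cds_set}
        assert all(df["L_aa"].to_numpy() == df["gene_id"].map(lengths).to_numpy())
        assert df["SCUO"].between(0, 1).all()
        assert (df["ENC"] <= 61.0 + 1e-9).all()
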