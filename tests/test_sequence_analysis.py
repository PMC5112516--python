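"""Tests of tagging, alignment scoring, charge, mass and basicity ordering."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sul7d.datasets import SAC7D_SEQUENCE, load_sac7d, load_study_sequences
from sul7d.sequence_analysis import (
    DEFAULT_PKA_TABLE,
    DEFAULT_SIMILARITY_SCHEME,
    STANDARD_RESIDUES,
    GlobalAlignment,
    ProteinRecord,
    SimilarityScheme,
    TaggingError,
    WATER_MASS,
    apply_expression_tag,
    average_mass,
    basicity_order,
    global_align,
    isoelectric_point,
    net_charge,
    pair_score,
)

residues = st.text(alphabet=STANDARD_RESIDUES, min_size=1, max_size=30)


def brute_force_best_alignment_score(a, b, match, mismatch, gap):
    """Independent oracle: enumerate all global alignments recursively (linear gaps)."""
    if not a:
        return gap * len(b)
    if not b:
        return gap * len(a)
    sub = match if a[0] == b[0] else mismatch
    return max(
        sub + brute_force_best_alignment_score(a[1:], b[1:], match, mismatch, gap),
        gap + brute_force_best_alignment_score(a[1:], b, match, mismatch, gap),
        gap + brute_force_best_alignment_score(a, b[1:], match, mismatch, gap),
    )


class TestExpressionTag:
    def test_minimal_legal_input(self):
        rec = apply_expression_tag(ProteinRecord(name="x", sequence="MK"))
        assert rec.sequence == "MRGSHHHHHHGSKLN"
        assert rec.tagged

    def test_last_lysine_rule(self):
        rec = apply_expression_tag(ProteinRecord(name="x", sequence="MAKVK"))
        assert rec.sequence == "MRGSHHHHHHGSAKVKLN"

    def test_residues_after_last_lysine_preserved(self):
        rec = apply_expression_tag(ProteinRecord(name="x", sequence="MAKVKAQ"))
        assert rec.sequence == "MRGSHHHHHHGSAKVKLNAQ"
        assert len(rec.sequence) == 7 + 13

    def test_tagged_sac7d_mass_is_9103(self):
        tagged = apply_expression_tag(load_sac7d())
        assert round(average_mass(tagged)) == 9103

    @pytest.mark.parametrize("seq", ["AKVK", "MAAA"])
    def test_rule_violations_rejected(self, seq):
        with pytest.raises(TaggingError):
            apply_expression_tag(ProteinRecord(name="x", sequence=seq))

    def test_double_tagging_rejected(self):
        tagged = apply_expression_tag(ProteinRecord(name="x", sequence="MK"))
        with pytest.raises(TaggingError, match="already"):
            apply_expression_tag(tagged)


class TestGlobalAlign:
    def test_self_alignment_is_gap_free_identity(self):
        aln = global_align(SAC7D_SEQUENCE, SAC7D_SEQUENCE)
        assert aln.a == aln.b == SAC7D_SEQUENCE
        assert pair_score(aln).identity_pct == 100.0

    def test_matches_exhaustive_enumeration(self):
        cases = [("KAE", "KE"), ("KRDE", "RKED"), ("MVKV", "MKV"), ("AC", "CA")]
        for a, b in cases:
            aln = global_align(a, b, match=1, mismatch=-1, gap_open=-2, gap_extend=-2)
            assert aln.score == brute_force_best_alignment_score(a, b, 1, -1, -2)

    def test_specific_gap_placement(self):
        aln = global_align("KAE", "KE", match=1, mismatch=-1, gap_open=-2, gap_extend=-2)
        assert (aln.a, aln.b) == ("KAE", "K-E")

    def test_score_symmetric(self):
        a, b = "MVKVKFKYKG", "MVKAKFKYG"
        assert global_align(a, b).score == global_align(b, a).score

    def test_gap_removal_restores_inputs(self):
        aln = global_align("MVKVKFKYKG", "MVKKFKYKGAA")
        assert aln.a.replace("-", "") == "MVKVKFKYKG"
        assert aln.b.replace("-", "") == "MVKKFKYKGAA"

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            global_align("", "KE")


class TestPairScore:
    def test_identical_sequences_score_100(self):
        aln = global_align("MVKVK", "MVKVK")
        s = pair_score(aln)
        assert s.identity_pct == s.similarity_pct == 100.0

    def test_conservative_substitutions_full_similarity_zero_identity(self):
        # K<->R (basic), R<->K, D<->E (acidic), E<->D: same-group everywhere
        aln = GlobalAlignment(a="KRDE", b="RKED", score=0.0)
        s = pair_score(aln)
        assert s.identity_pct == 0.0
        assert s.similarity_pct == 100.0

    def test_denominator_conventions(self):
        aln = global_align("KAE", "KE", match=1, mismatch=-1, gap_open=-2, gap_extend=-2)
        short = pair_score(aln, denominator="shorter_sequence")
        full = pair_score(aln, denominator="alignment_length")
        assert short.identity_pct == pytest.approx(100.0)  # 2 identities / 2
        assert full.identity_pct == pytest.approx(100.0 * 2 / 3)
        with pytest.raises(ValueError):
            pair_score(aln, denominator="bogus")

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(residues, residues)
    def test_identity_never_exceeds_similarity(self, a, b):
        s = pair_score(global_align(a, b))
        assert s.identity_pct <= s.similarity_pct + 1e-9

    def test_symmetric_in_sequence_order(self):
        pairs = itertools.combinations([r.sequence for r in load_study_sequences()][:5], 2)
        for a, b in pairs:
            sab = pair_score(global_align(a, b))
            sba = pair_score(global_align(b, a))
            assert sab.identity_pct == pytest.approx(sba.identity_pct)
            assert sab.similarity_pct == pytest.approx(sba.similarity_pct)


class TestSimilarityScheme:
    def test_default_partitions_all_20_residues(self):
        covered = "".join(DEFAULT_SIMILARITY_SCHEME.groups.values())
        assert sorted(covered) == sorted(STANDARD_RESIDUES)

    def test_overlap_and_gaps_rejected(self):
        with pytest.raises(ValueError):
            SimilarityScheme(groups={"a": "GAVLI", "b": "IFYW"})
        with pytest.raises(ValueError):
            SimilarityScheme(groups={"a": "GAVLI"})


class TestNetCharge:
    def test_polyglycine_termini_only(self):
        # hand Henderson-Hasselbalch: +1/(1+10^(7.4-8.6)) - 1/(1+10^(3.6-7.4))
        assert net_charge("GGGGG", 7.4) == pytest.approx(-0.0592, abs=5e-4)

    def test_full_protonation_limit_at_ph_0(self):
        seq = "MKRHKDE"
        expected = seq.count("K") + seq.count("R") + seq.count("H") + 1
        assert net_charge(seq, 0.0) == pytest.approx(expected, abs=0.2)

    def test_strictly_decreasing_in_ph(self):
        charges = [net_charge(SAC7D_SEQUENCE, ph) for ph in np.linspace(0, 14, 30)]
        assert np.all(np.diff(charges) < 0)

    def test_ph_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            net_charge("MK", -0.1)

    def test_all_pka_values_physical(self):
        for pka in DEFAULT_PKA_TABLE.side_chains.values():
            assert 0 < pka < 14


class TestAverageMass:
    def test_single_glycine(self):
        assert average_mass("G") == pytest.approx(75.07, abs=0.01)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(residues, residues)
    def test_concatenation_additivity(self, a, b):
        assert average_mass(a + b) == pytest.approx(
            average_mass(a) + average_mass(b) - WATER_MASS, abs=1e-9
        )

    def test_unknown_residue_rejected(self):
        with pytest.raises(ValueError, match="unknown residue"):
            average_mass("GX")


class TestBasicityOrder:
    def test_single_record(self):
        rec = ProteinRecord(name="a", sequence="MKKK")
        assert basicity_order([rec]) == [rec]

    def test_acidic_rich_sorts_first(self):
        acid = ProteinRecord(name="acid", sequence="MDDDDEEEE")
        base = ProteinRecord(name="base", sequence="MKKKKRRRR")
        assert [r.name for r in basicity_order([base, acid])] == ["acid", "base"]

    def test_isoelectric_point_is_charge_root(self):
        pi = isoelectric_point(SAC7D_SEQUENCE)
        assert abs(net_charge(SAC7D_SEQUENCE, pi)) < 1e-6
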