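from __future__ import annotations

import pytest

from conftest import random_gapped_alignment
from oracles import label_columns_and_group
from tgeclass.errors import ContractError, ValidationError
from tgeclass.homology import MainClass, PairwiseAlignment, align_local
from tgeclass.io_formats import ReferenceProtein
from tgeclass.variation import (
    assign_subclass,
    classify_terminals,
    compute_midline,
    detect_alt_start,
    extract_events,
    reconstruct_tge,
    subclass_label,
)


def _aln(q_aln, s_aln, matrix, q_start=1, s_start=1):
    q_res = sum(c != "-" for c in q_aln)
    s_res = sum(c != "-" for c in s_aln)
    return PairwiseAlignment(
        "q", "s", 1e-40, 100.0, q_start, q_start + q_res - 1,
        s_start, s_start + s_res - 1, q_aln, s_aln,
        compute_midline(q_aln, s_aln, matrix),
    )


class TestComputeMidline:
    def test_identity_columns_show_the_letter(self, blosum80):
        assert compute_midline("AC", "AC", blosum80) == "AC"

    def test_positive_substitution_is_plus(self, blosum80):
        assert blosum80["L", "I"] > 0
        assert compute_midline("L", "I", blosum80) == "+"

    def test_negative_substitution_is_space(self, blosum80):
        assert blosum80["G", "W"] < 0
        assert compute_midline("G", "W", blosum80) == " "

    def test_gap_column_is_space(self, blosum80):
        assert compute_midline("A-C", "ADC", blosum80) == "A C"

    def test_length_mismatch_rejected(self, blosum80):
        with pytest.raises(ValidationError):
            compute_midline("AC", "A", blosum80)

    def test_gap_on_gap_rejected(self, blosum80):
        with pytest.raises(ValidationError):
            compute_midline("A-C", "A-C", blosum80)


class TestExtractEvents:
    def test_single_similar_mismatch_is_ssap(self, blosum80):
        # D->N scores positive in BLOSUM80, hence SSAP not SAP
        assert blosum80["D", "N"] > 0
        events = extract_events(_aln("ACDEFG", "ACNEFG", blosum80))
        assert len(events) == 1
        e = events[0]
        assert (e.type, e.tge_start, e.tge_end, e.tge_seq, e.ref_seq) == (
            "SSAP", 3, 3, "D", "N",
        )

    def test_ten_consecutive_mismatches_are_one_sv(self, blosum80):
        q = "AA" + "W" * 10 + "AA"
        s = "AA" + "G" * 10 + "AA"
        events = extract_events(_aln(q, s, blosum80))
        assert [e.type for e in events] == ["SV"]

    def test_deletion_carries_reference_residues_only(self, blosum80):
        events = extract_events(_aln("AC-EF", "ACDEF", blosum80))
        assert len(events) == 1
        e = events[0]
        assert (e.type, e.tge_seq, e.ref_seq) == ("DEL", "", "D")
        assert (e.tge_start, e.tge_end, e.ref_start, e.ref_end) == (2, 2, 3, 3)

    def test_insertion_is_the_mirror_case(self, blosum80):
        events = extract_events(_aln("ACDEF", "AC-EF", blosum80))
        e = events[0]
        assert (e.type, e.tge_seq, e.ref_seq) == ("INS", "D", "")
        assert (e.tge_start, e.tge_end, e.ref_start, e.ref_end) == (3, 3, 2, 2)

    def test_offset_coordinates_follow_alignment_start(self, blosum80):
        events = extract_events(_aln("ACDEFG", "ACNEFG", blosum80, q_start=11, s_start=21))
        assert (events[0].tge_start, events[0].ref_start) == (13, 23)

    def test_matches_column_labelling_oracle_on_random_alignments(self, rng, blosum80):
        for _ in range(120):
            aln = random_gapped_alignment(rng, blosum80)
            got = [
                (e.type, e.tge_start, e.tge_end, e.ref_start, e.ref_end,
                 e.tge_seq, e.ref_seq)
                for e in extract_events(aln)
            ]
            expected = label_columns_and_group(
                aln.q_aln, aln.s_aln, aln.q_start, aln.s_start, blosum80
            )
            assert got == expected

    def test_every_nonidentity_column_is_in_exactly_one_event(self, rng, blosum80):
        for _ in range(40):
            aln = random_gapped_alignment(rng, blosum80)
            n_nonident = sum(
                1 for qc, sc in zip(aln.q_aln, aln.s_aln) if qc != sc
            )
            span = 0
            for e in extract_events(aln):
                if e.tge_seq and e.ref_seq:
                    span += len(e.tge_seq)
                else:
                    span += len(e.tge_seq) + len(e.ref_seq)
            assert span == n_nonident


class TestTerminals:
    def test_four_basic_kinds(self, blosum80):
        aln = _aln("ACDEFG", "ACDEFG", blosum80, q_start=1, s_start=21)
        n, c = classify_terminals(aln, tge_len=6, ref_len=26)
        assert (n.kind, n.ref_overhang_len) == ("truncated", 20)
        assert c.kind == "identical"

        aln = _aln("ACDEFG", "ACDEFG", blosum80, q_start=5, s_start=1)
        n, c = classify_terminals(aln, tge_len=10, ref_len=6)
        assert (n.kind, n.tge_overhang_len) == ("extended", 4)

        aln = _aln("ACDEFG", "ACDEFG", blosum80, q_start=3, s_start=4)
        n, _ = classify_terminals(aln, tge_len=8, ref_len=9)
        assert n.kind == "alternative"

    def test_full_coverage_is_identical_on_both_ends(self, blosum80):
        aln = _aln("ACDEFG", "ACDEFG", blosum80)
        n, c = classify_terminals(aln, 6, 6)
        assert (n.kind, c.kind) == ("identical", "identical")

    def test_out_of_range_coordinates_rejected(self, blosum80):
        aln = _aln("ACDEFG", "ACDEFG", blosum80)
        with pytest.raises(ValidationError):
            classify_terminals(aln, 5, 6)

    def test_subclass_labels_cover_the_15_terminal_combinations(self):
        from tgeclass.variation import TerminalVariation

        labels = set()
        for nk in ("identical", "truncated", "extended", "alternative"):
            for ck in ("identical", "truncated", "extended", "alternative"):
                lab = subclass_label(
                    (TerminalVariation("N", nk, 1, 1), TerminalVariation("C", ck, 1, 1))
                )
                if lab is not None:
                    labels.add(lab)
        assert len(labels) == 15


class TestAssignSubclass:
    def _terminals(self, blosum80, q, s, tge_len, ref_len, q_start=1, s_start=1):
        aln = _aln(q, s, blosum80, q_start=q_start, s_start=s_start)
        return aln, classify_terminals(aln, tge_len, ref_len)

    def test_full_length_sap_is_known_with_polymorphism(self, blosum80):
        aln, terms = self._terminals(blosum80, "ACDEFG", "ACNEFG", 6, 6)
        cls = assign_subclass(
            MainClass("candidate_variant", "s"), extract_events(aln), terms
        )
        assert (cls.main_class, cls.subclass) == ("known_with_polymorphism", None)

    def test_full_length_sv_is_novel_isoform_sv(self, blosum80):
        q = "AA" + "W" * 12 + "AA"
        s = "AA" + "G" * 12 + "AA"
        aln, terms = self._terminals(blosum80, q, s, 16, 16)
        cls = assign_subclass(
            MainClass("candidate_variant", "s"), extract_events(aln), terms
        )
        assert (cls.main_class, cls.subclass) == ("novel_isoform", "SV")

    def test_truncation_names_the_terminus(self, blosum80):
        aln, terms = self._terminals(blosum80, "ACDEFG", "ACDEFG", 6, 26, s_start=21)
        cls = assign_subclass(MainClass("candidate_variant", "s"), [], terms)
        assert (cls.main_class, cls.subclass) == ("novel_isoform", "N_truncated")

    def test_double_ended_label(self, blosum80):
        aln, terms = self._terminals(
            blosum80, "ACDEFG", "ACDEFG", tge_len=10, ref_len=26, q_start=3, s_start=21
        )
        cls = assign_subclass(MainClass("candidate_variant", "s"), [], terms)
        assert cls.subclass == "N_alternative+C_extended"

    def test_resolved_main_classes_are_rejected(self, blosum80):
        _, terms = self._terminals(blosum80, "ACDEFG", "ACDEFG", 6, 6)
        with pytest.raises(ContractError):
            assign_subclass(MainClass("known_protein", "s"), [], terms)


class TestDetectAltStart:
    ref = ReferenceProtein("R1", "M" + "AGLE" * 10 + "KVTSDQNH" * 5)

    def _aln_starting_at(self, s_start, tge_seq, blosum80):
        ref_part = self.ref.aa_sequence[s_start - 1 : s_start - 1 + len(tge_seq)]
        return _aln(tge_seq, ref_part, blosum80, q_start=1, s_start=s_start)

    def test_discounted_when_preceded_by_lysine(self, blosum80):
        # reference position 42 is K; a start at 43 ("V") must be discounted
        assert self.ref.aa_sequence[41] == "K"
        tge = self.ref.aa_sequence[42:62]
        alt = detect_alt_start(tge, self._aln_starting_at(43, tge, blosum80), self.ref)
        assert (alt.residue, alt.ref_pos, alt.discounted) == ("V", 43, True)

    def test_accepted_when_preceded_by_glycine(self, blosum80):
        assert self.ref.aa_sequence[2] == "G"
        tge = self.ref.aa_sequence[3:33]
        alt = detect_alt_start(tge, self._aln_starting_at(4, tge, blosum80), self.ref)
        assert (alt.residue, alt.discounted, alt.category) == ("L", False, "alt_start")

    def test_met_removed_reported_separately(self, blosum80):
        tge = self.ref.aa_sequence[1:31]
        alt = detect_alt_start(tge, self._aln_starting_at(2, tge, blosum80), self.ref)
        assert (alt.category, alt.ref_pos, alt.discounted) == ("met_removed", 2, False)

    def test_canonical_start_gives_none(self, blosum80):
        tge = self.ref.aa_sequence[:30]
        assert detect_alt_start(tge, self._aln_starting_at(1, tge, blosum80), self.ref) is None

    def test_partial_alignment_gives_none(self, blosum80):
        tge = "CC" + self.ref.aa_sequence[3:33]
        aln = _aln(tge[2:], self.ref.aa_sequence[3:33], blosum80, q_start=3, s_start=4)
        assert detect_alt_start(tge, aln, self.ref) is None


class TestReconstruction:
    def test_replaying_events_recovers_the_tge(self, rng, blosum80):
        """Round trip: reference + events + overhangs == TGE sequence."""
        for _ in range(50):
            aln = random_gapped_alignment(rng, blosum80)
            tge = "X" * (aln.q_start - 1) + aln.q_aln.replace("-", "") + "X" * 3
            ref = "Y" * (aln.s_start - 1) + aln.s_aln.replace("-", "") + "Y" * 2
            aln2 = PairwiseAlignment(
                "q", "s", aln.e_value, aln.bit_score, aln.q_start,
                aln.q_start + sum(c != "-" for c in aln.q_aln) - 1,
                aln.s_start, aln.s_start + sum(c != "-" for c in aln.s_aln) - 1,
                aln.q_aln, aln.s_aln, aln.midline,
            )
            events = extract_events(aln2)
            assert reconstruct_tge(tge, ref, aln2, events) == tge
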