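from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import enumerate_tryptic_peptides
from tgeclass.errors import ContractError, ValidationError
from tgeclass.evidence import (
    Occurrence,
    PeptideEvidence,
    build_tge_set,
    compute_qvalues,
    coverage,
    digest,
    find_occurrences,
    flag_variant_peptides,
    variant_regions,
)
from tgeclass.homology import MainClass, align_local
from tgeclass.io_formats import OrfRecord, PsmRecord
from tgeclass.variation import (
    TerminalVariation,
    TgeClassification,
    VariationEvent,
)

AA20 = "ACDEFGHIKLMNPQRSTVWY"


class TestDigest:
    def test_kp_site_is_not_cleaved(self):
        peps = [(p.peptide, p.start, p.end) for p in digest("MKRAGKP")]
        assert peps == [("MK", 1, 2), ("R", 3, 3), ("AGKP", 4, 7)]

    def test_sequence_without_sites_is_one_peptide(self):
        assert [(p.peptide, p.start, p.end) for p in digest("AAAA")] == [("AAAA", 1, 4)]

    def test_missed_cleavages_add_joined_peptides(self):
        peps = {p.peptide for p in digest("MKRAGK", missed_cleavages=1)}
        assert {"MKR", "RAGK"} <= peps

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValidationError):
            digest("")

    @pytest.mark.parametrize("mc", [0, 1, 2])
    def test_matches_enumeration_oracle(self, rng, mc):
        for _ in range(30):
            seq = "".join(rng.choice(list(AA20), size=int(rng.integers(5, 60))))
            got = [(p.peptide, p.start, p.end) for p in digest(seq, mc)]
            assert got == enumerate_tryptic_peptides(seq, mc)

    def test_kp_suppression_can_be_disabled(self):
        got = [(p.peptide, p.start, p.end) for p in digest("MKPA", kp_suppression=False)]
        assert got == enumerate_tryptic_peptides("MKPA", 0, kp_suppression=False)
        assert got[0][0] == "MK"


def _psm(spectrum, pep, score, decoy, q=0.0):
    return PsmRecord(spectrum, pep, ["X"], q, search_score=score, is_decoy=decoy)


class TestComputeQvalues:
    def test_hand_computed_target_decoy_example(self):
        out = compute_qvalues(
            [_psm("a", "PEPTIDEK", 10, False), _psm("b", "PEPTIDER", 9, True),
             _psm("c", "PEPTIDEL", 8, False)]
        )
        assert [p.q_value for p in out] == [0.0, 0.5]
        assert all(not p.is_decoy for p in out)

    def test_no_decoys_gives_zero_qvalues(self):
        out = compute_qvalues([_psm("a", "AK", 5, False), _psm("b", "CK", 4, False)])
        assert [p.q_value for p in out] == [0.0, 0.0]

    def test_all_decoys_gives_empty_output(self):
        assert compute_qvalues([_psm("a", "AK", 5, True)]) == []

    def test_missing_score_is_a_contract_error(self):
        with pytest.raises(ContractError):
            compute_qvalues([PsmRecord("a", "AK", ["X"], 0.0, is_decoy=False)])


def _orf(orf_id, seq, completeness="complete"):
    return OrfRecord(orf_id, orf_id, seq, completeness)


def _ipsm(pep, q=0.001):
    return PsmRecord(f"s_{pep}_{q}", pep, [], q)


class TestBuildTgeSet:
    seq_a = "MAAAGTKWWLLNDEKVVVTTTR"

    def test_one_peptide_is_not_enough(self):
        tges, _ = build_tge_set([_orf("o1", self.seq_a)], [_ipsm("MAAAGTK")])
        assert tges.tges == {}

    def test_two_peptides_retain_the_orf(self):
        tges, evidence = build_tge_set(
            [_orf("o1", self.seq_a)], [_ipsm("MAAAGTK"), _ipsm("WWLLNDEK")]
        )
        assert list(tges.tges) == ["o1"]
        assert {e.peptide for e in evidence} == {"MAAAGTK", "WWLLNDEK"}

    def test_q_above_threshold_is_excluded(self):
        tges, _ = build_tge_set(
            [_orf("o1", self.seq_a)],
            [_ipsm("MAAAGTK"), _ipsm("WWLLNDEK", q=0.011)],
            q_threshold=0.01,
        )
        assert tges.tges == {}

    def test_duplicate_sequences_merge_into_one_tge(self):
        tges, evidence = build_tge_set(
            [_orf("o2", self.seq_a), _orf("o1", self.seq_a)],
            [_ipsm("MAAAGTK"), _ipsm("WWLLNDEK")],
        )
        assert list(tges.tges) == ["o1"]
        assert tges.tges["o1"].member_orf_ids == ["o1", "o2"]
        # a peptide hitting both members of one merged TGE stays unique
        assert all(e.is_unique for e in evidence)

    def test_min_q_over_psms_is_kept(self):
        _, evidence = build_tge_set(
            [_orf("o1", self.seq_a)],
            [_ipsm("MAAAGTK", 0.004), _ipsm("MAAAGTK", 0.001), _ipsm("WWLLNDEK")],
        )
        q = {e.peptide: e.q_value for e in evidence}
        assert q["MAAAGTK"] == 0.001

    def test_identical_peptide_sets_form_one_ambiguity_group(self):
        seq_b = "MCCCGTKWWLLNDEKVVVTTTR"  # shares 2 of 3 peptides with seq_a
        tges, _ = build_tge_set(
            [_orf("o1", self.seq_a), _orf("o2", seq_b)],
            [_ipsm("WWLLNDEK"), _ipsm("VVVTTTR")],
        )
        assert tges.ambiguity_groups == [["o1", "o2"]]

    def test_subset_peptide_sets_attach_to_the_superset_group(self):
        seq_b = "MCCCGTKWWLLNDEKVVVTTTR"
        tges, _ = build_tge_set(
            [_orf("o1", self.seq_a), _orf("o2", seq_b)],
            [_ipsm("MAAAGTK"), _ipsm("WWLLNDEK"), _ipsm("VVVTTTR")],
        )
        # o2's peptide set is a strict subset of o1's
        assert tges.ambiguity_groups == [["o1", "o2"]]

    def test_filters_are_monotone(self, rng):
        orfs = []
        peptides = []
        for i in range(6):
            seq = "M" + "".join(rng.choice(list(AA20), size=60))
            orfs.append(_orf(f"o{i}", seq))
        psms = []
        for i, orf in enumerate(orfs):
            from tgeclass.evidence import digest as _dig

            for p in _dig(orf.aa_sequence, 0, 5, 30)[:3]:
                psms.append(_ipsm(p.peptide, q=0.001 * (i + 1)))
        strict, _ = build_tge_set(orfs, psms, q_threshold=0.003, min_peptides=2)
        loose, _ = build_tge_set(orfs, psms, q_threshold=0.006, min_peptides=1)
        assert set(strict.tges) <= set(loose.tges)


class TestVariantFlags:
    def _classification(self, tge_id="t1"):
        aln = align_local("M" + "A" * 49 + "W" + "A" * 49, "M" + "A" * 99)
        cls = TgeClassification(
            tge_id=tge_id, main_class="known_with_polymorphism",
            events=[VariationEvent("SAP", 51, 51, 51, 51, "W", "A")],
            terminals=(TerminalVariation("N", "identical"),
                       TerminalVariation("C", "identical")),
            best_hit="r", alignment=aln,
        )
        return cls

    def _evidence(self, spans, tge_id="t1"):
        return [
            PeptideEvidence(f"P{i}", 0.001, [Occurrence(tge_id, a, b)])
            for i, (a, b) in enumerate(spans)
        ]

    def test_peptide_across_a_sap_is_variant_and_junction(self):
        cls = self._classification()
        evid = self._evidence([(45, 55)])
        flag_variant_peptides(cls, evid, "M" + "A" * 49 + "W" + "A" * 49)
        occ = evid[0].occurrences[0]
        assert (occ.overlaps_variant, occ.is_junction) == (True, True)

    def test_peptide_away_from_variants_is_clean(self):
        cls = self._classification()
        evid = self._evidence([(5, 20)])
        flag_variant_peptides(cls, evid, "M" + "A" * 49 + "W" + "A" * 49)
        occ = evid[0].occurrences[0]
        assert (occ.overlaps_variant, occ.is_junction) == (False, False)

    def test_peptide_entirely_inside_an_overhang_is_not_junction(self):
        from tgeclass.homology import PairwiseAlignment

        tge = "C" * 20 + "M" + "A" * 79
        aligned = "M" + "A" * 79
        aln = PairwiseAlignment("t1", "r", 1e-60, 200.0, 21, 100, 1, 80,
                                aligned, aligned, aligned)
        cls = TgeClassification(
            tge_id="t1", main_class="novel_isoform", subclass="N_extended",
            terminals=(TerminalVariation("N", "extended", 20, 0),
                       TerminalVariation("C", "truncated", 0, 20)),
            best_hit="r", alignment=aln,
        )
        evid = self._evidence([(3, 15), (30, 40)])
        flag_variant_peptides(cls, evid, tge)
        inside, outside = evid[0].occurrences[0], evid[1].occurrences[0]
        assert (inside.overlaps_variant, inside.is_junction) == (True, False)
        assert (outside.overlaps_variant, outside.is_junction) == (False, False)

    def test_deletion_flags_its_flanking_residues(self):
        cls = TgeClassification(
            tge_id="t1", main_class="known_with_polymorphism",
            events=[VariationEvent("DEL", 30, 30, 31, 33, "", "DDD")],
            terminals=(TerminalVariation("N", "identical"),
                       TerminalVariation("C", "identical")),
        )
        assert variant_regions(cls, 100) == [(30, 31)]

    def test_junction_implies_variant_overlap(self, rng):
        cls = self._classification()
        spans = [(int(a), int(a) + 8) for a in rng.integers(1, 90, size=40)]
        evid = self._evidence(spans)
        flag_variant_peptides(cls, evid, "M" + "A" * 49 + "W" + "A" * 49)
        for e in evid:
            occ = e.occurrences[0]
            assert not occ.is_junction or occ.overlaps_variant


class TestCoverage:
    def test_no_peptides_is_zero(self):
        assert coverage("A" * 100, [], "t1") == 0.0

    def test_overlapping_peptides_count_residues_once(self):
        evid = [
            PeptideEvidence("P1", 0.0, [Occurrence("t1", 1, 10)]),
            PeptideEvidence("P2", 0.0, [Occurrence("t1", 6, 15)]),
        ]
        assert coverage("A" * 100, evid, "t1") == pytest.approx(0.15)

    def test_single_peptide_fraction(self):
        evid = [PeptideEvidence("P1", 0.0, [Occurrence("t1", 11, 20)])]
        assert coverage("A" * 100, evid, "t1") == pytest.approx(0.10)


def test_find_occurrences_reports_overlapping_hits():
    assert find_occurrences("AA", "AAA") == [(1, 2), (2, 3)]
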