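"""Peptide-level evidence: digestion, FDR, TGE retention and variant flags.

The sample's identification set is reduced to TGEs as follows: PSMs are
thresholded at a global q-value cut-off (default 1% FDR), peptides are
located in ORF sequences by exact substring search (every occurrence —
input accession lists are not trusted), ORFs with at least two distinct
identified peptides are retained, ORFs with identical amino-acid sequence
are merged into a single TGE, and protein ambiguity groups are formed from
TGEs with identical identified-peptide sets (TGEs whose peptide set is a
strict subset of a group's set are attached to that group).

Tryptic digestion cleaves after K or R except before P (the classic rule;
the proline suppression is configurable). Peptide uniqueness is defined
against the sample's own TGE set, not the reference proteome: a peptide
hitting two ORFs merged into one TGE is still unique.

A peptide occurrence *overlaps a variant* when its interval intersects any
event interval or terminal-overhang interval of the TGE (a deletion,
having no TGE extent, contributes its two flanking residues); it is a
*junction* peptide when it covers at least one residue strictly inside a
variant region and at least one residue aligned identically to the
reference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from pyteomics import parser as pyt_parser

from .errors import ContractError, ValidationError
from .io_formats import OrfRecord, PsmRecord
from .variation import TgeClassification

logger = logging.getLogger(__name__)

TRYPSIN_RULE = r"[KR](?!P)"
TRYPSIN_RULE_NO_EXCEPTION = r"[KR]"

DEFAULT_Q_THRESHOLD = 0.01
DEFAULT_MIN_PEPTIDES = 2
DEFAULT_MIN_PEP_LEN = 7
DEFAULT_MAX_PEP_LEN = 45


@dataclass(frozen=True)
class DigestedPeptide:
    peptide: str
    start: int  # 1-based inclusive
    end: int


def digest(
    sequence: str,
    missed_cleavages: int = 0,
    min_len: int = 1,
    max_len: Optional[int] = None,
    kp_suppression: bool = True,
) -> list[DigestedPeptide]:
    """In-silico tryptic digestion with coordinates.

    Returns every peptide with at most ``missed_cleavages`` internal
    cleavage sites and length within ``[min_len, max_len]``, ordered by
    position.
    """
    if not sequence:
        raise ValidationError("cannot digest an empty sequence")
    if missed_cleavages < 0:
        raise ValidationError("missed_cleavages must be >= 0")
    if min_len < 1 or (max_len is not None and max_len < min_len):
        raise ValidationError("require 1 <= min_len <= max_len")
    rule = TRYPSIN_RULE if kp_suppression else TRYPSIN_RULE_NO_EXCEPTION
    # the cleaver re-emits the terminal span once per missed-cleavage count;
    # a peptide is one (start, end) stretch, so deduplicate by span
    spans: dict[tuple[int, int], DigestedPeptide] = {}
    for start, pep in pyt_parser.icleave(
        sequence, rule, missed_cleavages=missed_cleavages,
        min_length=min_len, max_length=max_len, regex=True,
    ):
        spans.setdefault((start + 1, start + len(pep)),
                         DigestedPeptide(pep, start + 1, start + len(pep)))
    return [spans[k] for k in sorted(spans)]


def compute_qvalues(psms: Sequence[PsmRecord]) -> list[PsmRecord]:
    """Target-decoy q-values.

    PSMs are ranked by search score (descending, stable); the FDR at rank
    i is (#decoys at or above i) / (#targets at or above i) and the
    q-value is the cumulative minimum of FDR taken from the bottom of the
    list. Decoy PSMs are removed from the output.
    """
    for p in psms:
        if p.search_score is None:
            raise ContractError(f"PSM {p.spectrum_id!r} has no search score")
    ranked = sorted(psms, key=lambda p: -p.search_score)
    n_decoys = 0
    n_targets = 0
    fdrs: list[float] = []
    for p in ranked:
        if p.is_decoy:
            n_decoys += 1
        else:
            n_targets += 1
        fdrs.append(min(1.0, n_decoys / n_targets) if n_targets else 1.0)
    running = 1.0
    qvals = [0.0] * len(ranked)
    for i in range(len(ranked) - 1, -1, -1):
        running = min(running, fdrs[i])
        qvals[i] = running
    out = []
    for p, q in zip(ranked, qvals):
        if not p.is_decoy:
            out.append(
                PsmRecord(
                    spectrum_id=p.spectrum_id,
                    peptide=p.peptide,
                    accessions=list(p.accessions),
                    q_value=q,
                    search_score=p.search_score,
                    is_decoy=False,
                )
            )
    return out


@dataclass
class Occurrence:
    tge_id: str
    start: int
    end: int
    overlaps_variant: bool = False
    is_junction: bool = False


@dataclass
class PeptideEvidence:
    """One identified peptide with all its TGE occurrences."""

    peptide: str
    q_value: float  # minimum over contributing PSMs
    occurrences: list[Occurrence] = field(default_factory=list)

    @property
    def is_unique(self) -> bool:
        return len({o.tge_id for o in self.occurrences}) == 1


@dataclass
class TgeEntry:
    tge_id: str
    aa_sequence: str
    member_orf_ids: list[str]
    completeness: str  # 'complete' if any member ORF is complete


@dataclass
class TgeSet:
    tges: dict[str, TgeEntry]
    ambiguity_groups: list[list[str]]


def find_occurrences(peptide: str, sequence: str) -> list[tuple[int, int]]:
    """All (possibly overlapping) 1-based occurrences of a peptide."""
    hits = []
    pos = sequence.find(peptide)
    while pos != -1:
        hits.append((pos + 1, pos + len(peptide)))
        pos = sequence.find(peptide, pos + 1)
    return hits


def _merge_completeness(tags: Iterable[str]) -> str:
    tags = list(tags)
    return "complete" if "complete" in tags else sorted(tags)[0]


def build_tge_set(
    orfs: Sequence[OrfRecord],
    psms: Sequence[PsmRecord],
    q_threshold: float = DEFAULT_Q_THRESHOLD,
    min_peptides: int = DEFAULT_MIN_PEPTIDES,
) -> tuple[TgeSet, list[PeptideEvidence]]:
    """Apply the retention filters and build the sample's TGE set.

    Returns the TGE set (with ambiguity groups) and the peptide evidence
    mapped onto retained TGEs.
    """
    if not 0.0 < q_threshold <= 1.0:
        raise ValidationError("q_threshold must be in (0, 1]")
    if min_peptides < 1:
        raise ValidationError("min_peptides must be >= 1")

    peptide_q: dict[str, float] = {}
    claimed: dict[str, set[str]] = {}
    for p in psms:
        if p.is_decoy or p.q_value > q_threshold:
            continue
        prev = peptide_q.get(p.peptide)
        peptide_q[p.peptide] = p.q_value if prev is None else min(prev, p.q_value)
        claimed.setdefault(p.peptide, set()).update(p.accessions)

    # locate peptides in every ORF by substring search
    orf_peptides: dict[str, set[str]] = {o.orf_id: set() for o in orfs}
    for orf in orfs:
        for pep in peptide_q:
            if pep in orf.aa_sequence:
                orf_peptides[orf.orf_id].add(pep)
    for pep, accs in claimed.items():
        for acc in accs:
            orf = next((o for o in orfs if o.orf_id == acc), None)
            if orf is not None and pep not in orf.aa_sequence:
                logger.warning(
                    "peptide %s claimed for ORF %s but not found in its sequence; "
                    "occurrences recomputed by search", pep, acc
                )

    retained = [o for o in orfs if len(orf_peptides[o.orf_id]) >= min_peptides]

    # merge ORFs with identical sequences into one TGE
    by_seq: dict[str, list[OrfRecord]] = {}
    for orf in retained:
        by_seq.setdefault(orf.aa_sequence, []).append(orf)
    tges: dict[str, TgeEntry] = {}
    for seq, members in by_seq.items():
        ids = sorted(o.orf_id for o in members)
        tges[ids[0]] = TgeEntry(
            tge_id=ids[0],
            aa_sequence=seq,
            member_orf_ids=ids,
            completeness=_merge_completeness(o.completeness for o in members),
        )

    evidence: list[PeptideEvidence] = []
    tge_pepsets: dict[str, frozenset[str]] = {t: frozenset() for t in tges}
    for pep in sorted(peptide_q):
        occs = []
        for tge in tges.values():
            for start, end in find_occurrences(pep, tge.aa_sequence):
                occs.append(Occurrence(tge.tge_id, start, end))
        if occs:
            evidence.append(PeptideEvidence(pep, peptide_q[pep], occs))
            for tid in {o.tge_id for o in occs}:
                tge_pepsets[tid] = tge_pepsets[tid] | {pep}

    # ambiguity groups: identical peptide sets, then strict-subset attachment
    groups: dict[frozenset[str], list[str]] = {}
    for tid, pset in tge_pepsets.items():
        groups.setdefault(pset, []).append(tid)
    group_sets = sorted(groups, key=lambda s: (-len(s), sorted(s)))
    assigned: dict[str, int] = {}
    final_groups: list[list[str]] = []
    for pset in group_sets:
        idx = len(final_groups)
        final_groups.append(sorted(groups[pset]))
        for tid in groups[pset]:
            assigned[tid] = idx
    for pset in group_sets:
        for bigger in group_sets:
            if pset < bigger:  # strict subset: attach to the first superset group
                src = assigned[groups[pset][0]]
                dst = assigned[groups[bigger][0]]
                if src != dst:
                    for tid in list(final_groups[src]):
                        final_groups[dst].append(tid)
                        assigned[tid] = dst
                    final_groups[src] = []
                break
    ambiguity_groups = sorted(sorted(g) for g in final_groups if g)

    return TgeSet(tges=tges, ambiguity_groups=ambiguity_groups), evidence


def variant_regions(classification: TgeClassification, tge_len: int) -> list[tuple[int, int]]:
    """Variant intervals of a TGE: event extents plus terminal overhangs.

    Deletions contribute the two residues flanking their anchor (clipped
    to the sequence).
    """
    regions: list[tuple[int, int]] = []
    for ev in classification.events:
        if ev.tge_seq == "" and ev.type in ("DEL", "SV"):
            # no TGE extent: flag the residues flanking the anchor
            lo = max(1, ev.tge_start)
            hi = min(tge_len, ev.tge_start + 1)
            regions.append((lo, hi))
        else:
            regions.append((ev.tge_start, ev.tge_end))
    if classification.terminals is not None:
        n_term, c_term = classification.terminals
        if n_term.tge_overhang_len > 0:
            regions.append((1, n_term.tge_overhang_len))
        if c_term.tge_overhang_len > 0:
            regions.append((tge_len - c_term.tge_overhang_len + 1, tge_len))
    return regions


def _identity_residues(classification: TgeClassification) -> set[int]:
    """TGE residue positions sitting in identity columns of the alignment."""
    aln = classification.alignment
    if aln is None:
        return set()
    out = set()
    qpos = aln.q_start - 1
    for qc, sc in zip(aln.q_aln, aln.s_aln):
        if qc != "-":
            qpos += 1
            if qc == sc:
                out.add(qpos)
    return out


def flag_variant_peptides(
    classification: TgeClassification,
    evidence: Sequence[PeptideEvidence],
    tge_sequence: str,
) -> None:
    """Set overlaps_variant / is_junction on occurrences of one TGE in place."""
    tge_len = len(tge_sequence)
    regions = variant_regions(classification, tge_len)
    variant_set: set[int] = set()
    for lo, hi in regions:
        variant_set.update(range(lo, hi + 1))
    identical_set = _identity_residues(classification) - variant_set
    for pe in evidence:
        for occ in pe.occurrences:
            if occ.tge_id != classification.tge_id:
                continue
            span = range(occ.start, occ.end + 1)
            in_variant = any(p in variant_set for p in span)
            in_identical = any(p in identical_set for p in span)
            occ.overlaps_variant = in_variant
            occ.is_junction = in_variant and in_identical


def coverage(tge_sequence: str, evidence: Sequence[PeptideEvidence], tge_id: str) -> float:
    """Fraction of TGE residues covered by at least one identified peptide."""
    if not tge_sequence:
        return 0.0
    covered: set[int] = set()
    for pe in evidence:
        for occ in pe.occurrences:
            if occ.tge_id == tge_id:
                covered.update(range(occ.start, occ.end + 1))
    return len(covered) / len(tge_sequence)
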