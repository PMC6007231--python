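"""Polymorphism events, terminal taxonomy and alternative start codons.

Given the best local alignment of a TGE against its most homologous
reference protein, this module

* recomputes the BLAST-style midline (letter = identity, ``+`` = positive
  substitution score, space = mismatch or gap);
* scans alignment columns into variation events: SAP/SSAP (single-residue
  substitution, SSAP when the BLOSUM80 score is positive), ALT/SALT
  (2–9 substituted columns; SALT when every column is positive), INS/DEL
  (gap runs), and SV for any run of 10+ columns — the nine-residue bound
  reflects the shortest commonly accepted exon, so longer variations are
  treated as alternative-splice-type events;
* classifies each terminus as identical / truncated / extended /
  alternative from the alignment end coordinates, yielding the 15
  non-trivial terminal subclasses plus the internal SV subclass;
* detects alternative (non-methionine) start codons, discounting those
  where the preceding reference residue is K or R because a tryptic
  cleavage artefact could mimic them, and reporting N-terminal-Met-removed
  starts as their own category.

Coordinates are 1-based inclusive. A deletion has no extent on the TGE;
its anchor is the residue immediately left of the gap (0 at the start).
Insertions use the symmetric convention on the reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Optional, Sequence

from .errors import ContractError, ValidationError

if TYPE_CHECKING:  # pragma: no cover
    from .homology import MainClass, PairwiseAlignment
    from .io_formats import OrfRecord, ReferenceProtein

EVENT_TYPES = ("SAP", "SSAP", "ALT", "SALT", "INS", "DEL", "SV")
TERMINAL_KINDS = ("identical", "truncated", "extended", "alternative")

#: run length at and above which a variation is an alternative-splice-type event
SV_MIN_LENGTH = 10
#: longest substitution run still called ALT/SALT
ALT_MAX_LENGTH = 9


@dataclass(frozen=True)
class VariationEvent:
    """One polymorphism read off the alignment columns."""

    type: str
    tge_start: int
    tge_end: int
    ref_start: int
    ref_end: int
    tge_seq: str
    ref_seq: str

    def __post_init__(self) -> None:
        if self.type not in EVENT_TYPES:
            raise ValidationError(f"unknown event type {self.type!r}")


@dataclass(frozen=True)
class TerminalVariation:
    terminus: str  # "N" or "C"
    kind: str  # one of TERMINAL_KINDS
    tge_overhang_len: int = 0
    ref_overhang_len: int = 0


@dataclass(frozen=True)
class AltStartRecord:
    """A non-canonical translation start.

    ``category`` is ``"alt_start"`` for a non-methionine first residue or
    ``"met_removed"`` when the TGE matches the reference from position 2
    with the initiator methionine absent. ``discounted`` marks alt starts
    whose preceding reference residue is K or R (possible tryptic artefact).
    """

    residue: str
    ref_pos: int
    category: str  # "alt_start" | "met_removed"
    discounted: bool = False


@dataclass
class TgeClassification:
    """Full classification record for one TGE."""

    tge_id: str
    main_class: str
    subclass: Optional[str] = None
    events: list[VariationEvent] = field(default_factory=list)
    terminals: Optional[tuple[TerminalVariation, TerminalVariation]] = None
    alt_start: Optional[AltStartRecord] = None
    best_hit: Optional[str] = None
    alignment: Optional["PairwiseAlignment"] = None


def compute_midline(q_aln: str, s_aln: str, matrix) -> str:
    """BLAST-style midline for a pair of aligned (gapped) strings."""
    if len(q_aln) != len(s_aln):
        raise ValidationError(
            f"aligned strings differ in length ({len(q_aln)} vs {len(s_aln)})"
        )
    out = []
    for i, (qc, sc) in enumerate(zip(q_aln, s_aln)):
        if qc == "-" and sc == "-":
            raise ValidationError(f"gap aligned to gap at column {i + 1}")
        if qc == "-" or sc == "-":
            out.append(" ")
        elif qc == sc:
            out.append(qc)
        elif matrix[qc, sc] > 0:
            out.append("+")
        else:
            out.append(" ")
    return "".join(out)


def _substitution_type(length: int, all_positive: bool, sv_min_length: int) -> str:
    if length >= sv_min_length:
        return "SV"
    if length == 1:
        return "SSAP" if all_positive else "SAP"
    return "SALT" if all_positive else "ALT"


def extract_events(
    aln: "PairwiseAlignment", sv_min_length: int = SV_MIN_LENGTH
) -> list[VariationEvent]:
    """Scan alignment columns left to right into maximal variation events.

    Maximal runs of substitution columns become SAP/SSAP/ALT/SALT/SV by
    length and midline similarity; maximal gap runs become DEL (gap in the
    TGE) or INS (gap in the reference), promoted to SV at 10+ columns.
    Identity columns produce nothing.
    """
    aln.validate()
    events: list[VariationEvent] = []
    qpos = aln.q_start - 1  # last consumed TGE residue (0 = none yet)
    spos = aln.s_start - 1

    # column categories: "=", "sub", "qgap" (DEL), "sgap" (INS)
    cols = []
    for qc, sc, mc in zip(aln.q_aln, aln.s_aln, aln.midline):
        if qc == "-":
            cols.append(("qgap", qc, sc, mc))
        elif sc == "-":
            cols.append(("sgap", qc, sc, mc))
        elif qc == sc:
            cols.append(("=", qc, sc, mc))
        else:
            cols.append(("sub", qc, sc, mc))

    i = 0
    n = len(cols)
    while i < n:
        cat = cols[i][0]
        j = i
        while j < n and cols[j][0] == cat:
            j += 1
        run = cols[i:j]
        length = j - i
        if cat == "=":
            qpos += length
            spos += length
        elif cat == "sub":
            tge_seq = "".join(c[1] for c in run)
            ref_seq = "".join(c[2] for c in run)
            all_positive = all(c[3] == "+" for c in run)
            events.append(
                VariationEvent(
                    type=_substitution_type(length, all_positive, sv_min_length),
                    tge_start=qpos + 1,
                    tge_end=qpos + length,
                    ref_start=spos + 1,
                    ref_end=spos + length,
                    tge_seq=tge_seq,
                    ref_seq=ref_seq,
                )
            )
            qpos += length
            spos += length
        elif cat == "qgap":  # residues present in the reference only
            ref_seq = "".join(c[2] for c in run)
            events.append(
                VariationEvent(
                    type="SV" if length >= sv_min_length else "DEL",
                    tge_start=qpos,
                    tge_end=qpos,
                    ref_start=spos + 1,
                    ref_end=spos + length,
                    tge_seq="",
                    ref_seq=ref_seq,
                )
            )
            spos += length
        else:  # sgap: residues present in the TGE only
            tge_seq = "".join(c[1] for c in run)
            events.append(
                VariationEvent(
                    type="SV" if length >= sv_min_length else "INS",
                    tge_start=qpos + 1,
                    tge_end=qpos + length,
                    ref_start=spos,
                    ref_end=spos,
                    tge_seq=tge_seq,
                    ref_seq="",
                )
            )
            qpos += length
        i = j
    return events


def classify_terminals(
    aln: "PairwiseAlignment", tge_len: int, ref_len: int
) -> tuple[TerminalVariation, TerminalVariation]:
    """Classify both termini from the alignment end coordinates."""
    if not (1 <= aln.q_start <= aln.q_end <= tge_len):
        raise ValidationError(
            f"query coordinates {aln.q_start}..{aln.q_end} outside [1, {tge_len}]"
        )
    if not (1 <= aln.s_start <= aln.s_end <= ref_len):
        raise ValidationError(
            f"subject coordinates {aln.s_start}..{aln.s_end} outside [1, {ref_len}]"
        )

    def kind(tge_over: int, ref_over: int) -> str:
        if tge_over == 0 and ref_over == 0:
            return "identical"
        if tge_over == 0:
            return "truncated"
        if ref_over == 0:
            return "extended"
        return "alternative"

    n_t, n_r = aln.q_start - 1, aln.s_start - 1
    c_t, c_r = tge_len - aln.q_end, ref_len - aln.s_end
    return (
        TerminalVariation("N", kind(n_t, n_r), n_t, n_r),
        TerminalVariation("C", kind(c_t, c_r), c_t, c_r),
    )


def subclass_label(
    terminals: tuple[TerminalVariation, TerminalVariation]
) -> Optional[str]:
    """Systematic name for a non-identical terminal pair (15 labels)."""
    nk, ck = terminals[0].kind, terminals[1].kind
    parts = []
    if nk != "identical":
        parts.append(f"N_{nk}")
    if ck != "identical":
        parts.append(f"C_{ck}")
    return "+".join(parts) if parts else None


def assign_subclass(
    main: "MainClass",
    events: Sequence[VariationEvent],
    terminals: tuple[TerminalVariation, TerminalVariation],
    tge_id: str = "",
    alt_start: Optional[AltStartRecord] = None,
    alignment: Optional["PairwiseAlignment"] = None,
) -> TgeClassification:
    """Resolve a candidate-variant TGE to its final class and subclass.

    Full-length alignments with only sub-exon-scale events are known
    proteins with polymorphism; a full-length alignment containing an SV
    event is a novel isoform of subclass ``SV``; anything not covering both
    molecules end to end is a novel isoform named by its terminal pair.
    """
    if main.label != "candidate_variant":
        raise ContractError(
            f"assign_subclass requires a candidate_variant, got {main.label!r}"
        )
    label = subclass_label(terminals)
    if label is None:
        if any(e.type == "SV" for e in events):
            main_class, subclass = "novel_isoform", "SV"
        else:
            main_class, subclass = "known_with_polymorphism", None
    else:
        main_class, subclass = "novel_isoform", label
    return TgeClassification(
        tge_id=tge_id,
        main_class=main_class,
        subclass=subclass,
        events=list(events),
        terminals=terminals,
        alt_start=alt_start,
        best_hit=main.best_hit,
        alignment=alignment,
    )


def detect_alt_start(
    tge_sequence: str, aln: "PairwiseAlignment", ref: "ReferenceProtein"
) -> Optional[AltStartRecord]:
    """Detect an alternative or Met-removed start for a TGE.

    Only applies when the alignment reaches the very first TGE residue
    (``q_start == 1``). A TGE beginning with methionine aligned to
    reference position 1 is a canonical start (returns None). A TGE whose
    alignment begins at reference position 2 of a Met-initiated reference
    is reported as ``met_removed``. Any other non-methionine first residue
    is an alternative start, discounted when the preceding reference
    residue is K or R.
    """
    if aln.q_start != 1:
        return None
    first = tge_sequence[0]
    ref_seq = ref.aa_sequence
    if aln.s_start == 2 and ref_seq[:1] == "M":
        return AltStartRecord(residue=first, ref_pos=2, category="met_removed")
    if first == "M":
        return None
    discounted = aln.s_start > 1 and ref_seq[aln.s_start - 2] in "KR"
    return AltStartRecord(
        residue=first, ref_pos=aln.s_start, category="alt_start", discounted=discounted
    )


def reconstruct_tge(
    tge_sequence: str,
    ref_sequence: str,
    aln: "PairwiseAlignment",
    events: Sequence[VariationEvent],
) -> str:
    """Replay events and terminal overhangs onto the reference subsequence.

    Returns the sequence implied by the classification record; equality
    with the actual TGE sequence is the round-trip invariant.
    """
    core = []
    spos = aln.s_start  # next reference position to consume
    for ev in sorted(events, key=lambda e: (e.ref_start, e.tge_start)):
        if ev.type == "DEL" or (ev.type == "SV" and ev.tge_seq == "" and ev.ref_seq):
            core.append(ref_sequence[spos - 1 : ev.ref_start - 1])
            spos = ev.ref_end + 1
        elif ev.type == "INS" or (ev.type == "SV" and ev.ref_seq == "" and ev.tge_seq):
            core.append(ref_sequence[spos - 1 : ev.ref_start])
            spos = ev.ref_start + 1
            core.append(ev.tge_seq)
        else:  # substitution-type event
            core.append(ref_sequence[spos - 1 : ev.ref_start - 1])
            core.append(ev.tge_seq)
            spos = ev.ref_end + 1
    core.append(ref_sequence[spos - 1 : aln.s_end])
    n_over = tge_sequence[: aln.q_start - 1]
    c_over = tge_sequence[aln.q_end :]
    return n_over + "".join(core) + c_over
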