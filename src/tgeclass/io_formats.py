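"""Readers and writers for the pipeline's external representations.

Dialects handled here:

* **ORF FASTA** — Transdecoder-style headers; the token ``type:<tag>``
  carries the ORF completeness class (``complete``, ``5prime_partial``,
  ``3prime_partial``, ``internal``; defaults to ``complete`` when absent).
  Trailing ``*`` stop symbols are stripped and sequences are uppercased.
* **Reference FASTA** — UniProt-style headers (``sp|ACC|NAME ...`` or a
  bare accession). Whether an entry is an isoform is decided by a
  configurable rule: accession matches ``^[^-]+-\\d+$`` (UniProt isoform
  suffix) or the description contains the token ``isoform``.
* **PSM TSV** — tab-separated with mandatory columns ``spectrum_id``,
  ``peptide``, ``accessions`` (``;``-separated), ``q_value`` and optional
  ``score`` / ``is_decoy``. Bracketed or parenthesised modification
  annotations in peptides (e.g. ``AC[+57.02]DK``) are stripped so mapping
  is purely on amino-acid letters.
* **BLAST XML** (``-outfmt 5``) — one :class:`~tgeclass.homology.PairwiseAlignment`
  per HSP, midline and coordinates verbatim.
* **mzIdentML 1.1** (optional, minimal) — SpectrumIdentificationResult
  items with peptide sequence, mapped accessions and a q-value cv-param.

All coordinates everywhere in the package are 1-based inclusive (BLAST
convention).
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Blast import NCBIXML

from .errors import FormatError, SchemaError, ValidationError
from .homology import PairwiseAlignment

COMPLETENESS_TAGS = ("complete", "5prime_partial", "3prime_partial", "internal")

#: default rule for spotting isoform accessions (UniProt ``P12345-2`` style)
ISOFORM_ACCESSION_RE = re.compile(r"^[^-]+-\d+$")

_MOD_RE = re.compile(r"\[[^\]]*\]|\([^)]*\)")
_UNIPROT_HEADER_RE = re.compile(r"^(?:sp|tr)\|([^|]+)\|\S*")


@dataclass(frozen=True)
class OrfRecord:
    """One predicted ORF (amino-acid sequence plus completeness tag)."""

    orf_id: str
    transcript_id: str
    aa_sequence: str
    completeness: str = "complete"

    def __post_init__(self) -> None:
        if not self.aa_sequence:
            raise ValidationError(f"ORF {self.orf_id!r} has an empty sequence")
        if self.completeness not in COMPLETENESS_TAGS:
            raise ValidationError(
                f"ORF {self.orf_id!r}: unknown completeness tag {self.completeness!r}"
            )


@dataclass(frozen=True)
class ReferenceProtein:
    """One reference proteome entry."""

    accession: str
    aa_sequence: str
    is_isoform: bool = False
    description: str = ""

    def __post_init__(self) -> None:
        if not self.aa_sequence:
            raise ValidationError(f"reference {self.accession!r} has an empty sequence")


@dataclass
class PsmRecord:
    """One peptide-spectrum match row."""

    spectrum_id: str
    peptide: str
    accessions: list[str] = field(default_factory=list)
    q_value: float = 0.0
    search_score: float | None = None
    is_decoy: bool = False

    def __post_init__(self) -> None:
        if not self.peptide:
            raise ValidationError(f"PSM {self.spectrum_id!r} has an empty peptide")
        if not 0.0 <= self.q_value <= 1.0:
            raise ValidationError(
                f"PSM {self.spectrum_id!r}: q_value {self.q_value} outside [0, 1]"
            )


def strip_modifications(peptide: str) -> str:
    """Remove bracketed/parenthesised modification annotations and uppercase."""
    return _MOD_RE.sub("", peptide).upper()


def _check_fasta_shape(path: str | Path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise FormatError(f"{path}: line {lineno}: expected FASTA header, got {line!r}")
            return


def _parse_orf_header(record_id: str, description: str) -> tuple[str, str]:
    """Return (transcript_id, completeness) from a Transdecoder-style header."""
    completeness = "complete"
    for token in description.split():
        if token.startswith("type:"):
            completeness = token[len("type:"):]
            break
    transcript_id = record_id.rsplit(".p", 1)[0] if ".p" in record_id else record_id
    return transcript_id, completeness


def read_fasta(
    path: str | Path, role: Literal["orf", "reference"]
) -> list[OrfRecord] | list[ReferenceProtein]:
    """Read a FASTA file as ORFs or reference proteins.

    Parameters
    ----------
    path:
        FASTA file.
    role:
        ``"orf"`` parses Transdecoder completeness tags;
        ``"reference"`` applies the isoform rule.
    """
    if role not in ("orf", "reference"):
        raise ValidationError(f"unknown FASTA role {role!r}")
    _check_fasta_shape(path)
    out: list = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().rstrip("*")
        if role == "orf":
            transcript_id, completeness = _parse_orf_header(rec.id, rec.description)
            if rec.id in seen:
                raise ValidationError(f"duplicate ORF id {rec.id!r}")
            seen.add(rec.id)
            out.append(
                OrfRecord(
                    orf_id=rec.id,
                    transcript_id=transcript_id,
                    aa_sequence=seq,
                    completeness=completeness,
                )
            )
        else:
            m = _UNIPROT_HEADER_RE.match(rec.id)
            accession = m.group(1) if m else rec.id
            if accession in seen:
                raise ValidationError(f"duplicate reference accession {accession!r}")
            seen.add(accession)
            description = rec.description[len(rec.id):].strip()
            out.append(
                ReferenceProtein(
                    accession=accession,
                    aa_sequence=seq,
                    is_isoform=is_isoform_entry(accession, description),
                    description=description,
                )
            )
    return out


def is_isoform_entry(
    accession: str, description: str, accession_re: re.Pattern = ISOFORM_ACCESSION_RE
) -> bool:
    """Decide whether a reference entry is an isoform.

    True when the accession carries a UniProt isoform suffix (``-2`` etc.)
    or the description contains the token ``isoform`` (case-insensitive).
    """
    if accession_re.match(accession):
        return True
    return bool(re.search(r"\bisoform\b", description, flags=re.IGNORECASE))


_PSM_REQUIRED = ("spectrum_id", "peptide", "accessions", "q_value")


def read_psm_table(path: str | Path) -> list[PsmRecord]:
    """Read a PSM TSV table into :class:`PsmRecord` rows (no silent drops)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _PSM_REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s) {missing}")
    records: list[PsmRecord] = []
    for row in df.itertuples(index=False):
        q = float(row.q_value)
        if not 0.0 <= q <= 1.0:
            raise ValidationError(
                f"{path}: PSM {row.spectrum_id!r}: q_value {q} outside [0, 1]"
            )
        score = None
        if "score" in df.columns and str(row.score) != "":
            score = float(row.score)
        decoy = False
        if "is_decoy" in df.columns and str(row.is_decoy) != "":
            decoy = str(row.is_decoy).strip().lower() in ("1", "true", "yes")
        accessions = [a for a in str(row.accessions).split(";") if a]
        records.append(
            PsmRecord(
                spectrum_id=str(row.spectrum_id),
                peptide=strip_modifications(str(row.peptide)),
                accessions=accessions,
                q_value=q,
                search_score=score,
                is_decoy=decoy,
            )
        )
    return records


def write_psm_table(psms: Sequence[PsmRecord], path: str | Path) -> None:
    """Write PSM records in the TSV dialect read by :func:`read_psm_table`."""
    df = pd.DataFrame(
        {
            "spectrum_id": [p.spectrum_id for p in psms],
            "peptide": [p.peptide for p in psms],
            "accessions": [";".join(p.accessions) for p in psms],
            "q_value": [repr(p.q_value) for p in psms],
            "score": ["" if p.search_score is None else repr(p.search_score) for p in psms],
            "is_decoy": [str(p.is_decoy).lower() for p in psms],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_blast_xml(path: str | Path) -> list[PairwiseAlignment]:
    """Parse NCBI BLAST XML (outfmt 5) into one alignment per HSP."""
    alignments: list[PairwiseAlignment] = []
    with open(path) as handle:
        try:
            records = list(NCBIXML.parse(handle))
        except Exception as exc:  # ElementTree/expat errors
            raise FormatError(f"{path}: not parseable as BLAST XML: {exc}") from exc
    for record in records:
        query_id = record.query.split()[0] if record.query else record.query_id
        for hit in record.alignments:
            subject_id = hit.hit_def.split()[0] if hit.hit_def else hit.hit_id
            for hsp in hit.hsps:
                if hsp.match is None:
                    raise FormatError(f"{path}: HSP without Hsp_midline for query {query_id!r}")
                alignments.append(
                    PairwiseAlignment(
                        query_id=query_id,
                        subject_id=subject_id,
                        e_value=float(hsp.expect),
                        bit_score=float(hsp.bits),
                        q_start=int(hsp.query_start),
                        q_end=int(hsp.query_end),
                        s_start=int(hsp.sbjct_start),
                        s_end=int(hsp.sbjct_end),
                        q_aln=hsp.query,
                        s_aln=hsp.sbjct,
                        midline=hsp.match,
                    )
                )
    return alignments


def read_mzid(path: str | Path) -> list[PsmRecord]:
    """Restricted mzIdentML 1.1 reader.

    Only SpectrumIdentificationResult items are consulted: peptide
    sequence (via ``Peptide``), mapped accessions and decoy flags (via
    ``PeptideEvidence`` / ``DBSequence``), and a q-value cv-param (any
    name ending in ``q-value``, case-insensitive; MS-GF:QValue included).
    Everything else in the standard is ignored.
    """
    from lxml import etree

    def local(tag: str) -> str:
        return etree.QName(tag).localname

    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise FormatError(f"{path}: not parseable as mzIdentML: {exc}") from exc
    root = tree.getroot()

    peptides: dict[str, str] = {}
    db_accessions: dict[str, str] = {}
    pep_evidence: dict[str, tuple[str, bool]] = {}  # id -> (dbseq_ref, is_decoy)
    for el in root.iter():
        name = local(el.tag)
        if name == "Peptide":
            seq = next(
                (c.text or "" for c in el if local(c.tag) == "PeptideSequence"), ""
            )
            peptides[el.get("id", "")] = seq
        elif name == "DBSequence":
            db_accessions[el.get("id", "")] = el.get("accession", el.get("id", ""))
        elif name == "PeptideEvidence":
            pep_evidence[el.get("id", "")] = (
                el.get("dBSequence_ref", ""),
                el.get("isDecoy", "false").lower() == "true",
            )

    records: list[PsmRecord] = []
    for result in root.iter():
        if local(result.tag) != "SpectrumIdentificationResult":
            continue
        spectrum_id = result.get("spectrumID", result.get("id", ""))
        for item in result:
            if local(item.tag) != "SpectrumIdentificationItem":
                continue
            peptide = peptides.get(item.get("peptide_ref", ""), "")
            if not peptide:
                continue
            q_value = None
            accessions: list[str] = []
            decoy = False
            for child in item:
                cname = local(child.tag)
                if cname == "cvParam":
                    pname = (child.get("name") or "").lower()
                    if pname.endswith("q-value") or pname == "ms-gf:qvalue":
                        q_value = float(child.get("value", "0"))
                elif cname == "PeptideEvidenceRef":
                    ref = child.get("peptideEvidence_ref", "")
                    dbref, is_decoy = pep_evidence.get(ref, ("", False))
                    acc = db_accessions.get(dbref)
                    if acc:
                        accessions.append(acc)
                    decoy = decoy or is_decoy
            records.append(
                PsmRecord(
                    spectrum_id=spectrum_id,
                    peptide=strip_modifications(peptide),
                    accessions=accessions,
                    q_value=0.0 if q_value is None else q_value,
                    is_decoy=decoy,
                )
            )
    return records


CLASSIFICATION_COLUMNS = [
    "tge_id", "length", "main_class", "subclass", "best_hit", "evalue",
    "identity_pct", "n_events", "n_peptides", "n_unique_peptides",
    "n_variant_peptides", "n_unique_variant_peptides", "n_junction_peptides",
    "score_variant", "score_reference", "decision", "rating",
    "alt_start_residue", "alt_start_ref_pos",
]
EVENT_COLUMNS = [
    "tge_id", "event_index", "type", "tge_start", "tge_end",
    "ref_start", "ref_end", "tge_seq", "ref_seq",
]
EVIDENCE_COLUMNS = [
    "peptide", "q_value", "tge_id", "start", "end",
    "is_unique", "overlaps_variant", "is_junction",
]


def write_reports(classification_rows: Iterable[dict],
                  event_rows: Iterable[dict],
                  evidence_rows: Iterable[dict],
                  novel_sequences: dict[str, str],
                  out_dir: str | Path) -> dict[str, Path]:
    """Write the four report files with deterministic row order.

    ``classification_rows``/``event_rows``/``evidence_rows`` are dicts with
    the documented column schemas; ``novel_sequences`` maps tge_id to
    sequence for ``novel_tges.fasta``. Rows are sorted by ``tge_id`` (events
    additionally by ``event_index``, evidence by peptide and position).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    cls = pd.DataFrame(list(classification_rows), columns=CLASSIFICATION_COLUMNS)
    cls = cls.sort_values("tge_id", kind="stable")
    paths["classification"] = out / "classification.tsv"
    cls.to_csv(paths["classification"], sep="\t", index=False)

    ev = pd.DataFrame(list(event_rows), columns=EVENT_COLUMNS)
    ev = ev.sort_values(["tge_id", "event_index"], kind="stable")
    paths["variation_events"] = out / "variation_events.tsv"
    ev.to_csv(paths["variation_events"], sep="\t", index=False)

    pe = pd.DataFrame(list(evidence_rows), columns=EVIDENCE_COLUMNS)
    pe = pe.sort_values(["tge_id", "peptide", "start"], kind="stable")
    paths["peptide_evidence"] = out / "peptide_evidence.tsv"
    pe.to_csv(paths["peptide_evidence"], sep="\t", index=False)

    paths["novel_tges"] = out / "novel_tges.fasta"
    with open(paths["novel_tges"], "w") as fh:
        for tge_id in sorted(novel_sequences):
            fh.write(f">{tge_id}\n{novel_sequences[tge_id]}\n")
    return paths
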