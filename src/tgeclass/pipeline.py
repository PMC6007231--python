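"""End-to-end orchestration: ORFs + PSMs + reference -> classified TGEs.

Stage order: PSM thresholding and TGE retention -> homology search (BLAST
XML when supplied, internal aligner otherwise) -> main-class assignment ->
variation events, terminal subclass and alt-start detection -> variant /
junction peptide flags -> detectability calibration on known-protein TGEs
-> variant-vs-reference scoring -> evidence rating -> reports.

Outputs are deterministic: TGEs are processed in sorted id order and every
report is sorted before writing.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from . import evidence as ev
from . import homology as hom
from . import io_formats as iof
from . import scoring as sc
from . import variation as var
from .errors import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All tunables of the pipeline with their documented defaults."""

    orfs: Optional[str] = None
    psms: Optional[str] = None
    reference: Optional[str] = None
    blast_xml: Optional[str] = None
    out_dir: str = "tgeclass_out"

    evalue_threshold: float = hom.DEFAULT_EVALUE_THRESHOLD
    gap_open: int = 10
    gap_extend: int = 1
    matrix: str = "BLOSUM80"

    psm_fdr: float = ev.DEFAULT_Q_THRESHOLD
    min_peptides: int = ev.DEFAULT_MIN_PEPTIDES
    missed_cleavages: int = 0
    min_pep_len: int = ev.DEFAULT_MIN_PEP_LEN
    max_pep_len: int = ev.DEFAULT_MAX_PEP_LEN

    sv_min_length: int = var.SV_MIN_LENGTH
    alt_max_length: int = var.ALT_MAX_LENGTH

    score_margin: float = 0.0
    ref_denominator: float = sc.REFERENCE_DENOMINATOR
    undetected_denominator: float = sc.UNDETECTED_DENOMINATOR
    detectability_model: Optional[str] = None

    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValidationError(f"unknown config keys {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def alignment_params(self) -> hom.AlignmentParams:
        return hom.AlignmentParams(
            matrix_name=self.matrix,
            gap_open=self.gap_open,
            gap_extend=self.gap_extend,
        )


@dataclass
class TgeResult:
    """Everything the pipeline knows about one TGE."""

    tge_id: str
    classification: var.TgeClassification
    score: Optional[sc.VariantScore] = None
    rating: int = 1
    coverage: float = 0.0


@dataclass
class SampleResult:
    tge_set: ev.TgeSet
    evidence: list[ev.PeptideEvidence]
    results: dict[str, TgeResult] = field(default_factory=dict)
    calibration: Optional[sc.CalibrationTransform] = None

    def summary(self) -> pd.DataFrame:
        """Per-class counts mirroring the standard overview table rows."""
        rows = []
        classes = sorted({r.classification.main_class for r in self.results.values()})
        flags = _evidence_flags(self.evidence)
        for cls_label in classes:
            members = [
                r for r in self.results.values()
                if r.classification.main_class == cls_label
            ]
            rows.append(
                {
                    "main_class": cls_label,
                    "total": len(members),
                    "complete_orf": sum(
                        self.tge_set.tges[r.tge_id].completeness == "complete"
                        for r in members
                    ),
                    "with_specific_peptide": sum(
                        flags.get(r.tge_id, (False, False))[0] for r in members
                    ),
                    "with_unique_specific_peptide": sum(
                        flags.get(r.tge_id, (False, False))[1] for r in members
                    ),
                    "score_confirmed": sum(
                        r.score is not None and r.score.decision == "variant"
                        for r in members
                    ),
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "main_class", "total", "complete_orf", "with_specific_peptide",
                "with_unique_specific_peptide", "score_confirmed",
            ],
        )


def _evidence_flags(evidence: Sequence[ev.PeptideEvidence]) -> dict[str, tuple[bool, bool]]:
    """Per-TGE (has variant-overlapping peptide, has unique variant peptide)."""
    flags: dict[str, list[bool]] = {}
    for pe in evidence:
        for occ in pe.occurrences:
            cur = flags.setdefault(occ.tge_id, [False, False])
            if occ.overlaps_variant:
                cur[0] = True
                if pe.is_unique:
                    cur[1] = True
    return {k: (v[0], v[1]) for k, v in flags.items()}


def _alignment_identity_pct(aln: Optional[hom.PairwiseAlignment]) -> float:
    if aln is None:
        return 0.0
    ident = sum(qc == sc_ and qc != "-" for qc, sc_ in zip(aln.q_aln, aln.s_aln))
    return 100.0 * ident / len(aln.q_aln)


def classify_sample(
    orfs: Sequence[iof.OrfRecord],
    psms: Sequence[iof.PsmRecord],
    references: Sequence[iof.ReferenceProtein],
    blast_alignments: Optional[Sequence[hom.PairwiseAlignment]] = None,
    config: PipelineConfig = PipelineConfig(),
) -> SampleResult:
    """Run the full classification and scoring on in-memory inputs."""
    params = config.alignment_params()
    ref_by_acc = {r.accession: r for r in references}

    if psms and all(p.search_score is not None for p in psms) and any(
        p.is_decoy for p in psms
    ):
        logger.info("decoy PSMs present: recomputing q-values by target-decoy")
        psms = ev.compute_qvalues(psms)

    tge_set, pep_evidence = ev.build_tge_set(
        orfs, psms, q_threshold=config.psm_fdr, min_peptides=config.min_peptides
    )

    # index BLAST HSPs by TGE (queries are ORF ids; re-key to merged TGE ids)
    blast_by_tge: dict[str, list[hom.PairwiseAlignment]] = {}
    if blast_alignments:
        orf_to_tge = {
            orf_id: tge.tge_id
            for tge in tge_set.tges.values()
            for orf_id in tge.member_orf_ids
        }
        for aln in blast_alignments:
            tid = orf_to_tge.get(aln.query_id)
            if tid is not None:
                blast_by_tge.setdefault(tid, []).append(
                    dataclasses.replace(aln, query_id=tid)
                )
        logger.info("using supplied BLAST alignments; internal aligner skipped")

    result = SampleResult(tge_set=tge_set, evidence=pep_evidence)

    for tge_id in sorted(tge_set.tges):
        tge = tge_set.tges[tge_id]
        seq = tge.aa_sequence
        if blast_alignments:
            best = hom.best_hit(blast_by_tge.get(tge_id, []))
        else:
            best = hom.search_best_alignment(tge_id, seq, references, params)
        main = hom.assign_main_class(seq, best, ref_by_acc, config.evalue_threshold)

        if main.label in ("known_protein", "known_isoform"):
            cls = var.TgeClassification(
                tge_id=tge_id, main_class=main.label, best_hit=main.best_hit,
                alignment=best if best is not None and best.subject_id == main.best_hit else None,
            )
        elif main.label == "novel_tge":
            cls = var.TgeClassification(tge_id=tge_id, main_class="novel_tge")
        else:
            ref = ref_by_acc[best.subject_id]
            events = var.extract_events(best, config.sv_min_length)
            terminals = var.classify_terminals(best, len(seq), len(ref.aa_sequence))
            alt = var.detect_alt_start(seq, best, ref)
            cls = var.assign_subclass(
                main, events, terminals, tge_id=tge_id, alt_start=alt, alignment=best
            )
        ev.flag_variant_peptides(cls, pep_evidence, seq)
        result.results[tge_id] = TgeResult(tge_id=tge_id, classification=cls)

    # calibration on TGEs identified as known proteins / known isoforms
    identified_peptides = {pe.peptide for pe in pep_evidence}
    raw_scores: list[float] = []
    flags: list[bool] = []
    predictor = (
        sc.TsvDetectabilityModel(config.detectability_model)
        if config.detectability_model
        else sc.predict_detectability
    )
    for tge_id in sorted(tge_set.tges):
        if result.results[tge_id].classification.main_class in (
            "known_protein", "known_isoform"
        ):
            for pep in ev.digest(
                tge_set.tges[tge_id].aa_sequence,
                config.missed_cleavages, config.min_pep_len, config.max_pep_len,
            ):
                raw_scores.append(predictor(pep.peptide))
                flags.append(pep.peptide in identified_peptides)
    transform = sc.calibrate(raw_scores, flags)
    result.calibration = transform

    identified_q = {pe.peptide: pe.q_value for pe in pep_evidence}

    def s_of(peptide: str) -> float:
        return float(transform(predictor(peptide)))

    ev_flags = _evidence_flags(pep_evidence)
    for tge_id in sorted(tge_set.tges):
        res = result.results[tge_id]
        cls = res.classification
        if cls.main_class in ("known_with_polymorphism", "novel_isoform"):
            ref = ref_by_acc[cls.best_hit]
            V, R = sc.build_peptide_sets(
                tge_set.tges[tge_id].aa_sequence, cls, ref.aa_sequence,
                config.missed_cleavages, config.min_pep_len, config.max_pep_len,
            )
            if V or R:
                res.score = sc.score_variant_vs_reference(
                    V, R, identified_q, s_of, tge_id=tge_id,
                    margin=config.score_margin,
                    ref_denominator=config.ref_denominator,
                    undetected_denominator=config.undetected_denominator,
                )
            else:
                logger.info("TGE %s: empty V and R; scoring undefined", tge_id)
        has_var, has_unique_var = ev_flags.get(tge_id, (False, False))
        res.rating = sc.rate_tge(
            cls, has_var, has_unique_var,
            res.score.decision if res.score else None,
            tge_set.tges[tge_id].completeness,
        )
        res.coverage = ev.coverage(
            tge_set.tges[tge_id].aa_sequence, pep_evidence, tge_id
        )
    return result


def _report_rows(sample: SampleResult):
    cls_rows, event_rows, evid_rows = [], [], []
    novel: dict[str, str] = {}
    per_tge_peps: dict[str, set[str]] = {}
    per_tge_unique: dict[str, set[str]] = {}
    per_tge_var: dict[str, set[str]] = {}
    per_tge_unique_var: dict[str, set[str]] = {}
    per_tge_junction: dict[str, set[str]] = {}
    for pe in sample.evidence:
        for occ in pe.occurrences:
            per_tge_peps.setdefault(occ.tge_id, set()).add(pe.peptide)
            if pe.is_unique:
                per_tge_unique.setdefault(occ.tge_id, set()).add(pe.peptide)
            if occ.overlaps_variant:
                per_tge_var.setdefault(occ.tge_id, set()).add(pe.peptide)
                if pe.is_unique:
                    per_tge_unique_var.setdefault(occ.tge_id, set()).add(pe.peptide)
            if occ.is_junction:
                per_tge_junction.setdefault(occ.tge_id, set()).add(pe.peptide)
            evid_rows.append(
                {
                    "peptide": pe.peptide, "q_value": pe.q_value,
                    "tge_id": occ.tge_id, "start": occ.start, "end": occ.end,
                    "is_unique": pe.is_unique,
                    "overlaps_variant": occ.overlaps_variant,
                    "is_junction": occ.is_junction,
                }
            )
    for tge_id in sorted(sample.results):
        res = sample.results[tge_id]
        cls = res.classification
        tge = sample.tge_set.tges[tge_id]
        alt = cls.alt_start
        if alt is None:
            alt_residue, alt_pos = "", ""
        elif alt.category == "met_removed":
            alt_residue, alt_pos = "met_removed", alt.ref_pos
        else:
            alt_residue = f"{alt.residue}:discounted" if alt.discounted else alt.residue
            alt_pos = alt.ref_pos
        cls_rows.append(
            {
                "tge_id": tge_id,
                "length": len(tge.aa_sequence),
                "main_class": cls.main_class,
                "subclass": cls.subclass or "",
                "best_hit": cls.best_hit or "",
                "evalue": cls.alignment.e_value if cls.alignment else "",
                "identity_pct": round(_alignment_identity_pct(cls.alignment), 2)
                if cls.alignment else "",
                "n_events": len(cls.events),
                "n_peptides": len(per_tge_peps.get(tge_id, ())),
                "n_unique_peptides": len(per_tge_unique.get(tge_id, ())),
                "n_variant_peptides": len(per_tge_var.get(tge_id, ())),
                "n_unique_variant_peptides": len(per_tge_unique_var.get(tge_id, ())),
                "n_junction_peptides": len(per_tge_junction.get(tge_id, ())),
                "score_variant": res.score.score_variant if res.score else "",
                "score_reference": res.score.score_reference if res.score else "",
                "decision": res.score.decision if res.score else "",
                "rating": res.rating,
                "alt_start_residue": alt_residue,
                "alt_start_ref_pos": alt_pos,
            }
        )
        for i, event in enumerate(cls.events):
            event_rows.append(
                {
                    "tge_id": tge_id, "event_index": i, "type": event.type,
                    "tge_start": event.tge_start, "tge_end": event.tge_end,
                    "ref_start": event.ref_start, "ref_end": event.ref_end,
                    "tge_seq": event.tge_seq, "ref_seq": event.ref_seq,
                }
            )
        if cls.main_class == "novel_tge":
            novel[tge_id] = tge.aa_sequence
    return cls_rows, event_rows, evid_rows, novel


def run_pipeline(config: PipelineConfig) -> tuple[SampleResult, dict[str, Path]]:
    """File-level entry point: read inputs, classify, write reports."""
    if not (config.orfs and config.psms and config.reference):
        raise ValidationError("orfs, psms and reference inputs are all required")
    orfs = iof.read_fasta(config.orfs, "orf")
    if str(config.psms).endswith((".mzid", ".mzid.xml")):
        psms = iof.read_mzid(config.psms)
    else:
        psms = iof.read_psm_table(config.psms)
    references = iof.read_fasta(config.reference, "reference")
    blast = iof.read_blast_xml(config.blast_xml) if config.blast_xml else None

    sample = classify_sample(orfs, psms, references, blast, config)
    cls_rows, event_rows, evid_rows, novel = _report_rows(sample)
    paths = iof.write_reports(cls_rows, event_rows, evid_rows, novel, config.out_dir)
    summary = sample.summary()
    summary_path = Path(config.out_dir) / "summary.tsv"
    summary.to_csv(summary_path, sep="\t", index=False)
    paths["summary"] = summary_path
    return sample, paths
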