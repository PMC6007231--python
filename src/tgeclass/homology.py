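"""Reference-homology search and top-level TGE classification.

Each TGE is compared against the reference proteome by optimal local
alignment under BLOSUM80 with affine gaps (default open 10, extend 1 —
BLOSUM80 because TGEs and their references are closely related). When a
BLAST XML file is supplied its HSPs are authoritative; the internal
aligner is a fallback whose e-values are Karlin–Altschul approximations

    E = K * m * n * exp(-lambda * S),      bits = (lambda*S - ln K) / ln 2

with the gapped BLOSUM80 / open 10 / extend 1 constants from the NCBI
BLAST source distribution (lambda = 0.299, K = 0.071). No edge-length
correction or multi-HSP sum statistics are applied; the single best HSP
per subject is used.

Top-level classes:

* ``known_protein`` / ``known_isoform`` — TGE sequence exactly equal to a
  reference entry (canonical / isoform-flagged); exact equality takes
  precedence over any BLAST ranking.
* ``novel_tge`` — no alignment with e-value <= the threshold (default
  1e-30).
* ``candidate_variant`` — provisional; resolved downstream into
  ``known_with_polymorphism`` or ``novel_isoform`` by the variation module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import TYPE_CHECKING, Iterable, Mapping, Optional, Sequence

from Bio.Align import PairwiseAligner, substitution_matrices

from .errors import ValidationError
from .variation import compute_midline

if TYPE_CHECKING:  # pragma: no cover
    from .io_formats import ReferenceProtein

#: gapped Karlin-Altschul parameters for BLOSUM80, gap open 10 / extend 1
#: (NCBI BLAST source constants table)
BLOSUM80_GAPPED_LAMBDA = 0.299
BLOSUM80_GAPPED_K = 0.071

DEFAULT_EVALUE_THRESHOLD = 1e-30

MAIN_CLASSES = (
    "known_protein",
    "known_isoform",
    "known_with_polymorphism",
    "novel_isoform",
    "novel_tge",
    "candidate_variant",  # provisional only
)

_VALID_LETTERS = frozenset("ACDEFGHIKLMNPQRSTVWYX")


@dataclass(frozen=True)
class AlignmentParams:
    matrix_name: str = "BLOSUM80"
    gap_open: int = 10  # gap of length L costs open + extend*L
    gap_extend: int = 1
    karlin_lambda: float = BLOSUM80_GAPPED_LAMBDA
    karlin_k: float = BLOSUM80_GAPPED_K


@dataclass(frozen=True)
class PairwiseAlignment:
    """A local protein alignment (one HSP) in BLAST conventions."""

    query_id: str
    subject_id: str
    e_value: float
    bit_score: float
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    q_aln: str
    s_aln: str
    midline: str

    def validate(self) -> None:
        if not (len(self.q_aln) == len(self.s_aln) == len(self.midline)):
            raise ValidationError(
                f"{self.query_id}/{self.subject_id}: aligned string lengths differ "
                f"({len(self.q_aln)}, {len(self.s_aln)}, {len(self.midline)})"
            )
        if self.q_start > self.q_end or self.s_start > self.s_end:
            raise ValidationError(
                f"{self.query_id}/{self.subject_id}: inverted coordinates"
            )
        q_res = len(self.q_aln) - self.q_aln.count("-")
        s_res = len(self.s_aln) - self.s_aln.count("-")
        if q_res != self.q_end - self.q_start + 1:
            raise ValidationError(
                f"{self.query_id}/{self.subject_id}: query coordinates do not "
                f"match the aligned string"
            )
        if s_res != self.s_end - self.s_start + 1:
            raise ValidationError(
                f"{self.query_id}/{self.subject_id}: subject coordinates do not "
                f"match the aligned string"
            )


@dataclass(frozen=True)
class MainClass:
    label: str
    best_hit: Optional[str] = None


@lru_cache(maxsize=4)
def load_matrix(name: str = "BLOSUM80"):
    return substitution_matrices.load(name)


def _check_sequence(seq: str, what: str) -> None:
    if not seq:
        raise ValidationError(f"{what} sequence is empty")
    bad = set(seq) - _VALID_LETTERS
    if bad:
        raise ValidationError(f"{what} sequence contains invalid letters {sorted(bad)}")


@lru_cache(maxsize=4)
def _aligner(params: AlignmentParams) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = load_matrix(params.matrix_name)
    aligner.open_gap_score = -(params.gap_open + params.gap_extend)
    aligner.extend_gap_score = -params.gap_extend
    return aligner


def local_alignment_score(
    query: str, subject: str, params: AlignmentParams = AlignmentParams()
) -> float:
    """Optimal local alignment score only (cheap pre-screen for best-hit search)."""
    _check_sequence(query, "query")
    _check_sequence(subject, "subject")
    return float(_aligner(params).score(query, subject))


def align_local(
    query: str,
    subject: str,
    params: AlignmentParams = AlignmentParams(),
    query_id: str = "query",
    subject_id: str = "subject",
) -> Optional[PairwiseAlignment]:
    """Optimal local alignment of two protein sequences.

    Returns None when no positive-scoring local alignment exists. Ties
    between co-optimal alignments are broken deterministically (first
    alignment in Biopython's canonical enumeration order).
    """
    _check_sequence(query, "query")
    _check_sequence(subject, "subject")
    aligner = _aligner(params)
    alignments = aligner.align(query, subject)
    if alignments.score <= 0:
        return None
    aln = alignments[0]
    q_aln, s_aln = str(aln[0]), str(aln[1])
    coords = aln.coordinates
    q_start, q_end = int(coords[0][0]) + 1, int(coords[0][-1])
    s_start, s_end = int(coords[1][0]) + 1, int(coords[1][-1])
    matrix = load_matrix(params.matrix_name)
    midline = compute_midline(q_aln, s_aln, matrix)
    score = float(alignments.score)
    lam, kk = params.karlin_lambda, params.karlin_k
    e_value = kk * len(query) * len(subject) * math.exp(-lam * score)
    bit_score = (lam * score - math.log(kk)) / math.log(2)
    return PairwiseAlignment(
        query_id=query_id,
        subject_id=subject_id,
        e_value=e_value,
        bit_score=bit_score,
        q_start=q_start,
        q_end=q_end,
        s_start=s_start,
        s_end=s_end,
        q_aln=q_aln,
        s_aln=s_aln,
        midline=midline,
    )


def best_hit(alignments: Sequence[PairwiseAlignment]) -> Optional[PairwiseAlignment]:
    """Best alignment for one TGE: minimum e-value, ties by maximum bit
    score, then lexicographically smallest subject accession."""
    if not alignments:
        return None
    queries = {a.query_id for a in alignments}
    if len(queries) > 1:
        raise ValidationError(f"best_hit called with mixed query ids {sorted(queries)}")
    return min(alignments, key=lambda a: (a.e_value, -a.bit_score, a.subject_id))


def assign_main_class(
    tge_sequence: str,
    best: Optional[PairwiseAlignment],
    reference: Mapping[str, "ReferenceProtein"] | Iterable["ReferenceProtein"],
    e_threshold: float = DEFAULT_EVALUE_THRESHOLD,
) -> MainClass:
    """Assign the top-level class for one TGE.

    Exact sequence equality to a reference entry wins over any alignment
    ranking; equality to both a canonical and an isoform entry reports the
    canonical (``known_protein``).
    """
    if e_threshold <= 0:
        raise ValidationError("e_threshold must be positive")
    refs = reference.values() if isinstance(reference, Mapping) else reference
    exact_canonical = None
    exact_isoform = None
    for ref in refs:
        if ref.aa_sequence == tge_sequence:
            if ref.is_isoform:
                if exact_isoform is None or ref.accession < exact_isoform:
                    exact_isoform = ref.accession
            else:
                if exact_canonical is None or ref.accession < exact_canonical:
                    exact_canonical = ref.accession
    if exact_canonical is not None:
        return MainClass("known_protein", exact_canonical)
    if exact_isoform is not None:
        return MainClass("known_isoform", exact_isoform)
    if best is None or best.e_value > e_threshold:
        return MainClass("novel_tge", None)
    return MainClass("candidate_variant", best.subject_id)


def search_best_alignment(
    tge_id: str,
    tge_sequence: str,
    references: Sequence["ReferenceProtein"],
    params: AlignmentParams = AlignmentParams(),
) -> Optional[PairwiseAlignment]:
    """Align one TGE against every reference and return the best hit.

    Scores all pairs first (score-only DP, cheap) and materialises full
    alignments only for the top-scoring subjects, which is equivalent to
    ranking by e-value because e-values are monotone in score up to the
    m*n factor handled below.
    """
    scored: list[tuple[float, "ReferenceProtein"]] = []
    for ref in sorted(references, key=lambda r: r.accession):
        s = local_alignment_score(tge_sequence, ref.aa_sequence, params)
        if s > 0:
            scored.append((s, ref))
    if not scored:
        return None
    # e-value depends on score and subject length; keep every subject whose
    # (score, length) pair could win, then materialise those alignments.
    lam = params.karlin_lambda
    best_key = min(
        (-lam * s + math.log(len(r.aa_sequence)), r.accession) for s, r in scored
    )
    candidates = [
        (s, r)
        for s, r in scored
        if -lam * s + math.log(len(r.aa_sequence)) <= best_key[0] + 1e-9
    ]
    alignments = [
        align_local(tge_sequence, r.aa_sequence, params, tge_id, r.accession)
        for _, r in candidates
    ]
    return best_hit([a for a in alignments if a is not None])
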