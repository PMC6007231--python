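"""Detectability-calibrated variant-vs-reference scoring and TGE rating.

For a TGE with a resolved best alignment, let V be the tryptic peptides
that uniquely describe the variant (peptides of the TGE covering variant
regions, excluding any sequence also produced by digesting the reference)
and R the peptides that uniquely describe the reference (reference
peptides covering the reference-side projection of the variant regions,
excluding any sequence also produced by digesting the TGE). With A ⊆ V and
B ⊆ R the identified subsets (q = lowest q-value per peptide) and A' , B'
the unidentified remainders carrying calibrated detectability scores s:

    score_variant = [ sum_{a in A}  (1 - q_a)
                    - sum_{b in B}  (1 - q_b)/4
                    + sum_{b in B'} s_b/8
                    - sum_{a in A'} s_a/8 ] / (|V| + |R|)

and score_reference is the same expression with the roles of V and R
swapped. The denominator 4 keeps the two scores close when both variant-
and reference-specific peptides are observed (both forms present); the
denominator 8 reflects an anticipated LC-MS/MS peptide coverage of 12.5%.
The TGE is called a variant when score_variant - score_reference exceeds
the decision margin (default 0), the reference when the reverse holds,
otherwise undecided (including the V = R = empty-set case).

Raw detectability comes from a deterministic, fully documented default
predictor — a logistic function of tryptic-peptide length (bell penalty
outside 8-25 residues), mean Kyte-Doolittle hydropathy, charged-residue
fraction and proline count — behind a pluggable interface, and is then
*calibrated* to a sample-specific detection score s: candidate tryptic
peptides of TGEs already identified as known proteins are binned into
deciles of raw score, the per-bin identification frequency is regularised
by pool-adjacent-violators (isotonic regression), and the transform is
applied by linear interpolation. Calibration is what anchors s to this
sample; the absolute raw scores are secondary.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
from sklearn.isotonic import IsotonicRegression

from .errors import ContractError, ValidationError
from .evidence import DigestedPeptide, digest, variant_regions
from .variation import TgeClassification

logger = logging.getLogger(__name__)

#: Eq. denominator for identified reference peptides ("both present" damping)
REFERENCE_DENOMINATOR = 4
#: Eq. denominator for unidentified peptides (12.5% anticipated coverage)
UNDETECTED_DENOMINATOR = 8

_KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2, "X": 0.0,
}
_CHARGED = frozenset("DEKRH")

#: fixed coefficients of the default detectability model
_DETECT_COEF = {
    "intercept": 1.5,
    "length_penalty": -0.40,   # per residue outside the 8-25 window
    "hydropathy": -0.60,       # per unit |gravy - (-0.4)|
    "charge": -3.0,            # per unit |charged fraction - 0.2|
    "proline": -0.30,          # per proline
}


def predict_detectability(peptide: str) -> float:
    """Deterministic raw detectability of one peptide, in [0, 1]."""
    if not peptide:
        raise ValidationError("empty peptide")
    bad = set(peptide) - set(_KYTE_DOOLITTLE)
    if bad:
        raise ValidationError(f"peptide contains non-amino-acid letters {sorted(bad)}")
    length = len(peptide)
    length_penalty = max(0, 8 - length, length - 25)
    gravy = sum(_KYTE_DOOLITTLE[a] for a in peptide) / length
    charged_frac = sum(a in _CHARGED for a in peptide) / length
    n_pro = peptide.count("P")
    c = _DETECT_COEF
    z = (
        c["intercept"]
        + c["length_penalty"] * length_penalty
        + c["hydropathy"] * abs(gravy + 0.4)
        + c["charge"] * abs(charged_frac - 0.2)
        + c["proline"] * n_pro
    )
    return 1.0 / (1.0 + math.exp(-z))


class TsvDetectabilityModel:
    """Plug-in predictor backed by a two-column TSV (peptide, raw score).

    Peptides absent from the table fall back to the default model.
    """

    def __init__(self, path: str):
        import pandas as pd

        df = pd.read_csv(path, sep="\t", dtype={0: str})
        self.scores: dict[str, float] = dict(
            zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(float))
        )

    def __call__(self, peptide: str) -> float:
        return self.scores.get(peptide, predict_detectability(peptide))


@dataclass
class CalibrationTransform:
    """Monotone raw->s transform fitted on known-protein peptides."""

    bin_centers: np.ndarray
    bin_values: np.ndarray  # after pool-adjacent-violators
    identity: bool = False

    def __call__(self, raw) -> np.ndarray | float:
        scalar = np.isscalar(raw)
        raw_arr = np.atleast_1d(np.asarray(raw, dtype=float))
        if self.identity:
            out = np.clip(raw_arr, 0.0, 1.0)
        else:
            out = np.interp(raw_arr, self.bin_centers, self.bin_values)
        return float(out[0]) if scalar else out


def calibrate(
    raw_scores: Sequence[float],
    identified: Sequence[bool],
    n_bins: int = 10,
) -> CalibrationTransform:
    """Fit the sample-specific detection transform.

    Bins raw scores into deciles, takes the per-bin identified fraction,
    regularises by isotonic regression (weights = bin counts) and
    interpolates linearly between bin centers. Falls back to the identity
    transform with a warning when no peptides are supplied.
    """
    raw_arr = np.asarray(raw_scores, dtype=float)
    ident = np.asarray(identified, dtype=bool)
    if raw_arr.size == 0:
        logger.warning("no known-protein peptides available; using identity transform")
        return CalibrationTransform(np.array([0.0, 1.0]), np.array([0.0, 1.0]), identity=True)
    if raw_arr.shape != ident.shape:
        raise ValidationError("raw_scores and identified must have equal length")
    edges = np.unique(np.quantile(raw_arr, np.linspace(0, 1, n_bins + 1)))
    if edges.size < 2:  # all raw scores identical
        value = float(ident.mean())
        return CalibrationTransform(np.array([edges[0]]), np.array([value]))
    idx = np.clip(np.searchsorted(edges, raw_arr, side="right") - 1, 0, edges.size - 2)
    centers, means, counts = [], [], []
    for b in range(edges.size - 1):
        mask = idx == b
        if mask.any():
            centers.append(float(raw_arr[mask].mean()))
            means.append(float(ident[mask].mean()))
            counts.append(int(mask.sum()))
    iso = IsotonicRegression(y_min=0.0, y_max=1.0, increasing=True)
    fitted = iso.fit_transform(centers, means, sample_weight=counts)
    return CalibrationTransform(np.asarray(centers), np.asarray(fitted))


def build_peptide_sets(
    tge_sequence: str,
    classification: TgeClassification,
    ref_sequence: str,
    missed_cleavages: int = 0,
    min_len: int = 7,
    max_len: int = 45,
) -> tuple[list[DigestedPeptide], list[DigestedPeptide]]:
    """Construct V (variant-describing) and R (reference-describing).

    The TGE-side projection is the variant-region union; for a truncated
    terminus (variation lives entirely on the reference) the TGE junction
    residue at the alignment end is added so that a novel junction peptide
    created by the truncation can enter V. The reference-side projection
    mirrors this: event reference intervals (insertions contribute their
    flanking reference residues), reference terminal overhangs, and the
    reference junction residue for an extended terminus. Peptide sequences
    produced by digesting *both* molecules describe neither and are
    removed from both sets.
    """
    aln = classification.alignment
    if aln is None:
        raise ContractError("build_peptide_sets requires a resolved alignment")
    tge_len, ref_len = len(tge_sequence), len(ref_sequence)

    tge_iv = variant_regions(classification, tge_len)
    ref_iv: list[tuple[int, int]] = []
    for ev in classification.events:
        if ev.ref_seq == "":  # insertion: flank the reference anchor
            ref_iv.append((max(1, ev.ref_start), min(ref_len, ev.ref_start + 1)))
        else:
            ref_iv.append((ev.ref_start, ev.ref_end))
    if classification.terminals is not None:
        n_term, c_term = classification.terminals
        if n_term.ref_overhang_len > 0:
            ref_iv.append((1, n_term.ref_overhang_len))
        if c_term.ref_overhang_len > 0:
            ref_iv.append((ref_len - c_term.ref_overhang_len + 1, ref_len))
        # junction anchors for one-sided termini
        if n_term.kind == "truncated":
            tge_iv.append((aln.q_start, aln.q_start))
        if c_term.kind == "truncated":
            tge_iv.append((aln.q_end, aln.q_end))
        if n_term.kind == "extended":
            ref_iv.append((aln.s_start, aln.s_start))
        if c_term.kind == "extended":
            ref_iv.append((aln.s_end, aln.s_end))

    def overlapping(peps: list[DigestedPeptide], ivs: list[tuple[int, int]]):
        return [
            p for p in peps if any(p.start <= hi and p.end >= lo for lo, hi in ivs)
        ]

    tge_peps = digest(tge_sequence, missed_cleavages, min_len, max_len)
    ref_peps = digest(ref_sequence, missed_cleavages, min_len, max_len)
    tge_seqs = {p.peptide for p in tge_peps}
    ref_seqs = {p.peptide for p in ref_peps}
    V = [p for p in overlapping(tge_peps, tge_iv) if p.peptide not in ref_seqs]
    R = [p for p in overlapping(ref_peps, ref_iv) if p.peptide not in tge_seqs]
    return V, R


@dataclass
class VariantScore:
    tge_id: str
    V: frozenset[str]
    R: frozenset[str]
    A: frozenset[str]
    B: frozenset[str]
    A_prime: frozenset[str]
    B_prime: frozenset[str]
    score_variant: float
    score_reference: float
    decision: str  # "variant" | "reference" | "undecided"


def score_variant_vs_reference(
    V: Sequence[str] | Sequence[DigestedPeptide],
    R: Sequence[str] | Sequence[DigestedPeptide],
    identified_q: Mapping[str, float],
    s_of: Callable[[str], float],
    tge_id: str = "",
    margin: float = 0.0,
    ref_denominator: float = REFERENCE_DENOMINATOR,
    undetected_denominator: float = UNDETECTED_DENOMINATOR,
) -> VariantScore:
    """Evaluate the variant and reference scores and the decision.

    ``identified_q`` maps identified peptide sequences to their lowest
    q-value (peptides above the retention FDR threshold must already have
    been dropped by the caller); ``s_of`` returns the calibrated
    detectability of an unidentified peptide.
    """
    vset = frozenset(p if isinstance(p, str) else p.peptide for p in V)
    rset = frozenset(p if isinstance(p, str) else p.peptide for p in R)
    n = len(vset) + len(rset)
    if n == 0:
        raise ContractError("score undefined for empty V and R")
    A = frozenset(p for p in vset if p in identified_q)
    B = frozenset(p for p in rset if p in identified_q)
    A_prime = vset - A
    B_prime = rset - B
    sum_a = sum(1.0 - identified_q[p] for p in A)
    sum_b = sum(1.0 - identified_q[p] for p in B)
    s_a = sum(s_of(p) for p in A_prime)
    s_b = sum(s_of(p) for p in B_prime)
    d4, d8 = ref_denominator, undetected_denominator
    score_variant = (sum_a - sum_b / d4 + s_b / d8 - s_a / d8) / n
    score_reference = (sum_b - sum_a / d4 + s_a / d8 - s_b / d8) / n
    diff = score_variant - score_reference
    if diff > margin:
        decision = "variant"
    elif -diff > margin:
        decision = "reference"
    else:
        decision = "undecided"
    return VariantScore(
        tge_id=tge_id, V=vset, R=rset, A=A, B=B,
        A_prime=A_prime, B_prime=B_prime,
        score_variant=score_variant, score_reference=score_reference,
        decision=decision,
    )


def rate_tge(
    classification: TgeClassification,
    has_variant_peptide: bool,
    has_unique_variant_peptide: bool,
    decision: Optional[str],
    completeness: str,
) -> int:
    """Evidence rating ladder (5 strongest .. 1 weakest).

    5: a unique peptide occurrence covers a variant region; 4: any peptide
    covers a variant region; 3: the scoring model calls the variant with
    no variant-covering peptide; 2: retained TGE from a complete ORF
    without variant evidence; 1: everything else. Known proteins and
    isoforms have no variant region, so they land on 2 or 1.
    """
    if has_unique_variant_peptide:
        return 5
    if has_variant_peptide:
        return 4
    if decision == "variant":
        return 3
    if completeness == "complete":
        return 2
    return 1
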