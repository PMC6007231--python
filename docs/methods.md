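# Methods

This note records the model, the tunable parameters, the numerical
choices, and what the synthetic data does and does not emulate.

## Classification model

A TGE is an ORF retained by the evidence filters (below). Classification
is a function of its best local alignment against the reference proteome:

* **Exact equality first.** A TGE whose normalised sequence (uppercased,
  trailing stop stripped) equals a reference entry is a *known protein*
  (canonical) or *known isoform* (isoform-flagged entry), regardless of
  which hit an aligner would rank best. Equality to both resolves to the
  canonical. Isoform flags are derived from the reference FASTA header:
  accession matching `^[^-]+-\d+$` (UniProt isoform suffix) or a
  description containing the token "isoform"; the rule is configurable.
* **Novelty.** A TGE whose best alignment has e-value above 10⁻³⁰ (or no
  alignment at all) is a *novel TGE*. The threshold is inclusive: an
  alignment at exactly 10⁻³⁰ qualifies. The literature states the bound
  once as "below" for mapping and once as "above" for novelty; treating
  the boundary as qualifying makes the two readings consistent.
* **Variants.** Everything else is resolved through the alignment
  midline. Midline symbols follow BLAST: the letter for identities, `+`
  for substitutions with positive BLOSUM80 score, space otherwise.
  Maximal runs of non-identity columns become events:

  | columns | substitution run | gap in TGE | gap in reference |
  |---------|------------------|------------|------------------|
  | 1       | SAP (SSAP if `+`) | DEL       | INS              |
  | 2–9     | ALT (SALT if all `+`) | DEL   | INS              |
  | ≥ 10    | SV               | SV         | SV               |

  The 9/10 boundary reflects the shortest commonly accepted protein-coding
  exon (~27 nt), so any ≥10-residue variation is treated as an
  alternative-splice-scale event. The rule is applied to insertions and
  deletions as well as substitution runs: exon skipping manifests as a
  long deletion, so restricting SV to substitutions would misread the most
  common splice signature. Adjacent runs of different mechanism (a
  mismatch run abutting a gap run) are deliberately *not* merged; events
  remain in one-to-one correspondence with alignment column runs.

  A deletion has no extent on the TGE. Its anchor is the residue
  immediately left of the gap (`tge_start = tge_end = anchor`, 0 when the
  gap opens at the alignment start); insertions mirror this on the
  reference. Anchors give deletions a stable address for peptide-overlap
  tests (the two flanking residues).

* **Termini.** The N-terminus is classified from `(q_start, s_start)`:
  (1,1) identical, (1,>1) truncated, (>1,1) extended, (>1,>1) alternative;
  the C-terminus symmetrically from the distances to the sequence ends.
  A candidate variant with both termini identical is a *known protein
  with polymorphism* (or a novel isoform of subclass SV if it contains an
  SV event); otherwise it is a *novel isoform* named by its non-identical
  termini (`N_truncated`, `C_extended`, `N_alternative+C_truncated`, …) —
  15 terminal subclasses, 16 novel-isoform subclasses with SV. Together
  with the two known classes, the polymorphism classes and novel TGEs this
  is the full label set the synthetic generator exercises (28 labels
  including the three alternative-start categories).

* **Alternative starts.** Considered only when the alignment reaches TGE
  residue 1. A non-methionine first residue is an alternative start,
  *discounted* when the preceding reference residue is K or R, because a
  tryptic fragment of a truncated assembly would present exactly the same
  N-terminus. A TGE matching the reference from position 2 of a
  Met-initiated reference is reported as *Met-removed* — its own category,
  not subject to the K/R discount (co-translational Met excision is a real
  biological signal, not a tryptic artefact).

## Alignment

When a BLAST XML file is supplied, its HSPs are authoritative (single best
HSP per subject; no sum statistics). Otherwise an internal optimal local
aligner is used: BLOSUM80, affine gap cost `10 + L` for a gap of length L.
E-values follow the Karlin–Altschul form `E = K·m·n·e^(−λS)` with the
gapped BLOSUM80/10/1 constants from the NCBI BLAST source distribution,
λ = 0.299 and K = 0.071, without edge-length correction — adequate for
ranking and thresholding at fixture scale, and flagged as approximate
relative to BLAST's own statistics. Ties between co-optimal alignments are
broken by the aligner's canonical enumeration order; best hits are chosen
by minimum e-value, then maximum bit score, then lexicographic accession,
which makes the result independent of input order.

## Evidence filters

Defaults: PSM q ≤ 0.01 (global 1% FDR), ≥ 2 distinct identified peptides
per ORF. The built-in target-decoy computation ranks PSMs by search score
(stable sort), takes FDR(i) = decoys/targets at or above rank i, and
assigns q-values as the cumulative minimum from the bottom. Peptides are
mapped to ORFs by exact substring search over every retained sequence —
input accession lists are checked but never trusted — and uniqueness is
defined against the sample's own TGE set (a peptide hitting two ORFs
merged into one TGE is unique). A merged TGE is labelled `complete` if any
member ORF is complete: one fully assembled transcript suffices to
establish the ORF's completeness. Protein ambiguity groups join TGEs with
identical identified-peptide sets; a TGE whose set is a strict subset of
another group's is attached to the largest such group (ties by sorted
peptide set), a deterministic reconstruction of standard protein grouping.

In-silico digestion is tryptic: cleave after K/R, suppressed before P
(configurable). Candidate peptides for detectability and scoring use 0
missed cleavages and length 7–45, bracketing typical MS-observable tryptic
peptides; identified peptides are used as given.

## Variant-versus-reference scoring

V is the set of TGE tryptic peptides overlapping variant regions (event
intervals, deletion flanks, terminal overhangs) minus any sequence the
reference digest also produces; R mirrors this on the reference side. One
extension beyond the interval algebra: a *pure truncation* has no variant
region on the TGE side at all, yet truncation inside a tryptic peptide
creates a novel junction fragment. The peptide-set construction therefore
adds the junction anchor residue (TGE residue at the alignment start/end
for a truncated terminus; reference residue for an extended terminus) to
the projection — the shared-sequence subtraction then keeps exactly the
novel fragments. The per-occurrence `overlaps_variant` flag used for
evidence counting keeps the strict regions, so a shared peptide at a
truncation junction is never reported as variant-specific.

Scores follow the two-sided equation in the README. The denominators are
structural constants of the method: 4 damps identified reference peptides
so that the two scores stay close when both forms are present; 8 encodes
an anticipated LC–MS/MS peptide coverage of 12.5% for unidentified
peptides. They are named constants, overridable only through
configuration. Identified peptides with q above the retention threshold
are treated as unidentified, for consistency with the retention filter.
Two algebraic properties hold exactly and are tested to 10⁻¹²:
`score_variant + score_reference = ¾·Σ_identified(1−q)/(|V|+|R|)`, and
each score lies in [−¼, 1]. With no identifications the scores are exact
negatives of each other. An empty V ∪ R leaves the TGE *undecided*.

### Detectability and calibration

Raw detectability is a documented default model: a logistic in four
peptide features — length penalty `max(0, 8−L, L−25)`, distance of mean
Kyte–Doolittle hydropathy from −0.4, distance of the charged-residue
(DEKRH) fraction from 0.2, and proline count — with fixed coefficients
(1.5, −0.40, −0.60, −3.0, −0.30). It is a pure function of the peptide
string, pluggable (any peptide→score TSV can replace it). Absolute raw
scores are secondary because of calibration: candidate tryptic peptides of
TGEs already identified as known proteins are binned into deciles of raw
score, the per-bin identified fraction is regularised by
pool-adjacent-violators (isotonic regression weighted by bin counts), and
the transform is applied by linear interpolation between bin centers,
clipped to [0, 1]. Degenerate inputs (a single distinct raw value)
collapse to a constant transform; with no known-protein TGEs the transform
falls back to identity with a logged warning.

## Evidence rating

5 — a unique peptide occurrence covers a variant region; 4 — any peptide
covers a variant region; 3 — scoring calls the variant without a
variant-covering peptide; 2 — retained TGE from a complete ORF without
variant evidence; 1 — all other retained TGEs. Known proteins and isoforms
have no variant regions and land on 2 or 1.

## Synthetic data

The generator emulates the statistical structure the method assumes, not
raw mass spectrometry. References are random Met-initiated proteins of
120–200 residues with uniform residue frequencies (classification logic is
frequency-agnostic; Swiss-Prot frequencies are a configuration away), a
subset flagged as isoforms derived by an N-terminal swap. TGEs are edits
of a reference realising exactly one planned label: BLOSUM80-aware
substitution partners for SAP/SSAP/ALT/SALT (residues C, G and P have no
positive-scoring partner and are resampled for the similar classes),
3-residue indels, a 12-residue replacement for SV, 22–31-residue terminal
operations, suffix truncations at chosen positions for the alternative-
start cases, and fully random sequences for novel TGEs. Edited residues
are drawn from an alphabet without K, R and P so edits never create or
destroy cleavage sites at their boundaries — variant peptides are then
guaranteed to exist — except where the alt-start discount is deliberately
exercised. Every edit is verified at generation time against the *whole*
reference catalogue (an edit can align best to a different entry than its
source, changing the terminal subclass) and resampled on any mismatch, so
the plan is realisable under any seed; identical seeds give byte-identical
files.

PSM simulation observes each candidate tryptic peptide of each present
protein with a ground-truth detection probability — a steep logistic in
the raw detectability score spreading peptides over roughly [0.05, 0.95],
the regime of a deep experiment where detectability genuinely separates
peptides. Observed peptides get low q-values and high search scores;
decoy PSMs with well-separated lower scores are appended so the
target-decoy computation is exercised without ever flipping a target
below threshold. Sequences that must be retained are guaranteed two
observed peptides (logged when forcing is needed).

The validation analogue mirrors the published design at fixture scale:
isoform TGEs (truncated and alternative termini, one source protein each)
are classified against a canonical-only reference, so every one must come
out a novel isoform. Half are truly present; for the other half the
canonical form is present instead, and — as in real PIT data, where the
expressed canonical transcript is assembled too — the canonical joins the
ORF database as a carrier. This is what makes reference-specific peptides
identifiable at all in a search against sample-specific ORFs. The
score-based call is compared with the variant-specific-peptide rule, and
the score difference is ranked against ground truth (AUC).

What passing these tests shows: the classification taxonomy, event
algebra, filter semantics and scoring equations behave exactly as
specified on data satisfying the generative assumptions. What it does not
show: robustness to assembly chimeras, PTM-induced mass shifts,
I/L ambiguity (I and L are distinct letters throughout), shared-peptide
ambiguity across paralogue families, or real detectability prediction
accuracy — the default predictor is a stand-in whose absolute quality is
deliberately made secondary by calibration.

## Problem sizes

The round-trip experiment uses 28 labels × 10 TGEs against 30 canonical +
12 isoform references; the validation analogue uses 40 isoforms and 15
known proteins; scoring identities use 10³ random instances; calibration
recovery uses 10⁴ peptides. These sizes give stable statistics (binomial
error well inside the asserted bounds) while keeping the whole suite fast.

## Known limitations

* Internal e-values are approximations; supply BLAST XML when exact BLAST
  statistics matter.
* Single best HSP per subject: a TGE matching a reference in two widely
  separated blocks is read through one local alignment only.
* Uniqueness ignores the reference proteome by design (the sample's own
  identification set defines it); a count against the reference can be
  derived from the reports but is not the default.
* The 15-terminal-class naming is systematic (`N_kind+C_kind`), chosen for
  lossless readability rather than matching any particular figure's
  labels.
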