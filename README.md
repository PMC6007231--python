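# tgeclass

Classification and peptide-level confirmation of **translated genomic
elements (TGEs)** — sample-specific ORFs, derived from *de novo* assembled
transcripts, that are supported by mass-spectrometry peptide evidence.

In proteomics informed by transcriptomics (PIT), MS/MS spectra are searched
against ORFs predicted from the sample's own transcriptome rather than a
reference proteome. That makes it possible to observe proteins that carry
sample-specific variation — polymorphisms, splice isoforms, novel start
sites, entirely novel proteins — but it leaves a hard question open: which
putative TGEs are genuine variants, which are known proteins, and which are
artefacts of imperfect transcript assembly? `tgeclass` answers this by
comparing each TGE with a reference proteome and weighing the peptide
evidence for the variant against the evidence for the reference. It is
aimed at proteogenomics practitioners, particularly for non-model organisms
where no catalogue of known variants exists.

## What it does

1. **Retention.** PSMs are filtered at a global q-value threshold (default
   1% FDR; a target-decoy q-value computation is built in), peptides are
   located in ORFs by exact substring search, ORFs with ≥ 2 distinct
   identified peptides become TGEs, duplicate-sequence ORFs are merged, and
   protein ambiguity groups are formed from shared peptide sets.
2. **Homology.** Each TGE is aligned to the reference proteome (BLAST XML
   can be supplied; otherwise an internal Smith–Waterman with BLOSUM80,
   affine gaps 10/1, and Karlin–Altschul e-values is used). Exact sequence
   matches are *known proteins* / *known isoforms*; TGEs with no alignment
   at e ≤ 10⁻³⁰ are *novel TGEs*.
3. **Variation.** The best alignment's midline is scanned into events:
   SAP/SSAP (single substitutions; SSAP when BLOSUM80 > 0), ALT/SALT (2–9
   residue runs), INS/DEL (gap runs) and SV (≥ 10 columns, the
   alternative-splice-scale class). Alignment ends classify each terminus
   as identical / truncated / extended / alternative, giving 15 terminal
   isoform subclasses plus SV. Non-methionine starts are recorded, and
   discounted when the preceding reference residue is K or R (a tryptic
   artefact could mimic them); Met-removed starts are reported separately.
4. **Confirmation.** Identified peptides overlapping variant regions (and
   junction peptides spanning a variant/identical boundary) give direct
   evidence. In addition, a detectability-calibrated score compares the
   peptide sets that uniquely describe the variant (V) and the reference
   (R):

   ```
   score_variant  = [ Σ_{a∈A} (1−q_a) − Σ_{b∈B} (1−q_b)/4
                    + Σ_{b∈B'} s_b/8 − Σ_{a∈A'} s_a/8 ] / (|V|+|R|)
   ```

   with A ⊆ V, B ⊆ R the identified subsets, q the peptide's lowest
   q-value, and s a per-sample calibrated detectability for unidentified
   peptides; `score_reference` swaps the roles. The TGE is called a variant
   when `score_variant − score_reference` exceeds a margin (default 0).
5. **Rating.** Each TGE gets a 1–5 evidence rating, from "retained only"
   up to "unique peptide covering a variant region".

A synthetic-data generator (`tgeclass.fixtures` / `tgeclass simulate`)
produces ground-truth-labelled references, TGEs of every class, and
simulated PSM tables, so the entire pipeline is testable offline.

## Worked example

```bash
tgeclass simulate --out-dir fx --seed 7 --n-per-label 2 --n-reference 15
tgeclass run --orfs fx/tges.fasta --psms fx/psms.tsv \
             --reference fx/reference.fasta --out-dir out
```

prints the per-class summary

```
             main_class  total  complete_orf  with_specific_peptide  with_unique_specific_peptide  score_confirmed
          known_isoform      2             2                      0                             0                0
          known_protein      2             2                      0                             0                0
known_with_polymorphism     12            12                      6                             6                1
          novel_isoform     38            32                      9                             9                6
              novel_tge      2             2                      0                             0                0
```

i.e. of the 56 simulated TGEs (2 per class label), 12 are known proteins
with polymorphisms (2 each of SAP/SSAP/ALT/SALT/INS/DEL), 38 are novel
isoforms (SV, the 15 terminal subclasses and the 3 alternative-start
cases, 2 each), and the totals match the simulation plan exactly. Six of
the polymorphic TGEs have an identified peptide covering their variant
site. `out/classification.tsv` carries the per-TGE detail, e.g.

```
tge_id    length  main_class     subclass  best_hit  evalue      identity_pct  n_events
t0001.p1  196     known_protein            REF0001   1.12e-231   100.0         0
```

together with `variation_events.tsv` (one row per polymorphism),
`peptide_evidence.tsv` (per peptide occurrence, with variant-overlap and
junction flags) and `novel_tges.fasta`.

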