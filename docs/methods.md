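# Methods

## Pipeline model

The package treats protein-level confirmation of an alternative-splice (AS)
junction as a chain of four filters, each implemented as one module:

1. **Junction representation and classification** (`genome_io`). A junction
   is its intron interval `[start, end)` on a chromosome and strand, in
   0-based half-open coordinates (GTF input is converted on read). A
   junction is *known* iff the interval exactly matches an annotated intron
   of a gene model on the same chromosome and strand; one-sided matches are
   *novel*. Matching junctions rather than exons keeps the known/novel call
   exact and testable. Unstranded junction records are duplicated onto both
   strands with a warning. Duplicated junctions (same chromosome, strand,
   intron) merge with summed read counts, which makes merging commutative
   and associative.
2. **Translated junction database** (`junctiondb`). Each junction
   contributes a spliced window: `flank_nt` bases (default 75 = 25 aa)
   upstream of the intron joined to `flank_nt` bases from the intron end
   onward, clipped at the assigned gene's flanking exon boundaries (or
   chromosome bounds with `--genomic-flanks`); windows with an incomplete
   flank are dropped rather than padded, the simplest reading of "too-short
   junctions are filtered". Minus-strand windows are reverse-complemented
   into transcript orientation. Six-frame translation renders stops as `*`
   and N-containing codons as `X`; ORFs are maximal stop-free segments with
   no initiator-methionine requirement (the windows are internal transcript
   fragments; requiring ATG would discard nearly everything). A segment is
   emitted iff it is ≥ `min_orf_len` (default 30 aa) and spans the
   junction.
3. **In-silico identifiability** (`insilico_digest`). Trypsin cleaves after
   K/R, suppressed before P (the common search-engine default;
   `kp_rule=False` gives the variant without suppression). A junction is
   identifiable iff some frame yields a junction-spanning fully tryptic
   peptide of 6–30 aa (bounds inclusive) with at most the allowed missed
   cleavages. Per-gene summaries are unweighted means over genes, with
   junctions deduplicated by intron coordinates within a gene and
   zero-junction genes counting in denominators; identifiability is
   reported separately at 0 and ≤ 1 missed cleavages since the two regimes
   differ by roughly a factor of two.
4. **PSM post-processing** (`search_postprocess`). Decoys are whole-sequence
   reversals, one per target, generated over the reference+junction union
   so the decoy search space mirrors the target composition. The FDR
   estimator is `N_decoy / max(1, N_target)` at each score threshold
   (concatenated-search convention; the factor-2 variant is a one-line
   change), with q-values the running minimum from the permissive end. The
   novel-candidate subset gets its own curve computed from junction-only
   PSMs (targets and their decoys), because its error rate at the global
   threshold is several-fold higher. The homology filter replaces a BLAST
   step with an exhaustive equal-length Hamming scan with I/L treated as
   identical (isobaric residues); this is deterministic and strictly more
   stringent than a heuristic aligner for short peptides, and gapped
   homology is deliberately out of scope. PeptideProphet-style rescoring is
   not reimplemented: the probability column of the PSM table is the score,
   and any monotone score works. Spectrum quality is honored only as an
   optional precomputed-column cutoff.

## Boundary conventions

The residue whose codon uses any downstream-flank nucleotide is the
boundary residue (`boundary_aa`); the straddling codon therefore belongs to
the downstream side. For reverse frames the junction position is mapped
into the frame's own reading coordinates (`len(window) − boundary_nt`)
before the same rule is applied — otherwise reverse-frame ORFs could never
be classified as spanning. An entry spans its junction iff
`0 < boundary_aa < length`; segments whose boundary residue translates to
`X` are discarded as ambiguous. With both flanks required to be complete,
`boundary_nt` is always `flank_nt` on either strand. Partial codons at
window edges are dropped (standard six-frame behavior).

## Synthetic cohort: what it emulates

Defaults were chosen once to mirror the real mouse-tissue setting the
pipeline addresses: ~200 junctions over 40 multi-exon genes on two
chromosomes, both strands; 20% novel junctions; ~5% identifiable; 10,000
PSMs with 30% incorrect; a novel-subset naive FP rate calibrated to 0.38;
2,000 expression genes with a log-normal RPKM distribution, logistic
detection in log10 RPKM and a target log-log abundance/spectral-count
correlation of 0.53.

Two generator choices matter for test sharpness:

* **Identifiability is engineered, not sampled.** An identifiable junction
  gets flanks written as stop-free safe codons with an R codon 9 residues
  before and a K codon 6 residues after the boundary, so frame +0
  deterministically yields a 14-aa spanning tryptic peptide inside a 50-aa
  ORF. A non-identifiable junction gets a 12-nt cassette
  (`TTAATTAATTAA`, which contains a stop in every frame on both strands)
  immediately on each side of the boundary, so no spanning ORF of ≥ ~8 aa
  can exist in any frame. This yields exact per-junction truth labels; the
  guarantee assumes `min_orf_len` stays ≥ ~10 and full flanks.
* **PSM mixture calibration is analytic.** Correct scores are Beta(8, 1),
  incorrect Beta(1, 8) — a well-separated stand-in for posterior
  probabilities. The expected global threshold at the target FDR is solved
  from the Beta survival functions, and the junction share of incorrect
  matches is then set so the novel subset's naive FP rate at that threshold
  equals `subset_fp_rate` in expectation. Incorrect matches hit targets and
  decoys symmetrically (and junction decoys at the same share as junction
  targets), which is what keeps the subset decoy estimate unbiased.

Novel junctions are alternative-acceptor shifts (6 nt up to
`exon_len_min − 2·flank` into the downstream exon), which keeps every
engineered flank inside a single exon and every junction classifiable by
exact intron matching. Exon lengths must exceed `2·flank + 6` nt for this
layout; the generator raises an error otherwise. Because the generators
rewrite flank sequences, `generate_junctions` takes and returns the genome
alongside the junction list and truth table.

What the cohort does **not** emulate: read-level RNA-Seq noise, spectrum
physics and peptide flyability, shared peptides between paralogs,
non-uniform amino-acid composition, or intron-spanning gene overlaps.
Passing tests therefore demonstrate the correctness of the pipeline's
logic and calibration, not real-data identification rates.

## Numerical choices and degenerate inputs

* FDR q-values use exact score ties (distinct thresholds only); the
  threshold returned is the lowest score whose q ≤ target, `None` when
  unattainable; subsets without decoys return an undefined threshold with a
  warning rather than an error.
* `min_mismatch_distance` scans with vectorized sliding windows and exits
  early on exact matches; an empty reference gives distance = peptide
  length; `min_mismatches = 0` makes the homology filter the identity.
* Correlation is computed on log10-transformed RPKM and spectral counts
  over detected genes only (counts exist only there), and returns `None`
  on constant vectors. Binned detection fractions use log10 bins of width
  0.5 with a dedicated zero-RPKM bin; empty bins are omitted and raw
  counts are emitted alongside fractions so the caller controls any
  normalization.
* The expression generator sets the spectral-count noise variance on the
  *realized detected subpopulation*, compensating for the selection effect
  of logistic detection; integer rounding of counts attenuates the
  correlation by well under the ±0.05 testing tolerance at n = 2,000.
* Test and simulation sizes (1,000 digestion oracle sequences, 500
  homology pairs, 10,000 PSMs, 2,000 expression genes, ~200 junctions)
  were chosen as the smallest cohorts at which the binomial bands used in
  the tests are meaningfully narrow.

## Known limitations

* Known/novel status is checked at the nucleotide level against gene
  models here, and independently at the peptide level (reference-protein
  hits) in PSM novelty calls; the two can disagree for junctions whose
  translation coincides with an annotated protein, and both are reported.
* Gene assignment for novel junctions prefers genes whose exons flank the
  intron on both sides, then the tightest containing gene; junctions on
  chromosomes absent from the models stay unassigned.
* Only per-junction windows are built; multi-junction transcripts,
  transcript assembly and EST-style databases are out of scope, as are the
  search engine itself and protein inference.
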