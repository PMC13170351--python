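# Methods

## The detection problem

A-to-I editing deaminates adenosine to inosine, which reverse
transcription reads as guanosine. In a strand-specific (reverse)
library — R1 sequenced antisense to the transcript, pairs merged into
single reads that keep R1's orientation — a true editing event on a
plus-strand transcript therefore shows up as an A→G mismatch carried by
*reverse*-mapping reads, and on a minus-strand transcript as a genomic
T→C mismatch on *forward*-mapping reads. Three confounders must be
removed: genomic variants (present in matched DNA from the same
sample), sequencing error (low-frequency, quality-correlated, not
reproducible across replicates), and alignment artifacts (reads piling
up with identical start/end coordinates). The cascade encodes exactly
this: per-strand base identity and oriented read support, a minimum
editing level, minimum distinct alignment starts and ends, DNA
subtraction, and replicate consensus.

## Pipeline contract

Stages and their defaults (all configurable through `RunConfig` /
the TOML config; unknown keys are rejected):

| stage | parameters (defaults) |
|---|---|
| trimming | modified-Mott, error-probability limit 0.01; ≤ 1 ambiguous base; keep 50–150 nt |
| merging | ungapped overlap scan, match +1, mismatch −2, min score 8, no overhanging-end mismatches; conflicts resolve to the higher-quality base, ties to R1 |
| pileup quality | neighborhood radius 5, central quality ≥ 30, window mean ≥ 30 (strict-minimum aggregation available) |
| initial calls | coverage ≥ 4 and ≤ 100,000, alt count ≥ 2, frequency ≥ 0.1%, SNVs only; broken pairs and multimappers (mapq < 1) excluded |
| cascade | per-strand ref/alt identity, oriented count ≥ 3, oriented coverage ≥ 10, level ≥ 1%, unique starts ≥ 3, unique ends ≥ 3 |
| DNA subtraction | keyed on (position, alt); DNA samples pooled, called at the initial-call thresholds (stricter DNA thresholds configurable) |
| consensus | (position, alt, strand) in ≥ 2 replicates of a condition; conditions unioned before backfill |
| backfill | level = 100·G/(A+G) over orientation-consistent reads; low-coverage flag < 10; no pileup column at all = missing, distinct from 0% |

Coordinates are 0-based half-open internally; all emitted tables are
1-based inclusive and say so in a header line.

Editing levels use the A+G orientation-consistent denominator rather
than total coverage so that unrelated mismatches at the same position
cannot depress the level. Where a position lies in overlapping sense and
antisense features, both strand rules are evaluated and the site is
reported per feature — antisense transcripts are first-class citizens,
not annotation noise.

## Folding model

The structural question is whether the edited A sits unpaired in the
loop of a stem-loop, the geometry of the tRNA-Arg2 anticodon arm whose
wobble adenosine is the deaminase's canonical substrate. The default
folding backend is Nussinov-style maximum base pairing — Watson-Crick
plus GU wobble, minimum hairpin loop 3, deterministic traceback
(position i pairs the smallest qualifying j that achieves the
optimum) — not a thermodynamic model. Maximum pairing keeps the
classifier exactly testable by exhaustive structure enumeration and is
sufficient for a structural yes/no; a thermodynamic backend (the
RNAfold executable, when present) produces the same `FoldResult` shape
and feeds the same classifier.

The 17-nt window copies the arm's geometry: within the anticodon arm
the wobble position has 7 nt on its 5' side and 9 nt on its 3' side, so
the window is cut asymmetrically with the edited A at index 7
(`anchor="arm"`); a centered 8/8 window is available
(`anchor="center"`). The 37-nt window is centered ±18 under either
anchor. A window running off the genome is reported as
window-unavailable, never padded. "Stem-loop" means: edited A unpaired
inside a hairpin loop whose closing stem stacks ≥ 2 pairs (threshold
configurable; no canonical value exists).

One structural fact worth knowing: GU wobble pairing is *not* symmetric
under reverse complement (the complement of a GU pair is AC, which does
not pair), so mirrored windows are only guaranteed equal pair counts
when folding Watson-Crick-only (`allow_gu=False`); the symmetry
property test runs in that mode. Wobble stays on by default because the
arm itself relies on it.

## Statistics

Group comparisons are classical closed forms: Student/Welch t, one-way
ANOVA with optional Tukey HSD, and balanced two-way ANOVA by exact
sums-of-squares decomposition (unbalanced layouts are rejected rather
than silently approximated — the replicate design this analysis serves
is balanced). Benjamini-Hochberg is the step-up adjustment with
cumulative-minimum monotonicity; Šídák (1−(1−p)^k) serves planned
contrasts. Missing and low-coverage matrix entries are excluded from
tests, never imputed; z-scoring is per row over observed entries with
sample SD, and zero-variance rows are flagged and emitted as zeros.
TPM is count/length rates normalized to 10⁶; the codon-usage question
is a two-sided Fisher exact test on the 2×2 table of
tRNA-Arg2-dependent (CGU/CGA/CGC) versus other codons pooled over two
CDS sets. The row z-score is taken across *all* samples by default
(per-medium scoping available), matching heatmaps drawn over the full
sample set.

## What the simulator emulates — and what it does not

The generator builds a ≥ 1 kb linear chromosome of stranded features
(mRNA, one tRNA, antisense transcripts overlapping their host genes),
plants editing sites in three context classes — UACG embedded in a
verified hairpin (a designed 5-bp-stem/7-nt-loop arm mimic, accepted
only if the package's own folding model places the A in the loop), UACG
in arbitrary context, and non-UACG — and plants SNVs at allele
fractions 1.0/0.5, half of them deliberately disguised as
transcript-strand A→G so that DNA subtraction is genuinely exercised.
Editing is fragment-level Bernoulli at the site's rate; SNVs appear in
both DNA and RNA at their allele fraction; errors are uniform per-base
substitutions (default 0.2%) that carry low quality scores (Q12 vs Q40)
so the neighborhood filter has a real signal to act on. Per-fragment
randomness is drawn in transcript coordinates from streams keyed by
(seed, module, sample, feature), which makes read sets invariant under
genome mirroring and means adding a sample never perturbs existing
ones.

Not emulated: indels, PCR duplicates, GC and coverage bias, quality
miscalibration, mapping ambiguity (alignments are emitted at their true
coordinates; mapping itself is out of scope). Passing tests therefore
demonstrate the correctness of the calling logic under the stated noise
model, not robustness to alignment artifacts of real data.

## Study-scale choices

Desk-scale defaults stand in for deep sequencing of a bacterial
transcriptome: 12–15 features of 300 nt, fragment length 150 ± 15,
100-nt reads, RNA depth 50× (default) with matched DNA at 60×. The
recovery study runs 30 sites at rates 5–80% with 20 SNVs, three
replicates at 100× RNA: 100× is used for that study because a 5%-rate
site must produce ≥ 3 oriented reads to clear the cascade and
Binomial(50, 0.05) leaves that below a coin flip at 50×, whereas real
bacterial RNA-seq depth is orders of magnitude above either number.
Level accuracy is measured at 200× against the *realized*
edited-fragment fraction from read provenance — the quantity backfill
actually estimates — which isolates measurement error (merging, quality
filtering, orientation-consistent counting) from binomial sampling
noise; observed mean absolute error is a few hundredths of a
percentage point.

## Numerical and tie-break choices

- Mott trimming cuts at the largest maximizing index (keeps the longest
  prefix on ties); trimming is idempotent.
- Merge offset ties resolve to the largest overlap; base-call conflicts
  to the higher quality, then R1.
- Frequencies are compared at full precision; reports round for display
  only.
- The cascade evaluates every criterion and records each measured value
  in a `FilterReport`; the first failed criterion is named.
- Degenerate inputs fail loudly: reads past the genome end, windows off
  the genome, unbalanced two-way layouts, single-replicate consensus
  (explicit `min_shared=1` override), zero-expression TPM, out-of-frame
  CDS.

## Known limitations

Maximum-pairing folds over-pair GC-rich windows relative to a
thermodynamic model, so stem lengths reported for GC-rich contexts can
differ from RNAfold's (the stem-loop *flag* is robust in the planted
designs; the generator verifies each design before planting). DNA
subtraction pools all DNA samples by default; condition-matched
subtraction is available but untested against a condition-specific
variant scenario. The expression module is descriptive (TPM +
fold-change + Welch) and is not a replacement for count-based
differential-expression models.
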