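# Methods

`gaschip` reimplements, as a tested pipeline, the desk-side analysis that
accompanies a ChIP-cloning study of STAT5 binding sites in activated human
CD4 T cells: classifying mapped clone intervals by genomic context,
scanning their sequences for GAS motifs, summarizing the cohort, and
applying the three quantitative assay formulas used for validation
(qRT-PCR relative quantification, ChIP-qPCR percent input, dual-luciferase
fold induction). A synthetic-data generator supplies fully ground-truthed
inputs, so every stage is testable without any external download.

## Coordinate model

All in-memory coordinates are 0-based half-open; GFF3's 1-based closed
convention is converted at the parser boundary only. Gene models are
stranded with ordered non-overlapping exons; introns are the gaps between
consecutive exons and carry transcription-direction ordinals (intron 1 is
the intron nearest the TSS, i.e. the genomically last gap for a minus-strand
gene). The TSS is `tx_start` on the plus strand and `tx_end - 1` on the
minus strand. Cloned sites are deduplicated by exact `(chrom, start, end)`
equality — the cohort is counted as *unique binding sites*, not merged
peaks — and site sequences are stored in plus-strand orientation.

## GAS-motif scanning

Two degenerate 9-bp patterns are scanned: the canonical dimeric-STAT5 GAS
element `TTCNNNGAA` and the relaxed consensus `TTNNNNNAA` associated with
tetrameric binding. Pattern `N` matches exactly one of `{A,C,G,T}`; a
subject `N` (assembly gap) never matches, so no motif is called inside a
gap. Both patterns equal their own reverse complement as patterns, so a
single plus-strand scan is strand-complete: a minus-strand element is
necessarily a plus-strand match at the same offset. This is asserted as a
property test (matches on the reverse complement appear at mirrored
offsets) rather than assumed silently.

All overlapping matches are reported. A site's motif class is exclusive
with canonical precedence: `canonical` if it has at least one canonical
hit, else `general_only` if it has any relaxed hit, else `none`. Because
every canonical 9-mer also satisfies the relaxed pattern, the three classes
partition the cohort, which is what makes disjoint pie-style percentages
(26% + 68% + 6% ≈ 100%) meaningful. The scanner is verified against an
independent regex-lookahead oracle on 1,000 random sequences.

## Location classification

Each site is classified by its midpoint, `floor((start + end) / 2)`:
fragments are short (~0.2–1 kb) and receive exactly one category, and a
midpoint rule is deterministic at boundaries. Precedence:

1. midpoint inside an intron → `intron1` or `internal_intron` by the
   strand-aware ordinal; the host gene is the nominated target;
2. else midpoint within `(0, 10 kb]` 5′ of a TSS (strand-aware) →
   `upstream_lt10kb`, targeting the gene with the smallest such distance;
3. else midpoint inside exonic/UTR gene territory → `other`, flagged and
   reported separately (folding exonic hits into intron counts would
   corrupt the four-way summary);
4. else `intergenic`, nominating the nearest gene by TSS on each side (one
   at a chromosome end; none, with a warning, on a gene-free chromosome).

`dist_to_nearest_tss` is always the minimum `|midpoint − TSS|` over the
chromosome's genes. Ties (equidistant TSSs, or a midpoint in introns of two
overlapping genes) break by lexicographically smaller gene id. The 10 kb
upstream window is configurable; an `any_overlap` classification mode
exists for sensitivity analysis but is not used for the headline tables.
The classifier is checked against an exhaustive per-gene oracle on 200
random instances. A caveat: with genes packed closer together than the
upstream window, the upstream-before-exonic precedence means widening the
window could reclassify an exonic (`other`) site as upstream; under the
generator's ≥ 25 kb gene spacing the only transition a wider window can
cause is intergenic → upstream, and that is what the monotonicity test
asserts.

Interval-gap arithmetic (used to relate a published ChIP-seq peak to the
cloned GAS1 interval) returns 0 for overlapping or book-ended half-open
intervals and otherwise the distance between nearest ends; the printed chr2
coordinates give 1,162 bp.

## Cohort summaries

Category tables report count, raw fraction and an integer percent computed
by exact round-half-up (`Decimal`), the convention that reproduces every
printed cohort percentage (49/105 → 47, 12/105 → 11, 44/105 → 42,
14/105 → 13, 27/105 → 26, 71/105 → 68, 99/105 → 94). Percent columns may
sum to 99–101; fractions sum to 1 within 1e−12 and are always emitted, so
rounding loses nothing. The module reports whatever the input counts imply
and never forces marginal consistency (26 + 68 and a 94% any-motif fraction
cannot come from a single integer composition of 105; the table simply adds
a derived `any_motif` row = canonical + general_only).

## Assay formulas

* **qRT-PCR**: RQ = 2^−ΔCt with ΔCt = Ct(target) − Ct(reference), the
  reference being a housekeeping gene (18S in the motivating experiments).
  Replicate Cts are averaged on the cycle (log) scale before
  exponentiation, matching the additive error structure of threshold
  cycles. Amplification efficiency defaults to exactly 2.0 (perfect
  doubling); the parameter is exposed for sensitivity checks only.
* **ChIP-qPCR percent input**: the input Ct is first corrected for the
  input dilution, `Ct_input − log2(1/input_fraction)`, then
  `percent = 100 · 2^(adjusted_input − Ct_IP)`. The correction follows the
  standard kit convention; its two defining invariances — invariance to a
  common Ct shift, and exact truth recovery on noise-free synthetic data —
  are property-tested. Values above 100% warn (they signal an inverted Ct
  pair) but are returned.
* **Dual-luciferase**: firefly is normalized per well by the co-transfected
  Renilla signal; replicate wells are averaged on the ratio scale; fold
  induction is the induced mean ratio over the uninduced mean ratio, and is
  invariant to rescaling all four readings by a common factor.

No statistical testing across biological replicates is performed, and no
efficiency calibration from dilution series — the formulas mirror the
analysis they accompany. Induction kinetics are covered by parameter
recovery properties only, since no numeric fold values are available to
pin down.

## Synthetic data

The generator is the package's study stand-in, not a dial. Defaults:

| parameter | default | why |
| --- | --- | --- |
| genome | 3 chromosomes × 1.5 Mb, GC 0.41 | human-like base composition, large enough to pack 30 spaced genes |
| genes | 30, 2–6 exons, exons 100–300 bp, introns 1–3 kb, spacing ≥ 25 kb | multi-exon genes with room for every category; spacing > upstream window keeps categories well-separated |
| cohort | 105 sites: intergenic 49, upstream 12, intron1 14, internal 30 | the mapped-clone cohort composition (sub-counts are the unique integers consistent with the printed percentages under half-up rounding) |
| motif classes | canonical 27, general_only 71, none 7 | likewise the unique integers rounding to 26% / 68% |
| site length | uniform 200–1,000 bp | typical sonicated-chromatin clone insert |
| Ct noise | Gaussian, sd 0.2 cycles | routine qPCR replicate scatter |
| luciferase noise | log-normal, CV 0.1 | multiplicative well-to-well variation |

Planted midpoints keep ≥ 1 bp of margin from every category boundary
(upstream distances are drawn from [1, 9,999]), so recovery tests are never
decided by boundary ties; boundary behaviour is tested deliberately in the
annotation unit tests instead. Site backgrounds are made motif-free by
rejection: any window matching the relaxed pattern is redrawn until none
remain, then exactly one 9-mer is inserted for canonical
(`TTC` + 3 random + `GAA`) or general-only (`TT` + 5 random + `AA`,
rejecting draws that satisfy the canonical pattern) sites, and flanks are
re-scrubbed so the planted offset is the *only* relaxed match in the
sequence. Class recovery is therefore a hard guarantee — a failing
recovery test always indicates a pipeline bug, never generator noise. All
randomness flows from one integer seed through per-stage `numpy`
Generator streams; identical configs produce byte-identical output files.

What the generator does **not** emulate: ChIP fragment-length and
sonication-shear distributions, sequencing or mapping error, overlapping or
nested real gene annotation, assembly gaps, GC heterogeneity, and genuine
motif statistics of regulatory DNA (real backgrounds contain GAS-like
9-mers by chance; the scrubbed background deliberately removes them to make
tests exact). Passing tests therefore demonstrate correctness of the
computations, not robustness to annotation ambiguity in real genomes.

## Numerical and degenerate-input choices

Half-up integer rounding via `Decimal` (no float ties); empty cohorts are
errors for summaries, while an empty site file is a warned-about empty
cohort; a chromosome with no genes yields `intergenic` with no nominated
targets and a warning; Ct values ≥ 40 cycles are flagged as near
no-amplification; rejection sampling in the generator is bounded and raises
naming the limiting constraint rather than looping forever.

## Problem sizes

Tests and the acceptance script run the pipeline at the full 105-site
cohort scale on a 3 × 1.5 Mb genome (< 1 s per cohort); property suites use
1,000 random sequences for the scanner oracle, 200 random instances for
the annotation oracle, and 100 noisy replicates for fold-change recovery —
sizes chosen so the statistical assertions are well-powered while the whole
suite stays interactive.
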