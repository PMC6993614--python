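# Methods

This note documents the models, conventions and numerical choices behind
`eccseq`, and what its synthetic benchmarks do and do not demonstrate.

## Coordinate and insert-size conventions

All coordinates are 0-based half-open internally. BED is written natively;
the GFF3 writer converts to 1-based inclusive. Every merge operation —
per-pair regions, candidate assembly, per-sample and pooled call sets —
uses distance-0 semantics (overlapping *or bookended* intervals collapse),
matching bedtools `merge -d 0`.

The signed insert size of an opposite-strand pair is defined as
`5'(reverse mate) − 5'(forward mate)`, the distance between the 5′-most
aligned positions. A proper inward-facing pair is positive; an
outward-facing pair at a circle junction is negative. Aligners do not agree
on a sign convention for TLEN, so the package recomputes the insert from
mate positions rather than trusting the SAM field. Same-strand pairs are
never circle evidence.

## Detection

**Discordant track.** A pair is circle evidence iff it maps in opposite
orientations with negative insert, on one scaffold, with both MAPQ ≥ 10
(`min_mapq`), and |insert| ≥ read length + 5 (`min_nonoverlap`). Each
qualifying pair contributes its aligned extent
`[min aligned start, max aligned end)`. For full-length alignments this
equals the conventional `[min 5′ position, max 5′ position + read length)`;
for locally aligned (soft-clipped) junction reads of small circles it is
the correct extent, whereas adding the full read length would overrun the
junction. Extents merge into candidate regions carrying their pair counts.

**Split-read track.** Instead of an external rearrangement caller, the
package ships a minimal soft-clip re-anchoring junction caller: for a read
clipped ≥ 15 bp (`min_clip`), the clipped sequence is searched on the same
scaffold within the maximum circle size (50 kb), exact match first, then
allowing ≤ 1 mismatch (`max_mismatch`). A left-clip at position *a* whose
clip matches the reference ending at *b* (or the mirror case) calls the
junction (*a*, *b*); support counts distinct reads. Parameter parity with
full realignment-based callers is not claimed — the filter only needs a
second, independent evidence track — and multi-scaffold (translocation-like)
junctions are out of scope.

**Filter.** Candidates from both tracks are merged and scored against the
complete alignment stream: coverage fraction (any mapped read) and unique
fraction (reads with MAPQ ≥ 10, the same threshold used for read-level
uniqueness; no separate mappability track is assumed). High confidence
requires coverage ≥ 0.80 AND (both tracks OR ≥ 2 discordant pairs) AND
unique fraction ≥ 0.10. All thresholds are inclusive ("at least"
semantics). Coverage deliberately counts *all* mapped reads — concordant,
discordant and the aligned portion of clipped reads — the permissive of the
two defensible readings; a stricter concordant-only coverage can be
emulated by filtering the input. Calls are independent of input record
order (pairs are sorted internally), and raising any threshold can only
shrink the call set.

## Synthetic data generator

The generator emulates the structure of a compact avian-like genome and
the evidence signatures of a Circle-Seq library; it works at the alignment
level (positions, flags, CIGAR, MAPQ, sequences) rather than simulating
reads and mapping them, which keeps tests mapper-independent and fast.

* **Genome**: uniform-composition scaffolds at a configurable GC (default
  0.42); non-overlapping repeat intervals of seven RepeatMasker-style
  classes placed until a requested masked fraction (default 5.5%, the
  compact-genome regime; the realized fraction is enforced within ±20%
  relative); gene models with 2–6 exons and terminal UTRs at a requested
  density.
* **Circles**: default size distribution log-normal with mode 200 bp
  (σ = 0.6), bounded to [100 bp, 50 kb]; out-of-range draws are rejected,
  not clipped, so no boundary atom distorts the mode. The realized tail is
  thinner than real somatic eccDNA (which reaches tens of kb); multi-kb
  behaviour is exercised with explicit samplers. Placement is uniform,
  scaffold-length weighted, non-overlapping, optionally avoiding repeats.
* **Evidence**: concordant pairs tile each circle's interior at the
  requested fold coverage (fragment length ~ N(300, 30²) by default, 75-bp
  reads). Junction-spanning pairs are Poisson in number (rate ×
  interior pairs, floored at `min_junction_pairs` when a guaranteed-
  detectable benchmark is wanted) and emitted with the leftmost read
  reverse and the rightmost forward — negative insert under the convention
  above. When a wrapped fragment arm is shorter than the read, the read is
  soft-clipped at the junction with the clipped bases taken from the other
  side, exactly the local-alignment signature; this also makes small
  (< ~230 bp) circles detectable by the discordant track, as in real data.
  Additional clipped junction reads are emitted at `softclip_rate` to feed
  the split track independently.
* **MAPQ** is a two-point model: 42 for unique reads, 3 for reads
  overlapping a repeat interval — only the ≥ 10 threshold matters.
* **Spike-ins**: pBR322 (4,361 bp) and pUG72 (3,988 bp) at 10,000 copies;
  read pairs proportional to copies × length. **Background**: concordant
  pairs only. Rolling-circle amplification bias is modelled as a per-circle
  copy multiplier, not as chimeric artifacts. No sequencing-error model,
  base qualities or mitochondrial simulation.

Identical seeds give byte-identical SAM and truth files; pair emission is
exactly bookkept (nuclear pairs = circle pairs + background pairs).

Because the generator produces exactly the evidence the detector looks
for, recovery benchmarks demonstrate the *internal consistency* of the
pipeline (criteria, merging, scoring, filtering) — not robustness to
mapping artifacts, chimeras or coverage biases of real libraries.

## Quantification

`% reads/plasmid = plasmid reads × 100 / all mapped reads` and
`relative eccDNAs = detected eccDNAs / (% reads/plasmid)`; both are
invariant to uniform library-depth rescaling. Spike-in masses follow
`copies × length × 650 g/mol / N_A × 10⁹ ng/g`, reported to 2 significant
figures (4.7E-05 ng and 4.3E-05 ng for the two controls).

Genome counting stores the published constants verbatim: 2 marker (EFNB2)
copies per diploid genome, 650 g/mol/bp, 1.1 Gb genome, and
**2.257E-03 ng DNA per diploid cell**. The last value is *not* derived
from the others — 1.1 Gb × 650 g/mol gives 2.374E-03 ng — and the package
keeps the literal constant to reproduce the published arithmetic; the
discrepancy is surfaced here deliberately.

Length histograms use the standard bins (50 bp to 500 bp, 100 bp to 3 kb,
1 kb to 50 kb), left-closed right-open, with an overflow bucket.
Saturation curves subsample read *pairs* without replacement via a prefix
of one seeded permutation (deeper subsamples nest) and re-run the full
pipeline per depth; the canonical full-scale depth grid (0.25–15 million
reads) scales down to desk-size libraries.

## Annotation and enrichment

Gene-context categories form a deterministic partition: full containment
of exactly one gene → "contains one gene"; of two or more → "complete gene
or many"; otherwise ≥ 10% reciprocal overlap with any gene → partial; else
intergenic. The boundary between the first two categories is genuinely
ambiguous in the field's informal usage; containment count is the
tie-break adopted here.

Random region sets reproduce the observed size multiset exactly
(placement uniform, scaffold-weighted, with replacement; regions may
overlap each other). Feature overlap requires ≥ 10 bp with a single
annotated element. Significance is a Pearson chi-square without Yates
correction on the 2×2 table (overlapping vs non-overlapping, observed vs
pooled random); per-set p-values are also emitted. The pooled-table
construction is a design choice; under the null it is calibrated — the
type-I error over 200 seeded null runs sits inside the binomial envelope
around 5% (tested). GC comparisons use a two-sided equal-variance
Student's t-test on per-region GC, with all-N regions excluded.

Repeat quantification assigns a read to a class on any ≥ 1 bp overlap
(whole-read assignment, once per class, as with bedtools multicov), then
normalizes by library size and by the class's genomic fraction. With
finite-length reads the any-overlap rule inflates ratios slightly at
repeat edges (≈ intervals × (read length − 1) / genome); the unit-ratio
null benchmark therefore uses point placements, which isolate the counting
and normalization from this edge effect.

## Cohort statistics

Medians describe counts; SDs use the n−1 denominator. Mann-Whitney uses
the exact distribution for joint n ≤ 20 without ties, otherwise the normal
approximation with tie and continuity correction (at n = 10 per group the
two agree within 0.01). Headline fold-changes round half away from zero.

Post-hoc power draws both groups from normal models parameterized by the
sample mean and the *unbiased* (n−1) variance — the divisor is a
documented choice — and counts rejections at α = 0.05 over 10,000 rounds,
reporting the Monte-Carlo SE √(p(1−p)/rounds). P-values inside the power
loop come from the exact U null distribution (computed once by dynamic
programming; continuous draws are tie-free almost surely), which is both
faster and more accurate than per-round asymptotics; beyond n₁n₂ = 10,000
the continuity-corrected normal approximation takes over. Under the null
the estimated power equals the test's attainable size, which for the
group sizes used here (10 and 15) is within Monte-Carlo error of 0.05;
with very small groups the discreteness of U makes the attainable size
visibly smaller than α — an inherent property of rank tests, not a
calibration defect.

## Problem sizes used in the benchmarks

The shipped benchmarks run on 2 × 500-kb genomes with 50 planted circles
(≈ 40,000 read pairs) for recovery/specificity, 200-run null batteries for
enrichment calibration, and 10,000-round power simulations — sizes chosen
so the whole battery completes in well under a minute while keeping
Monte-Carlo error bands tight enough for the stated tolerances.

## Known limitations

* The split caller anchors clips by sequence search, so junctions inside
  long perfect repeats can be mis-anchored (they are then usually removed
  by the unique-fraction filter).
* Coverage scoring holds per-scaffold boolean masks in memory; genomes far
  beyond the hundreds-of-megabases range would need a sparse
  implementation.
* The simulator does not model chimeric rolling-circle artifacts,
  sequencing errors, GC-dependent coverage or mitochondrial circles; the
  linear-background false-positive benchmark is therefore optimistic about
  real libraries.
* Circles spanning multiple scaffolds and copy-number estimation per
  circle are out of scope.
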