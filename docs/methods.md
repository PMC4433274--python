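# Methods

This note records what the pipeline computes, the assumptions behind each
stage, what the synthetic-study generator does and does not emulate, and
the numerical and design choices that were genuinely open.

## Read classification

Reads are collapsed sequences with multiplicities; all cascade tallies sum
multiplicities. Classification is a strict first-match cascade:

1. **too_short** — length < `min_read_length` (default 18 nt). "High
   quality" is operationalized as length alone; instrument-side quality
   trimming happens upstream of this pipeline and is not modeled.
2. **unaligned** — no exact occurrence in the genome on either strand.
   Matching is exact substring search (both strands; minus-strand hits are
   stored in plus-strand coordinates). There is no mismatch tolerance and
   no alignment heuristics: at toy genome scale exact search is both
   sufficient and auditable.
3. **known_mirna** — full-length exact equality with a panel mature
   sequence. Reads that are proper substrings of a mature sequence fall
   through to the later categories; prefix-tolerant matching was rejected
   for determinism.
4. **ncrna** — exact substring of a non-miRNA ncRNA sequence.
5. **unannotated** — genome-matched leftovers, the discovery substrate.

Multi-mapping reads keep every genome hit but contribute their count once
to the cascade. Percentages round half-up to two decimals, the convention
used when such cascades are printed.

## Differential expression

Counts are normalized to reads per million of the per-sample
*genome-matched* total — not the column sum of the miRNA table. The test
is the pooled-variance Student's t (df = 4 for the 3 vs 3 design), applied
to the normalized per-sample values without log transform; a `--log2`
switch plus pseudocount exists for sensitivity analysis. Calls require
p < 0.05 AND ratio strictly outside [1/2, 2]; a ratio of exactly 2.0 is
not differential. A zero mid-group mean gives an infinite-ratio sentinel
and the call is decided by significance alone. No multiple-testing
correction is applied to the calls; a Benjamini–Hochberg column is
emitted, clearly supplementary.

Degenerate inputs are defined rather than NaN: zero pooled variance with
equal means gives (t = 0, p = 1); with unequal means, the (±inf, 0) limit.

**Known limitation — compositional shift.** Total-count normalization is
compositional: when planted changes are direction-unbalanced, the
late-group totals shift (×≈1.5 under the default planting) and every null
miRNA's RPM shifts oppositely. Calibration of the test must therefore be
assessed on a direction-balanced or all-null simulation; under the
all-null design the empirical type-I rate is ≈0.05 at all dispersions
tried. Under the unbalanced design the up-regulated ratios are compressed
toward the fold gate (4.0 → ≈2.5 observed), which dominates the recovery
misses: measured recovery of planted 4-fold changes is ≈0.91 overall
(≈0.99 for down-, ≈0.83 for up-regulated) at dispersion 0.05. This is a
property of the normalization scheme itself, faithfully reproduced.

## Novel-candidate discovery

This stage is a transparent rule-based stand-in for probabilistic
miRDeep-class discovery, which is deliberately out of scope. Retained
rules: the ≥ 10 total-count filter (read as the sum over all six samples,
consistent with the `_x<count>` id dialect), the perfect genome-mapping
requirement, and a hairpin-plausibility check.

Folding is a weighted Nussinov dynamic program: maximize total pair
weight (GC 3, AU 2, GU 1 — a monotone stability proxy, not free energies;
the score is never labeled kcal/mol) over nested structures with loop
≥ 3 nt. Traceback is deterministic: at ties the pairing branch with the
smallest 5′ partner index wins. `fold_nussinov` agrees with an exhaustive
enumeration oracle on all tested sequences of length ≤ 14.

A precursor passes as a hairpin iff (a) its pairs form one contiguous
nesting chain — two side-by-side helices are tolerated only when the
unpaired gap between them is shorter than a minimal loop, in which case
they cannot host an independent stem-loop; (b) the mature lies entirely
5′ or 3′ of the terminal loop; (c) ≥ 60 % of mature bases are paired.
Shuffled precursors of identical composition fail this check in ≈100 % of
trials; designed stem-loops always pass.

The precursor window is −20/+50 nt around the top read of the locus, both
orientations tried, better assessment kept (hairpin status first, then
score). Loci are unannotated-read groups whose genome hits fall within
30 nt of each other; candidate ids are `seq-<rank>_x<count>` by descending
total count.

## Conservation, targets, pathway

The seed is the 1-based inclusive slice [2, 8] of the mature (length 7 by
default; configurable, e.g. 2–9 for eight-base comparisons). Conservation
requires exact seed equality (no G:U tolerance) plus overall identity
≥ 50 %. Identity counts matched nucleotides in a global alignment with
free gaps (match 1, mismatch 0, gap 0 — equivalently the longest common
subsequence), divided by the *longer* sequence length by default, the most
conservative of the admissible denominators; `shorter` and `alignment`
denominators are selectable because the 50 %-of-overall-sequence rule is
ambiguous on this point.

Target prediction is exact occurrence of the reverse-complemented seed in
the 3′UTR, every offset reported, overlaps not masked (distinct-gene
counting makes masking immaterial). The same seed rule is applied to known
miRNAs and novel candidates alike — duplex-energy scoring à la miRanda is
out of scope, and uniformity makes the seed-sharing theorem exact: miRNAs
with equal seeds always receive identical target-gene sets.
Pathway-relatedness is ≥ 2 distinct targeted primary genes; the bundled
demonstration gene set holds the TGF-β ligands (TGFB2/3), receptors
(TGFBR1/2), SMAD transducers (SMAD2/3/4) and SAR1A.

## Clusters

Single-linkage chaining per chromosome on end-to-start gaps
(`max(0, next.start − prev.end) ≤ 10 kb`); midpoint distance was rejected
because it depends on feature length. Strand is ignored. Singletons are
dropped. A cluster is direction-concordant when all members with DE calls
share one direction (up/down) and at most one member lacks a call.

## qPCR

ΔCt = Ct(target) − Ct(U6) per sample, replicates mean-averaged first;
group ΔCt is the mean over samples (mean-then-difference; difference-
then-mean is equivalent in expectation); ΔΔCt = ΔCt(late) − ΔCt(mid);
ratio = 2^−ΔΔCt with amplification efficiency fixed at 2 (no efficiency
correction). Ratio < 1.0 strictly is "low" expression. Replicate SDs are
propagated into supplementary uncertainty columns. Platform agreement is
Pearson on log₂ ratios (Spearman selectable), requiring ≥ 3 shared finite
positive pairs.

## Synthetic-study generator

The generator emulates the study design at desk scale: two groups of
three samples; ~100,000 expected genome-matched reads per sample (the
published 12–13 M scaled by ≈1/125); per-sample depth factors uniform in
±10 % so normalization is non-trivial; planted late/mid ratios 4.0 and
0.25 (straddling the 2.0-fold gate, predominantly downward as in the
study) against nulls at 1.0; overdispersed counts.

Noise model: negative binomial with variance μ + αμ². The spec of the
generator treats α = 0 as the *exact* limit — counts equal their rounded
means — so null plantings at α = 0 provably produce no calls; α > 0 draws
NB counts. The default α = 0.05 is mild overdispersion, typical of
biological replicates at this depth.

Structure planted in the genome (six chromosomes × 80 kb): 40 known
miRNA loci, the first twelve arranged as six two-member clusters 2–8 kb
apart on six chromosomes (co-regulated 4-fold down, mirroring cluster
co-expression), the rest kept > 10 kb from those pairs; eight stem-loop
precursors (22-nt arm, 8-nt loop, reverse-complement arm with ≤ 2
mismatches, either strand) screened at generation time with the
pipeline's own excision windows and hairpin checker, so recovery is a
construction guarantee; eight unscreened shuffled decoy loci; six embedded
80-nt ncRNA genes. Unalignable (~14 % of high-quality) and short (~14 %
of raw) noise reads are added so every cascade category is populated,
echoing the published cascade shape.

UTRs (default 24 genes × 200 nt) are screened to contain no seed
complement of any annotated miRNA, then exactly one site per planted
(miRNA, gene) pair is written at a recorded offset; the default planting
includes a heavily multi-targeted hairpin, two-gene cases in both
directions, and a single-gene boundary case that must *not* be called
pathway-related. Ct tables are generated consistent with the planted
ratios (U6 reference ≈ 18 cycles per sample, 3 replicates, 0.2-cycle
noise) for a validation panel alternating the most down- and most
up-regulated planted miRNAs.

Everything is deterministic given `rng_seed` (byte-identical files), and
every planted entity is recorded in `truth.json`.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: sequencing errors and adapter artifacts; miRNA
isoforms (isomiRs) and imperfect Drosha/Dicer processing offsets;
realistic genome repeat structure and multi-mapping ambiguity;
thermodynamically realistic folding landscapes; UTR site context
(accessibility, multiple sites, 3′-compensatory pairing); and library-
preparation biases. Results on this generator validate the *rules*, not
their biological adequacy.

## Problem sizes used

The default study (6 samples × ~67 collapsed reads over a 480-kb genome)
runs the full pipeline in well under a minute; DE calibration runs use
200 miRNAs × 6 samples over 5–10 seeds. These sizes give the calibration
estimates standard errors of ≈0.007 (type-I) and ≈0.01 (recovery) while
keeping the whole suite fast enough for routine local runs.
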