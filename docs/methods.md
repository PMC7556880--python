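# Methods

## Scope and data model

The package analyzes paired ChIP-seq peak sets for evidence of shared
regulatory territory and grammar. Its inputs are plain-text: BED peak
files, a FASTA genome with a chromosome-size table, a flat TSV gene
annotation (gene_id, chrom, strand, tss, start, end), DE tables
(gene_id, log2fc, p_adj), and dual-luciferase well tables (construct,
condition, replicate, firefly, renilla). All genomic coordinates are
0-based half-open; BED round-trips are exact on coordinates.

## Interval arithmetic

*Replicate merging.* Intervals from all replicates are union-merged into
maximal runs wherever they share at least one base (book-ended intervals
are not merged); a run is kept when intervals from at least `min_support`
(default 2) distinct replicates contributed. This encodes "peaks shared
between replicates" as a support threshold on merged spans; merging a
merged set with itself is idempotent.

*Intersection.* An A-peak overlaps when it shares at least `min_bp`
(default 1) bases with a single B-interval; each A-peak counts once no
matter how many B-peaks it touches, so the reported fraction is a fraction
of A-peaks. Enlarging B can only increase that fraction.

*Nearest genes.* Assignment is TSS-anchored: the upstream gene is the one
with the largest TSS at or left of the peak start, the downstream gene the
smallest TSS at or right of the peak end; distances are edge-to-TSS. A TSS
inside the peak fills both slots at distance 0. Ties break on
lexicographically smaller gene id, for determinism. TSS anchoring (rather
than whole gene bodies) reflects the promoter-oriented use of peak–gene
assignment here; the choice matters mostly for long genes.

## Co-occupancy enrichment

The observed statistic is the number of A-peaks touching the union of B.
The null relocates every A-peak uniformly at random on its own chromosome,
preserving its length, independently per permutation; this conditions on
chromosome occupancy and peak lengths but not on local sequence
composition (no GC- or accessibility-matched background — a known
limitation relative to matched-background methods). Two p-values are
reported: the empirical `(1 + #{null ≥ obs}) / (1 + n_perm)`, which cannot
fall below the Monte-Carlo floor, and the upper normal tail at
`z = (obs − mean) / sd` of the null counts, which can express significance
beyond the floor. Fold is `obs / null_mean`.

Gene-set proximity enrichment counts `|set ∩ proximal|`; the null draws
same-size sets from the universe without replacement. Because that null
intersection count is exactly hypergeometric, the implementation samples
it directly from the hypergeometric distribution, which is equivalent to
(and much faster than) materializing random sets.

## Motif model

PWMs are position-probability matrices, pseudocounted (default 1e-3),
renormalized, and converted to log-odds against a uniform background. A
window's score is min–max normalized by the matrix's achievable range, so
`norm_score ∈ [0, 1]` and the hit threshold (default 0.8, "80% of max") is
independent of matrix scale. Degenerate matrices with zero range define
`norm_score = 1.0` everywhere. Windows containing N are skipped; both
strands are scored at every offset.

The bundled matrix `gbm_synthetic.pwm` is a synthetic stand-in
constructed for this package (the canonical Gli matrix it emulates is not
distributable here). It has consensus GACCACCC with a highly constrained
5th position, chosen so that under the 0.8 threshold:

- GACCACCC scores exactly 1.0;
- GACC**T**CCC (the divergent variant) scores ≈ 0.77 — below threshold;
- single substitutions at less constrained positions score ≈ 0.87 — above
  threshold, so the cGBM class tolerates peripheral degeneracy.

With a sharp matrix of uniform per-column information this separation is
impossible: every single mismatch costs exactly 1/8 of the range, leaving
any 7/8 match above 0.8. Discriminating the fifth position therefore
requires concentrating information there, which is also what the real
binding data show.

Peak classes are exhaustive and mutually exclusive: `cGBM` when the peak
has ≥1 PWM hit at threshold; else `dGBM` when it contains the CCTCC core
on either strand (GGAGG on the forward strand counts); else `neither`.
Overlapping core matches are all reported.

## K-mer census

Every window position contributes one count to its canonical k-mer — the
lexicographic minimum of the word and its reverse complement — so
palindromic windows are counted once, not twice. For even k there are
`(4^k − 4^(k/2))/2 + 4^(k/2)` canonical k-mers (32,896 for k = 8). Ranking
is competition-style by descending count with lexicographic tie-break;
absent k-mers rank after all present ones. Two incidence framings are
exposed because both are in common use: per-window occurrence counts
(the census) and per-peak presence (`kmer_peak_fraction`).

## Spacing and orientation

For each peak, every (PWM hit, E-box) pair with non-overlapping footprints
and edge-to-edge distance ≤ 100 bp yields one pair; a peak may yield many,
and the count of peaks with ≥1 pair is reported separately since either
denominator may be wanted. The gap is signed (positive when the E-box
starts after the GBM ends) and orientation has two states (GBM+ / GBM−):
CANNTG is its own reverse complement, so the E-box carries no strand.
Overlapping footprints are excluded deliberately: the same bases cannot be
bound by both factors simultaneously, and the GBM and E-box vocabularies
share a CACC core, so permissive PWM hits routinely straddle E-box words;
counting those as "gap 0" manufactures a spurious spacing preference.

The composite-site scan defaults to a laxer PWM threshold (0.75 in the
pipeline) than classification, so that low-affinity divergent sites
contribute pairs.

Configuration testing draws `n_perm` multinomials of the observed total
over all (orientation × gap) cells with uniform probabilities and reports
per-cell upper-tail empirical p-values, BH-adjusted across cells. The
uniform null is a descriptive yardstick — real gap distributions have
soft edge effects from finite peak lengths — and the Monte-Carlo
resolution must exceed the number of cells divided by the FDR level
(n_perm ≳ 402/0.05 ≈ 8,000) for any cell to be flaggable after
adjustment.

## Expression integration

DE filtering applies `|log2fc| > log2(1.5)` and `p_adj < 0.05`, both
strict, retaining the sign. Set overlap uses the exact upper-tail
hypergeometric with the universe taken as genes tested in both tables.
Concordance reports (up_up, down_down, discordant) fractions over a shared
gene set. DE-gene counts per peak class deduplicate at the gene level: a
gene near several peaks of one class counts once for that class, though it
may count in several classes.

## Reporter synergy

Each well is normalized as firefly/renilla, then scaled by the mean
control ratio of its construct, fixing the control mean at 1. The additive
null on this scale is `E[AB] = A + B − 1`: each activator's effect is its
excess over the shared baseline, and the baseline is counted once. The
test statistic is formed on the raw-ratio scale,
`D = mean(AB) − mean(A) − mean(B) + mean(control)`, a linear combination
of four independent condition means; its variance is the sum of squared
standard errors with Welch–Satterthwaite degrees of freedom, and the
one-sided p tests `D > 0`. Dividing D by the control mean gives the
reported excess without changing the t statistic, making the test
invariant to rescaling a construct's firefly readings. A stratified
bootstrap (resampling replicates within conditions, default 10,000
resamples, seeded) is available as an alternative. Pairwise condition
comparisons are two-sided Welch tests with star tiers at strict
0.05/0.01/0.001 thresholds; no correction is applied across constructs by
default.

Under the additive synthetic generator (interaction 1, CV 0.1, six
replicates) the delta test's measured type-I error is ≈ 0.05, and under a
two-fold interaction its power exceeds 0.8 (both checked by simulation in
the test suite).

## Synthetic data

All generators are deterministic under `SimConfig.seed`; each stage draws
from a generator seeded by (seed, stage tag), so outputs are independent
of call order and byte-identical across runs.

Defaults encode the study conditions the pipeline was designed around:
a 10-Mb genome (two 5-Mb chromosomes, GC 0.42), 1000 peaks per factor of
mean length 300 bp, 62% of A-peaks planted to co-occur with B (the rest
placed avoiding B, so the planted fraction is realized exactly);
co-occupied peaks planted 85% dGBM / 9% cGBM / 6% neither and A-only
peaks carrying the canonical 8-mer at 16% incidence; 2000 genes; DE tables
with 400 calls each sharing 50% of DE genes, fully concordant in sign
(the observed sharing in the motivating data was essentially
co-directional); and reporter wells with effects A = B = 2, an interaction
multiplier of 2 for the divergent construct and 1 (additive) for the
canonical one, log-normal ratio noise at CV 0.1, six replicates.

Class planting is rejection-based: background sequence is drawn i.i.d.,
the class-defining 8-mer inserted, and the draw retried until the
classifier confirms the intended label. This is necessary because random
background of realistic length contains accidental CCTCC cores and
near-canonical PWM hits at appreciable rates (~0.5 expected per 300-bp
peak each), which would otherwise contaminate planted classes. When an
E-box is co-planted its footprint avoids the GBM insert.

What the generator does **not** emulate: read-level noise, peak-calling
uncertainty, sequence-composition biases (GC isochores, repeats), spatial
clustering of peaks or genes, correlated DE effect sizes, or
plate/batch structure in reporter data. Passing tests therefore
demonstrate that each stage recovers the structure it is designed to
measure under clean planted conditions — not that the method is robust to
every artifact of real data.

## Problem sizes and numerical choices

The test suite and acceptance script run the pipeline at the default
10-Mb / 1000-peak scale (seconds per run) and use 200–2000 Monte-Carlo
replicates for calibration checks; permutation counts are 1000 by default
and ~10,000–20,000 where BH adjustment across 402 grid cells demands the
finer floor. Empirical p-values always include the +1 correction.
Hypergeometric tails use exact summation (scipy); concordance fractions
sum to 1 to ≤1e-12. Ties are broken deterministically everywhere
(documented per function), and every stochastic routine takes an explicit
seed.
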