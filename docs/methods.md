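# Methods

## The two-sample window scan

The caller compares exactly two methylomes with no replicates, so the unit
of evidence is the CpG site: within a genomic window the per-site
methylation levels of sample 1 and sample 2 are treated as two groups of
paired-by-position observations and compared with a Wilcoxon test.

**Windows.** Fixed grid per chromosome: starts at multiples of the step
(default 50 bp), width = window size (default 100 bp), so each interior
position is covered by two windows. Trailing windows that would overrun
the chromosome end are not emitted. Only CpG-context sites with depth ≥
`min_depth` (default 10) in **both** samples enter a window; a window is
tested when it holds at least one such site.

**Test.** The default is the two-group rank-sum (Mann–Whitney) form of the
Wilcoxon test on the two level lists:

- combined size ≤ 12 → exact permutation null: midranks are computed once
  and the rank sum is enumerated over all C(n₁+n₂, n₁) group assignments;
  the two-sided *p* is the fraction of assignments whose rank-sum deviation
  from the null mean is at least the observed one (statistic ties count,
  with a 10⁻⁹ tolerance). All-tied input gives *p* = 1 by construction.
- larger → normal approximation with the standard tie correction and a
  0.5 continuity correction.

The rank-sum form was chosen over the paired signed-rank because the
exact two-sided signed-rank test cannot reach *p* < 0.01 with fewer than
8 non-zero paired differences, which would contradict a 5-CpG window
minimum; the rank-sum at 5 vs 5 attains 2/252 ≈ 0.0079. The signed-rank
variant (zero differences dropped) remains available via
`DMRParams(test="signed_rank")`.

**Gates.** A tested window is significant when *p* < `alpha` (default
0.01, strict), it has ≥ `min_cpgs` sites (default 5) and |mean₁ − mean₂| ≥
`min_delta` (default 0.10). The three gates are conjunctive: a window
failing any one is dropped. No multiple-testing correction is applied by
default; the raw-*p* threshold is the region-calling convention this
procedure follows, and users can apply FDR control downstream on the
emitted window stream.

**Merging.** Significant windows that overlap or abut (gap ≤ 0 bp) and
share the direction of the mean difference merge into one DMR. Merging is
stratified by direction, so an interleaved opposite-direction window does
not break a run (the two resulting DMRs may then overlap). DMR statistics:
*p* = min constituent window *p*; CpG count and means over the distinct
sites of the run. Direction is defined by sample 1 minus sample 2
("hyper" = sample 1 more methylated); a window with exactly zero
difference is labelled hyper, a tie-break that is unreachable under any
positive `min_delta`.

**Depth convention.** The "10×" coverage requirement is read as depth ≥ 10
in both samples; it is a parameter, not a constant.

## Coordinates and strand

Everything internal is 0-based half-open; the 1-based positions of
cytosine reports are shifted on read and restored on write, so BED
intersection logic never needs an off-by-one adjustment. Each reported
cytosine is kept as its own stranded site; symmetric CpG pairs are *not*
collapsed by default (the report encodes per-strand counts), but
`MethylomeSample.collapse_strands()` sums a −-strand CG onto its +-strand
partner for users who want pair-level counts. Non-CpG contexts (CHG/CHH)
are parsed and retained for QC distributions but excluded from DMR calling.

## Annotation

Seven categories with fixed priority **upstream > UTR5 > exonic >
intronic > UTR3 > downstream > intergenic**; promoter-first because
promoter DMRs are the biologically actionable class in this design. The
upstream flank is (TSS − 2000, TSS) on +, (TSS, TSS + 2000) on −,
half-open, clipped at the chromosome start; downstream is the mirrored
flank at the transcript end. UTRs are derived from the CDS bounds
(cds_start = cds_end marks a non-coding transcript, whose exons count as
exonic). Any ≥ 1 bp overlap qualifies, for every feature class. A DMR may
link many transcripts (all contributing features are reported as gene
links) but contributes exactly once to its single category. Overlap
queries run on interval trees and are tested against quadratic all-pairs
oracles.

## Validation statistics

The per-sample summary of a clone matrix is the mean over all observed
entries (missing entries reduce the per-column denominators). The
hypermethylation call is `sample_mean > threshold` with a strict
inequality; the threshold (default 0.5, the midpoint) is deliberately a
parameter because clinical studies rarely publish their exact call rule —
an alternative "exceeds the maximum control mean" rule can be expressed by
passing that maximum as the threshold.

Fisher's exact test uses the two-sided probability-mass definition: the
*p*-value sums hypergeometric probabilities of all tables with the
observed margins whose probability does not exceed the observed table's
(relative tolerance 10⁻⁷ for ties; the sum is returned as exactly 1 when
every table qualifies). For the reference cohort table
[[12, 3], [0, 5]] this gives *p* = C(8,3)/C(20,15) = 56/15504 ≈ 0.0036,
and the implementation is cross-checked in the tests against both a direct
enumeration oracle and an independent library routine.

The methylation–expression association is the Pearson correlation of
per-sample mean methylation against relative expression with the usual
two-sided *t*-test on n − 2 degrees of freedom. Expression enters as
already-normalised relative values; ΔΔCt arithmetic is upstream of this
package.

## The synthetic-data generator

The generator's job is to produce data on which the window scan's
mechanics (the 5-CpG filter, the 10× depth filter, the rank test's power
at a 0.4 effect) behave as they would on real RRBS input.

- **CpG placement**: a two-state renewal process alternates dense islands
  (mean spacing 12 bp, mean length 600 bp) with sparse background (mean
  spacing 120 bp, mean length 3000 bp), so windows realistically vary in
  CpG count around the 5-site filter. The implied genome-wide rate is
  ~0.02 CpG/bp.
- **Baseline methylation**: one draw per renewal segment from a
  two-component Beta mixture concentrated near 0 and near 1 (weights
  0.45/0.55, shapes (0.6, 12) mirrored), with per-site Beta jitter at
  concentration 50. Drawing the mixture per *segment* rather than per site
  gives the local correlation real methylomes have; without it, window
  heterogeneity drowns the rank test regardless of the planted effect.
  The resulting genome-wide level histogram puts >80 % of sites in the
  extreme deciles.
- **Depth**: negative binomial (mean 30, dispersion 5), independently per
  site and sample; zero-depth sites occur naturally and exercise the
  coverage filter. The dispersion is set for testability — the real
  study's depth skew is unknown.
- **Planted regions**: runs of 10 consecutive CpGs confined to spans
  ≤ 150 bp (so a region fits the window grid), ≥ 500 bp apart (so two
  truths cannot merge into one call). A naive "shift and clip" of a
  near-0/near-1 baseline would erase the effect at the extremes, so the
  baseline inside a region is affinely compressed into the feasible band
  and sample 1 shifted by exactly ±Δ — every planted site carries the full
  effect. Direction is Bernoulli(0.5) per region.
- **Counts**: methylated reads ~ Binomial(depth, true level). The null
  configuration (`n_dmrs=0`) yields two binomial resamplings of one
  methylome — the matched null for false-positive calibration and the
  replicate pair for the correlation QC.
- **Cohort**: 15 cases / 5 controls, 20 clones × 20 CpGs; an affected case
  (probability 0.8 ≈ 12/15) draws clones Bernoulli(0.7) per CpG, everyone
  else Bernoulli(0.1); expression = exp(1 − 3·mean + N(0, 0.3²)) — a
  monotone negative, noisy link chosen because the observed association is
  monotone without a published functional form.

**What passing tests show, and what they don't.** The simulator has
independent sites given the segment structure, no bisulfite-conversion
failure, no mapping bias, no correlated coverage along fragments and no
strand asymmetry. Recovery and calibration results on it validate the
*mechanics* of the caller (grid, filters, test, merge) — they do not
certify sensitivity or FDR on real RRBS libraries, where dispersion and
spatial structure differ.

## Numerical and scale choices

- Exact rank-sum enumeration is capped at a combined n of 12
  (C(12,6) = 924 assignments, cached per shape); the cap balances
  exactness where the filter boundary lives (5 vs 5) against scan speed.
- The default simulated genome is 2 × 1 Mb (~38 k CpGs, ~25 k tested
  windows, seconds per scan); this is the problem size used by the
  recovery and null-calibration checks and in `scripts/acceptance.py`.
  Monte-Carlo assertions use ≥ 10 000 windows and a 3-standard-error
  margin.
- Histogram bins are right-closed on [0, 1] with the first bin including
  0, so the fully-unmethylated and fully-methylated spikes land in the
  outer bins unambiguously.
- BED scores encode −10·log₁₀ *p* capped at 1000 (*p* = 0 maps to the
  cap); reading DMRs back from BED reconstructs *p* only to that integer
  precision, so in-memory objects are used within a pipeline run.
- Gzipped outputs are written with a zeroed header timestamp so identical
  runs are byte-identical.

## Known limitations

- Two samples only; no replicate designs, no beta-binomial dispersion
  modelling, no smoothing/HMM callers.
- The asymptotic rank-sum branch is approximate for heavily tied windows
  with >12 sites; such windows are common in CpG islands at high depth,
  where the approximation is conservative in practice.
- Annotation assigns one category per DMR; studies that double-count a
  DMR serving two genes will report different category totals.
- The clone-cohort hypermethylation call rule is a free parameter; results
  of the validation arm depend on it and it is always logged in outputs.
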