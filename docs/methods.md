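# Methods

This note records the models, rules, and numerical choices behind
`shattercall`, and what the simulation-based tests do and do not
establish about real data.

## Coordinates, formats, and canonical forms

All internal coordinates are 1-based inclusive; segment length is
`end − start + 1`. BEDPE input (0-based half-open) is converted at the
boundary, collapsing each breakend interval to its midpoint (rounded
down) — breakend confidence intervals are irrelevant to cluster
statistics, and the detectors are jitter-invariant by construction.
Chromosome labels are unified by stripping a `chr` prefix. Segment tables
accept FACETS column dialects (`loc.start`, `cnlr.median`, `tcn.em`, …)
through an alias map. Intrachromosomal junctions are normalized to
`pos1 < pos2` with strands travelling with their breakends; orientation
class is a pure function of the strand pair — (+,−) deletion-like, (−,+)
duplication-like, (+,+) head-to-head inversion, (−,−) tail-to-tail
inversion — with interchromosomal junctions their own class. A missing
segment cell fraction is treated as 1.0 (older tables omit it; the CCF
filter then never rejects) and every call carries a `ccf_assumed` flag
disclosing it.

## Oscillation runs

A run is a maximal stretch of segments alternating between two integer CN
states: directly adjacent members must differ, and up to `max_deviations`
(default 0) interior segments with CN outside the state pair may be
bridged — excluded from the count — without breaking the run. Bridging
deliberately does not constrain the two members flanking a deviation: a
high-level amplification spike sitting inside an oscillating region (the
ecDNA case) interrupts the spatial alternation, and requiring phase
continuity across it would split exactly the runs the bridge exists to
preserve. Candidate windows are enumerated per state pair in a linear
scan, pruned to maximal ones, and a non-overlapping subset is selected
greedily (longest first, leftmost on ties). The greedy selection is
direction-dependent in rare tie cascades; the maximal-window set and the
longest run — the quantities the callers consume — are reversal-invariant,
and the enumeration is property-tested against an O(n³) brute-force
oracle.

Track concordance requires, at every internal boundary, that the
log-ratio change has the same sign as the integer-CN change, and — where
the allelic log-odds and minor CN are present on both sides — that the
log-odds change matches the change in allelic imbalance
(total − 2·minor). Missing tracks are skipped and the checked set is
recorded; sign(0) is treated as a contradiction, which noiseless
synthetic inputs never trigger and which errs toward conservatism on flat
tracks.

## Panel caller

The panel rule is a deterministic fixation of what was originally a
manual plot-review procedure: a chromosome is suggestive of
chromothripsis if some window of ≥ `min_panel_run` (default 5)
consecutive oscillating segments has size ratio ≤ `uniformity_max_ratio`
(default 10), minimum cell fraction ≥ `min_segment_ccf` (default 0.5),
and concordant tracks. Qualification is a *window* property searched
inside maximal runs, because a long genuine run whose extreme segments
violate the size bound still contains the printed pattern. "Uniformly
sized" is unquantified in its source; a scale-free max/min length-ratio
bound of 10 is this package's formalization and is configurable. Segments
whose CN exceeds `amp_baseline_factor` (default 5) × the chromosome
baseline — the length-weighted modal CN — are bridged out before rule
evaluation, since ecDNA spikes sit inside chromothriptic regions and
would otherwise break the alternation. Verdicts are chromosome-level;
the qualifying window's coordinates are still reported, and negative
verdicts name the filters that eliminated the longest run.

## WGS caller

Candidate regions per chromosome are breakend-density clusters
(consecutive intrachromosomal breakends ≤ 10 Mb apart, extended to cover
member junctions) plus always the whole chromosome, reflecting how often
whole-chromosome involvement occurs; the chromosome reports its most
confident region. Counts entering the criteria: interleaved
intrachromosomal SVs = the largest connected component of the graph whose
edges join junctions with overlapping, non-nested spans (an isolated
junction is not a cluster, so the result is 0 or ≥ 2); interchromosomal
junctions count toward a region if either breakend lies inside it.

The three statistical tests are this package's declared forms, chosen so
that chromothriptic simulations pass and scattered-rearrangement controls
fail:

- **Fragment joins**: equal proportions of the four orientation classes,
  chi-square (3 df) for n ≥ 20, exact multinomial enumeration below
  (p-value = total probability of outcomes no more probable than
  observed). Passes when *not* rejected at `alpha_joins` = 0.05.
- **Breakpoint exponential**: one-sample KS against uniformity on the
  region, equivalent to exponential spacings. Breakends within 1 kb
  collapse to one locus first: the two ligated sides of one cut (and
  caller jitter) otherwise appear as coincident duplicates that violate
  the KS distinct-points assumption and mimic clustering. Passes when not
  rejected.
- **Chromosomal enrichment**: one-sided binomial tail
  P[X ≥ n_chrom], X ~ Bin(n_genome, chromosome share of genome length).
  Passes when *rejected* toward excess. Chromosome and genome lengths
  default to the observed extent of the input; for a single-chromosome
  input the share is 1 and the test degenerates to p = 1 (never
  enriched), which is why the criteria accept the exponential test as an
  alternative. The benchmark supplies GRCh37 lengths explicitly.

A test whose precondition is unmet (no junctions; fewer than five
breakpoint loci) carries a NaN p-value and fails in the pass direction.
The five criteria are evaluated verbatim with `DetectorParams`
thresholds; any of i–iv gives *positive*, v alone gives *low_density*,
none gives *negative*. The engine is tested against an independent
truth-table oracle on 10⁴ random input tuples.

## CCF estimation

The expected VAF formula is implemented exactly as printed, with `cn_mut`
the expected mutant copy count supplied by the caller; when multiplicity
is unknown a helper falls back to the local total CN. The estimate is the
argmax of the binomial likelihood over a CCF grid on [0, 1] with step
0.01, ties resolving to the smaller CCF; the posterior under a uniform
grid prior yields a central 95% interval (widened if needed to contain
the point, a numerical-edge guard). Estimates wanting CCF > 1 clamp to
the grid edge and are flagged `capped`. Clonality is classed at the 0.8
cutoff, inclusive.

## Simulator

`simulate_chromothripsis` draws K distinct breakpoints uniformly on the
region (default: whole chromosome 11, GRCh37 length), shatters one
homolog of a diploid chromosome, retains each of the K+1 fragments with
probability r, and re-ligates survivors in a uniformly random
permutation with independent ½-probability flips. Junction strands follow
from the ligated fragment ends (+ keeps the reference left of the
breakend), which makes orientation classes uniform over the four types —
the null the fragment-joins test checks. An ecDNA subset of retained
fragments instead forms a permuted, flipped ring emitting one junction
per ring fragment; ecDNA copy number A is a fixed plateau, not a
birth–death process, because the detectors only need the plateau.
CN bookkeeping on the diploid baseline: lost 1, retained 2, ecDNA
2 − 1 + A, early-duplicated oncogene fragment 2 − 1 + 2A. Defaults:
K = 300 and r = 0.5, chosen to match the observed regime of hundreds of
SVs per chromothriptic case; σ (log-ratio noise) = 0.1; purity 0.8;
A = 60, so the duplicated-oncogene fragment sits at 121 copies — the
>100-copy magnitude seen in extreme ecDNA amplifications.

Controls scatter m (default 8) simple events — deletions (CN 1) and
tandem duplications (CN 3), alternating, ≥ 5 Mb apart — and are resampled
if the profile ever shows ≥ 4 contiguous alternating segments.
`simulate_control_genome` allocates the m events across GRCh37
chromosomes in proportion to length, which is how scattered
rearrangements actually distribute; the single-chromosome variant
remains available as a deliberately adversarial stress case.

### Rendering

WGS rendering converts the CN step function to segments with
`log_ratio = log2((p·cn + 2(1 − p))/2) + N(0, σ)`, allelic log-odds from
the major/minor mixture (denominator floored at 0.01: full LOH in a pure
tumor has unbounded imbalance and a finite-coverage assay caps it),
minor CN 1 wherever the intact homolog survives, cell fraction 1.0, and
junction positions jittered by ≤ 100 bp.

Panel rendering observes integer CN only at target midpoints, merges
consecutive equal-CN targets (`n_marks` = targets merged), and tiles the
covered extent: segment boundaries fall midway between neighbouring
target groups, the way marker-based segmentation places them. Tiling is
load-bearing: if rendered spans were the raw target footprints
(10–100 kb) then any multi-target merge would span Mb and the
uniform-size filter would reject essentially every window, collapsing
panel sensitivity to zero as a rendering artifact rather than an assay
property. The default synthetic panel places 505 gene-footprint targets
(10–100 kb) genome-wide in proportion to chromosome length, a third of
them clustered within 1 Mb of an earlier target the way gene families
cluster; the real assay's interval map is proprietary, so this geometry
is synthetic and configurable.

## Benchmark

For each replicate seed the harness simulates one chromothriptic genome
and one scattered-control genome, renders both assay views, runs both
callers, and scores detection (WGS: positive or low-density; panel:
suggestive-positive) on any chromosome — a call anywhere on a control
genome is a false positive. Sensitivity and specificity carry exact
Clopper–Pearson 95% intervals. Everything is deterministic given the
base seed, and each run writes a manifest of the thresholds applied.

## Problem sizes

The test suite and acceptance script run end-to-end benchmarks at 200
replicate seeds with K = 30, r = 0.5, σ = 0.1 (about a minute on one
CPU), calibration at 1000 Monte-Carlo replicates per test, oracle
comparisons at 10⁴ criterion tuples and 10³ junction sets, and CCF
recovery at depth 500 with 200 replicates per CCF level. The acceptance
script additionally reports the dense-shattering regime (default K = 300)
at 100 replicates.

## What the simulations do and do not show

The generator reproduces the *structure* of chromothripsis — two-state
oscillation, interleaved random-orientation junctions, uniform
breakpoints, ecDNA plateaus — but not several properties of real tumors:
no subclonality (all somatic segments render at cell fraction 1.0, so
the CCF filter is only exercised by explicit fixtures), no segmentation
error (integer CN is rendered exactly; real FACETS fits mis-segment and
mis-call states), no purity/ploidy mis-estimation, no multi-chromosome
co-shattering, and no breakage–fusion–bridge or chromoplexy mimics.
Detector operating characteristics measured here are therefore
upper bounds with respect to those error sources.

At panel resolution, sparse sampling both *hides* true oscillation
(fragments falling between targets shorten rendered runs — the mechanism
by which panel sensitivity falls below WGS sensitivity) and can *alias*
separate same-type focal events into an apparent oscillation when the
intervening event is unsampled. With scattered-genome controls the
aliasing false-positive rate is below ~1%; the adversarial
single-chromosome control (eight alternating events on one chromosome)
pushes it to 2–9% depending on panel geometry. A reported 100%
panel specificity on a handful of paired cases is statistically
compatible with either figure (an exact 95% interval on 11/11 reaches
down to ~0.72).

## Known limitations

Only BEDPE SV input is supported (no VCF breakend parsing); one segment
table per sample (no reconciliation of alternative segmentation fits);
chromosome-level verdicts; the three statistical tests are declared
substitutes with matching pass semantics for forms that are not printed
anywhere authoritative; and the uniform-size bound, panel geometry, and
control event count are package choices surfaced in configuration rather
than measured properties of any real assay.
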