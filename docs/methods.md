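# Methods

This note records the statistical model, the conventions and thresholds,
the design choices made where the design was genuinely open, and what the
synthetic-data generator does and does not emulate. It states no result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Coordinates and sizes

Intervals are stored half-open, `length = end − start`, on the 24
canonical human chromosomes (hg19 lengths are compiled in;
`"8"`/`"chr8"` are both accepted and normalized to `"chr8"`). Printed
1-based inclusive region strings are stored with their numbers unchanged:
the ±1 bp difference between conventions is far below kb resolution, and
0-based half-open BED input maps to the same internal representation
without shifting, so both encodings of one interval compare equal.

Event sizes in kb are `round((end − start)/1000)` with ties away from
zero. Round-to-nearest (rather than truncation) is forced by the
reference sizes the worked example must reproduce (e.g. a 1,396,925 bp
event is 1,397 kb, not 1,396). One coordinate pair in the example set
(chr1:146498360-147399145, 900,785 bp) is carried at its computed 901 kb.

## Rare-event filtering

Defaults, applied in order with a per-stage audit count:

| gate | rule | boundary |
|---|---|---|
| size | ≥ 100 kb | 100 kb events are in-analysis (the smallest bin is labelled 100k–400k) |
| probes | > 25 probes | strict, per the calling criterion; events without a probe count pass (simulated calls have none) |
| chromosome | autosomes only | sex-chromosome burden is out of scope (case cohorts are typically sex-imbalanced) |
| frequency | < 1% in **every** reference | strict `<`; matching requires strictly > 50% of the query event's length covered by a same-dosage reference event |

Open choices, resolved as follows and exposed as configuration:

* **Overlap direction.** "50% overlap of length" is computed on the
  cohort CNV as query — the natural reading of "is this event common?"
  and the permissive (conservative-for-rarity) choice. A `reciprocal`
  flag additionally requires > 50% of the reference event's length
  (off by default).
* **Multiple references.** Platform-control and DGV-style references are
  combined by a rare-in-all rule, mimicking sequential filtering against
  each source. Per-source thresholds are not separately configurable.
* **Reference encodings.** Carrier encoding (one row per carrier event;
  frequency = distinct matching carriers / N) and frequency encoding
  (per-record frequencies; an event takes the max over matching records)
  are both supported. Events matching nothing have frequency 0, not
  missing.

Reference lookups go through an interval tree with records grouped by
distinct interval (many carriers of one common CNV share a tree node);
the tests hold the indexed path equal to a brute-force all-pairs scan.

## ROI annotation and clinical tiers

* **Recurrent loci**: hit when ≥ 80% of the CNV's length is covered by
  the locus and the dosage corresponds (loss↔deletion, gain↔duplication,
  or a `both` locus). The threshold is applied as ≥ 0.8; the direction is
  configurable (`cnv` | `locus` | `either`, default `cnv`). The same rule
  serves both the burden category and clinical tiering.
* **Genes**: a loss counts on any overlap (`loss_intersect`). A gain
  counts only when a breakpoint lies strictly inside the open genic span
  (`gain_breakpoint`): a breakpoint exactly at a gene boundary does not
  interrupt the gene body, a gain entirely inside a gene still partially
  duplicates it and counts, and a gain cleanly spanning the gene does
  not.
* **Tiers**, in priority order (an event is counted once, under its
  highest basis): curated pathogenic region (≥ 80% coverage) →
  recurrent locus → high-risk-gene loss, all `pathogenic`; high-risk-gene
  gain → `uncertain`; otherwise untiered. Diagnostic yield = 100 × distinct
  individuals with ≥ 1 pathogenic event / individuals tested, to one
  decimal.

The packaged locus and pathogenic-region fixtures are hg19 spans derived
from the worked example's own CNV coordinates (unions where a region
recurs), and gene spans are approximate hg19 coordinates; both are
stand-ins adequate for the worked example, and real analyses should
supply curated BED files.

## Severity

CARS scores map to severity with 30–37 mild/moderate and 37–60 severe.
The two ranges share the boundary 37; it is assigned to **mild** — a
severity claim requires a score strictly above the shared boundary — and
the cut is configurable (`mild_max`). Scores outside [30, 60] are
rejected. Manifest severity labels must agree with a supplied CARS score.

## Burden table and permutation test

Strata: per dosage, the four half-open, lower-inclusive size bins
(100 ≤ s < 400, 400 ≤ s < 1000, 1000 ≤ s < 3000, s ≥ 3000 kb) plus an
`all` row, and one all-sizes row per ROI category (locus hit / high-risk
gene hit / LoF-intolerant gene hit). Within each dosage the bin counts
sum to `all` by construction. Categories are emitted only when their ROI
inputs were supplied; rate ratios print `inf` when only the numerator
group has events and `NA` when neither does.

The severity contrast uses case samples only; controls never enter its
permutations.

Permutation design:

* **Statistic**: difference of group means of a per-sample burden value
  (event count by default; total kb and carrier indicator are the other
  two measures). A difference rather than a ratio: the ratio is undefined
  under permutations with empty-denominator draws, and for fixed group
  sizes the difference ranks permutations identically to the group-1 sum,
  which is how it is computed (exact tie handling for integer statistics,
  ties counting toward the null).
* **Estimator**: one-sided add-one, p = (1 + #{T_b ≥ T_obs})/(B + 1),
  guaranteeing validity and p ≥ 1/(B+1). B defaults to 100,000.
* **Reproducibility**: each table row uses an RNG substream derived from
  (seed, contrast index, stratum index), so p-values are bit-reproducible
  and independent of row evaluation order; relabelling sample ids does
  not change them.
* **Multiple testing**: none — p-values are nominal, flagged in the
  output header.

The tests check this machinery against an exhaustive enumeration of all
C(8,4) = 70 label assignments on an 8-sample cohort, calibrate the
type-I error on 500 null replicates (two groups of 200 with Poisson(0.3)
per-sample counts, B = 999; rejection rate at α = 0.05 required inside
[0.03, 0.07]), and confirm power under a doubled group-1 rate.

## Synthetic cohorts

`simulate_cohort` emulates the structure the analysis assumes, with
defaults set to the example study's conditions: 197 controls, 177 mild
and 224 severe cases; control rates 0.259 losses and 0.893 gains per
individual; case multipliers 1.43 (loss) and 0.76 (gain); severe/mild
gain multiplier 1.43, losses severity-independent. The mild gain rate is
derived so the cohort-wide case rate honours the case multiplier while
severe = mild × 1.43.

* **Counts**: Poisson per individual per dosage; a negative-binomial
  option (`dispersion`) exists for overdispersion robustness checks.
* **Sizes**: bin sampled from the empirical bin mixture of the example
  cohort (losses ~85% in 100–400 kb), then log-uniform within the bin;
  the open-ended top bin is capped at 10 Mb.
* **Placement**: chromosome ∝ autosome length, start uniform, resampled
  if the event would cross the chromosome end; with probability
  `roi_hit_prob` (default 0.05) the event is instead anchored on a random
  ROI fixture.
* **Common pool**: 20 CNVs carried independently by each individual and
  by Binomial(2,691, 0.05) reference carriers, so pool events sit near 5%
  reference frequency and the 1% filter must remove them; the reference
  adds 200 private events near frequency 1/2,691. CARS scores are
  back-filled uniformly from the severity-matching range so labels
  round-trip.

What the generator does **not** emulate: CNV hotspot geography and
recurrence mechanisms, linkage between events in one genome, probe-level
intensity noise (probe counts are absent by design), sex chromosomes,
and genome-build mismatches between cohort and reference. Passing tests
therefore validate the statistical machinery and the filtering rules,
not array QC or call accuracy on real intensity data.

`cohort_from_margins` is the deterministic counterpart: it reconstructs
a cohort exactly matching published per-stratum counts, carving
ROI-category events out of the 100–400 kb bin and placing them on
dedicated synthetic ROI intervals on otherwise unused chromosomes (so
categories are exact and mutually disjoint), tiling the remaining events
at bin-representative sizes, and assigning events round-robin to
samples. Rates and rate ratios computed from it are exact consequences
of the margins; its permutation p-values are estimates under one
specific (maximally dispersed) allocation of events to carriers, which
marginal counts do not determine.

## Problem sizes

The shipped experiments use 200 replicate cohorts for parameter recovery
(mean estimated loss rate ratio within 5% of the 1.43 truth; the mean of
200 replicates has a relative standard error near 1%, and the small
upward bias of a ratio estimator at ~50 denominator events is ~2%), 500
replicates for type-I calibration at B = 999, and B = 999 permutations in
the acceptance script's burden table (the reported quantities there are
counts and ratios, which do not depend on B).

## Known limitations

* Clinical tiering implements three rule-based categories, not a full
  evidence-based CNV interpretation framework.
* No covariate adjustment (sex, platform batch) in the burden model;
  contrasts are marginal.
* No liftover: all inputs must share one genome build.
* The per-individual "size" burden measure totals event kb per sample;
  mean event size is reported only descriptively.
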