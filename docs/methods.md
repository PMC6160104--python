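# Methods

## Data model and coordinate conventions

All genomic coordinates are held 1-based inclusive, the dialect PennCNV
call tables print. BED export converts to 0-based half-open and a sidecar
TSV keeps the lossless 1-based form. CNVR length is defined as
`end − start`: published CNVR tables in this literature satisfy that
identity exactly (e.g. a region printed as 51,115,979–51,370,688 with
length 254,709), so the convention was adopted package-wide even though it
is one less than the inclusive bp count. Missing signal values stay NaN and
are excluded pairwise from every variance; nothing is imputed.

Total copy number (TCN) uses the standard array coding: 0 and 1 are
two-copy and one-copy deletions, 2 is neutral, 3 and 4 are single and
double duplications. A CNV call is non-neutral by definition, so TCN 2 is
rejected at parse time.

## Sample QC

Four per-sample metrics are computed from the LRR track:

* **call rate** — fraction of non-missing probes; cutoff ≥ 0.98.
* **DLRS** — SD (n−1 denominator) of first differences of LRR between
  adjacent probes, computed within chromosomes and pooled, divided by √2.
  Differences of i.i.d. noise have variance 2σ², so the √2 restores the
  probe-level σ while cancelling genuine long-range structure (real CNVs
  contribute only two boundary differences each). A MAD-based variant
  (×1.4826) is available behind `dlrs_robust` for heavy-tailed tracks.
* **wave factor** — Pearson correlation of LRR with probe GC fraction, the
  usual summary of long-range GC-correlated waviness. Cutoff |r| ≤ 0.10.
* **LRR SD** — plain SD of the track; kept samples need SD < 0.30
  (exclusive, matching the convention that 0.30 itself fails).

No published cutoff exists for DLRS outliers, so the default is a cohort
rule — DLRS > mean + 3 SD of the cohort distribution — with an explicit
fixed cutoff available (`dlrs_cutoff`), which also makes refiltering a kept
cohort a no-op. The cascade order is call rate → DLRS → wave → LRR SD and
each excluded sample is labeled with the first rule it fails. BAF-drift
style metrics from the caller are treated as pass-through annotations;
CNV calling itself is out of scope and calls are an input.

Note a real consequence visible in the demo cohort: carriers of a large
homozygous deletion legitimately fail the LRR SD rule, because a −3.5 LRR
excursion over hundreds of kb inflates the whole-track SD. That mirrors how
this filter behaves on real arrays and is not corrected for.

## CNVR construction

Regions are the connected components of the ≥ 1 bp overlap graph over
calls, per chromosome — transitive closure, so a chain A–B–C merges even if
A and C are disjoint. On 1-based inclusive intervals, book-ended intervals
sharing exactly one bp genuinely overlap and therefore merge; intervals
that touch with zero shared bp (start = end + 1) do not. The region span is
the union extent of its members (mergeBed semantics). Implementation is a
sorted sweep, O(n log n); the test suite checks it against a quadratic
union-find oracle on 1,000 random intervals.

State is gain if every member call is a duplication, loss if every member
is a deletion, complex otherwise. Length classes use half-open boundaries
[1, 10) / [10, 100) / [100, ∞) kb; sub-kb regions are kept in the first
class but flagged rather than silently dropped. Recurrence classes count
distinct carrier individuals (a sample contributing several adjacent calls
counts once): singleton 1, rare 2–4, moderately recurring 5–15, recurring
≥ 16. Genome coverage is total region bp over total autosome bp from the
supplied chromosome-size table.

## Cross-population comparison

The counting unit is focal-set regions: a region of breed A is "shared with
B" when ≥ 1 region of B overlaps it by ≥ 1 bp. Counts are therefore
directional and both directions are always reported, along with the Venn
partition (each focal region labeled by the subset of other breeds it
overlaps) and total shared bp per ordered pair. Shared-length summaries are
totals, not per-region means.

## CNV matrices

`presence` codes a cell 1 iff the sample has ≥ 1 call overlapping the
region; `copy_number` codes the overlapping call's TCN with 2 where there
is none, so `presence == (copy_number != 2)` cell-wise by construction.
When several calls of one sample overlap one region (complex regions), the
call covering the most bp of the region wins; ties go to the more extreme
state (|TCN − 2|), and a deletion wins an exact tie. The rule is arbitrary
but deterministic and favors the call with most evidence in the region.

The recurrence filter keeps regions with ≥ k carriers (k = 5 by default),
either overall or within every population; for the V_ST scan the filter is
applied per pair — a region enters the A-vs-B scan when it has ≥ k carriers
in A and ≥ k in B.

## Structure summaries

PCA centers columns (no scaling) and decomposes by SVD;
variance_explained_i = λ_i/Σλ. A fully constant matrix is returned flagged
degenerate with zero variance fractions rather than raising mid-pipeline.
Whether published CNV PCAs operate on the raw matrix or on a distance
matrix is usually ambiguous; the raw-matrix PCA is the default here, and
distances (Euclidean default, Jaccard on carrier indicators) are exposed
separately for the tree.

UPGMA is implemented directly: average linkage with merge height equal to
half the mean inter-cluster distance, so cophenetic distances are exactly
twice node heights and ultrametric inputs are reproduced verbatim (verified
against scipy's average linkage in tests). Ties are broken by the
lexicographically smallest pair of sorted member-label tuples, pinning the
topology under any input order. Bootstrap support resamples CNVR columns
with replacement; BP of an internal node is the fraction of replicate trees
containing the identical leaf clade. Columns are canonicalized by region id
before drawing so column permutation cannot shift the replicate stream.
Ordinary BP only — multiscale-bootstrap AU p-values are deliberately out of
scope.

## V_ST

Per SNP probe, V_ST = (V_T − V_S)/V_T with V_T the pooled two-population
LRR variance and V_S the size-weighted mean within-population variance.
Population (1/n) variances are used throughout: with them, identical
populations give exactly V_T = V_S and hence 0, and internally constant,
distinct populations give 1. An unbiased (n−1) mode exists but the
invariants are only exact in the default. Raw values can dip slightly
negative under sampling noise; they are clamped to [0, 1] with the raw
value retained in the output. Per-region V_ST is the arithmetic mean over
probes positioned in the closed interval [start, end]; probes where either
population has < 2 non-missing values are skipped and counted.

Two thresholding rules are computed per population pair across the scanned
regions: mean + 2 SD (strict >, the default for tabulated reporting) and
the 95th percentile of mean V_ST (values strictly above the quantile). Both
flags are always reported; with < 20 scanned regions a warning marks the
quantile as unstable.

## Synthetic cohorts

The generator emulates what the analysis consumes, not the array chemistry:
equally spaced probes with Uniform(0.3, 0.7) GC, per-probe LRR =
state mean + wave·(gc − mean gc) + N(0, σ), default state means
{0: −3.5, 1: −0.66, 2: 0, 3: +0.40, 4: +0.68} (conventional array signal
levels), default σ = 0.20. Each sample carries each CNV template
independently with its population's carrier frequency; truth calls carry
exact template bounds. Per-sample RNG substreams are derived from
(seed, sample index), so growing a cohort never perturbs existing samples.
BAF, when enabled, is a state-dependent mixture over canonical allele
ratios with 0.03 jitter — enough to exercise I/O, not allelic statistics.

What the generator does **not** model: linkage disequilibrium, probe-density
variation and clustering artifacts, caller boundary error (truth calls have
exact template bounds), batch effects beyond the single GC wave term, and
sex chromosomes. Passing tests therefore demonstrate the correctness of the
statistics and plumbing under a clean signal model, not robustness to every
failure mode of real arrays.

## Problem sizes and numerical choices

The test suite and the acceptance script run cohorts of 20–100 samples with
200–900 probes, 1–24 CNV templates, 200 bootstrap replicates, and 10,000
probes for noise-recovery checks — sizes at which the statistical
benchmarks (σ recovery within 5 %, strict monotonicity of mean V_ST across
frequency gaps 0/0.3/0.6/0.9, breed-split BP ≥ 0.95 at gap 0.8) are stable
across seeds while a full run stays in seconds. Quantiles use numpy's
default (linear interpolation); SDs are n−1 except the population variances
inside V_ST; all RNG is `numpy.random.default_rng` seeded explicitly.

## Known limitations

* The exclusion cascade reports only the first failing rule per sample.
* `venn_partition` supports at most three populations.
* Regions are compared by simple ≥ 1 bp overlap; reciprocal-overlap
  CNVR definitions and assembly liftover are out of scope.
* The V_ST scan operates on merged CNVRs; analyses defined on per-breed
  call sets must merge per breed first and pass those regions explicitly.
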