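# Methods

This note documents the statistical model, the tunable parameters, the
numerical conventions, and the design choices made where the method left
room — together with what the synthetic test bench does and does not
establish about real array data.

## Probe-level model

The input is a probes × samples matrix of normalized intensities (unitless;
typically quantile-normalized log-scale fluorescence), a negative/positive
label per sample, and per-probe metadata (protein, 1-based start position,
tiling step).  Every statistic is computed independently per positive
sample; negatives serve only as the reference group.

**Global test.**  The null is a normal distribution whose mean μ and SD σ
are the moments of *all* matrix cells.  The test statistic is
z = (x − μ)/σ − δ with `global_sd_shift` δ ≥ 0 (default 6), and
p_g = Φ̄(z).  The shift expresses "how many pooled SDs above the average
signal must binding be before it is interesting"; δ = 3, 6, 10 define the
inclusive, moderate and restrictive regimes.  Two caveats follow directly
from the definition and matter when interpreting results: (i) a probe whose
true effect is close to δ·σ has p_g near 0.5, i.e. the global test has no
power at its own threshold; (ii) σ is estimated from all cells, so in data
where signal occupies a non-negligible fraction of the matrix, σ is
inflated and the test becomes more conservative.

**Differential test.**  Each positive observation is treated as a sample of
size one sharing the probe's negative-group SD:
t = (x − x̄_neg − Δ)/(s_neg·√(1 + 1/n_neg)), df = n_neg − 1, one-sided.
`diff_abs_shift` Δ ≥ 0 (default 1) is an absolute shift on the normalized
scale — for log2 data, Δ = 1 demands more than a 2-fold difference.  The SD
is estimated from negatives only: each positive sample is tested singly, so
including positives would mix prospective signal into the null.  Per-probe
SDs are floored at the 1st percentile of all per-probe negative SDs (with a
fallback to the smallest positive SD when that percentile is 0) so that
constant-negative probes cannot yield infinite statistics; floored probes
are logged.  With few negatives the t reference has few degrees of freedom
(df = 4 at n_neg = 5), which is the dominant power constraint of the whole
pipeline — see "Known limitations".

**Combination and FDR.**  When both tests are enabled the combined p-value
is Wilkinson's max of two, p_c = max(p_g, p_d)², the Beta(2, 1) tail of the
larger of two uniform p-values; with one test enabled that layer passes
through.  Benjamini–Hochberg runs within each positive-sample column over
all probes (each sample's calls are separate decisions; a matrix-wide
option exists but is off by default).  Calls use strict `p_adj < cutoff`.
All p-values are clipped to [1e-300, 1] before any log/tan transform.

**One-hit filter.**  A called probe/sample pair survives if the previous or
next probe of the same protein (positional rank order, so mixed 2/4-aa
tilings behave consistently) is called in the same sample, or if the probe
is called in any other positive sample.  Removed entries become uncalled
and their adjusted p is set to 1.  The filter runs once, at probe level
only: "adjacent" has no meaning for proteins, and a single pass is already
a fixed point for this rule on every fixture we constructed (a same-sample
supporter is itself supported by the call it supports, and a cross-sample
supporter cannot have been removed).

## Epitope segmentation

Candidate regions are maximal runs of rank-adjacent probes called in *any*
positive sample.  Three methods turn calls into epitopes:

* **unique** — per-sample runs, deduplicated by id; overlapping blocks from
  different samples are all kept.
* **hclust** — contiguity-constrained complete-linkage clustering of each
  candidate region.  The linkage distance between adjacent blocks is the
  diameter (max pairwise base distance) of their union — equivalently,
  complete linkage on the interval-max embedded distance matrix, which is
  what forces every cluster to stay a contiguous block.  Only adjacent
  blocks are ever merged (ties merge the leftmost pair), so contiguity is
  guaranteed unconditionally rather than depending on tie-breaking inside a
  generic linkage routine.  Every tree cut k = 2..m is scored by the mean
  silhouette width on the *base* distances; the best k wins, ties toward
  larger k; if no cut scores above 0, or the region has fewer than 3
  probes, it stays whole.
* **skater** — the region is a path graph with an edge between rank-adjacent
  probes; removing edges leaves contiguous components.  For regions of up
  to 12 probes every cut subset is scored and the silhouette-optimal one
  is kept (ties prefer more components, then leftmost cut positions); this
  makes the method an exact optimizer of the silhouette objective at the
  scale where exhaustive search is cheap (≤ 2048 partitions).  Larger
  regions fall back to greedy stepwise removal: per round, the best single
  additional cut is kept while the score does not decrease.  The no-split
  rule is the same as for hclust.

Two base distances are available: `binary_hamming`, the number of
per-sample call disagreements between two probes, and `zscore_euclidean`,
the Euclidean distance between one-sided z-score vectors z = Φ⁻¹(1 − p)
with p clipped to [1e-16, 1 − 1e-16] (bounding |z| ≈ 8.2, so distances are
always finite).  Silhouette uses the standard conventions (singletons score
0; a partition of all singletons scores 0) and is always evaluated on the
base matrix — the interval-max embedding exists only to enforce contiguity
in the tree.  Segmentation contains no randomness.

Model-selection caveat: cutting a hierarchical tree offers only m − 1
nested partitions, and the silhouette-optimal contiguous partition is
outside that set for roughly a quarter of random small call patterns.  The
hclust method is therefore a fast heuristic for the silhouette objective,
while skater (in its exact range) is the reference optimizer.

## Epitope and protein p-values

Raw (not adjusted) p-values feed every roll-up; BH is applied once per
level.  Combining adjusted p-values would correct twice.

The combiners and their conventions, for k inputs:

| method | statistic | null / formula |
|---|---|---|
| wmax_r | r-th largest p | Beta(k−r+1, r) CDF; k < r → exactly 1 |
| wmin_r | r-th smallest p | Beta(r, k−r+1) CDF; order drops iteratively; k = 1 → that p |
| fisher | −2Σln p | χ² with 2k df |
| hmp | k/Σ(1/p) | Landau tail of the inverse mean (below) |
| cct | mean tan((½−p)π) | standard Cauchy tail |
| min_bonf | min p | min(1, k·min p) |

wmax_r ("most member probes must be significant") is the epitope default
(wmax2, tolerating one weak probe); wmin1/Tippett and min_bonf ("at least
one significant epitope") are the protein defaults.  Every combiner is
order-invariant and maps into [0, 1].

**Harmonic-mean details.**  The mean of k inverse uniform p-values,
T = (Σ 1/p_i)/k, has an α = 1 heavy tail; its asymptotically exact null is
a Landau distribution with location ln k + 1 − γ + ln(π/2) and scale π/2
(γ the Euler–Mascheroni constant), evaluated with `scipy.stats.landau`.
Since T = 1 is the null's minimum (every p at 1) where the true tail is
exactly 1 but the asymptotic approximation is not, T ≤ 1 returns 1.  The
bare harmonic-mean statistic is exposed separately
(`harmonic_mean_statistic`) for users who want the uncorrected quantity.

Proteins without any candidate epitope are omitted from the output rather
than padded at p = 1, keeping table sizes proportional to signal.  The same
adjusted-p cutoff is shared by the probe, epitope and protein levels by
default; each is overridable.

## Synthetic data generator

The generator emulates the *shape* of processed array data: proteins of
60–110 aa tiled by 16-mers at a configurable step (default 2 aa), i.i.d.
normal background per cell (default N(0, 1) on the normalized scale),
contiguous planted high-binding intervals present only in a carrier subset
of positive samples (default: 2 intervals of 20 aa, effect 6 background
SDs, 3 carriers of 6 positives, 5 negatives), and technical replicates
made by adding independent noise.  Probes overlapping a planted interval
by at least one residue receive the full additive effect; an optional
triangular taper scales the effect by overlap fraction for
boundary-sharpness studies, and an optional AR(1) mode (off by default)
correlates background along each protein as in smoothed data.  Generation
is bit-reproducible under a fixed seed.

What it deliberately does not model: scanner/spatial artifacts, quantile
normalization itself, probe-sequence-dependent affinity, replicate array
spots (ingest collapses duplicates by mean), heavy-tailed or sample-specific
background, and correlation between positive samples beyond shared planted
intervals.  Passing the test bench therefore demonstrates the correctness
of the statistics and the segmentation on idealized inputs, not robustness
to real-array noise structure.

A power fact worth stating explicitly because the default conditions sit
right on top of it: with 5 negatives the differential test has df = 4, and
a planted effect of 6 background SDs yields per-probe call power of only
~0.5 after BH at cutoff 0.05 — and the global test at SD shift 6 has
p ≈ 0.5 on 6-SD probes by construction.  Under these defaults called runs
fragment and exact boundary recovery fails; effects of ~10–12 SDs (or more
negative controls) are needed before planted boundaries are recovered
reliably, which is what the recovery tests use.  Separately, because any
positive-silhouette split is taken, a single dropped probe call in one
carrier can split an otherwise uniform region; this over-segmentation is
inherent to the selection rule and visible at any effect size.

## Test-bench problem sizes

The packaged studies use ~200-probe matrices (6 proteins, 11 samples),
10⁵ replicates for combiner calibration, 10⁶ draws for the Monte-Carlo
order-statistic oracle, 200 random regions of ≤ 8 probes for the
segmentation-oracle comparison, and 100 generator seeds for recovery
studies — sizes chosen so the whole suite runs in a few minutes on one CPU
while keeping Monte-Carlo standard errors well below the tested margins.

## Known limitations

* The global test's pooled moments include signal cells; on small or
  signal-dense matrices this inflates σ and depresses power (real
  proteome-scale arrays are signal-sparse, where the effect is negligible).
* hclust model selection is restricted to nested tree cuts (see above).
* The greedy skater fallback beyond 12-probe regions is not guaranteed
  optimal; it can under-cut when no single cut has positive silhouette but
  a pair does.
* The hmp Landau tail is asymptotic in k; at k = 2 it is mildly
  conservative near α = 0.05 and the T ≤ 1 boundary convention introduces
  a discontinuity at the no-signal end of its range.
* The one-hit filter is defined at probe level only; epitope- and
  protein-level outputs receive thresholding and K-of-N reporting instead.
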