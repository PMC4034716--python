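# Methods

## Problem and approach

Given a query multivariate time series (MTS) — `m` time points on `n`
channels, e.g. multichannel EEG, data-glove sensors, or force/torque
recordings — the package retrieves the `k` most similar items from a labeled
collection (whole matching) or the `k` most similar windows of one long
series (subsequence matching). It is a *dimension-combination* method: the
multivariate problem is decomposed into univariate searches, one per
dimension, whose results are then aggregated by rank-and-gap voting.

The pipeline:

1. **Per-item PCA.** Each item is mean-centered per channel and
   eigendecomposed on its sample covariance matrix; the item is represented
   by its principal-component (PC) series `D = X_c · C`. A single retained
   count `p` is chosen so the first `p` components keep strictly more than a
   threshold (default 90%) of total variance in *every* item.
2. **Univariate kNN per dimension.** For each retained dimension, the `k'`
   nearest univariate sequences are found under band-constrained DTW
   (`k' ≥ k`, default `2k`).
3. **Truncation.** Per-dimension hits are grouped by time overlap
   (connected components of "overlap > l/2" on the same source), groups
   covering fewer than half the dimensions are discarded, each surviving
   group is aligned to one candidate window at the rounded mean start, and
   candidates are re-ranked per dimension.
4. **Weighted BORDA ranking.** Each candidate's score in dimension `j` is
   `w_j (1 + k'(1 − d_i/d_k'))`, where `d_i` is its distance, `d_k'` the
   worst-ranked candidate distance in that dimension, and `w_j` an
   eigenvalue-derived dimension weight with `Σ w_j = 1`. Scores are summed
   over dimensions; the top `k` candidates win. The positional baseline
   ("borda") replaces the gap-sensitive score with classical BORDA points.

The weighted score's anchors: the query itself (distance 0) would score
`w_j (k' + 1)` and the worst-ranked neighbor scores `w_j`. The score is
strictly decreasing in `d_i` and depends on distances only through
`d_i / d_k'`, so rescaling any single dimension leaves its scores unchanged.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `pca_threshold` | 0.9 | variance fraction the retained components must strictly exceed in every item (the 90% figure is conventional, hence configurable) |
| `strategy` | `mean` | aggregation `f` over each dimension's eigenvalues across items (`min`/`mean`/`max`) in `w_i = f(V_i)/Σ_j f(V_j)` |
| `normalize` | true | divide each item's eigenvalue vector by its own total before aggregating, making items of different overall scale comparable; irrelevant for subsequence matching (single eigenvalue vector) |
| `band_fraction` | 0.05 | Sakoe–Chiba band as a fraction of the longer series length |
| `kprime` | `2k` | per-dimension univariate neighbors fetched before truncation |
| `exclusion_zone` | `l/2` | maximum tolerated overlap (points) between returned subsequence windows, preventing `k'` shifted duplicates of one event |
| `recompute_all` | false | re-measure every dimension of an aligned candidate instead of reusing stored distances |

## Numerical and procedural conventions

* **Band geometry.** Band width `w = max(1, ceil(band_fraction · max_len))`
  permits cells with `|i − j| ≤ w − 1`: a width-1 band is the diagonal only,
  so on equal-length series it reproduces the Euclidean distance exactly.
  Feasibility therefore requires `|len(a) − len(b)| ≤ w − 1`. Local cost is
  the squared difference; the reported distance is the square root of the
  accumulated cost (symmetric steps, no slope weights) — the most common DTW
  formulation, so third-party implementations can serve as oracles.
* **Covariance, not correlation**, with per-channel mean-centering before
  projection, so component variances equal eigenvalues; no further
  standardization of raw channels is applied.
* **Eigenvector sign.** PC series are defined only up to sign, but DTW
  between two items' PC series is sign-sensitive, so a deterministic
  convention is mandatory. Each eigenvector is flipped so its **entry sum is
  positive** (fallback: largest-magnitude entry positive when the sum is
  numerically zero). A convention anchored on the single largest entry was
  tried first and proved fragile: when two loadings are nearly tied the
  anchor index differs between otherwise similar items and negates one
  item's PC series, which shows up as isolated, systematic 1NN errors. The
  entry sum aggregates all loadings and is stable for generic loading
  vectors.
* **Ties** break deterministically everywhere: eigenvalue ties keep the
  original axis order; equal distances prefer the smaller start then the
  lexicographically smaller source id; equal scores prefer the earlier start
  then the smaller candidate key.
* **Strict readings.** Overlap grouping uses strictly greater than `l/2`;
  component retention uses strictly more than the threshold; a group is
  isolated iff `2·|members| < n_dims`.
* **Aligned windows** start at the half-up-rounded mean of member starts.
  Stored member distances are reused for covered dimensions even though
  alignment may shift the window a little (cheap and faithful to the
  procedure); `recompute_all` disables the shortcut. A window that would run
  past the series end is dropped with a warning rather than clamped.
* **`d_k'` after truncation** is re-anchored to the largest distance among
  surviving candidates per dimension, since truncation changes the candidate
  set; `k'` in the score is likewise the per-dimension candidate count.
* **Empty candidate fallback.** With `p ≥ 3` and small `k'`, every group can
  be isolated; deleting them all would leave 1NN classification undefined.
  The search then retains the best-covered groups instead (with a warning).
* **Degenerate inputs.** All-constant items (zero covariance) are rejected;
  missing values are rejected, never imputed; `d_k' = 0` (all candidates
  coincide with the query) collapses all scores in that dimension to the
  query anchor.

## Evaluation protocol

1NN classification with repeated stratified k-fold cross-validation
(default 10 folds × 10 repeats; folds are reduced with a warning when the
smallest class is smaller than the fold count). Fold assignment is seeded
and stratified; reports carry every fold error, the retained `p` per repeat,
the configuration, and the seed, and are bit-reproducible. The
component-count scan starts at the minimal `p` passing the variance
threshold and walks upward, stopping as soon as the error exceeds the
previous value (first local minimum); monotone-decreasing profiles scan to
`p = n`.

Measure comparisons use the Wilcoxon signed-rank test in one pinned
variant: zero differences dropped, average ranks for ties, normal
approximation without continuity correction, two-sided. This is the variant
under which the published six-dataset error-rate comparison of the two
voting measures yields p = 0.043 (the exact-distribution p for the same
pairs would be 0.0625).

## Synthetic data: what it emulates, and what it does not

`generate_labeled_mts` emulates labeled multi-class MTS whose classes differ
in latent PC structure: per class, `latent_rank` smooth unit-RMS waveforms
(sums of three random sinusoids, 1–4 cycles); per item, a smooth within-class
deviation, a random monotone time warp with peak shift ≤ 5% of `m` (matched
to the default DTW band, so elastic matching is actually exercised), a
shared column-orthogonal loading matrix with geometric gains (decay 0.7),
and white Gaussian noise. `separation` is the between-class latent distance
in units of the within-class deviation: 0 gives exchangeable classes
(chance-level 1NN error), 10 gives trivially separable ones.

`generate_long_with_motifs` plants noisy copies of a smooth rank-≤2 motif at
well-separated positions (≥ 1.5·l apart when the slots allow) in a white
Gaussian background of sd 0.5 relative to the unit-RMS motif, and returns the
clean motif as the query.

What passing tests on these generators do **not** show: robustness to
heavy-tailed or nonstationary noise, irregular sampling, channel dropout,
class structure expressed in eigenvector orientation rather than waveform
shape, or the high-dimensional regimes (dozens of channels) where aligned
candidates become hard to form — the known weak spot of the
dimension-combination approach.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` run at desk scale: labeled
datasets of 3 classes × 20 items (`m = 60`, `n = 6`, `latent_rank = 2`,
noise sd 0.1) under 10×10-fold CV, long series of `M = 600` with three
planted length-60 motifs over five seeds, and DTW checked against exhaustive
path enumeration on 100 seeded pairs of length ≤ 6. Because a 60-item null
dataset's realized 1NN error varies by several points across realizations,
the acceptance script averages each CV quantity over three replicate
datasets generated under identical conditions.

## Known limitations

* Subsequence search is exhaustive over sliding windows (no lower bounding,
  early abandoning, or indexing); cost grows linearly in `M` per dimension.
* Whole matching assumes comparable item lengths; the band makes very
  different lengths infeasible by construction.
* The measure is sensitive to the number of retained components: when many
  components are needed to reach the variance threshold, per-dimension hits
  rarely align and candidates degrade (mitigated, not solved, by the
  best-covered-group fallback).
* `S_BORDA`'s "votes" are counted via the same truncation grouping as the
  weighted measure, pinning down its loosely specified "very close time
  period".
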