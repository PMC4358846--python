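# Methods

## Model and pipeline

A grayscale raster is modelled as a surface `X(i, j)` (`M × N`, gray
levels nominally 0–255; any finite reals are accepted).  The analysis
follows the standard two-dimensional MF-DFA recipe:

1. **Partitioning.** For each scale `s`, the surface is tiled by
   `⌊M/s⌋ × ⌊N/s⌋` non-overlapping `s × s` segments.  Because `M, N` are
   generally not multiples of `s`, a margin is left over; the tiling is
   repeated from all four corners so that every edge of the image
   contributes, and the segments of the four tilings are **pooled** into
   one set (the `1/(M_s N_s)` normalizer becomes one over the pooled
   count).  Averaging the four tilings separately instead of pooling is
   numerically almost identical for homogeneous textures; pooling was
   chosen because it is a single generalized mean over one segment
   population and therefore preserves the monotonicity of `F_q` in `q`
   exactly.  On sizes where every scale tiles exactly, the four tilings
   coincide and pooling is a no-op (tested).
2. **Integration.** Each segment is double-cumulatively summed:
   `G(i,j) = Σ_{k1≤i} Σ_{k2≤j} X(k1,k2)`, with the raw gray values (no
   mean subtraction — the printed formula sums `X` directly).  Note the
   integral of a *constant* surface is `c·i·j`, which is not a plane, so
   flat image regions still produce positive fluctuations; a segment
   yields exactly zero fluctuation only if it is identically zero, in
   which case the `q ≤ 0` moments are undefined and a
   `DegenerateSurfaceError` is raised rather than silently dropping the
   segment (dropping would change the estimator).  The synthetic
   generators add a tiny positive dither (`1e-6 · U(0,1)` gray levels)
   for exactly this reason.
3. **Detrending.** A least-squares plane `a·i + b·j + c` (1-based grid
   coordinates) is removed from each integrated segment; the local
   fluctuation `F(m,n,s)` is the RMS residual.  Higher-order trend
   surfaces are out of scope — the detrending order is part of the
   method definition.
4. **Moments.** `F_q(s)` is the order-`q` generalized mean of the pooled
   segment fluctuations, computed in log space
   (`exp((logsumexp(q·ln F) − ln n)/q)`) so that `|q| = 15` neither
   overflows nor loses the small-`F` tail; `|q| < 1e-9` is routed to the
   geometric-mean (`q = 0`) limit.
5. **Regression.** `h(q)` is the OLS slope of `ln F_q(s)` on `ln s` over
   the **full** scale grid — no scaling subrange is tuned; the per-`q`
   `r²` is retained so users can detect scaling breaks themselves.

### Grids

* **Scales:** ~20 approximately geometrically spaced integers in
  `6 … ⌊min(M,N)/4⌋` (duplicates from rounding removed; at least 4 scales
  are required for the regression, so surfaces must have
  `min(M,N) ≥ 36` for the default grid, and `≥ 24` in general).
  Geometric spacing gives uniform leverage in `ln s`.
* **Moment orders:** integers `−15 … 15` plus `±0.5`.  The range matches
  the spectrum-width definition; the extra half-integer points improve
  the finite-difference derivative near `q = 0`, where the spectrum is
  best estimated.  Features read `h(q)` at exactly
  `q ∈ {−3, −2, −1, 1, 2, 3}`.

### Derived spectra

`τ(q) = q·h(q) − 2` (support dimension 2 for a surface; `τ(0) = −2`
identically).  `D_q = τ(q)/(q−1)` for `q ≠ 1`, with `D₂` read at
`q = 2`.  `D₁` comes from a separate box-entropy regression: per scale,
the top-left tiling's box masses normalized by the total mass give
probabilities `P`, and `D₁` is the slope of `Σ P ln P` against `ln s`
(empty boxes contribute the `p ln p → 0` limit; the single top-left
tiling is used because the probability normalization is defined on one
partition).  `α = τ′(q)` is a central finite difference of `τ` on the
`q` grid — differencing `τ` rather than `h` avoids compounding two
derivative estimates — and the one-sided endpoint estimates are
discarded, so `α`, `f = qα − τ` live on interior `q` only.  `Δα` and
`Δf` are read at the `q`'s attaining the `α` extrema; exact ties break
toward the smallest `|q|` (the best-estimated part of the spectrum).  A
non-monotone `α(q)` (spectrum folding, usually estimation noise at
extreme `q`) is reported as a warning, never silently repaired.

## Feature selection

For each of the 12 features, `σ_in(i)` is the standard deviation over
species `i`'s samples, `σ_in` their unweighted mean over species, and
`σ_bet` the standard deviation of the per-species means; `I₀ = σ_bet/σ_in`.
The sample (n−1) convention is the default for both (configurable to the
population convention); unweighted means match a balanced design.  `I₀`
is invariant under affine rescaling of a feature, so no standardization
is needed before ranking.  Ties in the top-k selection break by the
canonical feature order.  A feature with zero within-species variance is
flagged `+inf` with a warning rather than erroring: it is degenerate but
maximally separating whenever the species means differ.

## Classification

The heavy-tailed RBF kernel
`k(x,y) = exp(−(1/σ_k) Σ_d |x_d^a − y_d^a|^b)` uses the signed power
convention `sign(v)|v|^a`, keeping it well defined for negative features
(e.g. `h(−3)` on rough textures) and fractional `a`.  Defaults
`a = 1, b = 1` give the Laplacian-like heavy-tailed case; `a = 1, b = 2`
reduces exactly to the Gaussian RBF (tested to 1e−12).  `σ_k` defaults
to the median pairwise power distance of the training block of each
fold; the SVM cost is `C = 10`.  Features are z-scored with training-fold
statistics only (leakage-free).  Multi-class problems use one-vs-one
voting (scikit-learn's `SVC` with a precomputed Gram matrix), stratified
K-fold splits, and every repeat derives its shuffle seed from a single
`SeedSequence`, so identical seeds give bitwise-identical fold
accuracies, confusion matrices and dendrograms.  The confusion matrix
pools all folds of all repeats, making `mean_accuracy = trace/total` an
exact identity.

Hierarchical clustering of species uses the pairwise CV accuracy
*itself* as the distance: two species that are hard to distinguish have
low mutual accuracy and merge early.  This is deliberately literal — a
`one-minus` transform is available for users who prefer a conventional
dissimilarity.  Average linkage; equal distances merge in lowest-index
order (scipy's deterministic rule).

## Synthetic ground truth

* **Monofractal oracle.** `fbm_surface` synthesizes an isotropic
  fractional-Brownian surface `B` spectrally (power spectrum
  `∝ |k|^−(2H+2)`, folded over the first Fourier aliases so the
  small-scale scaling survives discretization — plain radial synthesis
  was measurably too smooth at low `H`) and returns its discrete double
  increment.  The analysis pipeline's per-segment cumulative sum
  re-integrates this field into a local copy of `B`, so the estimated
  `h(q)` recovers `H` at every `q`.  Returning `B` itself would be
  wrong: the pipeline would integrate an already-nonstationary surface
  and saturate at the first-order-detrending limit `h ≈ 2` regardless
  of `H` (measured: 1.92/1.99/2.01 for H = 0.2/0.5/0.8).
* **Multifractal oracle.** `cascade_surface` builds a 2×2 multiplicative
  cascade (weights `p₁..p₄`, `Σp = 1`, optionally shuffled placement per
  cell) with the closed form `τ_meas(q) = −log₂ Σ p_i^q` and its exact
  Legendre transform as analytic oracles; `box_counting_tau` estimates
  the same exponents by partition-function regression over dyadic boxes,
  independent of the MF-DFA route.  On exact cascades the box-counting
  regression is exact to rounding (~1e−15).
* **Gray mapping.** `cascade_to_gray` min-max scales the cascade mass
  itself to 0–255 (`mode="linear"`).  A log-transform mode exists but is
  not the default: the log-measure is a smooth additive field whose
  `h(q)` saturates near the detrending limit for *every* weight vector,
  which erases the identifiable differences between species (measured:
  species `I₀` ≈ 0.15 and near-chance classification under the log
  mapping, versus `I₀` up to ~12 under the linear one).
* **Species datasets.** `make_species_surfaces` assigns each species a
  weight vector with dominant weight `p₁ ∈ 0.30 … 0.70` (remaining mass
  split equally), so species differ gradually in heterogeneity;
  within-species variation comes from shuffled weight placement and
  additive Gaussian gray noise of SD 2 gray levels (a realistic scanner
  noise floor), clipped at black and re-dithered.
  `make_feature_dataset` skips the image stage and draws 12-feature
  vectors directly — Gaussian within species, with selected features
  carrying between-species mean shifts of a chosen multiple of the
  within-species SD — for fast classifier and selection tests, and
  accepts explicit species centers for planted similarity structure.

What the generators do **not** emulate: leaf shape, contours, veins,
segmentation masks, scanner backgrounds, anisotropy, or illumination
gradients.  Passing tests therefore show that the estimators and the
selection/classification machinery are correct on surfaces with known
scaling — not that any particular accuracy will be reached on real leaf
collections, which depends on image resolution, preprocessing and
species involved.

## Study conditions and problem sizes

The validation experiments (test suite and `scripts/acceptance.py`) use:
oracle agreement on random matrices up to 64×64 against a literal
loop transcription of the formulas (tolerance 1e−10); fBm recovery at
`H ∈ {0.2, 0.5, 0.8}`, 256², 5 seeds (`|mean ĥ(2) − H| ≤ 0.1`, mean
`Δα ≤ 0.3`); cascades with weights `(0.4, 0.3, 0.2, 0.1)` at depth 9
(512²) for exponent recovery (box-counting within 0.05 of analytic) and
the spectrum-width contrast against equal weights; I₀ selection over 100
trials of 5 species × 30 samples with 2-SD planted shifts; end-to-end
identification on 5 cascade species × 30 samples at 128² with 10-fold
CV repeated 10 times; and a planted 2+2+1 similarity structure for the
clustering cut at `g = 3` over 10 seeds.

## Known limitations

* First-order (plane) detrending bounds the measurable `h` from above;
  very smooth surfaces saturate near `h ≈ 2`.
* `h` estimates at `H ≤ 0.2` carry a positive small-scale bias of up to
  ~0.08 at 256² even with the alias-folded generator; larger images
  reduce it.
* The four corner tilings overlap except at exactly tileable sizes, so
  pooled small-scale segment sets are mildly correlated; this biases no
  expectation but understates the effective sample size at small `s`.
* `D₁` requires nonnegative surface values with positive total mass
  (gray images satisfy this; zero-mean fields do not).
* Kernel hyperparameters (`a`, `b`, `σ_k`, `C`) are conventions with
  documented defaults, not fitted quantities; real applications should
  tune them by nested cross-validation.
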