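# mfdfa2d

Two-dimensional multifractal detrended fluctuation analysis (2D MF-DFA)
for texture-based identification of plant species from leaf images — or
of any other classes of textured grayscale surfaces.

A grayscale image is treated as a surface `X(i, j)` whose roughness is
heterogeneous: different regions scale with different local exponents.
MF-DFA quantifies this by tiling the surface with `s × s` segments (from
all four corners, so no margin is wasted), integrating each segment
(double cumulative sum), removing a least-squares plane
`ã i + b̃ j + c̃`, and pooling the RMS residuals `F(m, n, s)` through a
generalized mean of order `q`:

```
F_q(s) = [ mean_segments F(m,n,s)^q ]^(1/q),      F_0(s) = exp(mean ln F)
```

The power law `F_q(s) ∝ s^h(q)` defines the generalized Hurst exponent
`h(q)`; from it follow the mass exponent `τ(q) = q·h(q) − 2`, the
generalized dimensions `D_q = τ(q)/(q−1)` (with the information dimension
`D₁` from a separate box-entropy regression), and the Legendre pair
`α(q) = τ′(q)`, `f(α) = q·α − τ(q)` whose width `Δα = α_max − α_min` and
asymmetry `Δf = f(α_max) − f(α_min)` summarize how multifractal the
texture is.

Each image yields a 12-feature vector
`{h(−3), h(−2), h(−1), h(1), h(2), h(3), α_max, α_min, Δα, Δf, D₁, D₂}`.
Features are ranked by the variance-ratio index `I₀ = σ_bet/σ_in`
(between-species spread of the per-species means over mean within-species
standard deviation), and the top three feed a soft-margin SVM with a
heavy-tailed radial basis kernel

```
k(x, y) = exp( −(1/σ_k) Σ_d |x_d^a − y_d^a|^b )
```

evaluated with stratified K-fold cross-validation.  Pairwise species
accuracies double as a similarity measure: hierarchical clustering on the
accuracy-as-distance matrix groups species that are hard to tell apart.

A synthetic module supplies surfaces with known ground truth —
fractional-Brownian fields (monofractal, `h(q) ≡ H`), 2×2 multiplicative
cascades (exactly multifractal, `τ_meas(q) = −log₂ Σ p_i^q`), and
labelled multi-species datasets — so the whole pipeline is verifiable
without any external image collection.

## Worked example

```python
import numpy as np
from mfdfa2d import (CascadeSpec, ScaleGrid, cascade_surface, cascade_to_gray,
                     compute_fluctuation_table, multifractal_spectrum, estimate_D1)

# a 256x256 multifractal surface with known weights (0.4, 0.3, 0.2, 0.1)
measure = cascade_surface(CascadeSpec((0.4, 0.3, 0.2, 0.1), depth=8, seed=0, shuffle=True))
gray = cascade_to_gray(measure, np.random.default_rng(0))

grid = ScaleGrid.default_for(*gray.shape)        # ~20 scales, 6 ... 64
spec = multifractal_spectrum(compute_fluctuation_table(gray, grid))
print(f"h(2)        = {spec.h_at(2):.3f}")
print(f"h(-3)       = {spec.h_at(-3):.3f}")
print(f"D2          = {spec.D2:.3f}")
print(f"D1          = {estimate_D1(gray, grid):.3f}")
print(f"delta_alpha = {spec.delta_alpha:.3f}  (alpha in [{spec.alpha_min:.3f}, {spec.alpha_max:.3f}])")
```

prints

```
h(2)        = 1.861
h(-3)       = 2.630
D2          = 1.721
D1          = 1.970
delta_alpha = 1.806  (alpha in [1.343, 3.149])
```

`h(q)` falls from 2.63 at q = −3 to 1.86 at q = 2 and the singularity
spectrum is wide (Δα ≈ 1.8): the surface is strongly multifractal, as a
cascade with unequal weights must be.  `D₁ ≈ 1.97` sits close to the
analytic information dimension `−Σ p log₂ p ≈ 1.85` of these weights,
and an equal-weight cascade run the same way gives Δα ≈ 0.

## Command line

The same pipeline is exposed as `mfdfa2d` subcommands:

```sh
mfdfa2d simulate -o data/ --n-species 5 --n-per-species 30 --seed 1
mfdfa2d extract data/ -o features.csv
mfdfa2d separability features.csv            # Table of sigma_bet, sigma_in, I0
mfdfa2d classify features.csv --seed 1       # JSON CV report
mfdfa2d pairwise features.csv                # binary accuracy per species pair
mfdfa2d cluster features.csv -g 5            # accuracy-distance dendrogram
mfdfa2d subsample features.csv --n-values 15,30
mfdfa2d compare-combos features.csv --combos 'h_m3,alpha_min,delta_alpha;h_p1,h_p2,delta_f'
```

`extract` accepts PNG/TIFF/JPEG images or dense CSV matrices; directory
names become species labels.  Kernel and CV settings can be collected in
a TOML file passed with `--config`.

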