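# Methods

## Observation model and objective

A 2-D MR slice is modelled as `Y = bX + n`: piecewise-constant tissue
intensities `X`, a smooth multiplicative bias field `b` with mean 1, and
i.i.d. zero-mean Gaussian noise `n`. The segmentation objective couples
a local data term and a nonlocal regularization term,

    J = Σ_i Σ_k u_ik^m Σ_{r∈Ω_k} K(r−k) [ α_k (1−S_ik)(x_k − b_k v_i)²
                                         + (1−α_k)(y_k − b_k v_i)² ],

with the membership constraint `Σ_i u_ik = 1`. The bracket does not
depend on the window offset r, and the truncated Gaussian kernel K is
renormalized over border-clipped windows, so `Σ_r K(r−k)` is exactly 1
everywhere and all block updates reduce to per-pixel closed forms. The
updates implemented here are the exact stationary points of J in each
block — the test suite verifies them against per-pixel numerical
minimization and finite-difference gradients. (A naively transcribed
fixed-point form of the center and bias denominators,
`b²(1−α)S u^m`, vanishes wherever `α_k = 1`; the correct factor,
obtained by setting the partial derivatives of J to zero, is
`α(1−S) + (1−α)` and is what this package computes.)

The objective is invariant under the gauge `(b, v) → (γb, v/γ)`. The
solver pins the gauge by renormalizing `b` to mean 1 over the
foreground after every bias update and rescaling the centers inversely;
this leaves J unchanged and makes bias fields comparable across runs.

## Ingredients

- **Local weight factor `S_ik`** — membership average over the square
  window around k (center excluded), each neighbour weighted by
  `1/(a_kr · d_kr)` with `a_kr = |x_k − x_r|` and `d_kr` the Euclidean
  distance between pixel coordinates. Zero intensity differences are
  floored at `δ = 1e−6 ×` dynamic range so identical neighbours get the
  largest finite weight. `S_ik ∈ [0, 1]`, equal to 1 when the whole
  window agrees on class i.
- **Adaptive trade-off `α_k = 1/(1 + var/x̄²)`** — population variance
  and mean over the clipped window (center included); `α = 1` in
  homogeneous windows (including the all-zero 0/0 case, resolved as the
  homogeneous limit). Computed once from the image.
- **Nonlocal average `y`** — for each pixel, candidates in the
  `(2u+1)²` search window are weighted by `exp(−D/h)` where D is the
  component-weighted squared patch difference; component weights depend
  only on the Chebyshev ring of the patch position,
  `σ^p = (1/s) Σ_{v=max(d,1)}^{s} (2v+1)^{−2}`, and sum to 1 over the
  patch. Weights are normalized per pixel (each `y_k` is a convex
  combination), the center candidate participates with distance 0, and
  borders are handled by dropping out-of-image components and
  renormalizing. `y` depends only on the image and is computed once
  before the iteration loop.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `c` | 4 | tissue classes (background, CSF, GM, WM) |
| `m` | 2 | fuzzifier (> 1); 2 is the standard choice |
| `epsilon` | 1e−3 | stop when max center change (normalized intensity units) falls below it |
| `max_iter` | 100 | iteration cap; non-convergence returns `converged=False`, not an error |
| `window_radius` | 1 | 3×3 window for `S` and `α` |
| `kernel_sigma` | 1.0 px | truncated Gaussian width; with unit kernel mass it does not affect the solution |
| `search_radius` u | 10 px | nonlocal search window radius |
| `patch_radius` s | 3 px | nonlocal patch radius |
| `h` | auto | similarity decay (intensity²); auto = `10 σ̂_n²` with σ̂ from the MAD of the Laplacian-filtered image, floored at 1e−12 |

Intensities are normalized to [0, 1] internally (by the foreground
maximum) and centers are rescaled on output, which makes `epsilon`, `h`
and the `S` floor scale-free. Initial centers are c evenly spaced
quantiles of the foreground intensities; if a dominant constant
background makes two quantiles coincide, the initializer falls back to
c evenly spaced levels between min and max (initial centers must be
distinct). A seeded 1-D k-means initializer is available as an option.
All methods (proposed and baselines) share this initializer and the
same stopping rule so comparisons are initialization-matched.

Other conventions: memberships with a zero distance to some class get a
one-hot assignment (standard FCM convention); a center whose update
denominator vanishes (empty cluster) is re-seeded to the foreground
intensity farthest from the remaining centers; bias pixels with no
intensity evidence keep gain 1. `S` at iteration t uses the previous
iteration's memberships; at t=1 it comes from plain-FCM memberships of
the initial centers.

## Baselines

FCM (no spatial term), BCFCM (neighbour-mean regularizer with weight
α/N_R, default α=1 over the 8-neighbourhood, with the per-pixel clipped
neighbour count at borders), SCFCM (the `(1−S_ik)` similarity with
plain FCM centers), and CLIC (kernel-weighted local clustering with a
bias field inside the window, default kernel σ=2, ρ=3 — the method
itself fixes no scale, and a moderate local window is a reasonable
default). BCFCM and CLIC updates are derived from their objectives by
the same Lagrangian recipe and validated by finite-difference
stationarity tests.

## Synthetic phantoms

The generator emulates the observation model directly: a labelled
piecewise-constant geometry (concentric equal-area rings mimicking
CSF/GM/WM inside a zero background, or a c-phase checker), a smooth
mean-1 bias field (planar ramp, Gaussian bump, or random quadratic
surface — the default, as coil inhomogeneity is typically a smooth
multi-directional trend) spanning ±amplitude before normalization, and
Gaussian noise with σ = noise% × the brightest tissue intensity (the
common simulated-brain-database convention). Negative noisy intensities
are clipped at 0, a deliberate deviation from pure Gaussian noise that
matters only in the dark background. Background is a class of its own;
evaluation excludes it from mean tissue JS by default.

What the phantoms do **not** emulate: anatomical geometry, partial
volume mixing at tissue interfaces, Rician noise statistics, 3-D
context. Passing tests therefore demonstrate correctness of the
algorithms and their qualitative behavior under noise and bias, not
clinical-grade performance on real acquisitions.

Problem sizes used in the tests and the acceptance script — 6×6 random
instances for the update oracles, 64×64 phantoms for solver fixtures,
128×128 phantoms with 5 seeds for the recovery and robustness studies —
were chosen as the smallest sizes at which the geometric classes are
well resolved and seed-to-seed variation is modest.

## Known limitations

- **The bias update is unregularized.** `b_k` is a per-pixel stationary
  point; nothing in the objective enforces the smoothness that real
  gain fields have. Two consequences, both visible in the acceptance
  results: (i) at low noise the estimated field carries pixel noise and
  its correlation with the true smooth field plateaus around 0.7–0.8
  (and degrades if the solver is run far past the standard stopping
  rule, as the coherence factor S drives the dominant-class data weight
  toward zero and the bias fit leans on the flattened nonlocal
  average); (ii) at high noise the extra per-pixel freedom lets the
  joint problem drift toward its degenerate optimum — merged centers
  with the bias absorbing class structure — so the proposed model's
  tissue overlap at 10% noise falls below SCFCM's, which estimates no
  bias. Kernel-smoothed bias variants and other values of `h` were
  examined and do not change this qualitative picture; a genuinely
  regularized (e.g. low-order parametric) bias model would, but is a
  different algorithm and out of scope here.
- The histogram-sharpening diagnostic is exact only on noiseless
  phantoms, where the corrected image collapses to one value per class.
- Convergence of the alternating scheme is monotone in J only while S
  is held fixed; across iterations S is refreshed from the previous
  memberships, so the objective trace is asserted non-increasing on the
  standard fixtures rather than guaranteed analytically.
- 2-D only; no skull stripping; class count must be supplied.
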