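# nlscfcm

Simultaneous brain-tissue segmentation and intensity-inhomogeneity
(bias-field) correction for 2-D MR slices, using a spatially coherent
fuzzy c-means model with nonlocal constraints — plus the four classical
algorithms it is usually compared against (FCM, BCFCM, SCFCM, CLIC), a
synthetic phantom generator with known ground truth, and Jaccard-based
evaluation tooling.

Intended users: researchers in medical image analysis who want a
self-contained, testable reference implementation of this family of
fuzzy-clustering segmentation algorithms, with every moving part
(spatial weight factor, nonlocal means, bias estimation) exposed as a
library function.

## The model

An observed MR slice is modelled as `Y = bX + n`: a piecewise-constant
tissue image `X`, a smooth multiplicative bias field `b` (RF-coil gain),
and additive zero-mean Gaussian noise `n`. Segmentation and bias
correction are obtained jointly by minimizing

```
J = Σ_i Σ_k u_ik^m Σ_{r∈Ω_k} K(r−k) [ α_k (1−S_ik)(x_k − b_k v_i)²
                                     + (1−α_k)(y_k − b_k v_i)² ]
```

subject to `Σ_i u_ik = 1`, where

- `u_ik` — fuzzy membership of pixel k in tissue class i (fuzzifier `m=2`),
- `v_i` — tissue cluster centers, `b_k` — per-pixel multiplicative gain,
- `S_ik` — local spatial coherence factor: neighbours' memberships
  averaged with weights `1/(|x_k−x_r|·‖p_k−p_r‖)` over a 3×3 window,
- `y_k` — nonlocal-means average of the image (search radius `u=10`,
  patch radius `s=3`, patch components weighted by Chebyshev ring),
- `α_k = 1/(1 + var(x)/x̄²)` — adaptive trade-off between the local data
  term and the nonlocal regularization term, from the local window
  statistics,
- `K` — truncated Gaussian kernel; with clipped-border renormalization
  its per-pixel mass is exactly 1.

Alternating closed-form updates (memberships → centers → bias) minimize
each block exactly; the bias field is gauge-fixed to mean 1 per
iteration. Iteration stops when the maximum center change falls below
`ε = 0.001` (on the internally normalized intensity scale).

Hard labels are the per-pixel membership argmax; the corrected image is
`Y / b̂` on the foreground.

## Worked example

```python
import numpy as np
from nlscfcm import ModelParams, fit, make_dataset, evaluate_segmentation

# 128x128 phantom: 4 classes (background/CSF/GM/WM at 0/60/120/180),
# 20% multiplicative inhomogeneity, 3% Gaussian noise
truth, observed = make_dataset(shape=(128, 128), bias_amplitude=0.2,
                               noise_percent=0.03, seed=0)

result = fit(observed, ModelParams(c=4))
report = evaluate_segmentation(result.labels, truth.labels, c=4,
                               bias_est=result.bias, bias_truth=truth.bias,
                               mask=truth.foreground)

print("converged:", result.converged, "after", result.iterations_run, "iterations")
print("cluster centers:", np.round(result.centers, 1))
print("per-class JS:", {k: round(v, 3) for k, v in report.per_class_js.items()})
print("mean tissue JS:", round(report.mean_js, 3))
print("bias-field correlation:", round(report.bias_correlation, 3))
```

prints

```
converged: True after 5 iterations
cluster centers: [  2.5  58.9 114.7 161.6]
per-class JS: {0: 0.99, 1: 0.991, 2: 0.993, 3: 1.0}
mean tissue JS: 0.994
bias-field correlation: 0.771
```

The centers land near the true tissue intensities (0/60/120/180), the
per-class Jaccard similarity (intersection over union against the
ground-truth masks, after label matching) is ≥ 0.99 for every class,
and the estimated gain field correlates 0.77 with the true one after
both are normalized to mean 1. See `docs/methods.md` for why the
bias-field estimate is the model's weakest output.

A command-line interface covers the same flow:

```
nlscfcm phantom --shape 181x217 --classes 4 --bias-amplitude 0.4 --noise 0.03 --seed 0 --out ph/
nlscfcm segment --input ph/image.tiff --classes 4 --out seg/
nlscfcm evaluate --pred seg/ --truth ph/ --out report.json
nlscfcm bench --noise 0.05:0.30:0.05 --methods proposed,fcm,scfcm --seeds 5 --out bench/
```

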