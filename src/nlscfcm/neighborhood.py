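"""Local spatial machinery: truncated Gaussian kernel, the local weight
factor S_ik, and the adaptive local/nonlocal trade-off alpha_k.

These three pieces are shared by the spatially coherent model and the
CLIC / SCFCM baselines.  Windows are always clipped at image borders (no
padding is invented) and kernel weights are renormalized over the clipped
support, which makes every per-pixel kernel mass exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "KernelWeights",
    "truncated_gaussian_kernel",
    "local_weight_factor",
    "adaptive_tradeoff",
    "kernel_smooth",
    "kernel_mass",
]


@dataclass(frozen=True)
class KernelWeights:
    """Truncated Gaussian kernel K(y) ∝ exp(−‖y‖²/2σ²) for ‖y‖ ≤ ρ.

    ``weights`` is the (2ρ+1)×(2ρ+1) stencil, zero outside the Euclidean
    truncation radius and normalized to sum to 1.
    """

    sigma: float
    rho: int
    weights: np.ndarray


def truncated_gaussian_kernel(sigma, rho) -> KernelWeights:
    """Build the normalized truncated Gaussian stencil.

    Offsets with Euclidean norm greater than ``rho`` get weight 0, so the
    ``rho=1`` kernel is the plus-shaped 5-point stencil and ``rho=0`` is a
    single unit weight.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    rho = int(rho)
    if rho < 0:
        raise ValueError("rho must be a non-negative integer")
    dy, dx = np.mgrid[-rho:rho + 1, -rho:rho + 1]
    d2 = dy**2 + dx**2
    w = np.exp(-d2 / (2.0 * sigma**2))
    w[d2 > rho**2] = 0.0
    return KernelWeights(sigma=float(sigma), rho=rho, weights=w / w.sum())


def kernel_mass(shape, kernel: KernelWeights, renormalize=True):
    """Per-pixel total kernel weight over the border-clipped support.

    With clipped-window renormalization (the package convention) this is
    identically 1; without it, border pixels fall short of 1.
    """
    ones = np.ones(shape, dtype=float)
    raw = ndimage.correlate(ones, kernel.weights, mode="constant", cval=0.0)
    return np.ones(shape) if renormalize else raw


def kernel_smooth(field, kernel: KernelWeights):
    """Kernel-weighted local average with clipped-border renormalization."""
    num = ndimage.correlate(np.asarray(field, float), kernel.weights,
                            mode="constant", cval=0.0)
    den = ndimage.correlate(np.ones(np.shape(field)), kernel.weights,
                            mode="constant", cval=0.0)
    return num / den


def _window_offsets(radius):
    """All (dy,dx) in the square window of given radius, center excluded."""
    return [(dy, dx)
            for dy in range(-radius, radius + 1)
            for dx in range(-radius, radius + 1)
            if (dy, dx) != (0, 0)]


def _shifted(a, dy, dx):
    """Value of ``a`` at pixel (r+dy, c+dx) with a validity mask.

    Out-of-image neighbours are flagged invalid (border clipping).
    """
    rows, cols = a.shape
    out = np.zeros_like(a, dtype=float)
    valid = np.zeros(a.shape, dtype=bool)
    rs = slice(max(dy, 0), rows + min(dy, 0))
    rd = slice(max(-dy, 0), rows + min(-dy, 0))
    cs = slice(max(dx, 0), cols + min(dx, 0))
    cd = slice(max(-dx, 0), cols + min(-dx, 0))
    out[rd, cd] = a[rs, cs]
    valid[rd, cd] = True
    return out, valid


def local_weight_factor(image, memberships, window_radius=1, delta_frac=1e-6):
    """Local spatial coherence factor S_ik.

    For each pixel k and class i, S_ik is the average of the neighbours'
    memberships u_ir over the square window (center excluded), weighted by
    1/(a_kr d_kr) with a_kr = |x_k − x_r| the grayscale difference and
    d_kr the Euclidean distance between pixel coordinates.  Similar, close
    neighbours therefore dominate.  S_ik ∈ [0, 1] and equals 1 when all
    window memberships for class i are 1.

    Zero grayscale differences would make the weight infinite; a_kr is
    floored at ``delta_frac`` times the image dynamic range so identical
    neighbours get the largest finite weight.
    """
    x = np.asarray(image, dtype=float)
    u = np.asarray(memberships, dtype=float)
    if u.ndim != 3 or u.shape[1:] != x.shape:
        raise ValueError("memberships must have shape (c, rows, cols)")
    if window_radius < 1:
        raise ValueError("window_radius must be >= 1")
    span = float(x.max() - x.min())
    delta = delta_frac * span if span > 0 else delta_frac

    num = np.zeros_like(u)
    den = np.zeros_like(x)
    for dy, dx in _window_offsets(window_radius):
        xs, valid = _shifted(x, dy, dx)
        a = np.abs(x - xs)
        g = valid / (np.maximum(a, delta) * np.hypot(dy, dx))
        den += g
        for i in range(u.shape[0]):
            us, _ = _shifted(u[i], dy, dx)
            num[i] += g * us
    return np.clip(num / den, 0.0, 1.0)


def adaptive_tradeoff(image, window_radius=1):
    """Per-pixel local/nonlocal trade-off alpha_k = 1/(1 + var(x)/x̄²).

    x̄ and var(x) are the mean and population variance over the clipped
    square window around k (center included).  alpha is large in
    homogeneous regions (pure local term) and shrinks where the window is
    noisy or crosses an edge.  The 0/0 case (all-zero window) is defined
    as alpha = 1, the homogeneous-region limit.  alpha depends only on
    the image, never on memberships, centers, or bias.
    """
    if window_radius < 1:
        raise ValueError("window_radius must be >= 1")
    x = np.asarray(image, dtype=float)
    size = 2 * window_radius + 1
    ones = np.ones((size, size))
    cnt = ndimage.correlate(np.ones_like(x), ones, mode="constant", cval=0.0)
    s1 = ndimage.correlate(x, ones, mode="constant", cval=0.0)
    s2 = ndimage.correlate(x * x, ones, mode="constant", cval=0.0)
    mean = s1 / cnt
    var = np.maximum(s2 / cnt - mean**2, 0.0)
    alpha = np.ones_like(x)
    ok = mean**2 > 0
    alpha[ok] = 1.0 / (1.0 + var[ok] / mean[ok] ** 2)
    alpha[var == 0] = 1.0
    return alpha
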