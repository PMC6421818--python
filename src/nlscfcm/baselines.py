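"""Reference fuzzy-clustering baselines: FCM, BCFCM, SCFCM, and CLIC.

All four share the proposed model's initialization (quantile centers,
plain-FCM starting memberships) and convergence rule (max center change
below epsilon) so comparisons are initialization-matched.  FCM, BCFCM,
and SCFCM do not model a bias field (``bias`` is 1 in their results);
CLIC estimates one through its kernel-smoothed local clustering.

BCFCM and CLIC closed-form updates are derived from their objectives by
the same Lagrangian recipe as the main model and are validated in the
test suite against numerical-gradient oracles.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .model import (SegmentationResult, _memberships_from_distances,
                    correct_image, init_centers, memberships_from_centers)
from .neighborhood import (KernelWeights, local_weight_factor,
                           truncated_gaussian_kernel)

__all__ = [
    "fcm_fit", "bcfcm_fit", "scfcm_fit", "clic_fit",
    "fcm_objective", "bcfcm_objective", "scfcm_objective", "clic_objective",
    "fcm_memberships", "fcm_centers",
    "bcfcm_memberships", "bcfcm_centers",
    "clic_memberships", "clic_centers", "clic_bias",
]

_TINY = 1e-30


# ---------------------------------------------------------------------------
# plain FCM

def fcm_objective(image, memberships, centers, m=2.0):
    x = np.asarray(image, float)
    v = np.asarray(centers, float).reshape(-1, 1, 1)
    u = np.asarray(memberships, float)
    return float(np.sum(u ** m * (x[None] - v) ** 2))


def fcm_memberships(image, centers, m=2.0):
    return memberships_from_centers(image, centers, m)


def fcm_centers(image, memberships, m=2.0):
    x = np.asarray(image, float)
    um = np.asarray(memberships, float) ** m
    num = np.sum(um * x[None], axis=(1, 2))
    den = np.sum(um, axis=(1, 2))
    return num / np.maximum(den, _TINY)


# ---------------------------------------------------------------------------
# BCFCM: FCM plus a neighbour-mean regularizer (weight alpha / N_R)

def _neighbor_moments(image, radius=1):
    """Clipped-window neighbour count, mean, and mean square (center
    excluded)."""
    x = np.asarray(image, float)
    size = 2 * radius + 1
    k = np.ones((size, size))
    k[radius, radius] = 0.0
    cnt = ndimage.correlate(np.ones_like(x), k, mode="constant", cval=0.0)
    m1 = ndimage.correlate(x, k, mode="constant", cval=0.0) / cnt
    m2 = ndimage.correlate(x * x, k, mode="constant", cval=0.0) / cnt
    return cnt, m1, m2


def bcfcm_objective(image, memberships, centers, m=2.0, alpha=1.0, radius=1):
    x = np.asarray(image, float)
    v = np.asarray(centers, float).reshape(-1, 1, 1)
    u = np.asarray(memberships, float)
    _, m1, m2 = _neighbor_moments(x, radius)
    nb = m2[None] - 2.0 * v * m1[None] + v ** 2  # (1/N_k) Σ_r (x_r − v_i)²
    return float(np.sum(u ** m * ((x[None] - v) ** 2 + alpha * nb)))


def bcfcm_memberships(image, centers, m=2.0, alpha=1.0, radius=1):
    x = np.asarray(image, float)
    v = np.asarray(centers, float).reshape(-1, 1, 1)
    _, m1, m2 = _neighbor_moments(x, radius)
    nb = m2[None] - 2.0 * v * m1[None] + v ** 2
    d = (x[None] - v) ** 2 + alpha * nb
    return _memberships_from_distances(np.maximum(d, 0.0), m)


def bcfcm_centers(image, memberships, m=2.0, alpha=1.0, radius=1):
    x = np.asarray(image, float)
    um = np.asarray(memberships, float) ** m
    _, m1, _ = _neighbor_moments(x, radius)
    num = np.sum(um * (x[None] + alpha * m1[None]), axis=(1, 2))
    den = (1.0 + alpha) * np.sum(um, axis=(1, 2))
    return num / np.maximum(den, _TINY)


# ---------------------------------------------------------------------------
# SCFCM: FCM with the (1 − S_ik) spatially coherent similarity measure

def scfcm_objective(image, memberships, centers, s_map, m=2.0):
    x = np.asarray(image, float)
    v = np.asarray(centers, float).reshape(-1, 1, 1)
    u = np.asarray(memberships, float)
    return float(np.sum(u ** m * (1.0 - s_map) * (x[None] - v) ** 2))


# ---------------------------------------------------------------------------
# CLIC: kernel-weighted local intensity clustering with bias estimation
#
# J = Σ_i Σ_k u_ik^m Σ_r K'(k,r) (x_k − b_r v_i)², with K' the kernel
# renormalized over the clipped window of k.  Writing sm(f) for the
# renormalized kernel average Σ_r K'(k,r) f_r, the per-pixel distance is
# x² − 2 x v sm(b) + v² sm(b²).

def _clic_smooth(field, kernel: KernelWeights):
    num = ndimage.correlate(np.asarray(field, float), kernel.weights,
                            mode="constant", cval=0.0)
    den = ndimage.correlate(np.ones(np.shape(field)), kernel.weights,
                            mode="constant", cval=0.0)
    return num / den


def clic_objective(image, memberships, centers, bias, kernel, m=2.0):
    x = np.asarray(image, float)
    v = np.asarray(centers, float).reshape(-1, 1, 1)
    u = np.asarray(memberships, float)
    b = np.asarray(bias, float)
    smb = _clic_smooth(b, kernel)
    smb2 = _clic_smooth(b * b, kernel)
    d = x[None] ** 2 - 2.0 * x[None] * v * smb[None] + v ** 2 * smb2[None]
    return float(np.sum(u ** m * d))


def clic_memberships(image, centers, bias, kernel, m=2.0):
    x = np.asarray(image, float)
    v = np.asarray(centers, float).reshape(-1, 1, 1)
    smb = _clic_smooth(bias, kernel)
    smb2 = _clic_smooth(np.asarray(bias, float) ** 2, kernel)
    d = x[None] ** 2 - 2.0 * x[None] * v * smb[None] + v ** 2 * smb2[None]
    return _memberships_from_distances(np.maximum(d, 0.0), m)


def clic_centers(image, memberships, bias, kernel, m=2.0):
    x = np.asarray(image, float)
    um = np.asarray(memberships, float) ** m
    smb = _clic_smooth(bias, kernel)
    smb2 = _clic_smooth(np.asarray(bias, float) ** 2, kernel)
    num = np.sum(um * x[None] * smb[None], axis=(1, 2))
    den = np.sum(um * smb2[None], axis=(1, 2))
    return num / np.maximum(den, _TINY)


def clic_bias(image, memberships, centers, kernel, m=2.0):
    """Stationary point of the CLIC objective in b_r (unnormalized).

    b_r = Σ_i v_i Σ_k K(r−k)/M_k u_ik^m x_k
          / Σ_i v_i² Σ_k K(r−k)/M_k u_ik^m,

    where M_k is the clipped-window kernel mass at k.  The backprojection
    Σ_k K(r−k)·g_k is a correlation with the (symmetric) kernel.
    """
    x = np.asarray(image, float)
    u = np.asarray(memberships, float)
    v = np.asarray(centers, float)
    mass = ndimage.correlate(np.ones_like(x), kernel.weights,
                             mode="constant", cval=0.0)
    num = np.zeros_like(x)
    den = np.zeros_like(x)
    for i in range(u.shape[0]):
        umi = u[i] ** m / mass
        back_x = ndimage.correlate(umi * x, kernel.weights,
                                   mode="constant", cval=0.0)
        back_1 = ndimage.correlate(umi, kernel.weights,
                                   mode="constant", cval=0.0)
        num += v[i] * back_x
        den += v[i] ** 2 * back_1
    # zero numerator = no intensity evidence (all-zero window): keep gain 1
    ok = (den > _TINY) & (num > _TINY)
    return np.where(ok, num / np.maximum(den, _TINY), 1.0)


# ---------------------------------------------------------------------------
# fit loops

def _normalize(image, mask=None):
    x = np.asarray(image, float)
    scale = float(x[mask].max() if mask is not None else x.max())
    scale = scale if scale > 0 else 1.0
    return x / scale, scale


def _result(u, v, b, x_raw, scale, trace, vhist, it, converged, method,
            mask=None, max_resid=0.0, shift=np.inf):
    labels = np.argmax(u, axis=0)
    corrected = correct_image(x_raw, b, mask)
    return SegmentationResult(
        memberships=u, centers=np.asarray(v) * scale, bias=b, labels=labels,
        corrected_image=corrected, objective_trace=trace,
        center_history=vhist, iterations_run=it, converged=converged,
        method=method, max_membership_residual=max_resid,
        final_center_shift=shift)


def fcm_fit(image, c, m=2.0, epsilon=1e-3, max_iter=100, init="quantile",
            seed=0, mask=None):
    """Standard fuzzy c-means (no spatial term, no bias field)."""
    x_raw = np.asarray(image, float)
    x, scale = _normalize(x_raw, mask)
    v = init_centers(x, c, init, seed, mask)
    trace, vhist = [], []
    converged, shift, max_resid, it = False, np.inf, 0.0, 0
    for it in range(1, max_iter + 1):
        u = fcm_memberships(x, v, m)
        max_resid = max(max_resid, float(np.abs(u.sum(axis=0) - 1.0).max()))
        v_new = fcm_centers(x, u, m)
        trace.append(fcm_objective(x, u, v_new, m))
        shift = float(np.max(np.abs(v_new - v)))
        v = v_new
        vhist.append(v * scale)
        if shift < epsilon:
            converged = True
            break
    b = np.ones_like(x)
    return _result(u, v, b, x_raw, scale, trace, vhist, it, converged,
                   "fcm", mask, max_resid, shift)


def bcfcm_fit(image, c, m=2.0, alpha=1.0, radius=1, epsilon=1e-3,
              max_iter=100, init="quantile", seed=0, mask=None):
    """FCM with the neighbour-mean regularizer (weight ``alpha``).

    ``alpha=0`` reduces exactly to :func:`fcm_fit`.  The neighbour term
    divides by the per-pixel clipped neighbour count, keeping the update
    a true stationary point at image borders.
    """
    x_raw = np.asarray(image, float)
    x, scale = _normalize(x_raw, mask)
    v = init_centers(x, c, init, seed, mask)
    trace, vhist = [], []
    converged, shift, max_resid, it = False, np.inf, 0.0, 0
    for it in range(1, max_iter + 1):
        u = bcfcm_memberships(x, v, m, alpha, radius)
        max_resid = max(max_resid, float(np.abs(u.sum(axis=0) - 1.0).max()))
        v_new = bcfcm_centers(x, u, m, alpha, radius)
        trace.append(bcfcm_objective(x, u, v_new, m, alpha, radius))
        shift = float(np.max(np.abs(v_new - v)))
        v = v_new
        vhist.append(v * scale)
        if shift < epsilon:
            converged = True
            break
    b = np.ones_like(x)
    return _result(u, v, b, x_raw, scale, trace, vhist, it, converged,
                   "bcfcm", mask, max_resid, shift)


def scfcm_fit(image, c, m=2.0, window_radius=1, epsilon=1e-3, max_iter=100,
              init="quantile", seed=0, mask=None, use_weight=True):
    """Spatially coherent FCM: similarity (1−S_ik)‖x_k−v_i‖².

    S_ik at iteration t uses the previous iteration's memberships.  The
    center update is the plain FCM one (as the method prescribes).
    ``use_weight=False`` forces S ≡ 0, reducing the loop to plain FCM.
    """
    x_raw = np.asarray(image, float)
    x, scale = _normalize(x_raw, mask)
    v = init_centers(x, c, init, seed, mask)
    u = memberships_from_centers(x, v, m)
    zero_s = np.zeros((c,) + x.shape)
    trace, vhist = [], []
    converged, shift, max_resid, it = False, np.inf, 0.0, 0
    for it in range(1, max_iter + 1):
        s_map = (local_weight_factor(x, u, window_radius)
                 if use_weight else zero_s)
        d = (1.0 - s_map) * (x[None] - np.reshape(v, (-1, 1, 1))) ** 2
        u = _memberships_from_distances(d, m)
        max_resid = max(max_resid, float(np.abs(u.sum(axis=0) - 1.0).max()))
        v_new = fcm_centers(x, u, m)
        trace.append(scfcm_objective(x, u, v_new, s_map, m))
        shift = float(np.max(np.abs(v_new - v)))
        v = v_new
        vhist.append(v * scale)
        if shift < epsilon:
            converged = True
            break
    b = np.ones_like(x)
    return _result(u, v, b, x_raw, scale, trace, vhist, it, converged,
                   "scfcm", mask, max_resid, shift)


def clic_fit(image, c, m=2.0, kernel: KernelWeights | None = None,
             epsilon=1e-3, max_iter=100, init="quantile", seed=0, mask=None):
    """Coherent local intensity clustering with bias-field estimation.

    Default kernel: truncated Gaussian with sigma=2, rho=3 (a moderate
    local window).  The bias field is gauge-normalized to mean 1 after
    each update, with centers rescaled inversely.
    """
    if kernel is None:
        kernel = truncated_gaussian_kernel(2.0, 3)
    x_raw = np.asarray(image, float)
    x, scale = _normalize(x_raw, mask)
    v = init_centers(x, c, init, seed, mask)
    b = np.ones_like(x)
    trace, vhist = [], []
    converged, shift, max_resid, it = False, np.inf, 0.0, 0
    for it in range(1, max_iter + 1):
        u = clic_memberships(x, v, b, kernel, m)
        max_resid = max(max_resid, float(np.abs(u.sum(axis=0) - 1.0).max()))
        v_new = clic_centers(x, u, b, kernel, m)
        b = clic_bias(x, u, v_new, kernel, m)
        mu = float(b[mask].mean() if mask is not None else b.mean())
        if mu > 0:
            b = b / mu
            v_new = v_new * mu
        trace.append(clic_objective(x, u, v_new, b, kernel, m))
        shift = float(np.max(np.abs(v_new - v)))
        v = v_new
        vhist.append(v * scale)
        if shift < epsilon:
            converged = True
            break
    return _result(u, v, b, x_raw, scale, trace, vhist, it, converged,
                   "clic", mask, max_resid, shift)
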