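"""Synthetic brain-like phantoms with known ground truth.

The observation model is the standard multiplicative-bias MR model

    Y = b * X + n

where ``X`` is a piecewise-constant "true" tissue image, ``b`` a smooth
multiplicative bias field (gain) with mean 1 over the grid, and ``n``
additive zero-mean Gaussian noise.  The noise level is parameterized as a
percentage of the brightest tissue intensity (BrainWeb's convention): 3%
noise means ``sigma = 0.03 * max(class_intensities)``.  Likewise a "40%
intensity nonuniformity" means the bias field spans ±40% around 1 before
its mean-1 renormalization.

Negative noisy intensities are clipped at 0 (images are stored unsigned),
a documented deviation from pure Gaussian noise that only affects the
dark background at realistic noise levels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "PhantomTruth",
    "make_phantom",
    "make_bias_field",
    "compose_observation",
    "make_dataset",
]

GEOMETRIES = ("nested_disks", "checker_blobs")
BIAS_KINDS = ("linear_ramp", "gaussian_bump", "polynomial2")

#: smallest admissible phantom side length
MIN_SIDE = 32
#: every class must occupy at least this fraction of pixels
MIN_CLASS_FRACTION = 0.02


@dataclass
class PhantomTruth:
    """Ground truth behind an observed phantom image.

    Attributes
    ----------
    true_image : ndarray
        Piecewise-constant tissue image ``X``; value at pixel ``k`` equals
        ``class_intensities[labels[k]]`` exactly.
    labels : ndarray of int
        Class map in ``{0..c-1}``; class 0 is the background.
    class_intensities : ndarray
        The c distinct tissue intensity levels.
    bias : ndarray
        Multiplicative gain ``b``, strictly positive, mean 1 over the grid.
    noise_sigma : float
        Standard deviation of the additive noise in intensity units
        (0 until an observation is composed).
    """

    true_image: np.ndarray
    labels: np.ndarray
    class_intensities: np.ndarray
    bias: np.ndarray = field(default=None)  # type: ignore[assignment]
    noise_sigma: float = 0.0

    def __post_init__(self):
        if self.bias is None:
            self.bias = np.ones_like(self.true_image, dtype=float)

    @property
    def n_classes(self) -> int:
        return len(self.class_intensities)

    @property
    def foreground(self) -> np.ndarray:
        """Boolean mask of non-background pixels."""
        return self.labels > 0


def _validate_intensities(class_intensities) -> np.ndarray:
    levels = np.asarray(class_intensities, dtype=float)
    if levels.ndim != 1 or levels.size < 2:
        raise ValueError("need at least 2 class intensities")
    if np.any(levels < 0):
        raise ValueError("class intensities must be non-negative")
    if len(np.unique(levels)) != levels.size:
        raise ValueError("degenerate classes: duplicate class intensities")
    return levels


def make_phantom(shape, class_intensities, geometry="nested_disks", seed=0):
    """Generate a labelled piecewise-constant phantom.

    Parameters
    ----------
    shape : (rows, cols)
        Image size; each side must be >= 32.
    class_intensities : sequence of float
        One distinct non-negative intensity per class.  By convention the
        first entry is the background level (0 for brain phantoms).
    geometry : {"nested_disks", "checker_blobs"}
        ``nested_disks`` places c-1 concentric equal-area rings (mimicking
        CSF/GM/WM) inside a background; ``checker_blobs`` tiles the grid
        with a c-phase checker pattern.
    seed : int
        Seeds the small geometric jitter; identical seeds give identical
        phantoms.

    Returns
    -------
    PhantomTruth
    """
    rows, cols = int(shape[0]), int(shape[1])
    if rows < MIN_SIDE or cols < MIN_SIDE:
        raise ValueError(f"shape too small: need at least {MIN_SIDE}x{MIN_SIDE}")
    levels = _validate_intensities(class_intensities)
    c = levels.size
    if geometry not in GEOMETRIES:
        raise ValueError(f"unknown geometry {geometry!r}")
    rng = np.random.default_rng(seed)

    if geometry == "nested_disks":
        labels = _nested_disks(rows, cols, c, rng)
    else:
        labels = _checker_blobs(rows, cols, c, rng)

    counts = np.bincount(labels.ravel(), minlength=c)
    if np.any(counts < MIN_CLASS_FRACTION * labels.size):
        raise ValueError("phantom geometry left a class under 2% of pixels")

    true_image = levels[labels]
    return PhantomTruth(true_image=true_image, labels=labels,
                        class_intensities=levels)


def _nested_disks(rows, cols, c, rng):
    half = min(rows, cols) / 2.0
    cy = rows / 2.0 + rng.uniform(-0.03, 0.03) * rows
    cx = cols / 2.0 + rng.uniform(-0.03, 0.03) * cols
    yy, xx = np.mgrid[0:rows, 0:cols]
    r = np.hypot(yy - cy, xx - cx)
    outer = 0.9 * half
    # equal-area rings: radii outer*sqrt(j/(c-1)), innermost disk = last class
    labels = np.zeros((rows, cols), dtype=np.int64)
    n_rings = c - 1
    for j in range(1, n_rings + 1):
        r_out = outer * np.sqrt((n_rings - j + 1) / n_rings)
        labels[r <= r_out] = j
    return labels


def _checker_blobs(rows, cols, c, rng):
    tile = max(min(rows, cols) // (2 * c), 4)
    off = rng.integers(0, tile, size=2)
    yy, xx = np.mgrid[0:rows, 0:cols]
    return (((yy + off[0]) // tile + (xx + off[1]) // tile) % c).astype(np.int64)


def make_bias_field(shape, amplitude, kind="polynomial2", seed=0):
    """Generate a smooth multiplicative bias field of mean 1.

    The field is built to span ``[1-amplitude, 1+amplitude]`` and then
    renormalized to mean 1 over the grid, so the returned range is that
    interval divided by a normalization constant close to 1.  All three
    kinds are low-order spatial forms with no high-frequency content:
    a planar ramp, a single Gaussian bump, or a random quadratic surface.

    Parameters
    ----------
    shape : (rows, cols)
    amplitude : float
        Fractional inhomogeneity in [0, 1); 0.4 emulates a "40% intensity
        nonuniformity" setting.
    kind : {"linear_ramp", "gaussian_bump", "polynomial2"}
    seed : int
        Seeds orientation/placement/coefficients.
    """
    if not 0 <= amplitude < 1:
        raise ValueError("amplitude must lie in [0, 1) to keep the bias positive")
    rows, cols = int(shape[0]), int(shape[1])
    if kind not in BIAS_KINDS:
        raise ValueError(f"unknown bias kind {kind!r}")
    if amplitude == 0:
        return np.ones((rows, cols), dtype=float)
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:rows, 0:cols]
    u = 2.0 * yy / max(rows - 1, 1) - 1.0
    v = 2.0 * xx / max(cols - 1, 1) - 1.0

    if kind == "linear_ramp":
        theta = rng.uniform(0.0, 2.0 * np.pi)
        g = u * np.cos(theta) + v * np.sin(theta)
    elif kind == "gaussian_bump":
        cu, cv = rng.uniform(-0.4, 0.4, size=2)
        width = 0.6
        g = np.exp(-((u - cu) ** 2 + (v - cv) ** 2) / (2.0 * width**2))
    else:  # polynomial2
        coeff = rng.normal(size=5)
        g = (coeff[0] * u + coeff[1] * v + coeff[2] * u * u
             + coeff[3] * u * v + coeff[4] * v * v)

    lo, hi = g.min(), g.max()
    if hi - lo < 1e-15:  # degenerate draw, fall back to flat field
        return np.ones((rows, cols), dtype=float)
    g = 2.0 * (g - lo) / (hi - lo) - 1.0  # exact range [-1, 1]
    b = 1.0 + amplitude * g
    return b / b.mean()


def compose_observation(truth: PhantomTruth, noise_percent, seed=0):
    """Render the observed image ``Y = b*X + n``.

    ``n`` is i.i.d. Gaussian with zero mean and
    ``sigma = noise_percent * max(class_intensities)``; negative values
    are clipped at 0.  Deterministic for a fixed seed.
    """
    if noise_percent < 0:
        raise ValueError("noise_percent must be >= 0")
    sigma = float(noise_percent) * float(truth.class_intensities.max())
    y = truth.bias * truth.true_image
    if sigma > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, sigma, size=y.shape)
        np.clip(y, 0.0, None, out=y)
    return y


def make_dataset(shape=(128, 128), class_intensities=(0, 60, 120, 180),
                 geometry="nested_disks", bias_amplitude=0.2,
                 bias_kind="polynomial2", noise_percent=0.03, seed=0):
    """One-call phantom + bias + noise bundle.

    Returns ``(truth, observed)`` where ``truth`` carries the attached bias
    field and the realized noise sigma.  The three random stages derive
    independent seeds from ``seed`` so geometry, bias, and noise decouple.
    """
    truth = make_phantom(shape, class_intensities, geometry, seed=seed)
    bias = make_bias_field(shape, bias_amplitude, bias_kind, seed=seed + 10007)
    sigma = float(noise_percent) * float(truth.class_intensities.max())
    truth = replace(truth, bias=bias, noise_sigma=sigma)
    observed = compose_observation(truth, noise_percent, seed=seed + 20011)
    return truth, observed
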