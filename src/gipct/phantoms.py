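"""Synthetic phantoms of the refractive-index decrement delta.

The generator emulates in-silico breast data at desk scale: a smooth
elliptical adipose-like background with randomly placed elliptical
inclusions of contrasting delta, piecewise smooth with edges strong enough
to drive phase wrapping in the simulated interferometer signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["PhantomImage", "make_breast_phantom", "make_disk_phantom"]

# fixed affine map delta -> mu used to make phase-stepping counts realistic;
# attenuation is simulated in projections only, never reconstructed
_MU_OFFSET = 0.02  # 1/mm, adipose-like baseline
_MU_SLOPE = 0.05  # 1/mm per unit of (delta / delta_max)


@dataclass(frozen=True)
class PhantomImage:
    """2D phantom: refractive-index decrement map and optional attenuation.

    delta is dimensionless (physical scale ~1e-7, or ~1 in unit-rescaled
    mode); mu is in 1/mm; mask marks the object support.
    """

    delta: np.ndarray
    mu: np.ndarray | None = None
    mask: np.ndarray | None = None

    def __post_init__(self):
        delta = np.asarray(self.delta, dtype=np.float64)
        if delta.ndim != 2:
            raise ValueError("delta must be 2D")
        if not np.all(np.isfinite(delta)):
            raise ValueError("delta must be finite")
        if np.any(delta < 0):
            raise ValueError("delta must be non-negative")
        object.__setattr__(self, "delta", delta)
        if self.mu is not None:
            mu = np.asarray(self.mu, dtype=np.float64)
            if mu.shape != delta.shape:
                raise ValueError("mu shape must match delta")
            if np.any(mu < 0):
                raise ValueError("mu must be non-negative")
            object.__setattr__(self, "mu", mu)
        if self.mask is not None:
            mask = np.asarray(self.mask, dtype=bool)
            if mask.shape != delta.shape:
                raise ValueError("mask shape must match delta")
            object.__setattr__(self, "mask", mask)

    @property
    def shape(self) -> tuple:
        return self.delta.shape


def _ellipse(xx, yy, cx, cy, ax, ay, theta):
    ct, st = np.cos(theta), np.sin(theta)
    u = (xx - cx) * ct + (yy - cy) * st
    v = -(xx - cx) * st + (yy - cy) * ct
    return (u / ax) ** 2 + (v / ay) ** 2 <= 1.0


def make_breast_phantom(
    shape: tuple,
    n_inclusions: int = 5,
    seed: int = 0,
    delta_range: tuple = (0.0, 1.0),
    smooth_sigma: float = 0.8,
) -> PhantomImage:
    """Generate a piecewise-smooth breast-like delta phantom.

    A large smooth ellipse of adipose-like background delta contains
    ``n_inclusions`` randomly placed ellipses with contrasting delta drawn
    within ``delta_range``. A paired mu map is produced by a fixed affine
    rescaling of delta. Deterministic given ``seed``.

    Parameters
    ----------
    shape : (rows, cols)
    n_inclusions : int
        Number of contrasting elliptical inclusions (>= 0).
    seed : int
        RNG seed; the phantom is a pure function of (arguments, seed).
    delta_range : (lo, hi)
        Bounds of the generated delta values, lo >= 0, hi > lo.
    smooth_sigma : float
        Gaussian smoothing (pixels) applied inside the support to keep the
        phantom piecewise smooth; edges at the support boundary stay sharp.
    """
    shape = tuple(int(s) for s in shape)
    if len(shape) != 2 or min(shape) < 8:
        raise ValueError("shape must be 2D with sides >= 8")
    if n_inclusions < 0:
        raise ValueError("n_inclusions must be >= 0")
    lo, hi = float(delta_range[0]), float(delta_range[1])
    if not (lo >= 0 and hi > lo):
        raise ValueError("delta_range must satisfy 0 <= lo < hi")

    rng = np.random.default_rng(seed)
    rows, cols = shape
    yy, xx = np.mgrid[0:rows, 0:cols].astype(np.float64)
    cy, cx = (rows - 1) / 2.0, (cols - 1) / 2.0

    # outer support: a big ellipse filling ~80% of the field of view
    support = _ellipse(xx, yy, cx, cy, 0.42 * cols, 0.42 * rows, 0.0)
    background = lo + 0.45 * (hi - lo)
    delta = np.where(support, background, 0.0)

    for _ in range(n_inclusions):
        # rejection-free placement inside the support ellipse
        r = 0.30 * np.sqrt(rng.uniform()) * min(rows, cols)
        ang = rng.uniform(0, 2 * np.pi)
        icx = cx + r * np.cos(ang)
        icy = cy + r * np.sin(ang)
        ax = rng.uniform(0.03, 0.12) * cols
        ay = rng.uniform(0.03, 0.12) * rows
        theta = rng.uniform(0, np.pi)
        # contrast alternates above/below background within the range
        if rng.uniform() < 0.5:
            value = rng.uniform(lo + 0.75 * (hi - lo), hi)
        else:
            value = rng.uniform(lo, lo + 0.2 * (hi - lo))
        inc = _ellipse(xx, yy, icx, icy, ax, ay, theta) & support
        delta[inc] = value

    if smooth_sigma > 0:
        smoothed = ndimage.gaussian_filter(delta, smooth_sigma)
        # keep the exterior exactly zero: sharp support edge drives wrapping
        delta = np.where(support, smoothed, 0.0)
    delta = np.clip(delta, lo, hi)
    delta[~support] = 0.0

    scale = hi if hi > 0 else 1.0
    mu = np.where(support, _MU_OFFSET + _MU_SLOPE * delta / scale, 0.0)
    return PhantomImage(delta=delta, mu=mu, mask=support)


def make_disk_phantom(
    shape: tuple,
    radius: float,
    delta_value: float = 1.0,
    pixel_size: float = 0.1,
) -> PhantomImage:
    """Centered binary disk times ``delta_value`` — the analytic test object.

    ``radius`` is in mm and must be positive and fit in the field of view.
    """
    shape = tuple(int(s) for s in shape)
    if radius <= 0:
        raise ValueError("radius must be positive")
    rows, cols = shape
    if radius > 0.5 * pixel_size * min(rows, cols):
        raise ValueError("radius does not fit in the field of view")
    yy, xx = np.mgrid[0:rows, 0:cols].astype(np.float64)
    x = (xx - (cols - 1) / 2.0) * pixel_size
    y = (yy - (rows - 1) / 2.0) * pixel_size
    mask = x**2 + y**2 <= radius**2
    delta = np.where(mask, float(delta_value), 0.0)
    return PhantomImage(delta=delta, mask=mask)
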