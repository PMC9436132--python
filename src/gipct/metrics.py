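"""Image-quality metrics: PSNR, SSIM, ROI-based SNR and CNR.

Definitions are printed with every report because SNR/CNR conventions vary
across the literature:

    PSNR = 10 log10(data_range^2 / MSE)             [dB]
    SNR  = mean(roi1) / std(roi1)
    CNR  = |mean(roi1) - mean(roi2)| / sqrt((var(roi1) + var(roi2)) / 2)

SSIM is the standard structural similarity index with a 7x7 uniform window
and sample-covariance normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = ["MetricReport", "psnr", "ssim", "snr_cnr"]

METRIC_DEFINITIONS = {
    "psnr": "10*log10(data_range**2 / mean((x - ref)**2)) [dB]",
    "ssim": "structural similarity, 7x7 uniform window, sample covariance, K1=0.01 K2=0.03",
    "snr": "mean(roi1) / std(roi1)  (population std)",
    "cnr": "|mean(roi1) - mean(roi2)| / sqrt((var(roi1) + var(roi2)) / 2)",
}


@dataclass
class MetricReport:
    """Bundle of image metrics plus the ROI rectangles and the metric
    definitions used (to avoid silent convention mismatch)."""

    psnr: float
    ssim: float
    snr: float | None = None
    cnr: float | None = None
    roi1: tuple | None = None
    roi2: tuple | None = None
    definitions: dict = field(default_factory=lambda: dict(METRIC_DEFINITIONS))


def psnr(x: np.ndarray, ref: np.ndarray, data_range: float | None = None) -> float:
    """Peak signal-to-noise ratio in dB; inf for identical images.

    ``data_range`` defaults to ref.max() - ref.min().
    """
    x = np.asarray(x, dtype=np.float64)
    ref = np.asarray(ref, dtype=np.float64)
    if x.shape != ref.shape:
        raise ValueError("shapes must match")
    if data_range is None:
        data_range = float(ref.max() - ref.min())
    if data_range <= 0:
        raise ValueError("data_range must be positive")
    mse = float(np.mean((x - ref) ** 2))
    if mse == 0.0:
        return float("inf")
    return 10.0 * np.log10(data_range**2 / mse)


def ssim(x: np.ndarray, ref: np.ndarray, data_range: float | None = None, win_size: int = 7, k1: float = 0.01, k2: float = 0.03) -> float:
    """Mean structural similarity index over a uniform sliding window.

    Matches the common reference implementation: sample-covariance
    normalization (N/(N-1)) and a border crop of win_size//2.
    """
    x = np.asarray(x, dtype=np.float64)
    ref = np.asarray(ref, dtype=np.float64)
    if x.shape != ref.shape:
        raise ValueError("shapes must match")
    if data_range is None:
        data_range = float(ref.max() - ref.min()) or 1.0
    npix = win_size**2
    cov_norm = npix / (npix - 1)
    filt = lambda a: ndimage.uniform_filter(a, size=win_size)
    ux, ur = filt(x), filt(ref)
    uxx, urr, uxr = filt(x * x), filt(ref * ref), filt(x * ref)
    vx = cov_norm * (uxx - ux * ux)
    vr = cov_norm * (urr - ur * ur)
    vxr = cov_norm * (uxr - ux * ur)
    c1 = (k1 * data_range) ** 2
    c2 = (k2 * data_range) ** 2
    s = ((2 * ux * ur + c1) * (2 * vxr + c2)) / ((ux**2 + ur**2 + c1) * (vx + vr + c2))
    pad = (win_size - 1) // 2
    return float(s[pad:-pad, pad:-pad].mean())


def _roi_slice(image: np.ndarray, roi: tuple) -> np.ndarray:
    r0, r1, c0, c1 = roi
    if not (0 <= r0 < r1 <= image.shape[0] and 0 <= c0 < c1 <= image.shape[1]):
        raise ValueError(f"ROI {roi} outside image of shape {image.shape}")
    return image[r0:r1, c0:c1]


def snr_cnr(x: np.ndarray, roi1: tuple, roi2: tuple):
    """ROI-based SNR and CNR; rectangles are (row0, row1, col0, col1).

    The ROIs must lie inside the image and not overlap. Zero variance in
    roi1 yields an infinite SNR (flagged as inf, not an error).
    """
    x = np.asarray(x, dtype=np.float64)
    a = _roi_slice(x, roi1)
    b = _roi_slice(x, roi2)
    r0a, r1a, c0a, c1a = roi1
    r0b, r1b, c0b, c1b = roi2
    if (r0a < r1b and r0b < r1a) and (c0a < c1b and c0b < c1a):
        raise ValueError("ROIs must not overlap")
    sa, sb = a.std(), b.std()
    snr = float("inf") if sa == 0 else float(a.mean() / sa)
    pooled = np.sqrt((a.var() + b.var()) / 2.0)
    cnr = float("inf") if pooled == 0 else float(abs(a.mean() - b.mean()) / pooled)
    return snr, cnr
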