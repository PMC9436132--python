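"""Acquisition geometry for 2D grating-interferometry CT.

Coordinate convention: pixel centers sit on a Cartesian grid centered at the
isocenter. Array index ``[0, 0]`` is the top-left pixel; ``x`` increases with
the column index and is the differentiation direction (perpendicular to the
grating lines); ``y`` increases downward with the row index. All lengths are
in millimetres unless noted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ScanGeometry", "InterferometerSpec", "parallel_geometry", "fan_geometry"]


@dataclass(frozen=True)
class ScanGeometry:
    """2D scan description for parallel- or fan-beam acquisition.

    Parameters
    ----------
    mode : {"parallel", "fan"}
        Beam geometry. Fan mode requires positive source-isocenter distance.
    angles : ndarray
        Strictly increasing rotation angles in radians.
    n_det : int
        Number of detector columns.
    det_pitch : float
        Detector element width (mm).
    pixel_size : float
        Image pixel pitch (mm).
    image_shape : tuple of int
        (rows, cols) of the reconstruction grid.
    src_iso, iso_det : float
        Source-to-isocenter and isocenter-to-detector distances (mm), fan only.
    """

    mode: str
    angles: np.ndarray
    n_det: int
    det_pitch: float
    pixel_size: float
    image_shape: tuple
    src_iso: float = 0.0
    iso_det: float = 0.0

    def __post_init__(self):
        if self.mode not in ("parallel", "fan"):
            raise ValueError(f"mode must be 'parallel' or 'fan', got {self.mode!r}")
        angles = np.asarray(self.angles, dtype=np.float64)
        if angles.ndim != 1 or angles.size < 1:
            raise ValueError("angles must be a non-empty 1D array")
        if angles.size > 1 and not np.all(np.diff(angles) > 0):
            raise ValueError("angles must be strictly increasing")
        object.__setattr__(self, "angles", angles)
        if self.n_det < 1:
            raise ValueError("n_det must be >= 1")
        if self.det_pitch <= 0:
            raise ValueError("det_pitch must be positive")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        shape = tuple(int(s) for s in self.image_shape)
        if len(shape) != 2 or min(shape) < 1:
            raise ValueError("image_shape must be (rows, cols) with positive entries")
        object.__setattr__(self, "image_shape", shape)
        if self.mode == "fan":
            if self.src_iso <= 0:
                raise ValueError("fan mode requires src_iso > 0")
            if self.iso_det < 0:
                raise ValueError("fan mode requires iso_det >= 0")

    @property
    def n_angles(self) -> int:
        return int(self.angles.size)

    @property
    def sino_shape(self) -> tuple:
        return (self.n_angles, self.n_det)

    def detector_coords(self) -> np.ndarray:
        """Centered detector-element coordinates along the detector (mm)."""
        m = np.arange(self.n_det, dtype=np.float64)
        return (m - (self.n_det - 1) / 2.0) * self.det_pitch

    def pixel_centers(self) -> tuple:
        """(x, y) coordinates of all pixel centers (mm), each of image_shape.

        x increases with column index, y increases downward with row index,
        origin at the isocenter.
        """
        rows, cols = self.image_shape
        j = np.arange(cols, dtype=np.float64)
        i = np.arange(rows, dtype=np.float64)
        x = (j - (cols - 1) / 2.0) * self.pixel_size
        y = (i - (rows - 1) / 2.0) * self.pixel_size
        return np.meshgrid(x, y)


@dataclass(frozen=True)
class InterferometerSpec:
    """Talbot-Lau interferometer sensitivity constants.

    The retrieved fringe phase relates to the refraction angle
    alpha = d/dx integral(delta dl) through the G2 pitch and the
    origin-to-G2 distance: phi = 2*pi*d2/g2 * alpha.

    Parameters
    ----------
    wavelength : float
        Design X-ray wavelength (m).
    d2 : float
        Distance from the sample (origin) to the analyzer grating G2 (m).
    g2 : float
        G2 grating pitch (m).
    """

    wavelength: float = 2.7e-11
    d2: float = 0.4
    g2: float = 4.2e-6

    def __post_init__(self):
        for name in ("wavelength", "d2", "g2"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be finite and positive")

    @property
    def sensitivity(self) -> float:
        """lambda * d2 / g2 (m) — the conventional sensitivity length."""
        return self.wavelength * self.d2 / self.g2

    @property
    def fringe_sensitivity(self) -> float:
        """2*pi*d2/g2, dimensionless factor mapping the refraction angle
        (itself d/dx of the delta line integral, per-mm derivative of a
        mm-integral, hence dimensionless) to fringe phase in radians."""
        return 2.0 * np.pi * self.d2 / self.g2


def parallel_geometry(
    image_side: int,
    n_angles: int,
    *,
    n_det: int | None = None,
    pixel_size: float = 0.1,
    det_pitch: float | None = None,
) -> ScanGeometry:
    """Convenience parallel-beam geometry: uniform angles over [0, pi)."""
    if n_det is None:
        n_det = image_side
    if det_pitch is None:
        det_pitch = pixel_size
    angles = np.arange(n_angles) * (np.pi / n_angles)
    return ScanGeometry(
        mode="parallel",
        angles=angles,
        n_det=n_det,
        det_pitch=det_pitch,
        pixel_size=pixel_size,
        image_shape=(image_side, image_side),
    )


def fan_geometry(
    image_side: int,
    n_angles: int,
    *,
    src_iso: float = 50.0,
    iso_det: float = 50.0,
    n_det: int | None = None,
    pixel_size: float = 0.1,
    det_pitch: float | None = None,
) -> ScanGeometry:
    """Convenience fan-beam geometry: uniform angles over [0, 2*pi)."""
    if n_det is None:
        # widen the detector to cover the magnified field of view
        mag = (src_iso + iso_det) / src_iso
        n_det = int(np.ceil(image_side * mag)) + 4
    if det_pitch is None:
        det_pitch = pixel_size
    angles = np.arange(n_angles) * (2.0 * np.pi / n_angles)
    return ScanGeometry(
        mode="fan",
        angles=angles,
        n_det=n_det,
        det_pitch=det_pitch,
        pixel_size=pixel_size,
        image_shape=(image_side, image_side),
        src_iso=src_iso,
        iso_det=iso_det,
    )
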