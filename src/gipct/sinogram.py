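"""Differential phase-contrast sinogram container."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import ScanGeometry

__all__ = ["DPCSinogram"]


@dataclass
class DPCSinogram:
    """Retrieved differential-phase projections in radians.

    ``phi`` has shape (n_angles, n_det). When produced by Fourier retrieval
    the values are wrapped to the principal branch (-pi, pi]; intermediate
    (unwrapped) model sinograms may exceed it. ``mask`` marks valid elements
    (False where retrieval flagged a dead pixel).
    """

    phi: np.ndarray
    geometry: ScanGeometry
    mask: np.ndarray | None = None

    def __post_init__(self):
        phi = np.asarray(self.phi, dtype=np.float64)
        if phi.shape != self.geometry.sino_shape:
            raise ValueError(
                f"phi shape {phi.shape} does not match geometry {self.geometry.sino_shape}"
            )
        if not np.all(np.isfinite(phi)):
            raise ValueError("phi must be finite")
        self.phi = phi
        if self.mask is not None:
            mask = np.asarray(self.mask, dtype=bool)
            if mask.shape != phi.shape:
                raise ValueError("mask shape must match phi")
            self.mask = mask

    @property
    def shape(self) -> tuple:
        return self.phi.shape
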