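"""Talbot-Lau phase-stepping simulation and Fourier retrieval.

The stepping curve per detector element is the sinusoid

    I_k = I0 * T * (1 + V0 * D * cos(k + Phi0 - phi)),

where k is the fringe phase of the k-th grating position, T the sample
transmission, D the dark-field visibility reduction and phi the
differential phase. Counts are Poisson draws with those means. Retrieval
takes the DFT of the stack along the step axis for both sample and flat
stacks and reads T from the zeroth harmonics, D from the visibility ratio
and phi from the first-harmonic argument difference, wrapped to (-pi, pi].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import InterferometerSpec, ScanGeometry
from .phantoms import PhantomImage
from .sinogram import DPCSinogram

__all__ = [
    "FlatFieldMaps",
    "PhaseSteppingStack",
    "RetrievedSignals",
    "wrap_phase",
    "simulate_phase_stepping",
    "retrieve_signals",
]


def wrap_phase(x):
    """Wrap phase(s) to the principal branch (-pi, pi]."""
    x = np.asarray(x, dtype=np.float64)
    if not np.all(np.isfinite(x)):
        raise ValueError("phase must be finite")
    wrapped = np.mod(-x + np.pi, 2.0 * np.pi)
    wrapped = np.pi - wrapped  # maps to (-pi, pi]
    if wrapped.ndim == 0:
        return float(wrapped)
    return wrapped


@dataclass
class FlatFieldMaps:
    """Per-element flat intensity I0 (counts), visibility V0 in (0, 1] and
    reference fringe phase Phi0 in (-pi, pi]."""

    I0: np.ndarray
    V0: np.ndarray
    Phi0: np.ndarray

    def __post_init__(self):
        self.I0 = np.asarray(self.I0, dtype=np.float64)
        self.V0 = np.asarray(self.V0, dtype=np.float64)
        self.Phi0 = np.asarray(self.Phi0, dtype=np.float64)
        if np.any(self.I0 <= 0):
            raise ValueError("I0 must be positive")
        if np.any((self.V0 <= 0) | (self.V0 > 1)):
            raise ValueError("V0 must lie in (0, 1]")
        if np.any((self.Phi0 <= -np.pi) | (self.Phi0 > np.pi)):
            raise ValueError("Phi0 must lie in (-pi, pi]")

    @classmethod
    def constant(
        cls,
        sino_shape: tuple,
        photons: float = 120000.0,
        visibility: float = 0.15,
        phi0: float = 0.0,
        rng: np.random.Generator | None = None,
        phi0_smooth_amplitude: float = 0.0,
    ) -> "FlatFieldMaps":
        """Spatially constant maps, optionally with a smooth random Phi0 field."""
        I0 = np.full(sino_shape, float(photons))
        V0 = np.full(sino_shape, float(visibility))
        Phi0 = np.full(sino_shape, float(phi0))
        if phi0_smooth_amplitude > 0:
            if rng is None:
                rng = np.random.default_rng(0)
            n_det = sino_shape[-1]
            coarse = rng.uniform(-1, 1, max(4, n_det // 16))
            fine = np.interp(
                np.linspace(0, 1, n_det), np.linspace(0, 1, coarse.size), coarse
            )
            Phi0 = Phi0 + phi0_smooth_amplitude * fine[None, :]
        return cls(I0=I0, V0=V0, Phi0=wrap_phase(Phi0))


@dataclass
class PhaseSteppingStack:
    """Counts of shape (n_steps, n_angles, n_det) with the grating positions
    expressed as fringe phases in [0, 2*pi)."""

    counts: np.ndarray
    step_phases: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.float64)
        self.step_phases = np.asarray(self.step_phases, dtype=np.float64)
        if self.counts.ndim != 3:
            raise ValueError("counts must have shape (n_steps, n_angles, n_det)")
        if self.step_phases.shape != (self.counts.shape[0],):
            raise ValueError("step_phases length must equal n_steps")
        if self.counts.shape[0] < 3:
            raise ValueError("need at least 3 phase steps")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        d = np.diff(self.step_phases)
        if np.any(d <= 0) or self.step_phases[0] < 0 or self.step_phases[-1] >= 2 * np.pi:
            raise ValueError("step_phases must be strictly increasing within [0, 2*pi)")

    @property
    def n_steps(self) -> int:
        return int(self.counts.shape[0])


@dataclass
class RetrievedSignals:
    """Transmission T, dark-field D and wrapped differential phase phi,
    with a validity mask (False where a dead pixel was flagged)."""

    T: np.ndarray
    D: np.ndarray
    phi: np.ndarray
    mask: np.ndarray


def _stepping_means(T, D, phi, flats: FlatFieldMaps, step_phases):
    k = step_phases[:, None, None]
    return flats.I0 * T * (1.0 + flats.V0 * D * np.cos(k + flats.Phi0 - phi))


def simulate_phase_stepping(
    phantom: PhantomImage,
    geometry: ScanGeometry,
    interferometer: InterferometerSpec | None = None,
    flats: FlatFieldMaps | None = None,
    n_steps: int = 5,
    photons: float = 120000.0,
    seed: int = 0,
    dark_field=None,
    noise: bool = True,
    operator=None,
):
    """Simulate sample and flat phase-stepping stacks.

    Computes line integrals of mu (transmission T), an optional dark-field
    epsilon map (D, else D = 1) and the DPC forward projection of delta
    (phi, via the Kaiser-Bessel operator pair), evaluates the stepping
    sinusoid at each grating position and draws Poisson counts with those
    means. Deterministic given ``seed``; ``noise=False`` returns the exact
    means (the infinite-photon limit).

    Returns
    -------
    (sample, flat) : tuple of PhaseSteppingStack
    """
    from .operators import DPCOperatorPair, FDOperatorPair

    if phantom.shape != geometry.image_shape:
        raise ValueError("phantom shape does not match geometry")
    if n_steps < 3:
        raise ValueError("need at least 3 phase steps")
    if photons <= 0:
        raise ValueError("photons must be positive")
    if interferometer is None:
        interferometer = InterferometerSpec()
    if operator is None:
        operator = DPCOperatorPair(geometry=geometry, interferometer=interferometer)
    if flats is None:
        flats = FlatFieldMaps.constant(geometry.sino_shape, photons=photons)

    phi = operator.forward(phantom.delta)

    # transmission from the attenuation line integral (unweighted ray sum
    # times the pixel-area quadrature of the same ray-sum projector)
    if phantom.mu is not None and np.any(phantom.mu > 0):
        ray_sum = FDOperatorPair(geometry=geometry, scale=1.0)
        mu_li = ray_sum._radon(phantom.mu.ravel())
        T = np.exp(-mu_li)
    else:
        T = np.ones(geometry.sino_shape)

    if dark_field is not None:
        ray_sum = FDOperatorPair(geometry=geometry, scale=1.0)
        eps_li = ray_sum._radon(np.asarray(dark_field, dtype=np.float64).ravel())
        D = np.exp(-eps_li)
    else:
        D = np.ones(geometry.sino_shape)

    # uniform grating positions make the two-harmonic DFT retrieval exact
    step_phases = 2.0 * np.pi * np.arange(n_steps) / n_steps

    sample_means = _stepping_means(T, D, phi, flats, step_phases)
    flat_means = _stepping_means(1.0, 1.0, 0.0, flats, step_phases)

    if noise:
        rng = np.random.default_rng(seed)
        sample_counts = rng.poisson(sample_means).astype(np.float64)
        flat_counts = rng.poisson(flat_means).astype(np.float64)
    else:
        sample_counts = sample_means
        flat_counts = flat_means

    return (
        PhaseSteppingStack(counts=sample_counts, step_phases=step_phases),
        PhaseSteppingStack(counts=flat_counts, step_phases=step_phases),
    )


def retrieve_signals(sample: PhaseSteppingStack, flat: PhaseSteppingStack) -> RetrievedSignals:
    """Fourier retrieval of (T, D, phi) from sample and flat stacks.

    The DFT along the step axis yields the zeroth (a0) and first (a1)
    harmonics per element. T = a0_sample / a0_flat; visibility V =
    2|a1|/a0 per stack; D = V_sample / V_flat; phi = wrap(arg(a1_flat) -
    arg(a1_sample)), the sign chosen so retrieval inverts the simulator.
    Elements with a vanishing a0 (dead pixels) are flagged False in the
    mask and set to sentinel values T=0, D=0, phi=0.
    """
    if sample.counts.shape != flat.counts.shape:
        raise ValueError("sample and flat stacks must have matching shapes")
    if not np.allclose(sample.step_phases, flat.step_phases):
        raise ValueError("sample and flat stacks must share step_phases")

    def harmonics(stack: PhaseSteppingStack):
        phase = stack.step_phases[:, None, None]
        n = stack.n_steps
        a0 = np.sum(stack.counts, axis=0) / n
        a1 = np.sum(stack.counts * np.exp(-1j * phase), axis=0) / n
        return a0, a1

    a0_s, a1_s = harmonics(sample)
    a0_f, a1_f = harmonics(flat)

    ok = (a0_s > 0) & (a0_f > 0)
    a0_s_safe = np.where(ok, a0_s, 1.0)
    a0_f_safe = np.where(ok, a0_f, 1.0)

    T = np.where(ok, a0_s / a0_f_safe, 0.0)
    v_s = 2.0 * np.abs(a1_s) / a0_s_safe
    v_f = 2.0 * np.abs(a1_f) / a0_f_safe
    v_f_safe = np.where(v_f > 0, v_f, 1.0)
    D = np.where(ok & (v_f > 0), v_s / v_f_safe, 0.0)
    # I_k ~ cos(k + Phi0 - phi): the first harmonic of the sample stack has
    # argument -(Phi0 - phi), of the flat stack -Phi0; their difference is -phi
    phi = np.where(ok, wrap_phase(np.angle(a1_f) - np.angle(a1_s)), 0.0)
    return RetrievedSignals(T=T, D=D, phi=phi, mask=ok)


def retrieve_dpc_sinogram(
    sample: PhaseSteppingStack, flat: PhaseSteppingStack, geometry: ScanGeometry
) -> DPCSinogram:
    """Convenience: retrieval returning only the wrapped DPC sinogram."""
    ret = retrieve_signals(sample, flat)
    return DPCSinogram(phi=ret.phi, geometry=geometry, mask=ret.mask)
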