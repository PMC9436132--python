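"""Iterative DPC-CT reconstruction.

The core solver alternates k_max L-BFGS updates of the quadratic data term
1/2 ||A delta - phi||^2 with one application of the certified non-expansive
denoiser (Plug-and-Play), restarting the quasi-Newton memory empty at every
outer iteration so the scheme is a meta-algorithm that re-runs L-BFGS from
ever better starting points. Comparators: plain PnP gradient descent,
Hilbert-filter filtered backprojection, a TV/Chambolle iterative baseline
and FBP followed by denoiser post-processing.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage.restoration import denoise_tv_chambolle

from .geometry import ScanGeometry
from .sinogram import DPCSinogram
from .stepping import PhaseSteppingStack, retrieve_signals

logger = logging.getLogger(__name__)

__all__ = [
    "LBFGSMemory",
    "ReconConfig",
    "ReconResult",
    "data_fidelity_and_grad",
    "lbfgs_direction",
    "pnp_lbfgs",
    "pnp_gd",
    "fbp_hilbert",
    "tv_reconstruct",
    "postprocess_fbp",
    "estimate_noise_level",
]


class LBFGSMemory:
    """Bounded store of (s, y) curvature pairs with a positivity guard.

    Pairs with s^T y <= tol * ||s|| ||y|| are refused (they would break the
    positive definiteness of the implicit inverse-Hessian estimate).
    """

    def __init__(self, capacity: int = 14, curvature_tol: float = 1e-12):
        if capacity < 1:
            raise ValueError("capacity must be >= 1")
        self.capacity = capacity
        self.curvature_tol = curvature_tol
        self.s: list = []
        self.y: list = []

    def __len__(self):
        return len(self.s)

    def push(self, s: np.ndarray, y: np.ndarray) -> bool:
        sy = float(np.sum(s * y))
        if sy <= self.curvature_tol * np.linalg.norm(s) * np.linalg.norm(y):
            return False
        self.s.append(s.copy())
        self.y.append(y.copy())
        if len(self.s) > self.capacity:
            self.s.pop(0)
            self.y.pop(0)
        return True

    def clear(self):
        self.s.clear()
        self.y.clear()


@dataclass
class ReconConfig:
    """Algorithm parameters: k_max inner data updates per outer iteration,
    stopping threshold epsilon_n on the data loss, a safety cap on outer
    iterations and Armijo line-search constants."""

    k_max: int = 15
    epsilon_n: float = 0.0
    max_outer: int = 50
    memory: int = 14
    armijo_c1: float = 1e-4
    backtrack_factor: float = 0.5
    max_backtracks: int = 40
    seed: int = 0

    def __post_init__(self):
        if self.k_max < 1:
            raise ValueError("k_max must be >= 1")
        if self.epsilon_n < 0:
            raise ValueError("epsilon_n must be >= 0")


@dataclass
class ReconResult:
    """Reconstruction output: the regularized image, the per-update data
    loss trace, iteration counts and the configuration snapshot."""

    delta_reg: np.ndarray
    loss_trace: list
    outer_count: int
    inner_count: int
    converged: bool
    config: ReconConfig
    outer_starts: list = field(default_factory=list)


def data_fidelity_and_grad(delta: np.ndarray, phi, op):
    """Data term 1/2 ||A delta - phi||^2 and its gradient A^T(A delta - phi).

    Masked sinogram elements (dead pixels flagged by retrieval) are
    excluded from both the loss and the gradient.
    """
    delta = np.asarray(delta, dtype=np.float64)
    if not np.all(np.isfinite(delta)):
        raise ValueError("delta must be finite")
    mask = None
    if isinstance(phi, DPCSinogram):
        mask = phi.mask
        phi_arr = phi.phi
    else:
        phi_arr = np.asarray(phi, dtype=np.float64)
    resid = op.forward(delta) - phi_arr
    if mask is not None:
        resid = np.where(mask, resid, 0.0)
    loss = 0.5 * float(np.sum(resid**2))
    grad = op.adjoint(resid)
    return loss, grad


def lbfgs_direction(gradient: np.ndarray, memory: LBFGSMemory) -> np.ndarray:
    """Two-loop recursion; empty memory returns the negative gradient.

    Uses the standard gamma = s^T y / y^T y initial Hessian scaling. The
    returned direction is a descent direction (d^T g < 0) whenever the
    stored pairs satisfy the curvature condition.
    """
    q = gradient.copy()
    if len(memory) == 0:
        return -q
    alphas = []
    rhos = []
    for s, y in zip(reversed(memory.s), reversed(memory.y)):
        rho = 1.0 / float(np.sum(y * s))
        alpha = rho * float(np.sum(s * q))
        q = q - alpha * y
        alphas.append(alpha)
        rhos.append(rho)
    s_last, y_last = memory.s[-1], memory.y[-1]
    gamma = float(np.sum(s_last * y_last)) / float(np.sum(y_last * y_last))
    r = gamma * q
    for (s, y), alpha, rho in zip(zip(memory.s, memory.y), reversed(alphas), reversed(rhos)):
        beta = rho * float(np.sum(y * r))
        r = r + (alpha - beta) * s
    return -r


def _loss_only(delta, phi, op) -> float:
    mask = phi.mask if isinstance(phi, DPCSinogram) else None
    phi_arr = phi.phi if isinstance(phi, DPCSinogram) else np.asarray(phi)
    resid = op.forward(delta) - phi_arr
    if mask is not None:
        resid = np.where(mask, resid, 0.0)
    return 0.5 * float(np.sum(resid**2))


def _armijo(delta, direction, loss, grad, phi, op, config: ReconConfig):
    """Backtracking line search from unit step; returns (step, new point,
    new loss). Falls back to the last tried step on failure."""
    slope = float(np.sum(grad * direction))
    if slope >= 0:  # not a descent direction: revert to steepest descent
        direction = -grad
        slope = -float(np.sum(grad * grad))
    step = 1.0
    for _ in range(config.max_backtracks):
        cand = delta + step * direction
        new_loss = _loss_only(cand, phi, op)
        if new_loss <= loss + config.armijo_c1 * step * slope:
            return step, cand, new_loss
        step *= config.backtrack_factor
    return step, delta + step * direction, None


def _pnp_outer_loop(phi, op, denoiser, config: ReconConfig, use_lbfgs: bool) -> ReconResult:
    geometry = op.geometry
    delta = np.zeros(geometry.image_shape)
    delta_reg = delta
    loss_trace: list = []
    outer_starts: list = []
    outer = 0
    inner = 0
    stagnant = 0
    converged = False
    memory = LBFGSMemory(capacity=config.memory)

    while outer < config.max_outer:
        loss_now = _loss_only(delta_reg if outer > 0 else delta, phi, op)
        if loss_now < config.epsilon_n:
            converged = True
            break
        memory.clear()
        if outer > 0:
            delta = delta_reg
        outer_starts.append(len(loss_trace))
        prev_delta = None
        prev_grad = None
        loss_at_outer_start = None
        for k in range(config.k_max):
            loss, grad = data_fidelity_and_grad(delta, phi, op)
            if k == 0:
                loss_at_outer_start = loss
            loss_trace.append(loss)
            if use_lbfgs and k > 0:
                memory.push(delta - prev_delta, grad - prev_grad)
            direction = lbfgs_direction(grad, memory) if use_lbfgs else -grad
            prev_delta, prev_grad = delta, grad
            step, delta, new_loss = _armijo(delta, direction, loss, grad, phi, op, config)
            inner += 1
            if new_loss is None:
                logger.warning("line search failed at outer %d inner %d", outer, k)
        outer += 1
        delta_reg = denoiser(delta) if denoiser is not None else delta
        end_loss = _loss_only(delta_reg, phi, op)
        # stagnation guard: several consecutive outer iterations without any
        # decrease of the data loss means the solver sits at its PnP fixed
        # point (or diverges); stop with a warning rather than spin
        if loss_at_outer_start is not None and end_loss > loss_at_outer_start * (1.0 + 1e-12):
            stagnant += 1
            if stagnant >= 3:
                warnings.warn("data loss did not decrease across 3 outer iterations; stopping")
                break
        else:
            stagnant = 0
    final_loss = _loss_only(delta_reg, phi, op)
    if final_loss < config.epsilon_n:
        converged = True
    return ReconResult(
        delta_reg=delta_reg,
        loss_trace=loss_trace,
        outer_count=outer,
        inner_count=inner,
        converged=converged,
        config=config,
        outer_starts=outer_starts,
    )


def pnp_lbfgs(phi, op, denoiser=None, config: ReconConfig | None = None, certified_product: float | None = None) -> ReconResult:
    """Plug-and-Play L-BFGS reconstruction.

    Outer loop: run ``k_max`` L-BFGS data updates (curvature memory reset
    at every outer start), then apply the denoiser once; starting from the
    all-zero image, restarting from the denoised iterate, and stopping when
    the data loss falls below ``epsilon_n``. ``denoiser`` is any callable
    image -> image (identity when None). If ``certified_product`` is given
    and exceeds 1 (plus tolerance), a warning is emitted — the convergence
    rationale assumes a non-expansive denoiser.
    """
    if config is None:
        config = ReconConfig()
    if certified_product is not None and certified_product > 1.0 + 1e-3:
        warnings.warn(
            f"denoiser certificate {certified_product:.4f} exceeds 1: non-expansiveness not guaranteed"
        )
    return _pnp_outer_loop(phi, op, denoiser, config, use_lbfgs=True)


def pnp_gd(phi, op, denoiser=None, config: ReconConfig | None = None) -> ReconResult:
    """Gradient-descent comparator: same outer structure as ``pnp_lbfgs``
    with the search direction fixed to the negative gradient."""
    if config is None:
        config = ReconConfig()
    return _pnp_outer_loop(phi, op, denoiser, config, use_lbfgs=False)


def fbp_hilbert(
    phi,
    geometry: ScanGeometry,
    sensitivity: float = 1.0,
    window: str = "hann",
    kb=None,
) -> np.ndarray:
    """Filtered backprojection with the Hilbert-type DPC filter.

    The differential data phi = c * dP/ds has Fourier transform
    c * (2*pi*i*nu) * FT(P); combining the inversion of that factor with
    the ramp |nu| of classical FBP yields the filter -i*sign(nu)/(2*pi*c)
    along the detector coordinate, optionally apodized with a Hann window.
    ``sensitivity`` is c (pass the operator pair's ``effective_sensitivity``
    so the output is on the phantom's delta scale). If ``kb`` (a KBProfile)
    is given, the blob footprint's transfer function is deconvolved as
    well, inverting the Kaiser-Bessel forward model rather than the ideal
    derivative ray transform. Parallel geometry only.
    """
    if isinstance(phi, DPCSinogram):
        phi = phi.phi
    phi = np.asarray(phi, dtype=np.float64)
    if geometry.mode != "parallel":
        raise ValueError("fbp_hilbert expects parallel geometry (rebin fan data first)")
    n_angles, n_det = phi.shape
    if n_angles < 8:
        warnings.warn("very few angles: FBP quality will be poor")
    npad = int(2 ** np.ceil(np.log2(2 * n_det)))
    nu = np.fft.fftfreq(npad, d=geometry.det_pitch)
    filt = -1j * np.sign(nu) / (2.0 * np.pi * sensitivity)
    if kb is not None:
        # transfer function of the normalized blob footprint along the
        # detector axis; floor guards against noise blow-up near its zeros
        h = np.trapezoid(
            kb.table_w[None, :] * np.cos(2.0 * np.pi * nu[:, None] * kb.grid[None, :]),
            kb.grid,
            axis=1,
        ) / kb.window_integral
        h_reg = np.where(h >= 0, 1.0, -1.0) * np.maximum(np.abs(h), 0.05)
        filt = filt / h_reg
    if window == "hann":
        filt = filt * (0.5 + 0.5 * np.cos(np.pi * nu / (np.abs(nu).max() or 1.0)))
    spec = np.fft.fft(phi, n=npad, axis=1) * filt[None, :]
    filtered = np.real(np.fft.ifft(spec, axis=1))[:, :n_det]

    xx, yy = geometry.pixel_centers()
    s = geometry.detector_coords()
    recon = np.zeros(geometry.image_shape)
    for a, theta in enumerate(geometry.angles):
        t = xx * np.cos(theta) + yy * np.sin(theta)
        recon += np.interp(t.ravel(), s, filtered[a], left=0.0, right=0.0).reshape(t.shape)
    # angular quadrature: d_theta over [0, pi), frequency integral measure
    recon *= np.pi / n_angles
    return recon


def tv_reconstruct(phi, op, tv_weight: float, n_outer: int = 10, config: ReconConfig | None = None) -> ReconResult:
    """Iterative baseline: data updates alternated with a TV proximal step.

    Structurally parallel to ``pnp_lbfgs`` with the denoiser replaced by
    the total-variation proximal operator, computed with Chambolle's dual
    projection algorithm. ``tv_weight`` is the TV denoising weight of the
    proximal step (must be positive).
    """
    if tv_weight <= 0:
        raise ValueError("tv_weight must be positive")
    if config is None:
        config = ReconConfig(max_outer=n_outer)
    else:
        config = ReconConfig(
            k_max=config.k_max,
            epsilon_n=config.epsilon_n,
            max_outer=n_outer,
            memory=config.memory,
            armijo_c1=config.armijo_c1,
            backtrack_factor=config.backtrack_factor,
            max_backtracks=config.max_backtracks,
            seed=config.seed,
        )

    def tv_prox(img):
        scale = np.abs(img).max()
        if scale == 0:
            return img
        return denoise_tv_chambolle(img / scale, weight=tv_weight / scale) * scale

    return _pnp_outer_loop(phi, op, tv_prox, config, use_lbfgs=True)


def postprocess_fbp(phi, geometry: ScanGeometry, denoiser, sensitivity: float = 1.0) -> np.ndarray:
    """FBP with the Hilbert filter followed by one denoiser application."""
    fbp = fbp_hilbert(phi, geometry, sensitivity=sensitivity)
    return denoiser(fbp) if denoiser is not None else fbp


def estimate_noise_level(flats, geometry: ScanGeometry, fallback: float | None = None) -> float:
    """Estimate epsilon_n, the noise floor of the data loss.

    Given a sequence of independently measured flat stacks, retrieves each
    against the first and accumulates the per-element variance of the
    retrieved phase; the expected value of 1/2 ||A delta* - phi_noisy||^2
    at the true image is approximately 1/2 * sum of those variances.
    A single flat realization carries no variance information: a
    user-supplied ``fallback`` is returned with a warning.
    """
    if isinstance(flats, PhaseSteppingStack):
        flats = [flats]
    flats = list(flats)
    if len(flats) < 2:
        if fallback is None:
            raise ValueError("need >= 2 flat realizations or an explicit fallback epsilon_n")
        warnings.warn("single flat realization: falling back to the supplied epsilon_n")
        return float(fallback)
    # disjoint pairs: a shared reference would make the retrieved phases
    # correlated and cancel the reference stack's own variance out of the
    # across-repetition estimate
    phis = []
    for i in range(0, len(flats) - 1, 2):
        ret = retrieve_signals(flats[i + 1], flats[i])
        phis.append(ret.phi)
    phis = np.stack(phis)
    # each retrieval mixes the noise of two independent stacks, exactly as a
    # sample-vs-flat retrieval does, so no variance rescaling is needed
    if len(phis) == 1:
        var = phis[0] ** 2  # single difference: E[phi^2] equals the variance
    else:
        var = np.var(phis, axis=0, ddof=1) + np.mean(phis, axis=0) ** 2
    return 0.5 * float(np.sum(var))
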