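"""Default in-silico study conditions.

Bundles the acquisition and simulation settings used throughout the
package's experiments: a desk-scale 2D parallel-beam scan of unit-rescaled
breast-like phantoms, the prototype-like Talbot-Lau sensitivity, a photon
budget of 120000 counts per flat exposure, low fringe visibility and 5
uniform phase steps. Under these conditions the retrieved sinograms are
dominated by visibility-limited phase noise, and high-contrast edges seen
tangentially push the true phase past +-pi, producing localized wrapping
artifacts — the data regime the reconstruction stack is designed for.

Images carry delta in units of ``delta_unit`` (array value 1.0 means a
physical refractive-index decrement of DELTA_UNIT); the operator scale
absorbs the unit, making this exactly equivalent to physical-scale maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import InterferometerSpec, ScanGeometry, parallel_geometry
from .operators import DPCOperatorPair, FDOperatorPair
from .phantoms import PhantomImage, make_breast_phantom
from .stepping import FlatFieldMaps, retrieve_dpc_sinogram, simulate_phase_stepping

__all__ = [
    "StudyConditions",
    "default_study",
    "make_study_phantoms",
    "make_training_set",
    "simulate_study_sinogram",
]

PHOTONS = 120000.0
VISIBILITY = 0.03
N_STEPS = 5
# Unit delta of the desk-scale phantoms. A clinical-size object (~100 mm) at
# delta ~ 1e-7 drives the retrieved phase past +-pi at its strongest edges; a
# 3.2 mm desk field at the same delta would stay far inside the principal
# branch. Scaling the represented delta by roughly the object-size ratio
# restores the regime of the full-scale problem: retrieved-phase noise from
# low fringe visibility dominates, while phase wrapping appears only at the
# strongest (tangential, high-contrast) edges.
DELTA_UNIT = 1.5e-6
PIXEL_SIZE = 0.1  # mm


@dataclass
class StudyConditions:
    """Geometry, interferometer and operator pair fixed for one study."""

    geometry: ScanGeometry
    interferometer: InterferometerSpec
    kb_op: DPCOperatorPair
    fd_op: FDOperatorPair
    photons: float = PHOTONS
    visibility: float = VISIBILITY
    n_steps: int = N_STEPS
    delta_unit: float = DELTA_UNIT

    def flats(self) -> FlatFieldMaps:
        return FlatFieldMaps.constant(
            self.geometry.sino_shape, photons=self.photons, visibility=self.visibility
        )


def default_study(image_side: int = 32, n_angles: int | None = None) -> StudyConditions:
    """Desk-scale parallel-beam study at the default conditions."""
    if n_angles is None:
        n_angles = (3 * image_side) // 2
    geometry = parallel_geometry(image_side, n_angles, pixel_size=PIXEL_SIZE)
    interferometer = InterferometerSpec()
    kb_op = DPCOperatorPair(geometry=geometry, interferometer=interferometer, delta_unit=DELTA_UNIT)
    fd_op = FDOperatorPair(geometry=geometry, interferometer=interferometer, delta_unit=DELTA_UNIT)
    return StudyConditions(
        geometry=geometry, interferometer=interferometer, kb_op=kb_op, fd_op=fd_op
    )


def make_study_phantoms(n: int, image_side: int = 32, seed: int = 0) -> list:
    """Family of unit-rescaled breast-like phantoms (delta in [0, 1])."""
    rng = np.random.default_rng(seed)
    phantoms = []
    for i in range(n):
        phantoms.append(
            make_breast_phantom(
                (image_side, image_side),
                n_inclusions=int(rng.integers(2, 7)),
                seed=int(rng.integers(0, 2**31 - 1)),
                delta_range=(0.0, 1.0),
            )
        )
    return phantoms


def make_training_set(study: StudyConditions, n_phantoms: int = 50, seed: int = 0, n_updates: int = 15) -> list:
    """Training pairs for the denoiser under the study conditions.

    Pairs are generated on the unit delta scale (where the reconstruction
    iterates live) and converted to physical delta units for training, so
    the Eq-16-style loss sees data at its physical magnitude; the bias-free
    network's positive homogeneity makes the two scales interchangeable at
    application time.
    """
    from .denoiser import TrainingPair, generate_training_pairs

    side = study.geometry.image_shape[0]
    phantoms = make_study_phantoms(n_phantoms, side, seed=seed)
    pairs = generate_training_pairs(
        phantoms,
        study.geometry,
        study.kb_op,
        interferometer=study.interferometer,
        flats=study.flats(),
        n_updates=n_updates,
        n_steps=study.n_steps,
        photons=study.photons,
        seed=seed + 1,
    )
    u = study.delta_unit
    return [TrainingPair(noisy=p.noisy * u, clean=p.clean * u) for p in pairs]


def simulate_study_sinogram(
    phantom: PhantomImage,
    study: StudyConditions,
    seed: int = 0,
    noise: bool = True,
):
    """Simulate one noisy scan and retrieve the wrapped DPC sinogram.

    Returns (retrieved sinogram, true unwrapped model sinogram).
    """
    sample, flat = simulate_phase_stepping(
        phantom,
        study.geometry,
        interferometer=study.interferometer,
        flats=study.flats(),
        n_steps=study.n_steps,
        photons=study.photons,
        seed=seed,
        noise=noise,
        operator=study.kb_op,
    )
    retrieved = retrieve_dpc_sinogram(sample, flat, study.geometry)
    phi_true = study.kb_op.forward(phantom.delta)
    return retrieved, phi_true
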