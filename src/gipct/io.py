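"""On-disk exchange: float32 TIFF for 2D images/sinograms, HDF5 for
phase-stepping stacks, denoiser weights and metadata sidecars."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import tifffile

from .geometry import ScanGeometry
from .nn import BiasFreeNet, ConvLayer, SpectralState
from .stepping import PhaseSteppingStack

__all__ = [
    "write_image",
    "read_image",
    "write_stack",
    "read_stack",
    "write_denoiser",
    "read_denoiser",
]


def write_image(path, array: np.ndarray, metadata: dict | None = None):
    """Single-page float32 TIFF; optional metadata goes to an HDF5 sidecar."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(array, dtype=np.float32))
    if metadata:
        with h5py.File(path.with_suffix(".h5"), "w") as fh:
            for k, v in metadata.items():
                fh.attrs[k] = json.dumps(v) if isinstance(v, (dict, list, tuple)) else v


def read_image(path) -> np.ndarray:
    return np.asarray(tifffile.imread(path), dtype=np.float64)


def _geometry_attrs(geometry: ScanGeometry) -> dict:
    return {
        "mode": geometry.mode,
        "angles": geometry.angles.tolist(),
        "n_det": geometry.n_det,
        "det_pitch": geometry.det_pitch,
        "pixel_size": geometry.pixel_size,
        "image_shape": list(geometry.image_shape),
        "src_iso": geometry.src_iso,
        "iso_det": geometry.iso_det,
    }


def write_stack(path, stack: PhaseSteppingStack, geometry: ScanGeometry | None = None):
    with h5py.File(path, "w") as fh:
        fh.create_dataset("counts", data=stack.counts)
        fh.create_dataset("step_phases", data=stack.step_phases)
        if geometry is not None:
            fh.attrs["geometry"] = json.dumps(_geometry_attrs(geometry))


def read_stack(path):
    with h5py.File(path, "r") as fh:
        stack = PhaseSteppingStack(
            counts=fh["counts"][()], step_phases=fh["step_phases"][()]
        )
        geometry = None
        if "geometry" in fh.attrs:
            g = json.loads(fh.attrs["geometry"])
            geometry = ScanGeometry(
                mode=g["mode"],
                angles=np.asarray(g["angles"]),
                n_det=g["n_det"],
                det_pitch=g["det_pitch"],
                pixel_size=g["pixel_size"],
                image_shape=tuple(g["image_shape"]),
                src_iso=g["src_iso"],
                iso_det=g["iso_det"],
            )
    return stack, geometry


def write_denoiser(path, net: BiasFreeNet, state: SpectralState | None = None, config: dict | None = None):
    """Weights, spectral certificate and config snapshot in one HDF5 file."""
    with h5py.File(path, "w") as fh:
        fh.attrs["channels"] = list(net.channels)
        fh.attrs["image_shape"] = list(net.image_shape)
        if net.skip_gain is not None:
            fh.attrs["skip_gain"] = float(net.skip_gain)
        for i, layer in enumerate(net.layers):
            fh.create_dataset(f"kernel_{i}", data=layer.kernel)
        if state is not None:
            fh.create_dataset("layer_norms", data=np.asarray(state.norms))
            fh.attrs["certified_product"] = net.certified_bound(state.norms)
        if config:
            fh.attrs["config"] = json.dumps(config)


def read_denoiser(path):
    """Returns (net, certified_product or None)."""
    with h5py.File(path, "r") as fh:
        channels = tuple(int(c) for c in fh.attrs["channels"])
        image_shape = tuple(int(s) for s in fh.attrs["image_shape"])
        kernels = [fh[f"kernel_{i}"][()] for i in range(len(channels) - 1)]
        product = float(fh.attrs["certified_product"]) if "certified_product" in fh.attrs else None
        skip_gain = float(fh.attrs["skip_gain"]) if "skip_gain" in fh.attrs else None
    net = object.__new__(BiasFreeNet)
    net.channels = channels
    net.image_shape = image_shape
    net.skip_gain = skip_gain
    net.layers = [ConvLayer(k) for k in kernels]
    net.input_shapes = [(k.shape[1], image_shape[0], image_shape[1]) for k in kernels]
    return net, product
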