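"""File I/O: HDF5 k-space containers, NIfTI maps, run manifests.

The k-space container layout is: datasets ``/kspace`` (coil, echo, z, y, x
complex), ``/mask`` (kz, ky bool), ``/sens`` (coil maps), ``/te`` (seconds)
and ``/b0``; acquisition metadata is stored as root attributes.  Image-
domain outputs (echo stacks, quantitative maps) are written as NIfTI with
the voxel size on the affine diagonal and no reorientation.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np

from .fat_model import EchoTrain, MultiEchoImage
from .phantom import CoilSet, KSpaceData, SamplingMask

__all__ = [
    "save_kspace",
    "load_kspace",
    "save_nifti",
    "load_nifti",
    "RunManifest",
    "write_manifest",
]


def save_kspace(path, kspace: KSpaceData, coils: CoilSet | None = None) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("kspace", data=kspace.data)
        f.create_dataset("mask", data=kspace.mask.mask)
        if coils is not None:
            f.create_dataset("sens", data=coils.maps)
        f.create_dataset("te", data=kspace.echoes.echo_times)
        f.create_dataset("b0", data=kspace.echoes.field_strength)
        f.attrs["acceleration"] = kspace.mask.acceleration
        f.attrs["pattern"] = kspace.mask.pattern
        f.attrs["calibration_lines"] = kspace.mask.calibration_lines
        f.attrs["noise_sd"] = kspace.noise_sd
        if kspace.seed is not None:
            f.attrs["seed"] = kspace.seed
        if kspace.echoes.repetition_time is not None:
            f.attrs["tr"] = kspace.echoes.repetition_time


def load_kspace(path):
    """Returns (KSpaceData, CoilSet or None)."""
    with h5py.File(path, "r") as f:
        data = f["kspace"][...]
        mask = SamplingMask(
            f["mask"][...],
            int(f.attrs["acceleration"]),
            str(f.attrs["pattern"]),
            int(f.attrs["calibration_lines"]),
        )
        echoes = EchoTrain(
            f["te"][...],
            float(f["b0"][()]),
            repetition_time=float(f.attrs["tr"]) if "tr" in f.attrs else None,
        )
        coils = CoilSet(f["sens"][...]) if "sens" in f else None
        seed = int(f.attrs["seed"]) if "seed" in f.attrs else None
        return KSpaceData(data, mask, echoes, float(f.attrs["noise_sd"]), seed), coils


def save_nifti(path, volume, voxel_size_mm=(1.0, 1.0, 1.0)) -> None:
    """Write a (z, y, x) map or (echo, z, y, x) stack as NIfTI.

    Complex stacks are written as magnitude and phase pairs is avoided:
    complex data are stored as a final real/imaginary axis.
    """
    arr = volume.data if isinstance(volume, MultiEchoImage) else np.asarray(volume)
    if np.iscomplexobj(arr):
        arr = np.stack([arr.real, arr.imag], axis=-1)
    affine = np.diag(list(voxel_size_mm[::-1]) + [1.0])
    if arr.ndim == 3:  # (z, y, x) map -> x-fastest on disk
        arr = arr.transpose(2, 1, 0)
    nib.save(nib.Nifti1Image(np.ascontiguousarray(arr), affine), str(path))


def load_nifti(path) -> np.ndarray:
    img = nib.load(str(path))
    arr = np.asarray(img.dataobj)
    if arr.ndim == 3:
        arr = arr.transpose(2, 1, 0)
    if arr.ndim >= 4 and arr.shape[-1] == 2:
        arr = arr[..., 0] + 1j * arr[..., 1]
    return arr


@dataclass
class RunManifest:
    """Provenance record written next to every pipeline output."""

    seed: int
    config_hash: str
    software_version: str
    inputs: dict
    timestamp: str

    @classmethod
    def create(cls, seed: int, config, inputs: dict | None = None) -> "RunManifest":
        from . import __version__

        blob = json.dumps(config, sort_keys=True, default=str).encode()
        return cls(
            seed=int(seed),
            config_hash=hashlib.sha256(blob).hexdigest()[:16],
            software_version=__version__,
            inputs=inputs or {},
            timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"),
        )


def write_manifest(path, manifest: RunManifest) -> None:
    Path(path).write_text(json.dumps(asdict(manifest), indent=2) + "\n")
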