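"""On-disk formats: HDF5 slice archives, NIfTI magnitude export, sidecars.

HDF5 layout (one group per slice, ``slice_000`` ...):

* ``kspace``   complex64, coils x h x w  (the undersampled measurements b)
* ``maps``     complex64, coils x h x w  (LR coil sensitivities)
* ``mask``     float,     h x w
* ``image_zf`` complex64, h x w          (zero-filled input)
* ``image_lr_gt`` complex64, h x w
* ``image_gt`` complex64, H x W          (HR ground truth)

A JSON sidecar records the protocol and its nominal/measured acceleration.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np

from .synth import SamplingProtocol, TrainingPair, acceleration_of

__all__ = ["save_pairs_h5", "load_pairs_h5", "write_sidecar", "export_nifti"]


def save_pairs_h5(path: str | Path, pairs: list[TrainingPair]) -> None:
    with h5py.File(path, "w") as f:
        for i, p in enumerate(pairs):
            g = f.create_group(f"slice_{i:03d}")
            g.create_dataset("kspace", data=p.b.astype(np.complex64))
            g.create_dataset("maps", data=p.maps_lr.astype(np.complex64))
            g.create_dataset("mask", data=p.mask.astype(np.float32))
            g.create_dataset("image_zf", data=p.x_lr_zf.astype(np.complex64))
            g.create_dataset("image_lr_gt", data=p.x_lr_gt.astype(np.complex64))
            g.create_dataset("image_gt", data=p.x_gt.astype(np.complex64))


def load_pairs_h5(path: str | Path,
                  protocol: SamplingProtocol | None = None) -> list[TrainingPair]:
    pairs = []
    with h5py.File(path, "r") as f:
        for key in sorted(f.keys()):
            g = f[key]
            pairs.append(TrainingPair(
                b=g["kspace"][()].astype(np.complex128),
                maps_lr=g["maps"][()].astype(np.complex128),
                mask=g["mask"][()].astype(np.float64),
                x_lr_zf=g["image_zf"][()].astype(np.complex128),
                x_lr_gt=g["image_lr_gt"][()].astype(np.complex128),
                x_gt=g["image_gt"][()].astype(np.complex128),
                protocol=protocol,
            ))
    return pairs


def write_sidecar(path: str | Path, protocol: SamplingProtocol,
                  mask: np.ndarray) -> dict:
    nominal, measured = acceleration_of(protocol, mask)
    meta = {
        "protocol": dataclasses.asdict(protocol),
        "accel_nominal": nominal,
        "accel_measured": measured,
    }
    Path(path).write_text(json.dumps(meta, indent=2, default=str))
    return meta


def export_nifti(path: str | Path, image: np.ndarray) -> None:
    """Write a magnitude image (modulus of complex input) as NIfTI."""
    mag = np.abs(image).astype(np.float32)
    nib.save(nib.Nifti1Image(mag[..., None], affine=np.eye(4)), str(path))
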