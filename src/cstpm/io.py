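"""HDF5 project container and NIfTI/CSV export.

The container is a self-contained HDF5 layout (conceptually ISMRMRD-like):

* ``/kspace_real``, ``/kspace_imag`` — float32, (coil, frame, encoding, ky, kx)
* ``/mask`` — optional uint8, (frame, encoding, ky), plus a ``/maskset``
  group with per-mask metadata
* ``/images_real``, ``/images_imag`` — optional reconstructed images
* root attributes ``venc_cm_s``, ``frame_interval_ms``, ``fov_mm``,
  ``schema_version``

Complex data are stored as paired float32 real/imaginary datasets for
portability across HDF5 bindings.  On load all container invariants are
validated; in particular a k-space with nonzero samples at masked-out
locations is rejected.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

from .containers import ImageSeries, KSpaceSeries
from .masks import SamplingMaskSet

__all__ = [
    "SCHEMA_VERSION",
    "write_container",
    "read_container",
    "export_nifti",
    "export_velocity_nifti",
]

SCHEMA_VERSION = 1


def _write_complex(group: h5py.Group, name: str, data: np.ndarray) -> None:
    group.create_dataset(f"{name}_real", data=np.real(data).astype(np.float32))
    group.create_dataset(f"{name}_imag", data=np.imag(data).astype(np.float32))


def _read_complex(group: h5py.Group, name: str) -> np.ndarray:
    return np.asarray(group[f"{name}_real"]) + 1j * np.asarray(group[f"{name}_imag"])


def write_container(
    path,
    kspace: KSpaceSeries,
    masks: SamplingMaskSet | None = None,
    images: ImageSeries | None = None,
    provenance: dict | None = None,
) -> None:
    """Write a k-space series (plus optional masks/images) to HDF5."""
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["venc_cm_s"] = kspace.venc
        f.attrs["frame_interval_ms"] = kspace.frame_interval
        f.attrs["fov_mm"] = list(kspace.fov)
        _write_complex(f, "kspace", kspace.data)
        if masks is not None:
            f.create_dataset("mask", data=masks.indicator())
            masks.to_hdf5(f.create_group("maskset"))
        if images is not None:
            _write_complex(f, "images", images.data)
        if provenance is not None:
            f.attrs["provenance"] = json.dumps(provenance)


@dataclass
class Container:
    kspace: KSpaceSeries
    masks: SamplingMaskSet | None = None
    images: ImageSeries | None = None
    provenance: dict = field(default_factory=dict)


def read_container(path) -> Container:
    """Load and validate a project container."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with h5py.File(path, "r") as f:
        version = int(f.attrs.get("schema_version", -1))
        if version != SCHEMA_VERSION:
            raise ValueError(
                f"unsupported container schema version {version} "
                f"(this build reads version {SCHEMA_VERSION})"
            )
        meta = dict(
            venc=float(f.attrs["venc_cm_s"]),
            frame_interval=float(f.attrs["frame_interval_ms"]),
            fov=tuple(np.asarray(f.attrs["fov_mm"], float)),
        )
        kspace = KSpaceSeries(data=_read_complex(f, "kspace"), **meta)
        masks = None
        if "maskset" in f:
            masks = SamplingMaskSet.from_hdf5(f["maskset"])
            indicator = masks.indicator()[None, :, :, :, None]
            if np.any(kspace.data[np.broadcast_to(indicator == 0, kspace.data.shape)]):
                raise ValueError(
                    "container invariant violated: nonzero k-space sample at a "
                    "masked-out (frame, encoding, ky) location"
                )
        images = None
        if "images_real" in f:
            images = ImageSeries(data=_read_complex(f, "images"), **meta)
            if images.data.shape != kspace.data.shape:
                raise ValueError(
                    "container invariant violated: image extents "
                    f"{images.data.shape} differ from k-space {kspace.data.shape}"
                )
        provenance = {}
        if "provenance" in f.attrs:
            provenance = json.loads(f.attrs["provenance"])
    return Container(kspace=kspace, masks=masks, images=images, provenance=provenance)


def _nifti_affine(pixel_spacing: tuple[float, float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0] = pixel_spacing[1]
    aff[1, 1] = pixel_spacing[0]
    return aff


def export_nifti(images: ImageSeries, out_prefix) -> list[Path]:
    """Write magnitude and phase NIfTI volumes per encoding (frames on axis 4).

    Coils are combined by root-sum-of-squares for magnitude; phase is taken
    from the coil-summed complex image.
    """
    import nibabel as nib

    out_prefix = Path(out_prefix)
    paths = []
    affine = _nifti_affine(images.pixel_spacing)
    for e in range(images.n_encodings):
        stack = images.data[:, :, e]  # (coil, frame, y, x)
        mag = np.sqrt(np.sum(np.abs(stack) ** 2, axis=0))  # (frame, y, x)
        phase = np.angle(np.sum(stack, axis=0))
        for label, vol in (("mag", mag), ("phase", phase)):
            arr = np.transpose(vol, (2, 1, 0))[..., None, :]  # x, y, z=1, t
            img = nib.Nifti1Image(arr.astype(np.float32), affine)
            img.header["descrip"] = f"{label}, encoding {e}"
            p = out_prefix.with_name(f"{out_prefix.name}_enc{e}_{label}.nii")
            nib.save(img, p)
            paths.append(p)
    return paths


def export_velocity_nifti(field, out_prefix) -> list[Path]:
    """One NIfTI per velocity component (cm/s), frames on the 4th axis."""
    import nibabel as nib

    out_prefix = Path(out_prefix)
    affine = _nifti_affine(field.pixel_spacing)
    paths = []
    for comp, label in enumerate(("vx", "vy", "vz")):
        vol = field.v[..., comp]  # (frame, y, x)
        arr = np.transpose(vol, (2, 1, 0))[..., None, :]
        img = nib.Nifti1Image(arr.astype(np.float32), affine)
        img.header["descrip"] = f"{label} in cm/s"
        p = out_prefix.with_name(f"{out_prefix.name}_{label}.nii")
        nib.save(img, p)
        paths.append(p)
    return paths
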