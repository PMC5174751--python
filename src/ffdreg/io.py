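"""Reading and writing images, displacement fields and run manifests.

Supported containers: NIfTI (``.nii``/``.nii.gz``, via nibabel),
MetaImage (``.mha``/``.mhd``, via SimpleITK), PNG (2-D only, via
imageio) and raw numpy arrays (``.npy``).  Displacement fields are
stored as multi-component volumes in the same containers, with the
component axis last in memory.

Arrays keep the package's in-memory axis convention (x, y[, z], axis 0
= x); the SimpleITK index order is transposed on the way in and out so
round-trips are identity.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np
import SimpleITK as sitk

from .errors import FormatError

__all__ = ["read_image", "write_image", "read_field", "write_field", "write_manifest"]

_IMAGE_EXTS = (".nii", ".nii.gz", ".mha", ".mhd", ".png", ".npy")


def _ext(path: Path) -> str:
    name = path.name.lower()
    if name.endswith(".nii.gz"):
        return ".nii.gz"
    return path.suffix.lower()


def read_image(path) -> np.ndarray:
    """Load a 2-D or 3-D scalar volume as float64."""
    path = Path(path)
    ext = _ext(path)
    if ext not in _IMAGE_EXTS:
        raise FormatError(f"unsupported image format {ext!r} for {path}")
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        if ext in (".nii", ".nii.gz"):
            arr = np.asarray(nib.load(str(path)).get_fdata())
        elif ext in (".mha", ".mhd"):
            img = sitk.ReadImage(str(path))
            arr = sitk.GetArrayFromImage(img).T  # (z,y,x) -> (x,y,z)
        elif ext == ".png":
            arr = np.asarray(iio.imread(path), dtype=np.float64)
            if arr.ndim == 3:  # RGB(A) -> luminance
                arr = arr[..., :3] @ np.array([0.299, 0.587, 0.114])
        else:
            arr = np.load(path)
    except FormatError:
        raise
    except Exception as exc:
        raise FormatError(f"cannot read image {path}: {exc}") from exc
    arr = np.asarray(arr, dtype=np.float64)
    if arr.ndim not in (2, 3):
        raise FormatError(f"{path} holds a {arr.ndim}-D array; expected 2-D or 3-D")
    return arr


def write_image(path, data: np.ndarray) -> None:
    """Write a scalar volume; format chosen by extension."""
    path = Path(path)
    ext = _ext(path)
    data = np.asarray(data, dtype=np.float64)
    try:
        if ext in (".nii", ".nii.gz"):
            nib.save(nib.Nifti1Image(data, np.eye(4)), str(path))
        elif ext in (".mha", ".mhd"):
            sitk.WriteImage(sitk.GetImageFromArray(data.T), str(path))
        elif ext == ".png":
            if data.ndim != 2:
                raise FormatError(f"PNG can hold 2-D images only, got {data.ndim}-D")
            clipped = np.clip(np.round(data), 0, 255).astype(np.uint8)
            iio.imwrite(path, clipped)
        elif ext == ".npy":
            np.save(path, data)
        else:
            raise FormatError(f"unsupported image format {ext!r} for {path}")
    except FormatError:
        raise
    except Exception as exc:
        raise FormatError(f"cannot write image {path}: {exc}") from exc


def read_field(path) -> np.ndarray:
    """Load a displacement field, shape ``spatial_shape + (D,)``."""
    path = Path(path)
    ext = _ext(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        if ext in (".nii", ".nii.gz"):
            arr = np.asarray(nib.load(str(path)).get_fdata())
        elif ext in (".mha", ".mhd"):
            img = sitk.ReadImage(str(path))
            arr = sitk.GetArrayFromImage(img)  # (z,y,x, D)
            nd = arr.ndim - 1
            arr = arr.transpose(tuple(range(nd - 1, -1, -1)) + (nd,))
        elif ext == ".npy":
            arr = np.load(path)
        else:
            raise FormatError(f"unsupported field format {ext!r} for {path}")
    except FormatError:
        raise
    except Exception as exc:
        raise FormatError(f"cannot read field {path}: {exc}") from exc
    arr = np.asarray(arr, dtype=np.float64)
    if arr.ndim not in (3, 4) or arr.shape[-1] != arr.ndim - 1:
        raise FormatError(
            f"{path}: expected spatial shape plus a trailing component axis of "
            f"matching dimension, got {arr.shape}"
        )
    return arr


def write_field(path, disp: np.ndarray) -> None:
    """Write a displacement field (trailing component axis)."""
    path = Path(path)
    ext = _ext(path)
    disp = np.asarray(disp, dtype=np.float64)
    if disp.ndim not in (3, 4) or disp.shape[-1] != disp.ndim - 1:
        raise FormatError(
            f"field must have a trailing component axis matching its spatial "
            f"dimension, got shape {disp.shape}"
        )
    try:
        if ext in (".nii", ".nii.gz"):
            nib.save(nib.Nifti1Image(disp, np.eye(4)), str(path))
        elif ext in (".mha", ".mhd"):
            nd = disp.ndim - 1
            arr = disp.transpose(tuple(range(nd - 1, -1, -1)) + (nd,))
            sitk.WriteImage(sitk.GetImageFromArray(arr, isVector=True), str(path))
        elif ext == ".npy":
            np.save(path, disp)
        else:
            raise FormatError(f"unsupported field format {ext!r} for {path}")
    except FormatError:
        raise
    except Exception as exc:
        raise FormatError(f"cannot write field {path}: {exc}") from exc


def write_manifest(path, manifest: dict) -> None:
    """Serialize a reproducibility manifest as JSON."""
    path = Path(path)
    try:
        path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    except Exception as exc:
        raise FormatError(f"cannot write manifest {path}: {exc}") from exc
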