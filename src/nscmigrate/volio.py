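"""Volume readers and writers.

Supported inputs: NIfTI (.nii/.nii.gz) for 3-D volumes, TIFF and PNG
for 2-D images, and NumPy archives (.npz) carrying either an intensity
grid (``data`` [, ``pixel_size``, ``brain_mask``]) or a precomputed
per-voxel tensor field (``tensors``).  Outputs mirror the input
geometry.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .field import ImageVolume, TensorField, tensor_field_from_tensors

__all__ = ["load_volume", "save_volume", "load_tensor_field"]


def _is_nifti(path: Path) -> bool:
    return path.name.endswith((".nii", ".nii.gz"))


def load_volume(path, pixel_size: float | None = None,
                brain_mask: np.ndarray | None = None) -> ImageVolume:
    """Read a 2-D or 3-D scalar volume into an :class:`ImageVolume`.

    ``pixel_size`` (um) overrides whatever the file header carries; for
    formats without physical metadata (TIFF/PNG without an explicit
    value, plain arrays) it defaults to 1 um.
    """
    path = Path(path)
    if _is_nifti(path):
        import nibabel as nib

        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=float)
        if pixel_size is None:
            zooms = img.header.get_zooms()
            pixel_size = float(zooms[0]) if zooms else 1.0
        return ImageVolume(data, pixel_size, brain_mask)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        data = np.asarray(tifffile.imread(str(path)), dtype=float)
        return ImageVolume(data, pixel_size or 1.0, brain_mask)
    if path.suffix.lower() == ".png":
        from PIL import Image

        data = np.asarray(Image.open(path).convert("F"), dtype=float)
        return ImageVolume(data, pixel_size or 1.0, brain_mask)
    if path.suffix.lower() == ".npz":
        with np.load(path) as z:
            if "data" not in z:
                raise ValueError(
                    f"{path}: .npz volume needs a 'data' array "
                    "(found: " + ", ".join(z.files) + ")")
            data = z["data"]
            ps = pixel_size or (float(z["pixel_size"]) if "pixel_size" in z
                                else 1.0)
            mask = brain_mask if brain_mask is not None else (
                z["brain_mask"] if "brain_mask" in z else None)
        return ImageVolume(data, ps, mask)
    raise ValueError(f"unsupported volume format: {path.name}")


def save_volume(path, data: np.ndarray, pixel_size: float = 1.0) -> None:
    """Write a scalar grid as NIfTI, TIFF, or NPZ by extension."""
    path = Path(path)
    data = np.asarray(data)
    if _is_nifti(path):
        import nibabel as nib

        affine = np.diag([pixel_size] * data.ndim + [1.0] * (4 - data.ndim))
        nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine),
                 str(path))
    elif path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(str(path), np.asarray(data, dtype=np.float32))
    elif path.suffix.lower() == ".npz":
        np.savez_compressed(path, data=data, pixel_size=pixel_size)
    else:
        raise ValueError(f"unsupported output format: {path.name}")


def load_tensor_field(path) -> TensorField:
    """Read a precomputed per-voxel tensor field from a .npz archive."""
    path = Path(path)
    with np.load(path) as z:
        if "tensors" not in z:
            raise ValueError(f"{path}: expected a 'tensors' array")
        tensors = z["tensors"]
    return tensor_field_from_tensors(tensors)
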