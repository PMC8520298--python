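"""Readers and writers for CT slice data.

Supported inputs: NIfTI volumes (``.nii``/``.nii.gz``), DICOM series
directories, and the paired-PNG layout written by
:func:`msaunet.phantom.generate_dataset` (uint16 image = HU + 1024,
uint8 mask). Volumes are always handled slice-wise along the last
(axial) axis.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .phantom import HU_PNG_OFFSET, CTSlice

__all__ = ["load_slices", "load_nifti_slices", "load_dicom_series",
           "write_probability_png", "write_mask_png"]


def load_nifti_slices(path, case_id: str | None = None) -> list:
    """Axial HU slices from a NIfTI volume (applies the scaling header)."""
    import nibabel as nib

    path = Path(path)
    img = nib.load(str(path))
    vol = np.asanyarray(img.get_fdata(dtype=np.float64))
    if vol.ndim == 2:
        vol = vol[..., None]
    if vol.ndim != 3:
        raise ValueError(f"expected a 2-D or 3-D NIfTI volume, got shape {vol.shape}")
    zooms = img.header.get_zooms()
    spacing = (float(zooms[0]), float(zooms[1])) if len(zooms) >= 2 else None
    cid = case_id or path.name.split(".")[0]
    return [CTSlice(hu=np.ascontiguousarray(vol[:, :, k]), mask=None,
                    case_id=cid, slice_index=k, spacing=spacing)
            for k in range(vol.shape[2])]


def load_dicom_series(directory, case_id: str | None = None) -> list:
    """HU slices from a DICOM series directory, sorted by slice position."""
    import pydicom

    directory = Path(directory)
    files = sorted(p for p in directory.iterdir()
                   if p.is_file() and p.suffix.lower() in (".dcm", ""))
    datasets = []
    for p in files:
        try:
            datasets.append((p, pydicom.dcmread(str(p))))
        except Exception:
            continue
    if not datasets:
        raise ValueError(f"no readable DICOM files in {directory}")

    def sort_key(item):
        ds = item[1]
        ipp = getattr(ds, "ImagePositionPatient", None)
        if ipp is not None:
            return float(ipp[2])
        return float(getattr(ds, "InstanceNumber", 0))

    datasets.sort(key=sort_key)
    cid = case_id or directory.name
    slices = []
    for k, (_, ds) in enumerate(datasets):
        arr = ds.pixel_array.astype(np.float64)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        spacing = getattr(ds, "PixelSpacing", None)
        spacing = (float(spacing[0]), float(spacing[1])) if spacing else None
        slices.append(CTSlice(hu=arr * slope + intercept, mask=None,
                              case_id=cid, slice_index=k, spacing=spacing))
    return slices


def load_png_slice(img_path, mask_path=None, case_id: str = "",
                   slice_index: int = 0) -> CTSlice:
    hu = iio.imread(img_path).astype(np.float64) - HU_PNG_OFFSET
    mask = None
    if mask_path is not None:
        mask = (iio.imread(mask_path) > 0).astype(np.uint8)
    return CTSlice(hu=hu, mask=mask, case_id=case_id, slice_index=slice_index)


def load_slices(path, case_id: str | None = None) -> list:
    """Dispatch on path type: NIfTI file, DICOM dir, or single PNG."""
    path = Path(path)
    if path.is_dir():
        return load_dicom_series(path, case_id)
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        return load_nifti_slices(path, case_id)
    if name.endswith(".png"):
        return [load_png_slice(path, case_id=case_id or path.stem)]
    raise ValueError(f"unrecognized input format: {path}")


def write_probability_png(path, prob: np.ndarray):
    """Store a (0,1) probability map as 16-bit PNG (value = p * 65535)."""
    arr = np.clip(np.asarray(prob, dtype=np.float64), 0.0, 1.0)
    iio.imwrite(Path(path), np.round(arr * 65535).astype(np.uint16))


def write_mask_png(path, mask: np.ndarray):
    iio.imwrite(Path(path), (np.asarray(mask) > 0).astype(np.uint8) * 255)
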