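"""Image and label-map I/O.

Gray images arrive as 8-bit PNG/TIFF (multi-channel inputs are collapsed
by the ITU-R 601 luminance weights) or as single-slice NIfTI, whose
floating values are rescaled min->0, max->255.  Label maps round-trip as
16-bit PNG or as CSV, chosen by extension.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np

from ._util import to_uint8

__all__ = [
    "read_gray_image",
    "write_gray_image",
    "write_label_map",
    "read_label_map",
    "write_boundary_overlay",
]

_LUMA = np.array([0.299, 0.587, 0.114])


def _is_nifti(path: Path) -> bool:
    name = path.name.lower()
    return name.endswith(".nii") or name.endswith(".nii.gz")


def read_gray_image(path: str | Path) -> np.ndarray:
    """Read a 2-D 8-bit gray image from PNG/TIFF/NIfTI.

    RGB(A) rasters are converted by luminance (alpha ignored); NIfTI data
    is squeezed to 2-D and linearly rescaled to the full 8-bit range
    (constant volumes map to 0).
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    if _is_nifti(path):
        import nibabel as nib

        data = np.asanyarray(nib.load(str(path)).dataobj).squeeze()
        if data.ndim != 2:
            raise ValueError(
                f"NIfTI input must be a single 2-D slice, got shape {data.shape}"
            )
        data = data.astype(np.float64)
        lo, hi = data.min(), data.max()
        if hi > lo:
            data = (data - lo) / (hi - lo) * 255.0
        else:
            data = np.zeros_like(data)
        arr = to_uint8(data)
    else:
        raw = iio.imread(path)
        if raw.size == 0:
            raise ValueError(f"zero-size image: {path}")
        if raw.ndim == 3:
            rgb = raw[..., :3].astype(np.float64)
            arr = to_uint8(rgb @ _LUMA)
        elif raw.ndim == 2:
            if raw.dtype != np.uint8:
                raw = to_uint8(raw.astype(np.float64))
            arr = raw
        else:
            raise ValueError(f"unsupported image dimensionality: {raw.ndim}")
    if arr.shape[0] < 1 or arr.shape[1] < 1:
        raise ValueError(f"zero-size image: {path}")
    return arr


def write_gray_image(image: np.ndarray, path: str | Path) -> None:
    """Write an 8-bit gray raster as PNG/TIFF."""
    iio.imwrite(Path(path), np.asarray(image, dtype=np.uint8))


def write_label_map(labels: np.ndarray, path: str | Path) -> None:
    """Write a label array as 16-bit PNG (``.png``) or CSV (``.csv``).

    All labels must be assigned (>= 0); PNG output requires labels to fit
    in 16 bits.
    """
    lab = np.asarray(labels)
    if lab.ndim != 2 or lab.size == 0:
        raise ValueError("label map must be a non-empty 2-D array")
    if lab.min() < 0:
        raise ValueError("label map has unassigned pixels")
    path = Path(path)
    if path.suffix.lower() == ".csv":
        np.savetxt(path, lab, fmt="%d", delimiter=",")
        return
    if lab.max() > np.iinfo(np.uint16).max:
        raise ValueError("more than 65535 labels; use CSV output")
    iio.imwrite(path, lab.astype(np.uint16))


def read_label_map(path: str | Path) -> np.ndarray:
    """Read a label map written by :func:`write_label_map`."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    if path.suffix.lower() == ".csv":
        return np.loadtxt(path, dtype=np.int32, delimiter=",", ndmin=2)
    return iio.imread(path).astype(np.int32)


def write_boundary_overlay(
    image: np.ndarray, labels: np.ndarray, path: str | Path
) -> None:
    """Write the gray image with superpixel boundaries burned in red."""
    from .superpixel import boundary_mask

    img = np.asarray(image, dtype=np.uint8)
    rgb = np.stack([img, img, img], axis=-1)
    b = boundary_mask(labels)
    rgb[b] = (255, 0, 0)
    iio.imwrite(Path(path), rgb)
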