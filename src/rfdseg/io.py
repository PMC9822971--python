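"""Readers and writers for the image formats the toolkit accepts.

Volumes: NIfTI (.nii/.nii.gz, via nibabel) and multipage TIFF (tifffile);
2-D slices: PNG (imageio) and single-page TIFF. All outputs use an identity
affine for NIfTI; masks must be integer-typed and geometry-identical to
their image.
"""

from __future__ import annotations

from pathlib import Path
from typing import Union

import imageio.v3 as iio
import nibabel as nib
import numpy as np
import tifffile

from .errors import ValidationError

__all__ = ["load_image", "load_mask", "save_volume", "save_mask"]

PathLike = Union[str, Path]


def _is_nifti(path: Path) -> bool:
    name = path.name.lower()
    return name.endswith(".nii") or name.endswith(".nii.gz")


def load_image(path: PathLike) -> np.ndarray:
    """Load a 2-D slice or 3-D volume as a numeric array (slice axis 0)."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"input file not found: {path}")
    if _is_nifti(path):
        data = np.asanyarray(nib.load(str(path)).dataobj)
        # store D,H,W with the slice axis leading
        return np.ascontiguousarray(data.T) if data.ndim == 3 else data
    if path.suffix.lower() in (".tif", ".tiff"):
        return tifffile.imread(str(path))
    return iio.imread(path)


def load_mask(path: PathLike) -> np.ndarray:
    """Load an integer label mask; non-integer storage is rejected unless
    every value is integral."""
    data = load_image(path)
    if not np.issubdtype(data.dtype, np.integer):
        rounded = np.rint(data)
        if not np.allclose(data, rounded, atol=1e-6):
            raise ValidationError(f"mask {path} contains non-integer labels")
        data = rounded
    return data.astype(np.int64)


def save_volume(path: PathLike, data: np.ndarray) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if _is_nifti(path):
        nib.save(nib.Nifti1Image(np.asarray(data).T, affine=np.eye(4)), str(path))
    elif path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(str(path), np.asarray(data))
    elif path.suffix.lower() == ".png":
        if np.asarray(data).ndim != 2:
            raise ValidationError("PNG output requires 2-D data")
        iio.imwrite(path, np.asarray(data).astype(np.uint8))
    else:
        raise ValidationError(f"unsupported output format: {path.suffix}")


def save_mask(path: PathLike, mask: np.ndarray) -> None:
    save_volume(path, np.asarray(mask).astype(np.uint8))
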