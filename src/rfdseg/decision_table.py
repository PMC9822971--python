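"""Information decision table for supervised brightness discretization.

A grayscale image with a gold-standard label mask is flattened into a table
S = (U, B, C, V, f): the pixel universe U, the brightness attribute B, the
region-category attribute C, the value range V and the positional mapping f.
All downstream stages (fuzzy c-means, rough-fuzzy approximation, the genetic
breakpoint search) operate on this table rather than on image geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import StructuralError, ValidationError

__all__ = [
    "DecisionTable",
    "CandidateBreakpointSet",
    "build_decision_table",
    "extract_candidate_breakpoints",
]


@dataclass(frozen=True)
class DecisionTable:
    """Flattened per-pixel brightness + label pairs.

    Attributes
    ----------
    brightness : (N,) float64
        Pixel brightness in the units of the source image (0-255 for 8-bit).
    labels : (N,) int64
        Region-category index per pixel, in ``0..num_classes-1``.
    num_classes : int
        Number of segmentation categories M (>= 2).
    value_range : tuple of float
        Declared representable brightness range (min, max).
    slice_id : (N,) int64, optional
        Slice index per pixel; present only in per-slice mode, where every
        later stage treats slices as independent universes.
    provenance : dict
        Free-form source description (path, shape, mode).
    """

    brightness: np.ndarray
    labels: np.ndarray
    num_classes: int
    value_range: tuple[float, float]
    slice_id: Optional[np.ndarray] = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.brightness.ndim != 1 or self.labels.ndim != 1:
            raise StructuralError("brightness and labels must be 1-D")
        if len(self.brightness) != len(self.labels):
            raise StructuralError(
                f"brightness ({len(self.brightness)}) and labels "
                f"({len(self.labels)}) lengths differ"
            )
        if len(self.brightness) == 0:
            raise ValidationError("decision table must contain at least one pixel")
        if self.num_classes < 2:
            raise ValidationError("num_classes must be >= 2")
        if self.labels.min() < 0 or self.labels.max() >= self.num_classes:
            raise ValidationError(
                f"labels must lie in 0..{self.num_classes - 1}, got range "
                f"[{self.labels.min()}, {self.labels.max()}]"
            )
        lo, hi = self.value_range
        if self.brightness.min() < lo or self.brightness.max() > hi:
            raise ValidationError(
                f"brightness outside declared value_range [{lo}, {hi}]"
            )
        if self.slice_id is not None and len(self.slice_id) != len(self.brightness):
            raise StructuralError("slice_id length must match brightness")

    def __len__(self) -> int:
        return len(self.brightness)

    @property
    def per_slice(self) -> bool:
        return self.slice_id is not None

    def slice_ids(self) -> np.ndarray:
        """Distinct slice indices, sorted; ``[0]`` for whole-volume tables."""
        if self.slice_id is None:
            return np.array([0], dtype=np.int64)
        return np.unique(self.slice_id)

    def pixels_of(self, scope: Optional[int]) -> np.ndarray:
        """Row indices of the pixels in ``scope`` (all rows when None)."""
        if scope is None or self.slice_id is None:
            return np.arange(len(self), dtype=np.int64)
        if scope not in self.slice_ids():
            raise ValidationError(f"slice {scope} not present in table")
        return np.flatnonzero(self.slice_id == scope)


@dataclass(frozen=True)
class CandidateBreakpointSet:
    """Sorted unique observed brightness values usable as cut points."""

    values: np.ndarray

    def __post_init__(self) -> None:
        if self.values.ndim != 1 or len(self.values) == 0:
            raise ValidationError("candidate set must be a non-empty vector")
        if np.any(np.diff(self.values) <= 0):
            raise ValidationError("candidates must be strictly increasing")

    @property
    def n(self) -> int:
        return len(self.values)


def _default_value_range(image: np.ndarray) -> tuple[float, float]:
    """Declared range from dtype: integer dtypes use their bit depth,
    anything else defaults to the 8-bit convention unless it overflows it."""
    if np.issubdtype(image.dtype, np.integer):
        info = np.iinfo(image.dtype)
        if info.bits <= 8:
            return (0.0, 255.0)
        if info.bits <= 16:  # declared high-bit-depth storage
            return (float(info.min), float(info.max))
    # float or generic wide-int input: no declared depth; assume the 8-bit
    # convention and widen only if the data exceeds it
    lo = min(0.0, float(image.min()))
    hi = max(255.0, float(image.max()))
    return (lo, hi)


def build_decision_table(
    image: np.ndarray,
    mask: np.ndarray,
    num_classes: int,
    mode: str = "per_slice",
    value_range: Optional[tuple[float, float]] = None,
) -> DecisionTable:
    """Flatten an image/mask pair into a decision table.

    Parameters
    ----------
    image : 2-D or 3-D array
        Brightness values; for 3-D input the slice axis is axis 0.
    mask : array of same shape
        Integer gold-standard labels, each < ``num_classes``.
    num_classes : int
        Number of region categories M.
    mode : {"per_slice", "whole_volume"}
        ``per_slice`` (default for 3-D input) records a slice index per
        pixel so discretization treats each 2-D slice independently.
    value_range : (min, max), optional
        Override the declared brightness range (default: from dtype,
        0-255 for 8-bit input).
    """
    image = np.asarray(image)
    mask = np.asarray(mask)
    if image.size == 0:
        raise ValidationError("empty image")
    if image.shape != mask.shape:
        raise StructuralError(
            f"image shape {image.shape} != mask shape {mask.shape}"
        )
    if image.ndim not in (2, 3):
        raise ValidationError(f"expected 2-D or 3-D input, got {image.ndim}-D")
    if mode not in ("per_slice", "whole_volume"):
        raise ValidationError(f"unknown mode {mode!r}")
    if mode == "per_slice" and image.ndim != 3:
        mode = "whole_volume"  # a single 2-D slice is its own scope

    if value_range is None:
        value_range = _default_value_range(image)

    brightness = image.reshape(-1).astype(np.float64)
    labels = mask.reshape(-1).astype(np.int64)
    slice_id = None
    if mode == "per_slice":
        n_per = int(np.prod(image.shape[1:]))
        slice_id = np.repeat(np.arange(image.shape[0], dtype=np.int64), n_per)

    return DecisionTable(
        brightness=brightness,
        labels=labels,
        num_classes=int(num_classes),
        value_range=(float(value_range[0]), float(value_range[1])),
        slice_id=slice_id,
        provenance={"shape": tuple(image.shape), "mode": mode},
    )


def extract_candidate_breakpoints(
    table: DecisionTable, scope: Optional[int] = None
) -> CandidateBreakpointSet:
    """Sorted unique brightness values of the scoped pixels.

    The candidates are the observed values themselves; a full-dynamic-range
    8-bit slice therefore yields exactly 256 candidates.
    """
    idx = table.pixels_of(scope)
    return CandidateBreakpointSet(values=np.unique(table.brightness[idx]))
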