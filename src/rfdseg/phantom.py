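"""Synthetic layered-retina OCT phantom with gold-standard masks.

Each slice contains a retina band (retinal edema area, REA) bounded by two
smooth sinusoidal surfaces, occupying roughly 61% of the slice area. An
ellipsoidal subretinal-fluid (SRF) blob sits strictly inside the band
(~0.7% of voxels) and a small pigment-epithelial-detachment (PED) bump sits
on the lower band boundary (~0.03%), mirroring the class imbalance of
clinical macular OCT volumes. Per-class base intensities are corrupted by
multiplicative gamma-distributed speckle — the canonical noise model of
coherent imaging — and quantized to 8 bits.

Classes: 0 background, 1 REA, 2 SRF, 3 PED.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError

__all__ = ["PhantomSpec", "generate_phantom", "CLASS_NAMES"]

CLASS_NAMES = ("background", "REA", "SRF", "PED")


@dataclass(frozen=True)
class PhantomSpec:
    """Generator settings.

    class_fractions : target voxel fractions for (REA, SRF, PED); the
        remainder is background. Targets, not constraints — realized
        fractions depend on geometry and are reported by the generator.
    intensity_means : base 8-bit brightness per class
        (background, REA, SRF, PED).
    speckle_looks : number of looks L of the multiplicative gamma speckle
        (mean 1, variance 1/L); ``inf`` disables noise.
    boundary_waviness : amplitude (voxels) of the sinusoidal undulation of
        the band boundaries.
    """

    shape: tuple[int, int, int] = (16, 64, 64)
    class_fractions: tuple[float, float, float] = (0.61, 0.007, 0.0003)
    intensity_means: tuple[float, float, float, float] = (30.0, 110.0, 180.0, 240.0)
    speckle_looks: float = 16.0
    boundary_waviness: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(s < 1 for s in self.shape):
            raise ValidationError("shape must be three positive integers")
        d, h, w = self.shape
        if d < 8 or h < 16 or w < 16:
            raise ValidationError("minimum phantom shape is (8, 16, 16)")
        if any(f < 0 for f in self.class_fractions):
            raise ValidationError("class fractions must be non-negative")
        if sum(self.class_fractions) >= 1.0:
            raise ValidationError("class fractions must sum to < 1")
        if self.speckle_looks <= 0:
            raise ValidationError("speckle_looks must be positive")


def _band_boundaries(
    spec: PhantomSpec, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Smooth top/bottom row indices of the retina band, per (slice, column)."""
    d, h, w = spec.shape
    thickness = spec.class_fractions[0] * h
    center = h / 2.0
    z = np.arange(d)[:, None]
    x = np.arange(w)[None, :]
    amp = spec.boundary_waviness
    ph1, ph2, ph3 = rng.uniform(0, 2 * math.pi, size=3)
    undulation = amp * np.sin(2 * math.pi * x / w + ph1) + 0.5 * amp * np.sin(
        2 * math.pi * (x / w * 2 + z / max(d, 1)) + ph2
    )
    tilt = 0.5 * amp * np.sin(2 * math.pi * z / max(d, 1) + ph3)
    top = center - thickness / 2.0 + undulation + tilt
    bottom = center + thickness / 2.0 + undulation + tilt
    return top, bottom


def _ellipsoid_mask(
    shape: tuple[int, int, int], center: np.ndarray, radii: np.ndarray
) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    acc = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii))
    return acc <= 1.0


def generate_phantom(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, dict]:
    """Generate (volume uint8, mask uint8, report dict). Seed-deterministic.

    The report records the realized per-class voxel fractions and the
    generator settings; infeasibly small classes (e.g. a PED below one
    voxel) are emitted empty with a warning.
    """
    rng = np.random.default_rng(spec.seed)
    d, h, w = spec.shape
    total = d * h * w
    mask = np.zeros(spec.shape, dtype=np.uint8)

    top, bottom = _band_boundaries(spec, rng)
    rows = np.arange(h)[None, :, None]
    band = (rows >= top[:, None, :]) & (rows < bottom[:, None, :])
    mask[band] = 1

    # SRF: ellipsoid strictly inside the band, sized to the target fraction
    frac_srf = spec.class_fractions[1]
    srf_target = frac_srf * total
    if srf_target >= 1.0:
        r = (srf_target * 3.0 / (4.0 * math.pi)) ** (1.0 / 3.0)
        radii = np.array([min(r, d / 3.0), r, r])
        center = np.array(
            [
                d / 2.0 + rng.uniform(-d / 8, d / 8),
                h / 2.0 + rng.uniform(-h / 16, h / 16),
                w / 2.0 + rng.uniform(-w / 8, w / 8),
            ]
        )
        srf = _ellipsoid_mask(spec.shape, center, radii) & band
        # keep SRF strictly interior to the band (no boundary contact)
        interior = (rows >= top[:, None, :] + 1) & (rows < bottom[:, None, :] - 1)
        srf &= interior
        mask[srf] = 2
    else:
        warnings.warn("SRF target below one voxel; class emitted empty")

    # PED: small half-ellipsoid bump touching the lower band boundary
    frac_ped = spec.class_fractions[2]
    ped_target = frac_ped * total
    if ped_target >= 1.0:
        r = max((ped_target * 3.0 / (2.0 * math.pi)) ** (1.0 / 3.0), 1.0)
        zc = d / 2.0
        xc = w / 4.0 + rng.uniform(0, w / 8)
        yc = float(np.interp(xc, np.arange(w), bottom[int(zc)])) - 1.0
        ped = _ellipsoid_mask(
            spec.shape, np.array([zc, yc, xc]), np.array([max(r, 1.0), r, r])
        )
        ped &= band  # stays within the band, adjacent to its lower edge
        if ped.any():
            mask[ped] = 3
        else:
            warnings.warn("PED bump infeasible for this geometry; class empty")
    else:
        warnings.warn("PED target below one voxel; class emitted empty")

    means = np.asarray(spec.intensity_means, dtype=np.float64)
    clean = means[mask]
    if math.isinf(spec.speckle_looks):
        noisy = clean
    else:
        looks = spec.speckle_looks
        speckle = rng.gamma(shape=looks, scale=1.0 / looks, size=spec.shape)
        noisy = clean * speckle
    volume = np.clip(np.rint(noisy), 0, 255).astype(np.uint8)

    realized = {
        name: float((mask == i).sum()) / total for i, name in enumerate(CLASS_NAMES)
    }
    report = {
        "shape": list(spec.shape),
        "seed": spec.seed,
        "speckle_looks": spec.speckle_looks,
        "target_fractions": {
            "REA": spec.class_fractions[0],
            "SRF": spec.class_fractions[1],
            "PED": spec.class_fractions[2],
        },
        "realized_fractions": realized,
        "intensity_means": list(spec.intensity_means),
    }
    return volume, mask, report
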