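"""Binary tumor volumes and per-slice pixel bookkeeping.

A tumor is an ordered stack of 2D binary slices.  On each slice ``A`` marks the
solid (radio-dense) pixels and ``B`` is the tumor mask: ``A`` with every
interior hole filled.  The difference ``B & ~A`` is the radio-lucent (air,
cavity, cyst, reticulation) portion of the slice.  All downstream imaging
biomarkers are functions of these two images.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "SlicePair",
    "TumorVolume",
    "PixelCounts",
    "fill_mask",
    "pixel_counts",
    "boundary_pixels",
    "lucent_components",
]

# 4-connected background / 8-connected foreground: a hole is a background
# component that cannot reach the image border through edge-adjacent steps.
_CROSS = ndimage.generate_binary_structure(2, 1)


def fill_mask(a: np.ndarray) -> np.ndarray:
    """Fill all interior holes of a binary slice, returning the tumor mask B.

    Holes are background components not connected to the image border
    (4-connected background, hence 8-connected foreground).

    Parameters
    ----------
    a : 2D array-like of bool
        Solid-pixel image A.  Must be a nonempty 2D array.

    Returns
    -------
    2D bool array with ``a`` as a subset.
    """
    a = np.asarray(a).astype(bool)
    if a.ndim != 2 or a.size == 0:
        raise ValueError("empty slice")
    return ndimage.binary_fill_holes(a, structure=_CROSS)


@dataclass(frozen=True)
class SlicePair:
    """One tumor slice: solid image A, filled mask B, and pixel spacing (mm)."""

    a: np.ndarray
    b: np.ndarray
    index: int = 0
    spacing: float = 1.0

    def __post_init__(self):
        a = np.asarray(self.a).astype(bool)
        b = np.asarray(self.b).astype(bool)
        if a.shape != b.shape:
            raise ValueError("A and B must have identical dimensions")
        if np.any(a & ~b):
            raise ValueError("every solid pixel of A must lie inside the mask B")
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "b", b)

    @classmethod
    def from_solid(cls, a: np.ndarray, index: int = 0, spacing: float = 1.0) -> "SlicePair":
        """Build the pair from the solid image alone; B is A hole-filled."""
        a = np.asarray(a).astype(bool)
        return cls(a=a, b=fill_mask(a), index=index, spacing=spacing)

    @property
    def holes(self) -> np.ndarray:
        """Lucent pixels of the slice (inside the mask, not solid)."""
        return self.b & ~self.a

    @property
    def has_hole(self) -> bool:
        return bool(np.any(self.holes))


@dataclass(frozen=True)
class PixelCounts:
    """Per-slice active-pixel counts P_A, P_B and their intersection."""

    pa: int
    pb: int
    pbia: int


def pixel_counts(sl: SlicePair) -> PixelCounts:
    """Count active pixels of A, B and of their intersection (== P_A)."""
    pa = int(np.count_nonzero(sl.a))
    pb = int(np.count_nonzero(sl.b))
    pbia = int(np.count_nonzero(sl.a & sl.b))
    return PixelCounts(pa=pa, pb=pb, pbia=pbia)


@dataclass
class TumorVolume:
    """Ordered stack of :class:`SlicePair` with consistent dimensions."""

    slices: list = field(default_factory=list)

    def __post_init__(self):
        if self.slices:
            shape = self.slices[0].a.shape
            for sl in self.slices:
                if sl.a.shape != shape:
                    raise ValueError("mixed slice dimensions")

    @classmethod
    def from_arrays(cls, solid_slices, spacing: float = 1.0) -> "TumorVolume":
        """Build a volume from an iterable of 2D solid images (or a 3D array).

        A 3D array is split along its first axis.  ``spacing`` may be a scalar
        in-plane pixel size in mm, or an (row, col) pair; anisotropic in-plane
        spacing is averaged with a warning.
        """
        spacing = _resolve_spacing(spacing)
        arrs = list(np.asarray(s) for s in solid_slices)
        return cls([SlicePair.from_solid(a, index=i, spacing=spacing)
                    for i, a in enumerate(arrs)])

    @property
    def n_tumor(self) -> int:
        """Number of slices with a nonempty mask."""
        return sum(1 for sl in self.slices if np.any(sl.b))

    @property
    def n_lucent(self) -> int:
        """Number of slices containing at least one hole."""
        return sum(1 for sl in self.slices if sl.has_hole)

    def tumor_slices(self):
        return [sl for sl in self.slices if np.any(sl.b)]

    def lucent_slices(self):
        return [sl for sl in self.slices if sl.has_hole]


def _resolve_spacing(spacing) -> float:
    if np.isscalar(spacing):
        return float(spacing)
    spacing = np.asarray(spacing, dtype=float).ravel()[:2]
    if not np.allclose(spacing[0], spacing[1]):
        warnings.warn(
            f"anisotropic in-plane spacing {tuple(spacing)}; using the mean",
            stacklevel=3,
        )
    return float(spacing.mean())


def boundary_pixels(mask: np.ndarray) -> np.ndarray:
    """(row, col) centers of mask pixels adjacent to background or image edge."""
    mask = np.asarray(mask).astype(bool)
    eroded = ndimage.binary_erosion(mask, structure=_CROSS, border_value=0)
    return np.argwhere(mask & ~eroded)


def lucent_components(sl: SlicePair):
    """Label the lucent regions of a slice (4-connected, like the background).

    Returns ``(labels, n)`` from :func:`scipy.ndimage.label` on ``sl.holes``.
    """
    return ndimage.label(sl.holes, structure=_CROSS)
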