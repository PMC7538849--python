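"""The nine imaging biomarkers (IBMs) of solid vs non-solid tumor composition.

Composition scores (RDC, RLC, DoC, AT_R) are per-slice pixel ratios averaged
over tumor-bearing slices.  Geometric scores (Span, LoSA, LoCA and their
ratios) are distances between boundary vertices, in pixel units scaled by the
in-plane spacing.  Solidity is the classical extent: solid pixels over the
mask bounding box.

Averaging conventions: ratio-of-pixel-count scores average over every slice
with a nonempty mask, while cavity-geometry scores (LoCA) average over slices
that actually contain a lucent region — a hole-free slice has no inner
diameter to contribute.  Hole-free volumes return 0 for LoSA/LoCA by
convention so solid controls flow through the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy.spatial.distance import cdist, pdist

from .volume import (
    SlicePair,
    TumorVolume,
    boundary_pixels,
    lucent_components,
    pixel_counts,
)

__all__ = [
    "IBMVector",
    "IBM_NAMES",
    "rdc",
    "rlc",
    "doc",
    "at_ratio",
    "span",
    "losa",
    "losa_ratio",
    "inner_diameter",
    "loca",
    "loca_ratio",
    "solidity",
    "compute_all",
    "ibm_table",
]

IBM_NAMES = ("rdc", "rlc", "doc", "at_r", "losa", "losa_r", "loca", "loca_r", "solidity")


@dataclass(frozen=True)
class IBMVector:
    """The nine imaging biomarker values for one subject."""

    rdc: float
    rlc: float
    doc: float
    at_r: float
    losa: float
    losa_r: float
    loca: float
    loca_r: float
    solidity: float

    def as_dict(self) -> dict:
        return asdict(self)


def _tumor_slices(volume: TumorVolume):
    slices = volume.tumor_slices()
    if not slices:
        raise ValueError("no tumor pixels in volume")
    return slices


def rdc(volume: TumorVolume) -> float:
    """Radio-dense composition: mean over slices of P_A / P_B."""
    ratios = []
    for sl in _tumor_slices(volume):
        c = pixel_counts(sl)
        ratios.append(c.pa / c.pb)
    return float(np.mean(ratios))


def rlc(volume: TumorVolume) -> float:
    """Radio-lucent composition: mean over slices of (P_B - P_A) / P_B."""
    ratios = []
    for sl in _tumor_slices(volume):
        c = pixel_counts(sl)
        ratios.append((c.pb - c.pa) / c.pb)
    return float(np.mean(ratios))


def doc(rdc_value: float, rlc_value: float) -> float:
    """Difference of composition, |RDC - RLC|."""
    return float(np.sqrt((rdc_value - rlc_value) ** 2))


def at_ratio(volume: TumorVolume) -> float:
    """Air-to-tissue ratio: mean over slices of (P_B - P_A) / P_(B∩A)."""
    ratios = []
    for sl in _tumor_slices(volume):
        c = pixel_counts(sl)
        if c.pbia == 0:
            raise ValueError(f"no solid tissue in slice {sl.index}")
        ratios.append((c.pb - c.pa) / c.pbia)
    return float(np.mean(ratios))


def _max_pairwise(points: np.ndarray) -> float:
    if len(points) < 2:
        return 0.0
    # boundary sets are small (O(perimeter)); exact pairwise search
    return float(pdist(points.astype(float)).max())


def span(volume: TumorVolume) -> float:
    """Longest distance between two boundary vertices of the mask (max Feret).

    The maximum over tumor-bearing slices of the per-slice maximum pairwise
    Euclidean distance between boundary pixel centers of B, times the pixel
    spacing.
    """
    best = 0.0
    for sl in _tumor_slices(volume):
        d = _max_pairwise(boundary_pixels(sl.b)) * sl.spacing
        best = max(best, d)
    return best


def _largest_hole_boundary(sl: SlicePair) -> np.ndarray | None:
    labels, n = lucent_components(sl)
    if n == 0:
        return None
    areas = np.bincount(labels.ravel())[1:]
    largest = int(np.argmax(areas)) + 1
    return boundary_pixels(labels == largest)


def losa(volume: TumorVolume, method: str = "directed") -> float:
    """Length of solid area: the thickest wall between lucency and the mask rim.

    Per lucency-bearing slice, the boundary vertices of the largest lucent
    region are matched against the outer-mask boundary vertices.  With
    ``method="directed"`` (default) each lucent vertex contributes its nearest
    wall vertex and the thickest such wall is kept; ``method="max_pair"``
    instead takes the single farthest (lucent, wall) vertex pair.  The result
    is the maximum over slices, 0 for hole-free volumes.
    """
    if method not in ("directed", "max_pair"):
        raise ValueError(f"unknown LoSA method {method!r}")
    _tumor_slices(volume)  # validates nonempty
    best = 0.0
    for sl in volume.lucent_slices():
        inner = _largest_hole_boundary(sl)
        wall = boundary_pixels(sl.b)
        d = cdist(inner.astype(float), wall.astype(float))
        value = d.min(axis=1).max() if method == "directed" else d.max()
        best = max(best, float(value) * sl.spacing)
    return best


def losa_ratio(volume: TumorVolume, method: str = "directed") -> float:
    """LoSA normalized by the mask diameter Span; in [0, 1] for the default method."""
    s = span(volume)
    if s == 0:
        raise ValueError("degenerate mask: span is zero")
    return losa(volume, method=method) / s


def inner_diameter(sl: SlicePair) -> float:
    """Mean area-equivalent circle diameter, 2*sqrt(area/pi), of the slice's lucent regions."""
    labels, n = lucent_components(sl)
    if n == 0:
        raise ValueError("no lucent area")
    areas = np.bincount(labels.ravel())[1:]
    diameters = 2.0 * np.sqrt(areas / np.pi) * sl.spacing
    return float(diameters.mean())


def loca(volume: TumorVolume) -> float:
    """Length of cavity area: mean inner diameter over lucency-bearing slices."""
    _tumor_slices(volume)
    values = [inner_diameter(sl) for sl in volume.lucent_slices()]
    return float(np.mean(values)) if values else 0.0


def loca_ratio(volume: TumorVolume) -> float:
    """LoCA normalized by the mask diameter Span."""
    s = span(volume)
    if s == 0:
        raise ValueError("degenerate mask: span is zero")
    return loca(volume) / s


def solidity(volume: TumorVolume) -> float:
    """Solid pixels over the axis-aligned bounding box of the mask, slice-averaged.

    This is the measure usually called "extent" in image analysis.
    """
    values = []
    for sl in _tumor_slices(volume):
        rows = np.flatnonzero(np.any(sl.b, axis=1))
        cols = np.flatnonzero(np.any(sl.b, axis=0))
        bbox = (rows[-1] - rows[0] + 1) * (cols[-1] - cols[0] + 1)
        values.append(np.count_nonzero(sl.a) / bbox)
    return float(np.mean(values))


def compute_all(volume: TumorVolume, losa_method: str = "directed") -> IBMVector:
    """Compute all nine imaging biomarkers for one tumor volume."""
    r_d = rdc(volume)
    r_l = rlc(volume)
    s = span(volume)
    if s == 0:
        raise ValueError("degenerate mask: span is zero")
    lo_s = losa(volume, method=losa_method)
    lo_c = loca(volume)
    return IBMVector(
        rdc=r_d,
        rlc=r_l,
        doc=doc(r_d, r_l),
        at_r=at_ratio(volume),
        losa=lo_s,
        losa_r=lo_s / s,
        loca=lo_c,
        loca_r=lo_c / s,
        solidity=solidity(volume),
    )


def ibm_table(volumes: dict, losa_method: str = "directed"):
    """Per-subject IBM table for a mapping subject_id -> TumorVolume."""
    import pandas as pd

    rows = []
    for subject_id, vol in volumes.items():
        rec = {"subject_id": subject_id}
        rec.update(compute_all(vol, losa_method=losa_method).as_dict())
        rec["n_slices"] = vol.n_tumor
        rec["n_lucent_slices"] = vol.n_lucent
        rows.append(rec)
    return pd.DataFrame(rows)
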