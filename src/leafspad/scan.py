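"""Scan processing: from a raw leaf scan to a per-part DN table and a
digitized width profile.

Stages (in pipeline order):

1. :func:`normalize_scan` — linear reflectance normalization per channel
   using the black/white cardboard standards (black mean -> 0, white
   mean -> 255), making DN comparable across scan sessions.
2. :func:`segment_leaf` — excess-green thresholding plus largest connected
   component to isolate the blade from the white scanner background.
3. :func:`extract_width_profile` — digitize the silhouette into a
   :class:`~leafspad.containers.LeafShape` (width vs distance from base)
   along the mask's principal axis.
4. :func:`slice_segments` — cut the blade into k parts of equal axial
   LENGTH (not equal area), base to tip.
5. :func:`segment_dn` — per-part mean DN per band after excluding the
   central midrib strip and an eroded margin, mimicking how an operator
   avoids veins and leaf edges when reading a SPAD meter.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.ndimage import binary_erosion
from skimage.measure import label
from skimage.morphology import disk

from .containers import LeafScan, LeafShape, SegmentTable
from .errors import (
    DegenerateShapeError,
    DegenerateStandardsError,
    EmptyPartError,
    EmptySegmentationError,
    InvalidInputError,
    InvalidParameterError,
)

__all__ = [
    "ExclusionConfig",
    "normalize_scan",
    "segment_leaf",
    "extract_width_profile",
    "slice_segments",
    "segment_dn",
]

#: Excess-green threshold separating green tissue from white background.
DEFAULT_GREENNESS_THRESHOLD = 30
#: Smallest connected component accepted as a leaf, px.
DEFAULT_MIN_PIXELS = 100


@dataclass(frozen=True)
class ExclusionConfig:
    """Vein/margin exclusion applied before averaging DN over a part.

    midrib_frac : central fraction of each transect's width dropped
        (the midrib runs along the blade axis).
    erosion_px : radius of the binary erosion removing margin pixels.
    """

    midrib_frac: float = 0.2
    erosion_px: int = 2

    def __post_init__(self) -> None:
        if not 0.0 <= self.midrib_frac < 1.0:
            raise InvalidParameterError("midrib_frac must lie in [0, 1)")
        if self.erosion_px < 0:
            raise InvalidParameterError("erosion_px must be non-negative")


def normalize_scan(scan: LeafScan) -> LeafScan:
    """Map each channel linearly so the black standard averages 0 and the
    white standard 255, clipping to [0, 255].

    Idempotent up to rounding; raises
    :class:`~leafspad.errors.DegenerateStandardsError` if the white standard
    is not brighter than the black one in every channel.
    """
    black = scan.standard_means("black")
    white = scan.standard_means("white")
    if np.any(white <= black):
        raise DegenerateStandardsError("white standard mean <= black standard mean")
    dn = scan.raster.astype(float)
    normalized = (dn - black[None, None, :]) * (255.0 / (white - black))[None, None, :]
    raster = np.clip(np.rint(normalized), 0, 255).astype(np.uint8)
    return replace(scan, raster=raster)


def segment_leaf(
    scan: LeafScan,
    greenness_threshold: float = DEFAULT_GREENNESS_THRESHOLD,
    min_pixels: int = DEFAULT_MIN_PIXELS,
) -> np.ndarray:
    """Binary mask of the leaf blade in a normalized scan.

    Pixels pass the excess-green criterion ``2G - R - B > threshold`` (green
    tissue scores high, the white background and the grey standards near 0);
    the largest connected component is returned. Both standard regions are
    excluded unconditionally.
    """
    dn = scan.raster.astype(np.int32)
    exg = 2 * dn[..., 1] - dn[..., 0] - dn[..., 2]
    candidate = exg > greenness_threshold
    for rect in scan.standard_regions.values():
        candidate[rect.row0:rect.row1, rect.col0:rect.col1] = False
    labels, n_labels = label(candidate, return_num=True)
    if n_labels == 0:
        raise EmptySegmentationError("no green component found")
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    best = int(np.argmax(sizes))
    if sizes[best] < min_pixels:
        raise EmptySegmentationError(
            f"largest green component has {sizes[best]} px < {min_pixels}")
    return labels == best


def _principal_coords(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Axial and transverse pixel coordinates along the mask's long axis.

    Returns (t, v): projections of each masked pixel onto the principal
    direction (shifted so min(t) = 0) and its perpendicular.
    """
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise InvalidInputError("empty mask")
    pts = np.column_stack([rows, cols]).astype(float)
    centered = pts - pts.mean(axis=0)
    cov = centered.T @ centered / pts.shape[0]
    eigvals, eigvecs = np.linalg.eigh(cov)
    axis = eigvecs[:, np.argmax(eigvals)]
    t = centered @ axis
    v = centered @ np.array([-axis[1], axis[0]])
    return t - t.min(), v


def _base_at_low_t(t: np.ndarray, v: np.ndarray) -> bool:
    """True if the low-t end looks like the base (wider adjacent 10 %)."""
    extent = t.max()
    if extent == 0:
        return True
    lo = t <= 0.1 * extent
    hi = t >= 0.9 * extent
    width_lo = v[lo].max() - v[lo].min() if lo.any() else 0.0
    width_hi = v[hi].max() - v[hi].min() if hi.any() else 0.0
    return width_lo >= width_hi


def _oriented_axial(mask: np.ndarray, base: str) -> tuple[np.ndarray, np.ndarray]:
    """Axial coordinates with t = 0 at the base end.

    ``base``: 'auto' uses the wider-end heuristic, 'low'/'high' force the
    base to the low-/high-t end of the principal axis.
    """
    if base not in ("auto", "low", "high"):
        raise InvalidParameterError("base must be 'auto', 'low' or 'high'")
    t, v = _principal_coords(mask)
    flip = base == "high" or (base == "auto" and not _base_at_low_t(t, v))
    if flip:
        t = t.max() - t
    return t, v


def extract_width_profile(
    mask: np.ndarray,
    dpi: int,
    n_stations: int = 101,
    base: str = "auto",
) -> LeafShape:
    """Digitize a leaf mask into a width-vs-position profile.

    The blade axis is the principal direction of the mask; at ``n_stations``
    evenly spaced stations the width is the transect extent of the mask
    perpendicular to the axis, converted to cm (2.54/dpi per pixel). The
    profile runs base (position 0) to tip; the tip width is zero by
    construction of :class:`~leafspad.containers.LeafShape`.
    """
    if n_stations < 3:
        raise InvalidParameterError("n_stations must be at least 3")
    t, v = _oriented_axial(mask, base)
    extent = t.max()
    if extent <= 0:
        raise DegenerateShapeError("mask has no axial extent")
    if np.unique(np.rint(t)).size < 3:
        raise DegenerateShapeError("fewer than 3 transects with nonzero width")
    cm_per_px = 2.54 / dpi
    stations = np.linspace(0.0, extent, n_stations)
    half_window = max(0.5, extent / (n_stations - 1) / 2.0)
    widths_px = np.zeros(n_stations)
    for j, s in enumerate(stations):
        sel = np.abs(t - s) <= half_window
        if sel.any():
            widths_px[j] = v[sel].max() - v[sel].min() + 1.0
    if np.count_nonzero(widths_px) < 3:
        raise DegenerateShapeError("fewer than 3 stations with nonzero width")
    widths_px[-1] = 0.0  # blade tapers to a point at the tip
    return LeafShape(
        length_cm=extent * cm_per_px,
        positions_cm=stations * cm_per_px,
        widths_cm=widths_px * cm_per_px,
    )


def slice_segments(mask: np.ndarray, k: int, base: str = "auto") -> list[np.ndarray]:
    """Partition a leaf mask into k parts of equal axial length.

    Part 1 contains the base end. Returns k boolean masks that are pairwise
    disjoint and union to the input mask.
    """
    if k < 1:
        raise InvalidParameterError("k must be at least 1")
    t, _ = _oriented_axial(mask, base)
    extent = t.max()
    if k > extent + 1:
        raise InvalidParameterError(
            f"k = {k} exceeds axial pixel length {extent + 1:.0f}")
    bin_width = (extent + 1.0) / k
    part_idx = np.minimum((t / bin_width).astype(int), k - 1)
    rows, cols = np.nonzero(mask)
    parts = []
    for i in range(k):
        m = np.zeros_like(mask, dtype=bool)
        sel = part_idx == i
        m[rows[sel], cols[sel]] = True
        parts.append(m)
    return parts


def segment_dn(
    scan: LeafScan,
    parts: list[np.ndarray],
    exclusion: ExclusionConfig | None = None,
) -> SegmentTable:
    """Per-part mean DN per band, with vein/margin exclusion.

    Area per part is computed from the FULL part pixel count (exclusion only
    affects which pixels contribute to the DN means). The ``spad`` column is
    left NaN until a calibration is applied.
    """
    if not parts:
        raise InvalidInputError("parts must be non-empty")
    exclusion = exclusion or ExclusionConfig()
    full_mask = np.zeros_like(parts[0], dtype=bool)
    for p in parts:
        full_mask |= p

    surviving = full_mask
    if exclusion.erosion_px > 0:
        surviving = binary_erosion(full_mask, structure=disk(exclusion.erosion_px))
    if exclusion.midrib_frac > 0:
        surviving = surviving & ~_midrib_band(full_mask, exclusion.midrib_frac)

    dn = scan.raster.astype(float)
    area_per_px = scan.cm_per_px**2
    records = []
    for i, part in enumerate(parts, start=1):
        n_px = int(part.sum())
        surv = part & surviving
        if not surv.any():
            raise EmptyPartError(f"part {i} has no pixels after exclusion")
        means = dn[surv].mean(axis=0)
        records.append({
            "part": i,
            "area_cm2": n_px * area_per_px,
            "dn_r": means[0],
            "dn_g": means[1],
            "dn_b": means[2],
            "spad": np.nan,
            "pixel_count": n_px,
        })
    return SegmentTable(pd.DataFrame.from_records(records))


def _midrib_band(mask: np.ndarray, midrib_frac: float) -> np.ndarray:
    """Boolean mask of the central midrib strip.

    For each 1-px axial transect, pixels within the central ``midrib_frac``
    of the transect's transverse extent are flagged.
    """
    t, v = _principal_coords(mask)
    rows, cols = np.nonzero(mask)
    df = pd.DataFrame({"t": np.rint(t).astype(int), "v": v})
    g = df.groupby("t")["v"]
    vmin = g.transform("min").to_numpy()
    vmax = g.transform("max").to_numpy()
    center = (vmin + vmax) / 2.0
    half_band = midrib_frac * (vmax - vmin) / 2.0
    hit = np.abs(v - center) <= half_band
    band = np.zeros_like(mask, dtype=bool)
    band[rows[hit], cols[hit]] = True
    return band
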