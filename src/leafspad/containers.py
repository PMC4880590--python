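"""Domain containers shared across the pipeline.

A rice leaf blade is represented three ways here:

* :class:`LeafShape` — the digitized silhouette: blade width (cm) as a
  function of distance from the leaf base (cm).
* :class:`ChlorophyllProfile` — a quadratic model of the SPAD value (a
  unitless chlorophyll index) against distance L from the leaf base,
  ``SPAD(L) = a2*L^2 + a1*L + a0``.
* :class:`LeafScan` — an 8-bit RGB raster from a flatbed scanner, with the
  black/white cardboard reflectance standards located in pixel coordinates.

:class:`SegmentTable` holds the per-part summary (the blade cut into k
equal-length parts from base to tip): area, mean digital number (DN) per
band, and the SPAD value assigned to the part.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

from .errors import DegenerateStandardsError, InvalidInputError, InvalidParameterError

__all__ = [
    "LeafShape",
    "ChlorophyllProfile",
    "LeafScan",
    "SegmentTable",
    "Rect",
]


class Rect(NamedTuple):
    """Half-open pixel rectangle [row0, row1) x [col0, col1)."""

    row0: int
    col0: int
    row1: int
    col1: int


@dataclass(frozen=True)
class LeafShape:
    """Width profile of a leaf blade.

    Parameters
    ----------
    length_cm
        Blade length from base to tip, cm.
    positions_cm
        Strictly increasing sample positions; first must be 0, last must be
        ``length_cm``.
    widths_cm
        Blade width at each position, cm; non-negative, zero at the tip.
    strict
        When False, the taper-to-zero tip requirement is waived. Real and
        generated blades always taper; the relaxed mode exists for analytic
        reference shapes (e.g. an exact constant-width slab) used to check
        the area integrals against closed forms.
    """

    length_cm: float
    positions_cm: np.ndarray
    widths_cm: np.ndarray
    strict: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "positions_cm", np.asarray(self.positions_cm, dtype=float))
        object.__setattr__(self, "widths_cm", np.asarray(self.widths_cm, dtype=float))
        p, w = self.positions_cm, self.widths_cm
        if not np.isfinite(self.length_cm) or self.length_cm <= 0:
            raise InvalidParameterError("length_cm must be positive")
        if p.ndim != 1 or p.shape != w.shape or p.size < 2:
            raise InvalidInputError("positions and widths must be 1-D, equal length >= 2")
        if np.any(np.diff(p) <= 0):
            raise InvalidInputError("positions must be strictly increasing")
        if p[0] != 0 or not np.isclose(p[-1], self.length_cm):
            raise InvalidInputError("positions must span [0, length_cm]")
        if np.any(w < 0):
            raise InvalidInputError("widths must be non-negative")
        if self.strict and w[-1] != 0:
            raise InvalidInputError("width at the tip must be 0")

    @property
    def samples(self) -> list[tuple[float, float]]:
        return list(zip(self.positions_cm.tolist(), self.widths_cm.tolist()))

    def width_at(self, position_cm):
        """Linearly interpolated width at one or more positions (cm)."""
        return np.interp(position_cm, self.positions_cm, self.widths_cm)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"position_cm": self.positions_cm, "width_cm": self.widths_cm}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "LeafShape":
        df = pd.read_csv(path)
        pos = df["position_cm"].to_numpy(float)
        return cls(length_cm=float(pos[-1]), positions_cm=pos,
                   widths_cm=df["width_cm"].to_numpy(float))


@dataclass(frozen=True)
class ChlorophyllProfile:
    """Quadratic chlorophyll profile SPAD(L) = a2*L^2 + a1*L + a0.

    L is the distance (cm) from the leaf base; ``length_cm`` bounds the
    physical domain. Field-observed profiles are concave (a2 < 0): SPAD
    rises from the base, peaks at 50-60 % of the blade, and falls to the tip.
    """

    a2: float
    a1: float
    a0: float
    length_cm: float

    def __post_init__(self) -> None:
        coeffs = (self.a2, self.a1, self.a0)
        if not all(np.isfinite(c) for c in coeffs):
            raise InvalidParameterError("profile coefficients must be finite")
        if not np.isfinite(self.length_cm) or self.length_cm <= 0:
            raise InvalidParameterError("length_cm must be positive")

    def __call__(self, L):
        L = np.asarray(L, dtype=float)
        out = self.a2 * L**2 + self.a1 * L + self.a0
        return float(out) if out.ndim == 0 else out

    @property
    def coefficients(self) -> tuple[float, float, float]:
        """(a2, a1, a0), highest degree first."""
        return (self.a2, self.a1, self.a0)

    @property
    def vertex_position_cm(self) -> float:
        if self.a2 == 0:
            raise InvalidParameterError("linear profile has no vertex")
        return -self.a1 / (2.0 * self.a2)

    @property
    def vertex_spad(self) -> float:
        return self(self.vertex_position_cm)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"a2": self.a2, "a1": self.a1, "a0": self.a0,
             "length_cm": self.length_cm}, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "ChlorophyllProfile":
        d = json.loads(Path(path).read_text())
        return cls(a2=d["a2"], a1=d["a1"], a0=d["a0"], length_cm=d["length_cm"])


@dataclass
class LeafScan:
    """8-bit RGB scanner raster with reflectance-standard regions.

    ``standard_regions`` maps ``"black"``/``"white"`` to :class:`Rect`
    rectangles covering the cardboard standards; the white region must be
    brighter than the black one in every channel.

    ``ground_truth`` is populated only by the synthetic renderer (true leaf
    mask, generating shape/profile) so round-trip tests can compare against
    it; it is never read by the processing code.
    """

    raster: np.ndarray
    dpi: int
    standard_regions: dict[str, Rect]
    ground_truth: dict | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        r = np.asarray(self.raster)
        if r.ndim != 3 or r.shape[2] != 3:
            raise InvalidInputError("raster must be HxWx3")
        if r.dtype != np.uint8:
            if r.min() < 0 or r.max() > 255:
                raise InvalidInputError("DN values must lie in [0, 255]")
            r = r.astype(np.uint8)
        self.raster = r
        if self.dpi <= 0:
            raise InvalidParameterError("dpi must be positive")
        for name in ("black", "white"):
            if name not in self.standard_regions:
                raise InvalidInputError(f"missing {name!r} standard region")
            rect = Rect(*self.standard_regions[name])
            if not (0 <= rect.row0 < rect.row1 <= r.shape[0]
                    and 0 <= rect.col0 < rect.col1 <= r.shape[1]):
                raise InvalidInputError(f"{name!r} standard region out of bounds")
            self.standard_regions[name] = rect
        if np.any(self.standard_means("white") <= self.standard_means("black")):
            raise DegenerateStandardsError(
                "white standard must be brighter than black in every channel")

    def standard_means(self, name: str) -> np.ndarray:
        """Per-channel mean DN of one standard region."""
        r = self.standard_regions[name]
        patch = self.raster[r.row0:r.row1, r.col0:r.col1, :]
        return patch.reshape(-1, 3).mean(axis=0)

    @property
    def cm_per_px(self) -> float:
        return 2.54 / self.dpi


_SEGMENT_COLUMNS = ["part", "area_cm2", "dn_r", "dn_g", "dn_b", "spad", "pixel_count"]


@dataclass
class SegmentTable:
    """Per-part summary of a blade divided into k equal-length parts.

    Part 1 is at the base, part k at the tip. ``spad`` is NaN until a
    DN-to-SPAD calibration has been applied.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in _SEGMENT_COLUMNS if c not in df.columns]
        if missing:
            raise InvalidInputError(f"SegmentTable missing columns {missing}")
        if len(df) < 1:
            raise InvalidInputError("SegmentTable needs at least one part")
        parts = df["part"].to_numpy()
        if not np.array_equal(parts, np.arange(1, len(df) + 1)):
            raise InvalidInputError("part indices must run 1..k consecutively")
        if np.any(df["area_cm2"].to_numpy() <= 0):
            raise InvalidInputError("part areas must be positive")

    @property
    def k(self) -> int:
        return len(self.data)

    @property
    def spad(self) -> np.ndarray:
        return self.data["spad"].to_numpy(float)

    @property
    def areas_cm2(self) -> np.ndarray:
        return self.data["area_cm2"].to_numpy(float)

    def with_spad(self, spad_values: np.ndarray) -> "SegmentTable":
        spad_values = np.asarray(spad_values, dtype=float)
        if spad_values.shape != (self.k,):
            raise InvalidInputError("spad vector length must equal k")
        df = self.data.copy()
        df["spad"] = spad_values
        return SegmentTable(df)

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "SegmentTable":
        return cls(pd.read_csv(path))
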