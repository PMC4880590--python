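"""Image and sidecar I/O for leaf scans.

A :class:`~leafspad.containers.LeafScan` round-trips as an 8-bit RGB PNG
plus a JSON sidecar (same stem, ``.json``) carrying the dpi and the pixel
rectangles of the black/white reflectance standards — metadata a PNG cannot
hold reliably.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from PIL import Image

from .containers import LeafScan, Rect

__all__ = ["write_scan", "read_scan"]


def _sidecar_path(image_path: str | Path) -> Path:
    return Path(image_path).with_suffix(".json")


def write_scan(scan: LeafScan, image_path: str | Path) -> None:
    """Write the raster as PNG and the metadata as a JSON sidecar."""
    image_path = Path(image_path)
    Image.fromarray(scan.raster, mode="RGB").save(image_path)
    meta = {
        "dpi": scan.dpi,
        "standard_regions": {
            name: list(rect) for name, rect in scan.standard_regions.items()
        },
    }
    _sidecar_path(image_path).write_text(json.dumps(meta, indent=2))


def read_scan(
    image_path: str | Path,
    dpi: int | None = None,
    standard_regions: dict | None = None,
) -> LeafScan:
    """Read a PNG/TIFF/JPEG scan.

    dpi and standard regions come from the JSON sidecar when present;
    explicit arguments override it.
    """
    image_path = Path(image_path)
    raster = np.asarray(Image.open(image_path).convert("RGB"))
    meta: dict = {}
    sidecar = _sidecar_path(image_path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    if dpi is None:
        dpi = meta.get("dpi")
    if standard_regions is None:
        standard_regions = meta.get("standard_regions")
    if dpi is None or standard_regions is None:
        raise ValueError(
            "dpi and standard_regions must be given or present in the sidecar")
    regions = {name: Rect(*vals) for name, vals in standard_regions.items()}
    return LeafScan(raster=raster, dpi=int(dpi), standard_regions=regions)
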