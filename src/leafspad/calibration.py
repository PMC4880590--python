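"""Linear DN-to-SPAD calibration for flatbed scanner bands.

A SPAD chlorophyll meter and a flatbed scanner see the same pigment: over
the working range the red-band digital number (DN) of a scanned rice leaf
is linearly related to its SPAD reading. The shipped constant
:func:`published_model` is the red-band least-squares fit

    SPAD = -0.2509 * R + 52.735        (r^2 = 0.851, n = 39)

obtained from field-sampled leaves at tillering; :func:`fit_dn_spad` refits
the relation from local (dn, spad) pairs when a scanner-specific
calibration is available.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidParameterError, SingularDesignError

__all__ = ["CalibrationModel", "fit_dn_spad", "dn_to_spad", "published_model"]

logger = logging.getLogger(__name__)

_BANDS = ("red", "green", "blue")


@dataclass(frozen=True)
class CalibrationModel:
    """Linear map SPAD = slope * DN + intercept for one scanner band.

    ``p_value`` is the F-test p of the regression; NaN for the published
    constant (the source reports only significance at p < 0.01).
    """

    band: str
    slope: float
    intercept: float
    r2: float
    n: int
    p_value: float = math.nan

    def __post_init__(self) -> None:
        if self.band not in _BANDS:
            raise InvalidParameterError(f"band must be one of {_BANDS}")
        if not 0.0 <= self.r2 <= 1.0:
            raise InvalidParameterError("r2 must lie in [0, 1]")
        if self.n < 2:
            raise InvalidParameterError("n must be at least 2")
        if not math.isnan(self.p_value) and not 0.0 <= self.p_value <= 1.0:
            raise InvalidParameterError("p_value must lie in [0, 1] or be NaN")

    def predict(self, dn):
        return dn_to_spad(self, dn)

    def summary(self) -> str:
        return (
            f"DN->SPAD calibration ({self.band} band)\n"
            f"  SPAD = {self.slope:+.4f} * DN + {self.intercept:.3f}\n"
            f"  r2 = {self.r2:.3f}   n = {self.n}   p = {self.p_value:.3g}"
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "CalibrationModel":
        return cls(**json.loads(Path(path).read_text()))


def fit_dn_spad(pairs, band: str = "red") -> CalibrationModel:
    """Ordinary least-squares fit of SPAD against DN.

    Parameters
    ----------
    pairs
        Sequence of (dn, spad) tuples, or a DataFrame with ``dn`` and
        ``spad`` columns.
    band
        Scanner band the pairs were measured on.
    """
    if isinstance(pairs, pd.DataFrame):
        dn = pairs["dn"].to_numpy(float)
        spad = pairs["spad"].to_numpy(float)
    else:
        arr = np.asarray(list(pairs), dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
            raise InvalidParameterError("need at least two (dn, spad) pairs")
        dn, spad = arr[:, 0], arr[:, 1]
    if np.ptp(dn) == 0:
        raise SingularDesignError("all DN values are equal; slope is undefined")
    res = stats.linregress(dn, spad)
    # For simple regression the F-test p equals the slope t-test p.
    return CalibrationModel(
        band=band,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        n=int(dn.size),
        p_value=float(res.pvalue),
    )


def dn_to_spad(model: CalibrationModel, dn):
    """Apply a calibration to one DN value or an array of them."""
    dn_arr = np.asarray(dn, dtype=float)
    if np.any(dn_arr < 0) or np.any(dn_arr > 255):
        logger.warning("DN values outside [0, 255] passed to dn_to_spad")
    out = model.slope * dn_arr + model.intercept
    return float(out) if out.ndim == 0 else out


def published_model() -> CalibrationModel:
    """The shipped red-band calibration constant (see module docstring).

    Use when no scanner-local calibration pairs exist.
    """
    return CalibrationModel(band="red", slope=-0.2509, intercept=52.735,
                            r2=0.851, n=39)
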