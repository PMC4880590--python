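"""Quadratic chlorophyll-distribution model along the blade.

Along a rice leaf blade the SPAD value rises from the base, peaks at 50-60 %
of the length and falls toward the tip; a concave quadratic

    SPAD(L) = a2*L^2 + a1*L + a0,   a2 < 0

describes the profile well. This module fits that quadratic by least
squares, evaluates it, and provides the max-normalization used to compare
profiles across leaves of different overall greenness.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .containers import ChlorophyllProfile
from .errors import InvalidInputError, SingularDesignError

__all__ = [
    "ProfileFitReport",
    "fit_profile",
    "evaluate_profile",
    "normalize_to_max",
    "relative_range",
    "plot_profile",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ProfileFitReport:
    """Result of a quadratic profile fit.

    Carries the fitted :class:`~leafspad.containers.ChlorophyllProfile`
    (coefficients in cm of distance from the base), the same quadratic
    re-expressed against proportional position ``f = L / length`` (as used
    when pooling leaves of different length), r^2, and the vertex.
    """

    profile: ChlorophyllProfile
    r2: float
    n: int
    vertex_position_cm: float
    vertex_spad: float
    #: (a2', a1', a0') of SPAD(f) with f = L/length in [0, 1].
    proportional_coefficients: tuple[float, float, float]

    def summary(self) -> str:
        a2, a1, a0 = self.profile.coefficients
        return (
            "Quadratic chlorophyll profile fit\n"
            f"  SPAD(L) = {a2:+.4f} L^2 {a1:+.4f} L {a0:+.3f}   (L in cm)\n"
            f"  r2 = {self.r2:.4f}   n = {self.n}\n"
            f"  vertex: L = {self.vertex_position_cm:.3f} cm, "
            f"SPAD = {self.vertex_spad:.3f}"
        )

    def to_json(self, path: str | Path) -> None:
        a2, a1, a0 = self.profile.coefficients
        Path(path).write_text(json.dumps({
            "a2": a2, "a1": a1, "a0": a0,
            "length_cm": self.profile.length_cm,
            "r2": self.r2, "n": self.n,
            "vertex_position_cm": self.vertex_position_cm,
            "vertex_spad": self.vertex_spad,
            "proportional_coefficients": list(self.proportional_coefficients),
        }, indent=2))


def fit_profile(points, length_cm: float | None = None) -> ProfileFitReport:
    """Least-squares quadratic fit of SPAD against position.

    Parameters
    ----------
    points
        Sequence of (position_cm, spad) pairs; at least 3 distinct positions.
    length_cm
        Physical blade length bounding the profile's domain; defaults to the
        largest observed position.

    With exactly 3 distinct positions the fit interpolates them exactly.
    The quadratic is solved through an orthogonal (SVD) decomposition of the
    Vandermonde design, giving the exact least-squares minimizer.
    """
    arr = np.asarray(list(points), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise InvalidInputError("points must be (position_cm, spad) pairs")
    pos, spad = arr[:, 0], arr[:, 1]
    if np.unique(pos).size < 3:
        raise SingularDesignError("need at least 3 distinct positions")
    # polyfit in the polynomial package solves the Vandermonde LS via SVD.
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", np.exceptions.RankWarning)
        c = np.polynomial.polynomial.polyfit(pos, spad, deg=2)  # [a0, a1, a2]
    fitted = c[0] + c[1] * pos + c[2] * pos**2
    ss_res = float(np.sum((spad - fitted) ** 2))
    ss_tot = float(np.sum((spad - spad.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else max(0.0, min(1.0, 1.0 - ss_res / ss_tot))
    length = float(length_cm) if length_cm is not None else float(pos.max())
    profile = ChlorophyllProfile(a2=float(c[2]), a1=float(c[1]), a0=float(c[0]),
                                 length_cm=length)
    if c[2] != 0:
        vx = profile.vertex_position_cm
        vy = profile.vertex_spad
    else:
        vx, vy = np.nan, np.nan
    return ProfileFitReport(
        profile=profile,
        r2=r2,
        n=int(pos.size),
        vertex_position_cm=vx,
        vertex_spad=vy,
        proportional_coefficients=(
            float(c[2]) * length**2, float(c[1]) * length, float(c[0])),
    )


def evaluate_profile(profile: ChlorophyllProfile, L_cm):
    """Evaluate SPAD(L); warns when L lies outside [0, length_cm]."""
    L = np.asarray(L_cm, dtype=float)
    if np.any(~np.isfinite(L)):
        raise InvalidInputError("L must be finite")
    if L.size and (L.min() < 0 or L.max() > profile.length_cm):
        logger.warning("evaluating profile outside [0, %.3f] cm", profile.length_cm)
    return profile(L_cm)


def plot_profile(report: ProfileFitReport, points=None, path: str | Path | None = None):
    """Plot the fitted profile, its vertex, and optionally the data points.

    Returns the matplotlib figure; writes a PNG when ``path`` is given.
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    L = np.linspace(0, report.profile.length_cm, 200)
    ax.plot(L, report.profile(L), label=f"fit (r$^2$ = {report.r2:.3f})")
    if points is not None:
        pts = np.asarray(list(points), dtype=float)
        ax.plot(pts[:, 0], pts[:, 1], "o", ms=4, label="readings")
    if np.isfinite(report.vertex_position_cm):
        ax.plot(report.vertex_position_cm, report.vertex_spad, "k^",
                label="vertex")
    ax.set_xlabel("distance from leaf base (cm)")
    ax.set_ylabel("SPAD")
    ax.legend(frameon=False)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def normalize_to_max(spad_values) -> np.ndarray:
    """Divide SPAD values by their maximum (relative SPAD, max maps to 1)."""
    values = np.asarray(spad_values, dtype=float)
    if values.size == 0:
        raise InvalidInputError("empty input")
    vmax = values.max()
    if not vmax > 0:
        raise InvalidInputError("maximum must be positive")
    return values / vmax


def relative_range(relative_values) -> float:
    """Spread of relative SPAD values, (max - min) * 100, in percent."""
    values = np.asarray(relative_values, dtype=float)
    if values.size == 0:
        raise InvalidInputError("empty input")
    return float((values.max() - values.min()) * 100.0)
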