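"""Synthetic rice-leaf generator.

Produces leaf silhouettes, quadratic chlorophyll profiles, noisy SPAD
readings, and rendered flatbed-scanner images with the statistical structure
the downstream analysis assumes, so the whole pipeline is testable without
any field data.

The forward model for a rendered scan inverts the linear red-band DN-to-SPAD
calibration: inside the leaf silhouette the *true* red digital number at
axial position L is ``(SPAD(L) - intercept) / slope``. The scanner is then
emulated as a global affine response ``observed = gain * true + offset``
(applied to leaf, background and both cardboard standards alike) plus
additive Gaussian sensor noise, rounded and clipped to 8 bits. Because the
black/white standards are rendered at true DN 0 and 255, the reflectance
normalization stage recovers the true DN frame exactly (up to rounding).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import beta as beta_fn

from .calibration import CalibrationModel
from .containers import ChlorophyllProfile, LeafScan, LeafShape, Rect
from .errors import DomainError, GeometryError, InvalidParameterError

__all__ = [
    "GeneratorConfig",
    "make_leaf_shape",
    "make_profile",
    "sample_spad_readings",
    "render_leaf_scan",
    "analytic_blade_area",
    "u_shaped_part_sd",
    "simulate_part_spad",
]

#: Width of the blade at the base, as a fraction of the maximum width.
DEFAULT_BASE_FRAC = 0.02


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic scanner.

    noise_sd_spad : SD of SPAD-meter reading noise (SPAD units; ~0.3 matches
        typical meter repeatability).
    noise_sd_dn : SD of additive scanner sensor noise (DN units).
    dpi : raster resolution; 300 is the standard flatbed setting.
    gain, offset : the emulated global scanner response
        ``observed = gain * true + offset``; undone by normalization.
    """

    seed: int = 0
    noise_sd_spad: float = 0.3
    noise_sd_dn: float = 1.0
    dpi: int = 300
    gain: float = 0.92
    offset: float = 8.0
    max_canvas_px: int = 8000

    def __post_init__(self) -> None:
        if self.noise_sd_spad < 0 or self.noise_sd_dn < 0:
            raise InvalidParameterError("noise SDs must be non-negative")
        if self.dpi <= 0:
            raise InvalidParameterError("dpi must be positive")


def make_leaf_shape(
    length_cm: float,
    max_width_cm: float,
    peak_frac: float,
    n_samples: int,
    base_frac: float = DEFAULT_BASE_FRAC,
) -> LeafShape:
    """Build a single-peaked blade silhouette.

    The width rises from a small positive base width (``base_frac`` of the
    maximum) to ``max_width_cm`` at ``peak_frac * length_cm`` and tapers to
    zero at the tip. The family is a linearly tapering pedestal plus a
    beta-like bump ``(x/p) * ((Lt-x)/(Lt-p))**beta`` with the exponent solved
    so the bump peaks at p; its integral has a closed form (beta function),
    see :func:`analytic_blade_area`.
    """
    if length_cm <= 0 or max_width_cm <= 0:
        raise InvalidParameterError("length_cm and max_width_cm must be positive")
    if not 0 < peak_frac < 1:
        raise InvalidParameterError("peak_frac must lie in (0, 1)")
    if n_samples < 3:
        raise InvalidParameterError("n_samples must be at least 3")
    if not 0 <= base_frac < 1:
        raise InvalidParameterError("base_frac must lie in [0, 1)")

    Lt = float(length_cm)
    p = peak_frac * Lt
    x = np.linspace(0.0, Lt, n_samples)
    b = base_frac * max_width_cm
    bump_amp = max_width_cm - b * (1.0 - peak_frac)
    if bump_amp <= 0:
        raise InvalidParameterError("base width too large for requested peak")
    beta_exp = (Lt - p) / p
    bump = (x / p) * ((Lt - x) / (Lt - p)) ** beta_exp
    w = b * (1.0 - x / Lt) + bump_amp * bump
    w[-1] = 0.0  # exact tip
    return LeafShape(length_cm=Lt, positions_cm=x, widths_cm=w)


def analytic_blade_area(
    length_cm: float,
    max_width_cm: float,
    peak_frac: float,
    base_frac: float = DEFAULT_BASE_FRAC,
) -> float:
    """Closed-form area (cm^2) of the :func:`make_leaf_shape` width family.

    Pedestal contributes ``b*Lt/2``; the bump integral reduces to a beta
    function after substituting u = x/Lt.
    """
    Lt = float(length_cm)
    p = peak_frac * Lt
    b = base_frac * max_width_cm
    bump_amp = max_width_cm - b * (1.0 - peak_frac)
    beta_exp = (Lt - p) / p
    u_peak = peak_frac
    bump_integral = (
        Lt * beta_fn(2.0, beta_exp + 1.0) / (u_peak * (1.0 - u_peak) ** beta_exp)
    )
    return b * Lt / 2.0 + bump_amp * bump_integral


def make_profile(
    length_cm: float, base_spad: float, peak_spad: float, peak_frac: float
) -> ChlorophyllProfile:
    """Concave quadratic SPAD profile from vertex form.

    The vertex sits at ``(peak_frac * length_cm, peak_spad)`` and the value
    at the base (L = 0) is ``base_spad``, so the curvature is
    ``-(peak - base) / vertex**2`` and a2 < 0 always.
    """
    if peak_spad <= base_spad:
        raise InvalidParameterError("peak_spad must exceed base_spad")
    if not 0 < peak_frac < 1:
        raise InvalidParameterError("peak_frac must lie in (0, 1)")
    v = peak_frac * length_cm
    s = (peak_spad - base_spad) / v**2
    return ChlorophyllProfile(a2=-s, a1=2.0 * s * v, a0=base_spad,
                              length_cm=length_cm)


def sample_spad_readings(
    profile: ChlorophyllProfile,
    positions_cm,
    noise_sd_spad: float,
    seed: int,
) -> list[tuple[float, float]]:
    """Noisy SPAD-meter readings at the given positions along the blade."""
    positions = np.asarray(positions_cm, dtype=float)
    if positions.size and (positions.min() < 0 or positions.max() > profile.length_cm):
        raise DomainError("positions must lie within [0, length_cm]")
    if noise_sd_spad < 0:
        raise InvalidParameterError("noise_sd_spad must be non-negative")
    values = np.atleast_1d(profile(positions))
    if noise_sd_spad > 0:
        rng = np.random.default_rng(seed)
        values = values + rng.normal(0.0, noise_sd_spad, size=positions.shape)
    return list(zip(positions.tolist(), values.tolist()))


# Rendering layout, in px at the working dpi.
_MARGIN_PX = 12
_PATCH_CM = (1.0, 0.5)  # width x height of each reflectance standard


def render_leaf_scan(
    shape: LeafShape,
    profile: ChlorophyllProfile,
    calibration: CalibrationModel,
    config: GeneratorConfig,
) -> LeafScan:
    """Render an 8-bit RGB scan of one blade plus reflectance standards.

    The blade lies horizontally, base at the left, silhouette symmetric
    about its midline. Green is an affine function of red
    (``0.55*red + 110``) and blue is a constant 20, reproducing the
    observed band ordering green > red > blue while keeping red the
    information carrier.
    """
    if calibration.slope == 0:
        raise InvalidParameterError("calibration slope must be non-zero")
    px_per_cm = config.dpi / 2.54
    leaf_len_px = int(round(shape.length_cm * px_per_cm))
    max_halfw_px = float(np.max(shape.widths_cm)) * px_per_cm / 2.0
    band_h = int(np.ceil(2 * max_halfw_px)) + 4
    patch_w = int(round(_PATCH_CM[0] * px_per_cm))
    patch_h = int(round(_PATCH_CM[1] * px_per_cm))

    height = _MARGIN_PX + patch_h + _MARGIN_PX + band_h + _MARGIN_PX
    width = _MARGIN_PX + max(leaf_len_px, 2 * patch_w + 3 * _MARGIN_PX) + _MARGIN_PX
    if height > config.max_canvas_px or width > config.max_canvas_px:
        raise GeometryError(
            f"canvas {height}x{width}px exceeds limit {config.max_canvas_px}px"
        )

    true = np.full((height, width, 3), 255.0)

    # Reflectance standards near the top edge: black left, white right.
    black = Rect(_MARGIN_PX, _MARGIN_PX, _MARGIN_PX + patch_h, _MARGIN_PX + patch_w)
    white = Rect(_MARGIN_PX, width - _MARGIN_PX - patch_w,
                 _MARGIN_PX + patch_h, width - _MARGIN_PX)
    true[black.row0:black.row1, black.col0:black.col1, :] = 0.0
    true[white.row0:white.row1, white.col0:white.col1, :] = 255.0

    # Leaf silhouette: per column axial position L, half-width in px.
    leaf_row0 = _MARGIN_PX + patch_h + _MARGIN_PX
    mid = leaf_row0 + band_h / 2.0
    cols = np.arange(leaf_len_px)
    L = (cols + 0.5) / px_per_cm
    halfw_px = shape.width_at(L) * px_per_cm / 2.0
    rows = np.arange(height)
    mask = np.zeros((height, width), dtype=bool)
    mask[:, _MARGIN_PX:_MARGIN_PX + leaf_len_px] = (
        np.abs(rows[:, None] + 0.5 - mid) <= halfw_px[None, :]
    )

    red_true = (profile(L) - calibration.intercept) / calibration.slope
    red_cols = np.zeros(width)
    red_cols[_MARGIN_PX:_MARGIN_PX + leaf_len_px] = red_true
    red_field = np.broadcast_to(red_cols, (height, width))
    true[..., 0] = np.where(mask, red_field, true[..., 0])
    true[..., 1] = np.where(mask, 0.55 * red_field + 110.0, true[..., 1])
    true[..., 2] = np.where(mask, 20.0, true[..., 2])

    rng = np.random.default_rng(config.seed)
    observed = config.gain * true + config.offset
    if config.noise_sd_dn > 0:
        observed = observed + rng.normal(0.0, config.noise_sd_dn, size=true.shape)
    raster = np.clip(np.rint(observed), 0, 255).astype(np.uint8)

    return LeafScan(
        raster=raster,
        dpi=config.dpi,
        standard_regions={"black": black, "white": white},
        ground_truth={"mask": mask, "shape": shape, "profile": profile,
                      "leaf_col0": _MARGIN_PX, "leaf_len_px": leaf_len_px},
    )


def u_shaped_part_sd(
    k: int = 10,
    sd_min: float = 0.3,
    curvature: float = 10.0,
    center_frac: float = 0.7,
) -> np.ndarray:
    """Per-part SPAD noise SDs following the U-shape seen along real blades.

    Measurement variance is highest near the base and tip and lowest in the
    60-80 % region; with the default center at 0.7 the minimum is shared by
    parts 7 and 8 of 10. SD at part midpoint m is
    ``sd_min + curvature * (m - center_frac)**2``.
    """
    m = (np.arange(1, k + 1) - 0.5) / k
    return sd_min + curvature * (m - center_frac) ** 2


def simulate_part_spad(
    profile: ChlorophyllProfile,
    part_sd: np.ndarray,
    n_leaves: int,
    seed: int,
) -> np.ndarray:
    """Simulate per-part SPAD means for a population of leaves.

    Returns an ``(n_leaves, k)`` array: the profile evaluated at each part
    midpoint plus independent Gaussian noise with the part-specific SD.
    """
    part_sd = np.asarray(part_sd, dtype=float)
    if np.any(part_sd < 0):
        raise InvalidParameterError("part SDs must be non-negative")
    if n_leaves < 1:
        raise InvalidParameterError("n_leaves must be at least 1")
    k = part_sd.size
    midpoints = (np.arange(1, k + 1) - 0.5) / k * profile.length_cm
    means = profile(midpoints)
    rng = np.random.default_rng(seed)
    return means[None, :] + rng.normal(0.0, 1.0, size=(n_leaves, k)) * part_sd[None, :]
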