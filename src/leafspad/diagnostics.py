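"""Variance diagnostics, position selection, chlorophyll extraction, and
SPAD-vs-nitrogen regression machinery.

Two variance views motivate where on the blade to place the SPAD meter:

* :func:`part_sd` — SD of per-part SPAD values across a population of
  scanned blades (variance along the blade; lowest in the 60-80 % region).
* :func:`dipositional_sd` — SD across replicate leaves of meter readings
  taken at the a (1/3), b (1/2) and c (2/3) positions and their averaged
  combinations ab, ac, bc, abc.

:func:`select_position` applies the selection rule: among the candidate
positions where the profile attains the representative value, recommend the
one sitting in the lowest-variance part (ties break toward 2/3).

:func:`chla_b` is the spectrophotometric chlorophyll a+b concentration from
ethanol-extract absorbances, and :func:`regress_linear` /
:func:`regress_quadratic` provide the OLS machinery (with 95 % pointwise
confidence bands) used to relate SPAD indicators to chlorophyll and leaf
nitrogen concentration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .containers import SegmentTable
from .errors import InvalidInputError, NoCandidateError, SingularDesignError

__all__ = [
    "DiPositionalReadings",
    "AbsorbanceSample",
    "RegressionReport",
    "SelectionResult",
    "part_sd",
    "dipositional_sd",
    "select_position",
    "chla_b",
    "regress_linear",
    "regress_quadratic",
]

POSITIONS = ("a", "b", "c")  # 1/3, 1/2, 2/3 of the distance from the base
COMBINATIONS = ("a", "b", "c", "ab", "ac", "bc", "abc")
LEAF_RANKS = ("LFT1", "LFT2", "LFT3", "LFT4")


def part_sd(tables: list[SegmentTable]) -> np.ndarray:
    """Per-part sample SD (n-1 denominator) of SPAD across blades.

    All tables must share the same part count k; returns an array of k SDs,
    base to tip.
    """
    if len(tables) < 2:
        raise InvalidInputError("need at least 2 tables")
    k = tables[0].k
    if any(t.k != k for t in tables):
        raise InvalidInputError("all tables must have the same part count")
    spad = np.vstack([t.spad for t in tables])
    if np.any(~np.isfinite(spad)):
        raise InvalidInputError("tables contain unset (NaN) SPAD values")
    return spad.std(axis=0, ddof=1)


@dataclass(frozen=True)
class DiPositionalReadings:
    """SPAD-meter readings at the a/b/c positions on replicate leaves.

    ``data`` columns: replicate (any hashable id), position ('a'|'b'|'c'),
    spad. Every replicate must carry all three positions.
    """

    leaf_rank: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.leaf_rank not in LEAF_RANKS:
            raise InvalidInputError(f"leaf_rank must be one of {LEAF_RANKS}")
        df = self.data
        for col in ("replicate", "position", "spad"):
            if col not in df.columns:
                raise InvalidInputError(f"readings missing column {col!r}")
        if not set(df["position"]).issubset(POSITIONS):
            raise InvalidInputError("positions must be 'a', 'b' or 'c'")
        if np.any(~np.isfinite(df["spad"].to_numpy(float))):
            raise InvalidInputError("readings must be finite")
        counts = df.pivot_table(index="replicate", columns="position",
                                values="spad", aggfunc="count")
        if counts.shape[1] < 3 or (counts != 1).any().any():
            raise InvalidInputError(
                "every replicate needs exactly one reading per position a/b/c")

    @property
    def n_replicates(self) -> int:
        return self.data["replicate"].nunique()

    def wide(self) -> pd.DataFrame:
        """Replicate-by-position table of readings."""
        return self.data.pivot(index="replicate", columns="position",
                               values="spad")[list(POSITIONS)]


def dipositional_sd(readings: DiPositionalReadings) -> dict[str, float]:
    """SD across replicates for each position combination.

    For a combination (e.g. 'bc') each replicate leaf contributes the MEAN
    of its member-position readings; the SD (n-1) is then taken across
    replicates. Returns all 7 combinations a, b, c, ab, ac, bc, abc.
    """
    if readings.n_replicates < 2:
        raise InvalidInputError("need at least 2 replicates")
    wide = readings.wide()
    out = {}
    for combo in COMBINATIONS:
        scores = wide[list(combo)].mean(axis=1)
        out[combo] = float(scores.std(ddof=1))
    return out


@dataclass(frozen=True)
class SelectionResult:
    """Recommended measurement position plus the reasoning trail."""

    position_frac: float
    part: int
    rationale: dict = field(repr=False)


def select_position(
    candidate_positions_frac,
    sd_by_part,
    preferred_frac: float = 2.0 / 3.0,
) -> SelectionResult:
    """Pick the candidate position lying in the lowest-variance part.

    Candidates are fractions of the blade length (typically the two roots of
    the profile at the representative value). The part containing fraction p
    is ``ceil(p * k)`` with k = len(sd_by_part); ties in part SD break
    toward the candidate closest to ``preferred_frac`` (2/3 by default,
    the distal reading position a field operator can locate reliably).
    """
    candidates = np.asarray(candidate_positions_frac, dtype=float)
    if candidates.size == 0:
        raise NoCandidateError("no candidate positions")
    sd_by_part = np.asarray(sd_by_part, dtype=float)
    k = sd_by_part.size
    if k < 1:
        raise InvalidInputError("sd_by_part must be non-empty")
    parts = np.clip(np.ceil(candidates * k).astype(int), 1, k)
    sds = sd_by_part[parts - 1]
    best_sd = sds.min()
    tied = np.isclose(sds, best_sd)
    dist = np.where(tied, np.abs(candidates - preferred_frac), np.inf)
    idx = int(np.argmin(dist))
    return SelectionResult(
        position_frac=float(candidates[idx]),
        part=int(parts[idx]),
        rationale={
            "candidates_frac": candidates.tolist(),
            "candidate_parts": parts.tolist(),
            "candidate_part_sd": sds.tolist(),
            "rule": "lowest part SD, tie toward preferred fraction",
            "preferred_frac": preferred_frac,
        },
    )


@dataclass(frozen=True)
class AbsorbanceSample:
    """Ethanol-extract absorbances for one leaf sample.

    A665/A649: absorbance at 665 and 649 nm; V: extract volume in liters;
    m: fresh sample mass in grams.
    """

    A665: float
    A649: float
    V: float
    m: float

    def __post_init__(self) -> None:
        if self.A665 < 0 or self.A649 < 0:
            raise InvalidInputError("absorbances must be non-negative")
        if self.V <= 0 or self.m <= 0:
            raise InvalidInputError("V and m must be positive")


def chla_b(sample: AbsorbanceSample) -> float:
    """Chlorophyll a+b concentration (mg per g fresh mass).

    Chla+b = (5.1*A665 + 20.04*A649) * V / m, the standard two-wavelength
    formula for 96 % ethanol extracts.
    """
    return (5.1 * sample.A665 + 20.04 * sample.A649) * sample.V / sample.m


@dataclass(frozen=True)
class RegressionReport:
    """OLS fit of y on x (linear or quadratic in x).

    ``coefficients`` are in ascending degree order (intercept first).
    ``confidence_halfwidth(x)`` gives the half-width of the pointwise 95 %
    confidence band for the regression mean at x.
    """

    form: str
    coefficients: tuple[float, ...]
    r2: float
    n: int
    p_value: float
    _cov_params: np.ndarray = field(repr=False)
    _df_resid: int = field(repr=False)

    def predict(self, x):
        x = np.asarray(x, dtype=float)
        out = sum(c * x**d for d, c in enumerate(self.coefficients))
        return float(out) if np.ndim(out) == 0 else out

    def confidence_halfwidth(self, x, level: float = 0.95):
        """Half-width of the pointwise confidence band for the mean at x."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        deg = len(self.coefficients) - 1
        X = np.vander(x, deg + 1, increasing=True)
        var = np.einsum("ij,jk,ik->i", X, self._cov_params, X)
        t = sps.t.ppf(0.5 + level / 2.0, self._df_resid)
        hw = t * np.sqrt(var)
        return float(hw[0]) if hw.size == 1 else hw

    def summary(self) -> str:
        terms = " + ".join(f"{c:.4g}*x^{d}" if d else f"{c:.4g}"
                           for d, c in enumerate(self.coefficients))
        return (
            f"{self.form} OLS fit: y = {terms}\n"
            f"  r2 = {self.r2:.4f}   n = {self.n}   p(F) = {self.p_value:.3g}"
        )


def _regress(x, y, degree: int) -> RegressionReport:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidInputError("x and y must be equal-length 1-D arrays")
    if np.unique(x).size < degree + 1:
        raise SingularDesignError(
            f"need at least {degree + 1} distinct x values")
    X = np.vander(x, degree + 1, increasing=True)
    res = sm.OLS(y, X).fit()
    p = float(res.f_pvalue)
    if math.isnan(p):  # perfect fit: F-statistic degenerates
        p = 0.0
    return RegressionReport(
        form="linear" if degree == 1 else "quadratic",
        coefficients=tuple(float(c) for c in res.params),
        r2=float(min(max(res.rsquared, 0.0), 1.0)),
        n=int(x.size),
        p_value=p,
        _cov_params=np.asarray(res.cov_params()),
        _df_resid=int(res.df_resid),
    )


def regress_linear(x, y) -> RegressionReport:
    """OLS straight-line fit with r2, F-test p and 95 % confidence band."""
    return _regress(x, y, degree=1)


def regress_quadratic(x, y) -> RegressionReport:
    """OLS quadratic fit with r2, F-test p and 95 % confidence band."""
    return _regress(x, y, degree=2)
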