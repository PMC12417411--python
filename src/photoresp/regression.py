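"""Trend regression of respiratory fluxes on ambient CO2.

Photorespiration and day respiration respond unimodally to ambient CO2
(rising while respired-CO2 recycling dominates, falling once
carboxylation competitively inhibits oxygenation), while dark
respiration declines roughly linearly. These shapes are summarized by
ordinary least squares on a polynomial basis — degree 2 by default, the
minimal unimodal form — fitted to replicate means per C_a level.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = ["TrendFit", "fit_trend", "peak_ca"]


@dataclass
class TrendFit:
    """Polynomial/linear OLS trend of a flux against C_a.

    ``coefficients`` are in ascending power (intercept first); units
    follow the axes (flux vs μmol mol⁻¹). ``x_at_extremum`` is the
    stationary point of the fitted polynomial inside the data range,
    or None if the derivative has no root there.
    """

    kind: str
    degree: int
    coefficients: np.ndarray
    r2: float
    x_at_extremum: Optional[float]
    n: int

    def predict(self, x):
        return np.polynomial.polynomial.polyval(np.asarray(x, dtype=float),
                                                self.coefficients)

    def to_dict(self) -> dict:
        return {"kind": self.kind, "degree": self.degree,
                "coefficients": [float(c) for c in self.coefficients],
                "r2": float(self.r2),
                "x_at_extremum": None if self.x_at_extremum is None
                else float(self.x_at_extremum),
                "n": self.n}


def fit_trend(x: Sequence[float], y: Sequence[float], kind: str = "polynomial",
              degree: int = 2) -> TrendFit:
    """OLS fit of ``y`` on the polynomial basis of ``x``.

    ``kind`` is "polynomial" (any ``degree`` ≥ 1) or "linear"
    (forces degree 1). Requires n ≥ degree + 2 so the fit is a
    regression rather than an interpolation, and a full-rank design.
    r² = 1 − SSR/SStot about the mean.
    """
    if kind == "linear":
        degree = 1
    elif kind != "polynomial":
        raise ValueError(f"unknown kind {kind!r}")
    if degree < 1:
        raise ValueError("degree must be >= 1")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = x.size
    if n < degree + 2:
        raise ValueError(f"need at least degree + 2 = {degree + 2} points, got {n}")
    design = np.vander(x, degree + 1, increasing=True)
    if np.linalg.matrix_rank(design) < degree + 1:
        raise ValueError("rank-deficient design (too few distinct x values)")
    model = sm.OLS(y, design).fit()
    coeffs = np.asarray(model.params, dtype=float)

    deriv = np.polynomial.polynomial.polyder(coeffs)
    roots = np.polynomial.polynomial.polyroots(deriv) if deriv.size else np.array([])
    real = roots[np.abs(roots.imag) < 1e-9].real if roots.size else np.array([])
    inside = real[(real >= x.min()) & (real <= x.max())]
    extremum = float(inside[0]) if inside.size else None

    return TrendFit(kind=kind, degree=degree, coefficients=coeffs,
                    r2=float(model.rsquared), x_at_extremum=extremum, n=n)


@dataclass
class PeakResult:
    ca_at_peak: float
    peak_value: float
    monotone: bool
    smoothed_ca_at_peak: Optional[float]


def peak_ca(series: Sequence, trend: Optional[TrendFit] = None) -> PeakResult:
    """C_a of the maximal mean flux in an ordered (C_a, flux) series.

    Ties break toward the lowest C_a. A series whose maximum sits at
    either end of the grid is flagged monotone (no interior peak). When
    a :class:`TrendFit` is supplied (or the series supports a degree-2
    fit), its smoothed extremum is reported alongside the grid peak.
    """
    arr = np.asarray(series, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] == 0:
        raise ValueError("need a non-empty (ca, flux) series")
    order = np.argsort(arr[:, 0], kind="stable")
    ca, y = arr[order, 0], arr[order, 1]
    i = int(np.argmax(y))
    monotone = i in (0, len(ca) - 1)
    smoothed = None
    if trend is None and len(ca) >= 4:
        try:
            trend = fit_trend(ca, y, "polynomial", 2)
        except ValueError:
            trend = None
    if trend is not None:
        smoothed = trend.x_at_extremum
    return PeakResult(ca_at_peak=float(ca[i]), peak_value=float(y[i]),
                      monotone=monotone, smoothed_ca_at_peak=smoothed)
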