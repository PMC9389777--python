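"""Calibration curves and mixture quantification from derivative amplitudes."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import ConfigurationError, DataError, DegenerateDesignError
from .simulate import ExcitationEmissionMatrix
from .transform import (
    SynchronousSpectrum,
    amplitude_at,
    first_derivative,
    subtract_blank,
    synchronous_scan,
)

__all__ = [
    "CalibrationCurve",
    "Prediction",
    "fit_calibration",
    "predict_concentration",
    "quantify_mixture",
]


@dataclass(frozen=True)
class CalibrationCurve:
    """Ordinary least-squares line of derivative amplitude vs concentration.

    ``slope`` is signed (the derivative amplitude at a readout wavelength
    may decrease with concentration); ``residual_sd`` is
    ``sqrt(SSE / (n - 2))`` and feeds the LOD/LOQ formulas.
    """

    analyte: str
    wavelength_nm: float
    slope: float
    intercept: float
    r_squared: float
    residual_sd: float
    n_points: int
    range_ng_ml: tuple[float, float]
    delta_lambda_nm: float | None = None
    window_points: int | None = None

    def __post_init__(self) -> None:
        if self.n_points < 3:
            raise DegenerateDesignError("calibration needs at least 3 points")
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise DataError(f"r_squared out of [0, 1]: {self.r_squared}")
        if not self.range_ng_ml[0] < self.range_ng_ml[1]:
            raise DataError("calibration range low must be < high")


@dataclass(frozen=True)
class Prediction:
    """Inverse-regression result with range/sign flags (never an error:
    honest recovery statistics near the LOD need negative estimates)."""

    analyte: str
    ng_ml: float
    in_range: bool
    below_zero: bool

    def __float__(self) -> float:
        return self.ng_ml


def fit_calibration(
    concentrations: Sequence[float],
    amplitudes: Sequence[float],
    analyte: str,
    wavelength_nm: float,
    delta_lambda_nm: float | None = None,
    window_points: int | None = None,
) -> CalibrationCurve:
    """Unweighted OLS fit of amplitude on concentration (>= 3 distinct levels)."""
    x = np.asarray(concentrations, float)
    y = np.asarray(amplitudes, float)
    if x.shape != y.shape or x.ndim != 1:
        raise DataError("concentrations and amplitudes must be equal-length vectors")
    if len(np.unique(x)) < 3:
        raise DegenerateDesignError(
            "calibration requires at least 3 distinct concentrations"
        )
    res = stats.linregress(x, y)
    fitted = res.intercept + res.slope * x
    sse = float(np.sum((y - fitted) ** 2))
    n = len(x)
    residual_sd = float(np.sqrt(sse / (n - 2)))
    rvalue = float(res.rvalue) if np.isfinite(res.rvalue) else 0.0  # constant response
    return CalibrationCurve(
        analyte=analyte,
        wavelength_nm=float(wavelength_nm),
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=min(rvalue**2, 1.0),
        residual_sd=residual_sd,
        n_points=n,
        range_ng_ml=(float(np.min(x)), float(np.max(x))),
        delta_lambda_nm=delta_lambda_nm,
        window_points=window_points,
    )


def predict_concentration(curve: CalibrationCurve, amplitude: float) -> Prediction:
    """Invert the regression: c = (amplitude - intercept) / slope."""
    if curve.slope == 0:
        raise DataError(f"calibration slope for {curve.analyte} is zero")
    c = (amplitude - curve.intercept) / curve.slope
    low, high = curve.range_ng_ml
    return Prediction(
        analyte=curve.analyte,
        ng_ml=float(c),
        in_range=bool(low <= c <= high),
        below_zero=bool(c < 0),
    )


def quantify_mixture(
    eem_or_spectrum: ExcitationEmissionMatrix | SynchronousSpectrum,
    curves: Mapping[str, CalibrationCurve],
    delta_lambda_nm: float = 25.0,
    window_points: int = 5,
    blank: ExcitationEmissionMatrix | SynchronousSpectrum | None = None,
) -> dict[str, Prediction]:
    """Quantify every calibrated analyte in one measurement.

    Composes synchronous extraction (when given an EEM), optional blank
    subtraction, first-derivative transformation, amplitude readout at
    each curve's analytical wavelength, and inverse regression.
    """
    if not curves:
        raise ConfigurationError("no calibration curves supplied")
    wavelengths = [c.wavelength_nm for c in curves.values()]
    if len(set(wavelengths)) != len(wavelengths):
        raise ConfigurationError("analytical wavelengths must be distinct per analyte")

    if isinstance(eem_or_spectrum, ExcitationEmissionMatrix):
        sync = synchronous_scan(eem_or_spectrum, delta_lambda_nm)
    else:
        sync = eem_or_spectrum
    if blank is not None:
        blank_sync = (
            synchronous_scan(blank, sync.delta_lambda_nm)
            if isinstance(blank, ExcitationEmissionMatrix)
            else blank
        )
        sync = subtract_blank(sync, blank_sync)
    deriv = first_derivative(sync, window_points)

    results: dict[str, Prediction] = {}
    for name, curve in curves.items():
        if curve.analyte != name:
            raise ConfigurationError(
                f"curve registered under {name!r} is for analyte {curve.analyte!r}"
            )
        amp = amplitude_at(deriv, curve.wavelength_nm)
        results[name] = predict_concentration(curve, amp)
    return results
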