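"""Synchronous scans, Savitzky-Golay first derivatives, and amplitude readout.

A constant-wavelength synchronous scan cuts the diagonal
``S(lam_em) = I(lam_em - delta_lambda, lam_em)`` through an EEM, turning
broad, overlapping emission bands into narrower synchronous bands.  The
five-point quadratic Savitzky-Golay first derivative of that trace
removes the constant background and creates zero crossings at each
band's synchronous maximum; reading the derivative at the *interfering*
analyte's zero crossing yields an amplitude proportional to one analyte
only.  With the packaged band models and ``delta_lambda = 25`` nm the
zero crossings fall at 286 nm (PSE band centre, used to read FEX) and
293 nm (FEX synchronous maximum, used to read PSE).

No interpolation is performed anywhere: ``delta_lambda`` must be
commensurate with the scan grids, which keeps every operation linear and
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .errors import ConfigurationError, DataError, GridMismatchError, InvalidParameterError
from .simulate import ExcitationEmissionMatrix, WavelengthGrid

__all__ = [
    "SynchronousSpectrum",
    "DerivativeSpectrum",
    "synchronous_scan",
    "first_derivative",
    "amplitude_at",
    "subtract_blank",
    "locate_analytical_wavelengths",
    "optimize_delta_lambda",
    "DeltaLambdaResult",
]


@dataclass(frozen=True)
class SynchronousSpectrum:
    """Constant-delta-lambda trace, indexed by emission wavelength.

    Every point satisfies ``lam_ex = lam_em - delta_lambda_nm``.
    """

    delta_lambda_nm: float
    axis: WavelengthGrid
    intensities: np.ndarray
    blank_corrected: bool = False
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.delta_lambda_nm <= 0:
            raise InvalidParameterError("delta_lambda_nm must be > 0")
        if len(self.intensities) != self.axis.n_points:
            raise DataError("intensity vector length does not match axis")


@dataclass(frozen=True)
class DerivativeSpectrum:
    """First-derivative trace in intensity units per nm."""

    order: int
    window_points: int
    axis: WavelengthGrid
    amplitudes: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.order != 1:
            raise InvalidParameterError("only first-order derivatives are supported")
        if self.window_points % 2 == 0 or self.window_points < 3:
            raise InvalidParameterError("window_points must be odd and >= 3")
        if len(self.amplitudes) != self.axis.n_points:
            raise DataError("amplitude vector length does not match axis")


def synchronous_scan(
    eem: ExcitationEmissionMatrix, delta_lambda_nm: float
) -> SynchronousSpectrum:
    """Extract the constant-offset diagonal S(lam_em) = I(lam_em - dl, lam_em).

    ``delta_lambda_nm`` must be an integer multiple of both grid steps
    and the diagonal must intersect the EEM; intensities are copied, not
    interpolated.
    """
    if delta_lambda_nm <= 0:
        raise InvalidParameterError("delta_lambda_nm must be > 0")
    ex, em = eem.ex_grid, eem.em_grid
    for step, name in ((ex.step_nm, "excitation"), (em.step_nm, "emission")):
        ratio = delta_lambda_nm / step
        if abs(ratio - round(ratio)) > 1e-9:
            raise GridMismatchError(
                f"delta_lambda = {delta_lambda_nm} nm is not a multiple of the "
                f"{name} grid step ({step} nm)"
            )

    em_values = em.values
    ex_idx = []
    em_idx = []
    for j, lam in enumerate(em_values):
        i = ex.index_of(lam - delta_lambda_nm)
        if i is not None:
            ex_idx.append(i)
            em_idx.append(j)
    if not em_idx:
        raise GridMismatchError(
            f"the delta_lambda = {delta_lambda_nm} nm diagonal does not "
            "intersect the measured EEM"
        )

    axis = WavelengthGrid(
        float(em_values[em_idx[0]]), float(em_values[em_idx[-1]]), em.step_nm
    )
    intensities = eem.intensities[ex_idx, em_idx].astype(float)
    return SynchronousSpectrum(
        delta_lambda_nm=float(delta_lambda_nm),
        axis=axis,
        intensities=intensities,
        metadata=dict(eem.metadata),
    )


def subtract_blank(
    spectrum: SynchronousSpectrum, blank: SynchronousSpectrum
) -> SynchronousSpectrum:
    """Subtract a blank's synchronous trace point-by-point.

    Because the derivative is linear, correcting before or after
    derivatisation is equivalent; the pipeline corrects before.
    """
    if blank.axis != spectrum.axis or blank.delta_lambda_nm != spectrum.delta_lambda_nm:
        raise DataError("blank trace does not share the spectrum's axis/delta_lambda")
    return SynchronousSpectrum(
        spectrum.delta_lambda_nm,
        spectrum.axis,
        spectrum.intensities - blank.intensities,
        blank_corrected=True,
        metadata=dict(spectrum.metadata),
    )


def first_derivative(
    spectrum: SynchronousSpectrum, window_points: int = 5
) -> DerivativeSpectrum:
    """Savitzky-Golay first derivative (quadratic fit, default 5 points).

    Interior points use the classical quadratic 5-point convolution
    weights ``(-2, -1, 0, 1, 2) / (10 h)``; the first/last half-window is
    obtained by evaluating the derivative of the same local polynomial
    fitted to the first/last full window, so the output has the same
    length as the input.  Exact for polynomials up to degree 2.
    """
    if window_points % 2 == 0 or window_points < 3:
        raise InvalidParameterError(
            f"window_points must be odd and >= 3, got {window_points}"
        )
    n = len(spectrum.intensities)
    if n < window_points:
        raise DataError(
            f"spectrum has {n} points, fewer than the derivative window "
            f"({window_points})"
        )
    amplitudes = savgol_filter(
        spectrum.intensities,
        window_length=window_points,
        polyorder=2,
        deriv=1,
        delta=spectrum.axis.step_nm,
        mode="interp",
    )
    meta = dict(spectrum.metadata)
    meta["delta_lambda_nm"] = spectrum.delta_lambda_nm
    return DerivativeSpectrum(
        order=1,
        window_points=window_points,
        axis=spectrum.axis,
        amplitudes=amplitudes,
        metadata=meta,
    )


def amplitude_at(
    spectrum: DerivativeSpectrum | SynchronousSpectrum, wavelength_nm: float
) -> float:
    """Signed value at the grid point nearest ``wavelength_nm``.

    Ties (requests exactly between two grid points) resolve toward the
    lower wavelength.  Out-of-range requests are an error.
    """
    axis = spectrum.axis
    if not axis.covers(wavelength_nm):
        raise DataError(
            f"wavelength {wavelength_nm} nm outside the spectrum axis "
            f"[{axis.start_nm}, {axis.stop_nm}] nm"
        )
    values = (
        spectrum.amplitudes
        if isinstance(spectrum, DerivativeSpectrum)
        else spectrum.intensities
    )
    idx = int(np.argmin(np.abs(axis.values - wavelength_nm)))  # first-min = lower tie
    return float(values[idx])


def locate_analytical_wavelengths(
    pure_spectra: Mapping[str, SynchronousSpectrum],
) -> dict[str, float]:
    """Zero-crossing readout wavelengths from single-analyte traces.

    For a binary mixture, each analyte is read at the *other* analyte's
    synchronous band maximum — the wavelength where the interferent's
    first derivative crosses zero.  Input traces should be noiseless
    single-analyte scans at the working ``delta_lambda``.
    """
    if len(pure_spectra) != 2:
        raise ConfigurationError(
            "zero-crossing wavelength location is defined for exactly two analytes"
        )
    (name_a, spec_a), (name_b, spec_b) = pure_spectra.items()
    peak = {
        name_a: float(spec_a.axis.values[int(np.argmax(spec_a.intensities))]),
        name_b: float(spec_b.axis.values[int(np.argmax(spec_b.intensities))]),
    }
    return {name_a: peak[name_b], name_b: peak[name_a]}


@dataclass(frozen=True)
class DeltaLambdaResult:
    """Outcome of the delta-lambda grid search."""

    chosen_nm: float
    score: float
    analytical_wavelengths: dict[str, float]
    table: pd.DataFrame


def optimize_delta_lambda(
    eems_by_analyte: Mapping[str, tuple[ExcitationEmissionMatrix, float]],
    candidates: Iterable[float] = tuple(range(20, 101, 5)),
    window_points: int = 5,
    max_cross_fraction: float = 0.05,
) -> DeltaLambdaResult:
    """Grid-search the synchronous offset for sensitivity and selectivity.

    Parameters
    ----------
    eems_by_analyte :
        ``{name: (noiseless single-analyte EEM, concentration ng/mL)}``
        at equal-effect concentrations.
    candidates :
        Offsets to evaluate (default 20-100 nm in 5 nm steps).
    max_cross_fraction :
        Selectivity constraint: each analyte's derivative amplitude at
        the other analyte's readout wavelength must stay below this
        fraction of its amplitude at its own readout wavelength.

    The score of a feasible offset is the smaller of the per-unit-
    concentration derivative sensitivities; the chosen offset maximises
    it.  A single-analyte input has no selectivity constraint and
    reduces to maximising the derivative sensitivity at the analyte's
    own strongest derivative feature.  The full score table is always
    returned (and attached to the diagnostic error when no candidate is
    feasible).
    """
    if len(eems_by_analyte) not in (1, 2):
        raise ConfigurationError("delta-lambda optimisation requires one or two analytes")
    names = list(eems_by_analyte)
    rows = []
    for delta in candidates:
        row: dict = {"delta_lambda_nm": float(delta)}
        try:
            deriv = {}
            sync = {}
            for name, (eem, conc) in eems_by_analyte.items():
                if conc <= 0:
                    raise ConfigurationError(f"non-positive concentration for {name}")
                sync[name] = synchronous_scan(eem, delta)
                deriv[name] = first_derivative(sync[name], window_points)
            if len(names) == 1:
                (name,) = names
                d = deriv[name]
                idx = int(np.argmax(np.abs(d.amplitudes)))
                row[f"wavelength_{name}"] = float(d.axis.values[idx])
                row[f"sensitivity_{name}"] = float(
                    np.abs(d.amplitudes[idx]) / eems_by_analyte[name][1]
                )
                row["feasible"] = True
                row["score"] = row[f"sensitivity_{name}"]
                rows.append(row)
                continue
            readout = locate_analytical_wavelengths(sync)
            feasible = True
            score = np.inf
            for name in names:
                other = names[1] if name == names[0] else names[0]
                own = abs(amplitude_at(deriv[name], readout[name]))
                cross = abs(amplitude_at(deriv[name], readout[other]))
                sens = own / eems_by_analyte[name][1]
                frac = cross / own if own > 0 else np.inf
                row[f"sensitivity_{name}"] = sens
                row[f"cross_fraction_{name}"] = frac
                row[f"wavelength_{name}"] = readout[name]
                feasible &= frac < max_cross_fraction
                score = min(score, sens)
            row["feasible"] = feasible
            row["score"] = score
        except GridMismatchError as exc:
            row["feasible"] = False
            row["score"] = np.nan
            row["note"] = str(exc)
        rows.append(row)

    table = pd.DataFrame(rows)
    feasible = table[table["feasible"]]
    if feasible.empty:
        best = table.sort_values("score", ascending=False).head(3)
        err = DataError(
            "no candidate delta_lambda satisfies the cross-sensitivity "
            f"constraint (< {max_cross_fraction:.0%}); best scores:\n{best}"
        )
        err.table = table  # type: ignore[attr-defined]
        raise err
    ibest = feasible["score"].idxmax()
    chosen = float(table.loc[ibest, "delta_lambda_nm"])
    wavelengths = {name: float(table.loc[ibest, f"wavelength_{name}"]) for name in names}
    return DeltaLambdaResult(
        chosen_nm=chosen,
        score=float(table.loc[ibest, "score"]),
        analytical_wavelengths=wavelengths,
        table=table,
    )
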