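"""CSV/JSON interchange for spectra, EEMs and calibration curves.

Dialect: UTF-8, comma-separated, ``.`` decimal separator, ``# key=value``
metadata header lines, floats written with 10 significant digits.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import IO, Mapping

import numpy as np

from .errors import ParseError
from .quantify import CalibrationCurve
from .simulate import ExcitationEmissionMatrix, WavelengthGrid
from .transform import DerivativeSpectrum, SynchronousSpectrum

__all__ = [
    "write_spectrum_csv",
    "read_spectrum_csv",
    "write_eem_csv",
    "read_eem_csv",
    "save_curve",
    "load_curve",
]

_FLOAT_FMT = "{:.10g}"


def _format_metadata(metadata: Mapping[str, object]) -> list[str]:
    return [f"# {key}={value}" for key, value in metadata.items()]


def _parse_header(fh: IO[str]) -> tuple[dict, list[str], int]:
    """Read ``# key=value`` lines; returns (metadata, remaining lines, offset)."""
    metadata: dict = {}
    lines = fh.read().splitlines()
    i = 0
    for i, line in enumerate(lines):
        if not line.startswith("#"):
            break
        body = line.lstrip("#").strip()
        if "=" in body:
            key, _, value = body.partition("=")
            metadata[key.strip()] = value.strip()
    else:
        i = len(lines)
    return metadata, lines[i:], i


def write_spectrum_csv(
    spectrum: SynchronousSpectrum | DerivativeSpectrum,
    path: str | Path,
    extra_metadata: Mapping[str, object] | None = None,
) -> None:
    """Write a 1-D spectrum with its provenance metadata."""
    meta: dict = {}
    if isinstance(spectrum, SynchronousSpectrum):
        meta["delta_lambda_nm"] = _FLOAT_FMT.format(spectrum.delta_lambda_nm)
        meta["blank_corrected"] = spectrum.blank_corrected
        values = spectrum.intensities
        column = "intensity"
    else:
        meta["derivative_order"] = spectrum.order
        meta["window_points"] = spectrum.window_points
        if "delta_lambda_nm" in spectrum.metadata:
            meta["delta_lambda_nm"] = _FLOAT_FMT.format(
                float(spectrum.metadata["delta_lambda_nm"])
            )
        values = spectrum.amplitudes
        column = "amplitude_per_nm"
    if extra_metadata:
        meta.update(extra_metadata)

    lines = _format_metadata(meta)
    lines.append(f"wavelength_nm,{column}")
    for lam, v in zip(spectrum.axis.values, values):
        lines.append(f"{_FLOAT_FMT.format(lam)},{_FLOAT_FMT.format(v)}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_spectrum_csv(path: str | Path):
    """Read a spectrum CSV back into its typed object.

    Returns a :class:`DerivativeSpectrum` when the metadata declares a
    derivative order, otherwise a :class:`SynchronousSpectrum` (the
    ``delta_lambda_nm`` metadatum is required for the latter).
    Wavelengths must be strictly ascending and uniformly spaced.
    """
    path = Path(path)
    with path.open() as fh:
        metadata, lines, offset = _parse_header(fh)
    rows = [line for line in lines if line.strip()]
    if not rows:
        raise ParseError(f"{path}: no data rows")
    header = rows[0].split(",")
    if len(header) != 2 or header[0] != "wavelength_nm":
        raise ParseError(f"{path}: line {offset + 1}: expected 'wavelength_nm,<value>' header")

    wavelengths, values = [], []
    for lineno, row in enumerate(rows[1:], start=offset + 2):
        parts = row.split(",")
        if len(parts) != 2:
            raise ParseError(f"{path}: line {lineno}: expected 2 columns, got {len(parts)}")
        try:
            wavelengths.append(float(parts[0]))
            values.append(float(parts[1]))
        except ValueError:
            raise ParseError(f"{path}: line {lineno}: non-numeric value") from None
    lam = np.asarray(wavelengths)
    if len(lam) < 2:
        raise ParseError(f"{path}: need at least 2 points")
    steps = np.diff(lam)
    if np.any(steps <= 0):
        raise ParseError(f"{path}: wavelengths are not strictly ascending")
    if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
        raise ParseError(f"{path}: wavelength grid is not uniform")

    axis = WavelengthGrid(float(lam[0]), float(lam[-1]), float(round(steps[0], 9)))
    arr = np.asarray(values)
    if "derivative_order" in metadata:
        return DerivativeSpectrum(
            order=int(metadata["derivative_order"]),
            window_points=int(metadata.get("window_points", 5)),
            axis=axis,
            amplitudes=arr,
            metadata=metadata,
        )
    if "delta_lambda_nm" not in metadata:
        raise ParseError(f"{path}: missing '# delta_lambda_nm=' metadata line")
    return SynchronousSpectrum(
        delta_lambda_nm=float(metadata["delta_lambda_nm"]),
        axis=axis,
        intensities=arr,
        blank_corrected=str(metadata.get("blank_corrected", "False")) == "True",
        metadata=metadata,
    )


def write_eem_csv(
    eem: ExcitationEmissionMatrix,
    path: str | Path,
    metadata: Mapping[str, object] | None = None,
) -> None:
    """Long-format EEM: columns excitation_nm, emission_nm, intensity."""
    lines = _format_metadata(metadata or {})
    for grid, tag in ((eem.ex_grid, "ex"), (eem.em_grid, "em")):
        lines.append(
            f"# {tag}_grid={_FLOAT_FMT.format(grid.start_nm)}:"
            f"{_FLOAT_FMT.format(grid.stop_nm)}:{_FLOAT_FMT.format(grid.step_nm)}"
        )
    lines.append("excitation_nm,emission_nm,intensity")
    ex_vals, em_vals = eem.ex_grid.values, eem.em_grid.values
    for i, ex in enumerate(ex_vals):
        row = eem.intensities[i]
        for j, em in enumerate(em_vals):
            lines.append(
                f"{_FLOAT_FMT.format(ex)},{_FLOAT_FMT.format(em)},"
                f"{_FLOAT_FMT.format(row[j])}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


def _parse_grid(spec: str) -> WavelengthGrid:
    start, stop, step = (float(x) for x in spec.split(":"))
    return WavelengthGrid(start, stop, step)


def read_eem_csv(path: str | Path) -> ExcitationEmissionMatrix:
    path = Path(path)
    with path.open() as fh:
        metadata, lines, offset = _parse_header(fh)
    try:
        ex_grid = _parse_grid(metadata.pop("ex_grid"))
        em_grid = _parse_grid(metadata.pop("em_grid"))
    except KeyError as exc:
        raise ParseError(f"{path}: missing '# {exc.args[0]}=' metadata line") from None
    rows = [line for line in lines if line.strip()]
    if not rows or rows[0].split(",") != ["excitation_nm", "emission_nm", "intensity"]:
        raise ParseError(f"{path}: bad or missing column header")
    expected = ex_grid.n_points * em_grid.n_points
    if len(rows) - 1 != expected:
        raise ParseError(
            f"{path}: expected {expected} data rows for the declared grids, "
            f"got {len(rows) - 1}"
        )
    intensities = np.empty((ex_grid.n_points, em_grid.n_points))
    for lineno, row in enumerate(rows[1:], start=offset + 2):
        parts = row.split(",")
        if len(parts) != 3:
            raise ParseError(f"{path}: line {lineno}: expected 3 columns")
        try:
            ex, em, val = (float(p) for p in parts)
        except ValueError:
            raise ParseError(f"{path}: line {lineno}: non-numeric value") from None
        i, j = ex_grid.index_of(ex), em_grid.index_of(em)
        if i is None or j is None:
            raise ParseError(f"{path}: line {lineno}: wavelength off the declared grid")
        intensities[i, j] = val
    return ExcitationEmissionMatrix(ex_grid, em_grid, intensities, metadata)


def save_curve(curve: CalibrationCurve, path: str | Path) -> None:
    Path(path).write_text(json.dumps(dataclasses.asdict(curve), indent=2, sort_keys=True) + "\n")


def load_curve(path: str | Path) -> CalibrationCurve:
    raw = json.loads(Path(path).read_text())
    raw["range_ng_ml"] = tuple(raw["range_ng_ml"])
    return CalibrationCurve(**raw)
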