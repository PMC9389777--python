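"""Synthetic fluorescence data: excitation–emission matrices and study designs.

This module emulates a scanning spectrofluorometer measuring binary
mixtures of fexofenadine hydrochloride (FEX) and pseudoephedrine
hydrochloride (PSE) in micellar (SDS) medium.  FEX emits at 294 nm when
excited at 267 nm; PSE emits at 286 nm when excited at 261 nm, so their
conventional emission bands sit only 8 nm apart and overlap heavily —
the situation the synchronous/derivative method resolves.

The signal model is bilinear: each fluorophore contributes a separable
excitation × emission Gaussian band scaled by concentration, a per-ng/mL
response factor, a dimensionless enhancement multiplier (surfactant/pH
scenario), and a matrix recovery factor::

    I(lam_ex, lam_em) = sum_i  c_i * response_i * enhancement_i * recovery
                               * Ex_i(lam_ex) * Em_i(lam_em)
                        + background (+ noise)

Band positions are the drugs' published maxima.  Band widths, absolute
response factors and noise levels are *reconstructions* — no raw spectra
are published for this method — chosen so the simulated spectra
reproduce the method's qualitative behaviour (see docs/methods.md):
equal 10 nm excitation/emission FWHMs give synchronous bands that are
narrow enough to show two distinct maxima in a 1:2 mixture at
``delta_lambda = 25`` nm and exactly symmetric about their grid-point
centres, so the first-derivative zero crossings used for quantification
are exact.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigurationError, DataError, InvalidParameterError

__all__ = [
    "WavelengthGrid",
    "FluorophoreModel",
    "MatrixModel",
    "Sample",
    "ExcitationEmissionMatrix",
    "StudyDesign",
    "band_profile",
    "simulate_eem",
    "simulate_study",
    "default_fluorophores",
    "default_matrix",
    "FEX",
    "PSE",
    "DEFAULT_EX_GRID",
    "DEFAULT_EM_GRID",
]

_LN2 = math.log(2.0)


@dataclass(frozen=True)
class WavelengthGrid:
    """A uniform, ascending instrument scan axis in nanometres.

    Parameters
    ----------
    start_nm, stop_nm :
        First and last wavelength of the scan; ``start_nm < stop_nm``.
    step_nm :
        Scan increment; ``(stop_nm - start_nm) / step_nm`` must be an
        integer so the grid closes exactly on ``stop_nm``.
    """

    start_nm: float
    stop_nm: float
    step_nm: float = 1.0

    def __post_init__(self) -> None:
        if not self.step_nm > 0:
            raise InvalidParameterError(f"step_nm must be > 0, got {self.step_nm}")
        if not self.start_nm < self.stop_nm:
            raise InvalidParameterError(
                f"start_nm ({self.start_nm}) must be < stop_nm ({self.stop_nm})"
            )
        n = (self.stop_nm - self.start_nm) / self.step_nm
        if abs(n - round(n)) > 1e-9 * max(1.0, abs(n)):
            raise InvalidParameterError(
                "grid does not close: (stop-start)/step = "
                f"{n!r} is not an integer"
            )

    @property
    def n_points(self) -> int:
        return int(round((self.stop_nm - self.start_nm) / self.step_nm)) + 1

    @property
    def values(self) -> np.ndarray:
        return self.start_nm + self.step_nm * np.arange(self.n_points)

    def index_of(self, wavelength_nm: float, tol: float = 1e-6) -> int | None:
        """Exact grid index of ``wavelength_nm``, or None if off-grid."""
        pos = (wavelength_nm - self.start_nm) / self.step_nm
        idx = int(round(pos))
        if abs(pos - idx) > tol or not 0 <= idx < self.n_points:
            return None
        return idx

    def covers(self, wavelength_nm: float) -> bool:
        return self.start_nm <= wavelength_nm <= self.stop_nm


#: Default instrument scan axes (excitation and emission), 220-340 nm at 1 nm.
DEFAULT_EX_GRID = WavelengthGrid(220.0, 340.0, 1.0)
DEFAULT_EM_GRID = WavelengthGrid(220.0, 340.0, 1.0)


@dataclass(frozen=True)
class FluorophoreModel:
    """Separable Gaussian excitation/emission band model for one analyte.

    ``response`` is the fluorescence intensity (arbitrary units) produced
    at the excitation/emission band maximum per ng/mL of analyte under
    the reference (fully enhanced) conditions; ``enhancement`` is a
    dimensionless multiplier encoding surfactant/pH scenarios relative
    to that reference (1.0 = optimised SDS + pH 2 conditions).
    """

    name: str
    ex_center_nm: float
    em_center_nm: float
    ex_fwhm_nm: float = 10.0
    em_fwhm_nm: float = 10.0
    response: float = 1.0
    enhancement: float = 1.0

    def __post_init__(self) -> None:
        if self.ex_fwhm_nm <= 0 or self.em_fwhm_nm <= 0:
            raise InvalidParameterError(f"{self.name}: band FWHM must be > 0")
        if self.response <= 0:
            raise InvalidParameterError(f"{self.name}: response must be > 0")
        if self.enhancement < 0:
            raise InvalidParameterError(f"{self.name}: enhancement must be >= 0")

    def excitation_profile(self, grid: WavelengthGrid | np.ndarray) -> np.ndarray:
        return band_profile(self.ex_center_nm, self.ex_fwhm_nm, grid)

    def emission_profile(self, grid: WavelengthGrid | np.ndarray) -> np.ndarray:
        return band_profile(self.em_center_nm, self.em_fwhm_nm, grid)


#: Packaged analyte presets.  Band centres are the drugs' published
#: excitation/emission maxima; widths and responses are reconstructions
#: (responses chosen so 1000 ng/mL FEX and 800 ng/mL PSE — the
#: concentrations used in the method's illustration spectra — give equal
#: peak intensities of 500 a.u.).
FEX = FluorophoreModel("FEX", ex_center_nm=267.0, em_center_nm=294.0, response=0.5)
PSE = FluorophoreModel("PSE", ex_center_nm=261.0, em_center_nm=286.0, response=0.625)


def default_fluorophores() -> dict[str, FluorophoreModel]:
    return {"FEX": FEX, "PSE": PSE}


@dataclass(frozen=True)
class MatrixModel:
    """Sample-matrix model: background, noise, and signal recovery.

    ``recovery_factor`` scales the analyte signal only (not the
    background): 1.0 for solvent/tablet extracts, ~0.95 for plasma after
    protein precipitation, mirroring the ~95% recoveries observed in
    spiked plasma.  ``noise_sd`` is additive Gaussian detector noise in
    intensity units; ``noise_cv`` is optional multiplicative
    (signal-proportional) noise.
    """

    background: float = 2.0
    noise_sd: float = 0.3
    noise_cv: float = 0.0
    recovery_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0 or self.noise_cv < 0:
            raise InvalidParameterError("noise parameters must be >= 0")
        if not 0.0 <= self.recovery_factor <= 1.0:
            raise InvalidParameterError("recovery_factor must be in [0, 1]")

    @property
    def noiseless(self) -> "MatrixModel":
        return replace(self, noise_sd=0.0, noise_cv=0.0)


_MATRIX_PRESETS = {
    "solvent": MatrixModel(background=2.0, noise_sd=0.3, recovery_factor=1.0),
    "tablet": MatrixModel(background=2.0, noise_sd=0.3, recovery_factor=1.0),
    "plasma": MatrixModel(background=12.0, noise_sd=0.3, recovery_factor=0.95),
}

VALID_MATRICES = tuple(_MATRIX_PRESETS)


def default_matrix(kind: str = "solvent") -> MatrixModel:
    """Packaged matrix presets for ``solvent``, ``tablet`` and ``plasma``."""
    try:
        return _MATRIX_PRESETS[kind]
    except KeyError:
        raise ConfigurationError(
            f"unknown matrix {kind!r}; expected one of {VALID_MATRICES}"
        ) from None


@dataclass(frozen=True)
class Sample:
    """One prepared flask: analyte concentrations (ng/mL) in a matrix."""

    concentrations: Mapping[str, float]
    matrix: str = "solvent"
    seed: int | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if self.matrix not in VALID_MATRICES:
            raise ConfigurationError(
                f"unknown matrix {self.matrix!r}; expected one of {VALID_MATRICES}"
            )
        for name, c in self.concentrations.items():
            if c < 0:
                raise InvalidParameterError(
                    f"negative concentration for {name}: {c}"
                )


@dataclass(frozen=True)
class ExcitationEmissionMatrix:
    """Fluorescence landscape I(lam_ex, lam_em) on a pair of scan grids.

    ``intensities`` is indexed ``[excitation, emission]``.
    """

    ex_grid: WavelengthGrid
    em_grid: WavelengthGrid
    intensities: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        shape = (self.ex_grid.n_points, self.em_grid.n_points)
        if self.intensities.shape != shape:
            raise DataError(
                f"intensity matrix shape {self.intensities.shape} does not "
                f"match grids {shape}"
            )


def band_profile(
    center_nm: float, fwhm_nm: float, grid: WavelengthGrid | np.ndarray
) -> np.ndarray:
    """Unit-peak Gaussian band evaluated on a wavelength grid.

    The profile is ``exp(-4 ln2 (lam - center)^2 / fwhm^2)``: 1.0 at the
    centre and 0.5 at ``center +/- fwhm/2``.
    """
    if fwhm_nm <= 0:
        raise InvalidParameterError(f"fwhm_nm must be > 0, got {fwhm_nm}")
    lam = grid.values if isinstance(grid, WavelengthGrid) else np.asarray(grid, float)
    return np.exp(-4.0 * _LN2 * ((lam - center_nm) / fwhm_nm) ** 2)


def simulate_eem(
    sample: Sample,
    fluorophores: Mapping[str, FluorophoreModel] | None = None,
    matrix_model: MatrixModel | None = None,
    ex_grid: WavelengthGrid = DEFAULT_EX_GRID,
    em_grid: WavelengthGrid = DEFAULT_EM_GRID,
    seed: int | np.random.Generator | None = None,
) -> ExcitationEmissionMatrix:
    """Simulate one measured EEM for a sample.

    The noiseless landscape is exactly bilinear in the sample
    concentrations (sum of rank-one excitation x emission products plus
    a constant background).  Multiplicative noise (if configured) is
    applied first, then additive detector noise.  For a fixed ``seed``
    the output is reproducible; with noise disabled it is deterministic.

    Raises
    ------
    ConfigurationError
        If an analyte in the sample has no fluorophore model, or a model's
        band centre falls outside the scan grids.
    """
    fluorophores = default_fluorophores() if fluorophores is None else fluorophores
    if matrix_model is None:
        matrix_model = default_matrix(sample.matrix)

    signal = np.zeros((ex_grid.n_points, em_grid.n_points))
    for name, conc in sample.concentrations.items():
        model = fluorophores.get(name)
        if model is None:
            raise ConfigurationError(f"no fluorophore model for analyte {name!r}")
        if not (ex_grid.covers(model.ex_center_nm) and em_grid.covers(model.em_center_nm)):
            raise ConfigurationError(
                f"scan grids do not cover the {name} band centres "
                f"({model.ex_center_nm}/{model.em_center_nm} nm)"
            )
        if conc == 0.0:
            continue
        amp = conc * model.response * model.enhancement * matrix_model.recovery_factor
        signal += amp * np.outer(
            model.excitation_profile(ex_grid), model.emission_profile(em_grid)
        )

    intensities = signal + matrix_model.background
    if matrix_model.noise_cv > 0 or matrix_model.noise_sd > 0:
        if isinstance(seed, np.random.Generator):
            rng = seed
        else:
            rng = np.random.default_rng(sample.seed if seed is None else seed)
        if matrix_model.noise_cv > 0:
            intensities = intensities * (
                1.0 + rng.normal(0.0, matrix_model.noise_cv, intensities.shape)
            )
        if matrix_model.noise_sd > 0:
            intensities = intensities + rng.normal(
                0.0, matrix_model.noise_sd, intensities.shape
            )

    meta = {"label": sample.label, "matrix": sample.matrix}
    if sample.seed is not None or seed is not None:
        meta["seed"] = seed if isinstance(seed, int) else sample.seed
    return ExcitationEmissionMatrix(ex_grid, em_grid, intensities, meta)


# ---------------------------------------------------------------------------
# Study designs
# ---------------------------------------------------------------------------

#: Tablet-ratio (1:2 FEX:PSE) mixture levels used throughout the
#: validation studies: five pairs spanning the lower halves of the two
#: linear ranges.
TABLET_RATIO_PAIRS: tuple[tuple[float, float], ...] = (
    (100.0, 200.0),
    (150.0, 300.0),
    (200.0, 400.0),
    (250.0, 500.0),
    (300.0, 600.0),
)


@dataclass(frozen=True)
class StudyDesign:
    """Concentration layout of a complete simulated study.

    Defaults mirror the method's validation design: single-analyte
    calibration series spanning 100-1500 ng/mL (FEX) and 50-1000 ng/mL
    (PSE), five 1:2 synthetic mixtures, and five 1:2 spiked-plasma
    samples at the same levels.  ``n_determinations`` replicate scans are
    averaged per reported value, as in the tables' footnotes.
    """

    calibration_levels: Mapping[str, Sequence[float]] = field(
        default_factory=lambda: {
            "FEX": (100.0, 250.0, 500.0, 750.0, 1000.0, 1500.0),
            "PSE": (50.0, 100.0, 250.0, 500.0, 750.0, 1000.0),
        }
    )
    mixture_pairs: Sequence[tuple[float, float]] = TABLET_RATIO_PAIRS
    plasma_pairs: Sequence[tuple[float, float]] = TABLET_RATIO_PAIRS
    n_blanks: int = 3
    n_determinations: int = 3

    def __post_init__(self) -> None:
        if not self.calibration_levels and not self.mixture_pairs and not self.plasma_pairs:
            raise ConfigurationError("empty study design")
        if self.n_determinations < 1 or self.n_blanks < 1:
            raise ConfigurationError("n_determinations and n_blanks must be >= 1")


def _spawn_seeds(seed: int, n: int) -> list[int]:
    # independent per-sample seeds, kept below 2**31 for portability
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def simulate_study(
    design: StudyDesign | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
    fluorophores: Mapping[str, FluorophoreModel] | None = None,
    matrices: Mapping[str, MatrixModel] | None = None,
    ex_grid: WavelengthGrid = DEFAULT_EX_GRID,
    em_grid: WavelengthGrid = DEFAULT_EM_GRID,
) -> dict:
    """Generate every (Sample, EEM) pair of a study design.

    Returns a manifest dictionary with one entry per sample: label,
    matrix, true concentrations, child seed, group, and (when
    ``out_dir`` is given) the path of the written long-format EEM CSV.
    The in-memory EEMs are attached under the non-serialised key
    ``"_eems"`` (a list parallel to ``manifest["samples"]``).  Two runs
    with the same design and seed produce byte-identical manifests.
    """
    from .io import write_eem_csv  # local import: io depends on this module

    design = StudyDesign() if design is None else design
    fluorophores = default_fluorophores() if fluorophores is None else dict(fluorophores)
    matrices = dict(matrices) if matrices is not None else dict(_MATRIX_PRESETS)

    samples: list[Sample] = []

    def add(label: str, conc: Mapping[str, float], matrix: str, group: str) -> None:
        samples.append(Sample(dict(conc), matrix=matrix, label=label))
        groups.append(group)

    groups: list[str] = []
    for i in range(design.n_blanks):
        add(f"blank_solvent_{i + 1}", {}, "solvent", "blank")
    for analyte, levels in design.calibration_levels.items():
        for level in levels:
            for rep in range(design.n_determinations):
                add(
                    f"cal_{analyte}_{level:g}_{rep + 1}",
                    {analyte: float(level)},
                    "solvent",
                    f"calibration:{analyte}",
                )
    for fex_c, pse_c in design.mixture_pairs:
        for rep in range(design.n_determinations):
            add(
                f"mix_{fex_c:g}_{pse_c:g}_{rep + 1}",
                {"FEX": fex_c, "PSE": pse_c},
                "solvent",
                "mixture",
            )
    for i in range(design.n_blanks):
        add(f"blank_plasma_{i + 1}", {}, "plasma", "blank_plasma")
    for fex_c, pse_c in design.plasma_pairs:
        for rep in range(design.n_determinations):
            add(
                f"plasma_{fex_c:g}_{pse_c:g}_{rep + 1}",
                {"FEX": fex_c, "PSE": pse_c},
                "plasma",
                "plasma",
            )

    if not samples:
        raise ConfigurationError("empty study design")

    child_seeds = _spawn_seeds(seed, len(samples))
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        (out_path / "eems").mkdir(parents=True, exist_ok=True)

    entries = []
    eems = []
    for sample, group, child in zip(samples, groups, child_seeds):
        matrix_model = matrices.get(sample.matrix, default_matrix(sample.matrix))
        eem = simulate_eem(
            sample, fluorophores, matrix_model, ex_grid, em_grid, seed=child
        )
        eems.append(eem)
        entry = {
            "label": sample.label,
            "group": group,
            "matrix": sample.matrix,
            "true_concentrations_ng_ml": {
                k: float(v) for k, v in sorted(sample.concentrations.items())
            },
            "seed": child,
        }
        if out_path is not None:
            rel = f"eems/{sample.label}.csv"
            write_eem_csv(eem, out_path / rel, metadata={"seed": child, "label": sample.label})
            entry["path"] = rel
        entries.append(entry)

    manifest = {
        "seed": seed,
        "design": {
            "calibration_levels": {
                k: [float(x) for x in v] for k, v in design.calibration_levels.items()
            },
            "mixture_pairs": [[float(a), float(b)] for a, b in design.mixture_pairs],
            "plasma_pairs": [[float(a), float(b)] for a, b in design.plasma_pairs],
            "n_blanks": design.n_blanks,
            "n_determinations": design.n_determinations,
        },
        "samples": entries,
    }
    if out_path is not None:
        (out_path / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n"
        )
    manifest["_eems"] = eems
    return manifest
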