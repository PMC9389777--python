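"""ICH-style validation statistics and method-comparison tests.

Recovery summaries, LOD/LOQ, pooled t / variance-ratio F comparisons,
standard-addition recovery, and a seeded robustness runner that re-runs
the simulated assay under deliberate parameter perturbations.

Display convention (matching the assay's reported tables): individual
percent recoveries are rounded to 2 decimal places *before* the
mean/RSD are computed, and RSD always uses the sample (n-1) standard
deviation.  Rounding can be disabled for full-precision pipelines.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import ConfigurationError, DataError, DegenerateDesignError
from .quantify import CalibrationCurve, fit_calibration, predict_concentration, quantify_mixture
from .simulate import (
    FluorophoreModel,
    MatrixModel,
    Sample,
    WavelengthGrid,
    default_fluorophores,
    default_matrix,
    simulate_eem,
)
from .transform import (
    amplitude_at,
    first_derivative,
    locate_analytical_wavelengths,
    subtract_blank,
    synchronous_scan,
)

__all__ = [
    "RecoverySummary",
    "MethodSummary",
    "MethodComparison",
    "ValidationReport",
    "RobustnessConfig",
    "RobustnessEntry",
    "percent_recovery",
    "summarize_recoveries",
    "lod_loq",
    "compare_methods",
    "compare_methods_raw",
    "standard_addition",
    "robustness",
    "DEFAULT_PERTURBATIONS",
]


def percent_recovery(added: float, found: float) -> float:
    """100 x found/added; ``added`` must be strictly positive."""
    if added <= 0:
        raise DataError(f"added concentration must be > 0, got {added}")
    return 100.0 * found / added


@dataclass(frozen=True)
class RecoverySummary:
    """Added/found rows with their mean percent recovery and RSD."""

    analyte: str
    rows: tuple[tuple[float, float, float], ...]  # (added, found, %recovery)
    mean_recovery: float
    rsd: float
    n: int

    def __post_init__(self) -> None:
        if self.n != len(self.rows):
            raise DataError("n does not match number of rows")


def summarize_recoveries(
    rows: Sequence[tuple[float, float]],
    analyte: str = "",
    round_decimals: int | None = 2,
) -> RecoverySummary:
    """Mean and relative standard deviation of percent recoveries.

    ``rows`` are (added, found) pairs.  With the default
    ``round_decimals=2`` each recovery is rounded as tabulated before
    summarising; pass ``None`` for full precision.
    """
    if len(rows) < 2:
        raise DegenerateDesignError("recovery summary requires at least 2 rows")
    recs = []
    out_rows = []
    for added, found in rows:
        r = percent_recovery(added, found)
        if round_decimals is not None:
            r = round(r, round_decimals)
        recs.append(r)
        out_rows.append((float(added), float(found), float(r)))
    arr = np.asarray(recs, float)
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1))
    rsd = 100.0 * sd / mean if mean != 0 else math.inf
    return RecoverySummary(
        analyte=analyte,
        rows=tuple(out_rows),
        mean_recovery=mean,
        rsd=float(rsd),
        n=len(out_rows),
    )


def lod_loq(
    curve: CalibrationCurve,
    sigma: float | None = None,
) -> tuple[float, float]:
    """ICH limits of detection and quantification.

    ``LOD = 3.3 sigma / |S|`` and ``LOQ = 10 sigma / |S|`` with ``S`` the
    calibration slope.  ``sigma`` defaults to the curve's residual
    standard deviation (the ICH "standard deviation of the response"
    option); supply the blank SD or intercept SD to use the other ICH
    conventions.  The slope magnitude is used because derivative-readout
    slopes are signed.
    """
    if curve.slope == 0:
        raise DataError("calibration slope is zero; LOD/LOQ undefined")
    s = sigma if sigma is not None else curve.residual_sd
    if s < 0:
        raise DataError("sigma must be >= 0")
    return 3.3 * s / abs(curve.slope), 10.0 * s / abs(curve.slope)


@dataclass(frozen=True)
class MethodSummary:
    """(mean %R, RSD %, n) triple describing one method's replicate set."""

    mean: float
    rsd: float
    n: int

    @property
    def sd(self) -> float:
        return self.rsd * self.mean / 100.0

    @property
    def variance(self) -> float:
        return self.sd**2


@dataclass(frozen=True)
class MethodComparison:
    """Two-sample comparison of percent-recovery summaries."""

    method_a: MethodSummary
    method_b: MethodSummary
    t_statistic: float
    f_statistic: float
    t_critical: float
    f_critical: float

    @property
    def t_significant(self) -> bool:
        return self.t_statistic > self.t_critical

    @property
    def f_significant(self) -> bool:
        return self.f_statistic > self.f_critical


def _as_summary(obj) -> MethodSummary:
    if isinstance(obj, MethodSummary):
        return obj
    if isinstance(obj, RecoverySummary):
        return MethodSummary(mean=obj.mean_recovery, rsd=obj.rsd, n=obj.n)
    raise ConfigurationError(f"cannot interpret {type(obj).__name__} as a method summary")


def compare_methods(
    summary_a,
    summary_b,
    alpha: float = 0.05,
    t_variant: str = "pooled",
) -> MethodComparison:
    """Student's t-test and variance-ratio F-test between two methods.

    F places the larger variance in the numerator (so F >= 1) with the
    matching degrees of freedom; t uses the classical pooled-variance
    two-sample statistic by default (``t_variant="welch"`` for unequal
    variances).  Critical values are two-sided at ``alpha`` for t and
    upper-tail at ``alpha`` for F, from the degrees of freedom implied by
    the two ``n`` values (2.306 and 6.388 for n = 5 vs 5).
    """
    a, b = _as_summary(summary_a), _as_summary(summary_b)
    if a.n < 2 or b.n < 2:
        raise DegenerateDesignError("method comparison requires n >= 2 in both groups")
    va, vb = a.variance, b.variance
    if va == 0 and vb == 0:
        raise DataError("both methods have zero variance; F undefined")

    if va >= vb:
        f_stat = va / vb if vb > 0 else math.inf
        df_num, df_den = a.n - 1, b.n - 1
    else:
        f_stat = vb / va
        df_num, df_den = b.n - 1, a.n - 1

    if t_variant == "pooled":
        df_t = a.n + b.n - 2
        sp2 = ((a.n - 1) * va + (b.n - 1) * vb) / df_t
        se = math.sqrt(sp2 * (1.0 / a.n + 1.0 / b.n))
    elif t_variant == "welch":
        se = math.sqrt(va / a.n + vb / b.n)
        df_t = (va / a.n + vb / b.n) ** 2 / (
            (va / a.n) ** 2 / (a.n - 1) + (vb / b.n) ** 2 / (b.n - 1)
        )
    else:
        raise ConfigurationError(f"unknown t_variant {t_variant!r}")
    t_stat = abs(a.mean - b.mean) / se if se > 0 else math.inf

    return MethodComparison(
        method_a=a,
        method_b=b,
        t_statistic=float(t_stat),
        f_statistic=float(f_stat),
        t_critical=float(stats.t.ppf(1.0 - alpha / 2.0, df_t)),
        f_critical=float(stats.f.ppf(1.0 - alpha, df_num, df_den)),
    )


def compare_methods_raw(
    values_a: Sequence[float], values_b: Sequence[float], **kwargs
) -> MethodComparison:
    """Convenience: build (mean, RSD, n) summaries from raw replicate
    vectors and compare; equals the summary route to machine precision."""
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    mk = lambda v: MethodSummary(
        mean=float(v.mean()), rsd=100.0 * float(v.std(ddof=1)) / float(v.mean()), n=len(v)
    )
    return compare_methods(mk(a), mk(b), **kwargs)


def standard_addition(
    base_found: float,
    additions: Sequence[tuple[float, float]],
    analyte: str = "",
    round_decimals: int | None = 2,
) -> RecoverySummary:
    """Recovery of pure standard spiked onto an already-quantified sample.

    ``additions`` are (added, total_found) pairs; each pure-addition
    recovery is ``100 * (total_found - base_found) / added``.  Negative
    increments yield negative recoveries, which are reported (flagged by
    their sign), not raised.
    """
    if not additions:
        raise DegenerateDesignError("no additions supplied")
    rows = [(added, total - base_found) for added, total in additions]
    return summarize_recoveries(rows, analyte=analyte, round_decimals=round_decimals)


# ---------------------------------------------------------------------------
# Robustness
# ---------------------------------------------------------------------------

#: Deliberate method perturbations: an instrument-setting shift of the
#: synchronous offset, and sample-chemistry variations (pH, buffer
#: volume) expressed as fluorescence-enhancement multipliers.
DEFAULT_PERTURBATIONS: dict[str, dict] = {
    "null": {},
    "delta_lambda:+1nm": {"delta_shift_nm": 1.0},
    "delta_lambda:-1nm": {"delta_shift_nm": -1.0},
    "ph:+0.1": {"enhancement_factor": 1.01},
    "ph:-0.1": {"enhancement_factor": 0.99},
    "buffer_volume:+0.1mL": {"enhancement_factor": 1.005},
    "buffer_volume:-0.1mL": {"enhancement_factor": 0.995},
}


@dataclass(frozen=True)
class RobustnessConfig:
    """Settings for the perturbation study.

    The scan grids default to a 0.5 nm pitch so the half-step band
    shifts produced by a +/-1 nm ``delta_lambda`` change stay on-grid and
    the analytical wavelengths can be re-located at the observed zero
    crossings, exactly as an analyst re-reads the recorded spectra.
    """

    fluorophores: Mapping[str, FluorophoreModel] = field(
        default_factory=default_fluorophores
    )
    matrix: MatrixModel = field(default_factory=lambda: default_matrix("solvent"))
    ex_grid: WavelengthGrid = WavelengthGrid(220.0, 340.0, 0.5)
    em_grid: WavelengthGrid = WavelengthGrid(220.0, 340.0, 0.5)
    delta_lambda_nm: float = 25.0
    window_points: int = 5
    calibration_levels: Mapping[str, Sequence[float]] = field(
        default_factory=lambda: {
            "FEX": (100.0, 250.0, 500.0, 750.0, 1000.0, 1500.0),
            "PSE": (50.0, 100.0, 250.0, 500.0, 750.0, 1000.0),
        }
    )
    mixture: Mapping[str, float] = field(
        default_factory=lambda: {"FEX": 250.0, "PSE": 500.0}
    )
    n_replicates: int = 8
    n_determinations: int = 3


@dataclass(frozen=True)
class RobustnessEntry:
    perturbation: str
    analyte: str
    mean_recovery: float
    rsd: float
    n: int


def _mean_derivative_amplitude(
    sample: Sample,
    fluorophores,
    matrix: MatrixModel,
    cfg: RobustnessConfig,
    delta: float,
    wavelength: float,
    blank_sync,
    rng: np.random.Generator,
    n_determinations: int,
) -> float:
    vals = []
    for _ in range(n_determinations):
        eem = simulate_eem(
            sample, fluorophores, matrix, cfg.ex_grid, cfg.em_grid, seed=rng
        )
        sync = synchronous_scan(eem, delta)
        if blank_sync is not None:
            sync = subtract_blank(sync, blank_sync)
        vals.append(amplitude_at(first_derivative(sync, cfg.window_points), wavelength))
    return float(np.mean(vals))


def robustness(
    config: RobustnessConfig | None = None,
    perturbations: Mapping[str, dict] | Sequence[str] | None = None,
    seed: int = 0,
) -> list[RobustnessEntry]:
    """Re-run the simulated assay under each perturbation and summarise.

    A ``delta_shift_nm`` perturbation is an instrument setting: both the
    calibration standards and the test mixtures are scanned at the
    shifted offset and the analytical wavelengths are re-located on the
    perturbed pure-standard spectra.  An ``enhancement_factor``
    perturbation models sample-preparation chemistry: it scales the test
    samples' fluorescence while the calibration stays nominal, so a
    +/-x% factor shifts recoveries by at most x% (linear response).

    All perturbations replay the same noise stream (identical seed), so
    the ``null`` perturbation reproduces the unperturbed assay exactly.
    """
    cfg = RobustnessConfig() if config is None else config
    if perturbations is None:
        perturbations = DEFAULT_PERTURBATIONS
    elif not isinstance(perturbations, Mapping):
        try:
            perturbations = {k: DEFAULT_PERTURBATIONS[k] for k in perturbations}
        except KeyError as exc:
            raise ConfigurationError(f"unknown perturbation key {exc.args[0]!r}") from None
    for name, spec in perturbations.items():
        unknown = set(spec) - {"delta_shift_nm", "enhancement_factor"}
        if unknown:
            raise ConfigurationError(
                f"perturbation {name!r} has unknown parameters {sorted(unknown)}"
            )

    entries: list[RobustnessEntry] = []
    for name, spec in perturbations.items():
        delta = cfg.delta_lambda_nm + spec.get("delta_shift_nm", 0.0)
        enh = spec.get("enhancement_factor", 1.0)
        rng = np.random.default_rng(seed)  # same stream for every perturbation

        # re-locate zero crossings on noiseless pure standards at this offset
        pure_sync = {}
        for analyte, model in cfg.fluorophores.items():
            eem = simulate_eem(
                Sample({analyte: 500.0}),
                cfg.fluorophores,
                cfg.matrix.noiseless,
                cfg.ex_grid,
                cfg.em_grid,
            )
            pure_sync[analyte] = synchronous_scan(eem, delta)
        wavelengths = locate_analytical_wavelengths(pure_sync)

        blank_eem = simulate_eem(
            Sample({}), cfg.fluorophores, cfg.matrix, cfg.ex_grid, cfg.em_grid, seed=rng
        )
        blank_sync = synchronous_scan(blank_eem, delta)

        curves: dict[str, CalibrationCurve] = {}
        for analyte, levels in cfg.calibration_levels.items():
            amps = [
                _mean_derivative_amplitude(
                    Sample({analyte: float(level)}),
                    cfg.fluorophores,
                    cfg.matrix,
                    cfg,
                    delta,
                    wavelengths[analyte],
                    blank_sync,
                    rng,
                    cfg.n_determinations,
                )
                for level in levels
            ]
            curves[analyte] = fit_calibration(
                list(levels), amps, analyte, wavelengths[analyte], delta, cfg.window_points
            )

        perturbed_models = {
            analyte: replace(model, enhancement=model.enhancement * enh)
            for analyte, model in cfg.fluorophores.items()
        }
        found: dict[str, list[float]] = {a: [] for a in cfg.mixture}
        for _ in range(cfg.n_replicates):
            amps = {
                analyte: _mean_derivative_amplitude(
                    Sample(dict(cfg.mixture)),
                    perturbed_models,
                    cfg.matrix,
                    cfg,
                    delta,
                    curves[analyte].wavelength_nm,
                    blank_sync,
                    rng,
                    cfg.n_determinations,
                )
                for analyte in cfg.mixture
            }
            for analyte, amp in amps.items():
                found[analyte].append(predict_concentration(curves[analyte], amp).ng_ml)

        for analyte, values in found.items():
            summary = summarize_recoveries(
                [(cfg.mixture[analyte], v) for v in values], analyte=analyte
            )
            entries.append(
                RobustnessEntry(
                    perturbation=name,
                    analyte=analyte,
                    mean_recovery=summary.mean_recovery,
                    rsd=summary.rsd,
                    n=summary.n,
                )
            )
    return entries


@dataclass(frozen=True)
class ValidationReport:
    """Collected validation figures for one analyte."""

    analyte: str
    linearity_range_ng_ml: tuple[float, float]
    lod_ng_ml: float
    loq_ng_ml: float
    accuracy_recovery: float
    repeatability_rsd: float
    intermediate_precision_rsd: float
    robustness_entries: tuple[RobustnessEntry, ...] = ()
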