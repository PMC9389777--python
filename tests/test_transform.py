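"""Synchronous extraction, Savitzky-Golay derivatives, zero-crossing readout."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from synchrofluor import (
    DataError,
    ExcitationEmissionMatrix,
    GridMismatchError,
    InvalidParameterError,
    Sample,
    SynchronousSpectrum,
    WavelengthGrid,
    amplitude_at,
    band_profile,
    first_derivative,
    locate_analytical_wavelengths,
    optimize_delta_lambda,
    simulate_eem,
    subtract_blank,
    synchronous_scan,
)

GRID = WavelengthGrid(220.0, 340.0, 1.0)


def make_sync(values, start=245.0, step=1.0, delta=25.0):
    values = np.asarray(values, float)
    axis = WavelengthGrid(start, start + step * (len(values) - 1), step)
    return SynchronousSpectrum(delta, axis, values)


class TestSynchronousScan:
    def test_constant_eem_gives_constant_trace(self):
        eem = ExcitationEmissionMatrix(GRID, GRID, np.full((121, 121), 7.5))
        sync = synchronous_scan(eem, 25.0)
        assert np.all(sync.intensities == 7.5)
        # axis restricted to emission wavelengths whose partner is on-grid
        assert sync.axis.start_nm == 245.0 and sync.axis.stop_nm == 340.0

    def test_single_band_pair_peak_matches_brute_force_product(self, noiseless_eem):
        # independent oracle: maximise Ex(lam-25)*Em(lam) over the grid
        sync = synchronous_scan(noiseless_eem(FEX=1000.0), 25.0)
        lam = sync.axis.values
        oracle = band_profile(267.0, 10.0, lam - 25.0) * band_profile(294.0, 10.0, lam)
        assert lam[np.argmax(sync.intensities)] == lam[np.argmax(oracle)] == 293.0

    def test_default_mixture_shows_two_resolved_synchronous_maxima(self, noiseless_eem):
        sync = synchronous_scan(noiseless_eem(FEX=1000.0, PSE=800.0), 25.0)
        v = sync.intensities
        maxima = [
            sync.axis.values[i]
            for i in range(1, len(v) - 1)
            if v[i] > v[i - 1] and v[i] > v[i + 1]
        ]
        assert len(maxima) == 2
        lo, hi = sorted(maxima)
        assert abs(lo - 286.0) <= 1.5  # PSE band
        assert abs(hi - 293.0) <= 1.5  # FEX band

    def test_off_grid_delta_rejected(self, noiseless_eem):
        with pytest.raises(GridMismatchError):
            synchronous_scan(noiseless_eem(FEX=100.0), 25.4)

    def test_disjoint_diagonal_rejected(self):
        ex = WavelengthGrid(220.0, 240.0, 1.0)
        em = WavelengthGrid(320.0, 340.0, 1.0)
        eem = ExcitationEmissionMatrix(ex, em, np.zeros((21, 21)))
        with pytest.raises(GridMismatchError):
            synchronous_scan(eem, 25.0)


class TestFirstDerivative:
    def test_straight_line_derivative_is_slope_everywhere(self):
        axis = np.arange(245.0, 301.0)
        sync = make_sync(3.0 + 0.25 * axis)
        deriv = first_derivative(sync, 5)
        np.testing.assert_allclose(deriv.amplitudes, 0.25, rtol=1e-10)
        assert len(deriv.amplitudes) == len(sync.intensities)

    def test_symmetric_gaussian_has_zero_derivative_at_center(self):
        lam = np.arange(245.0, 346.0)
        sync = make_sync(np.exp(-0.01 * (lam - 295.0) ** 2))
        deriv = first_derivative(sync, 5)
        assert amplitude_at(deriv, 295.0) == pytest.approx(0.0, abs=1e-14)

    def test_cubic_matches_per_window_least_squares_oracle(self):
        # oracle: quadratic fit on each 5-point window, derivative at centre
        lam = np.arange(0.0, 21.0)
        y = lam**3
        sync = SynchronousSpectrum(25.0, WavelengthGrid(0.0, 20.0, 1.0), y)
        deriv = first_derivative(sync, 5)
        for i in range(2, 19):
            window = np.arange(i - 2, i + 3, dtype=float)
            coeffs = np.polyfit(window, y[i - 2 : i + 3], 2)
            oracle = 2 * coeffs[0] * lam[i] + coeffs[1]
            assert deriv.amplitudes[i] == pytest.approx(oracle, rel=1e-9)

    @pytest.mark.parametrize("window", [4, 2, -1])
    def test_even_or_invalid_window_rejected(self, window):
        with pytest.raises(InvalidParameterError):
            first_derivative(make_sync(np.zeros(20)), window)

    def test_too_short_spectrum_rejected(self):
        with pytest.raises(DataError):
            first_derivative(make_sync([1.0, 2.0, 3.0]), 5)

    @settings(derandomize=True, max_examples=30)
    @given(
        a=st.floats(-2.0, 2.0),
        b=st.floats(-2.0, 2.0),
        seed=st.integers(0, 2**16),
    )
    def test_derivative_is_a_linear_operator(self, a, b, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=40)
        y = rng.normal(size=40)
        combo = first_derivative(make_sync(a * x + b * y), 5).amplitudes
        parts = (
            a * first_derivative(make_sync(x), 5).amplitudes
            + b * first_derivative(make_sync(y), 5).amplitudes
        )
        np.testing.assert_allclose(combo, parts, rtol=1e-9, atol=1e-12)

    def test_blank_correction_commutes_with_derivatisation(self, rng):
        sample = make_sync(rng.normal(size=50))
        blank = make_sync(rng.normal(size=50))
        before = first_derivative(subtract_blank(sample, blank), 5).amplitudes
        after = (
            first_derivative(sample, 5).amplitudes
            - first_derivative(blank, 5).amplitudes
        )
        np.testing.assert_allclose(before, after, rtol=1e-12, atol=1e-12)


class TestAmplitudeReadout:
    def test_exact_grid_point_and_nearest_rule(self):
        sync = make_sync(np.arange(50.0))
        assert amplitude_at(sync, 286.0) == 41.0
        assert amplitude_at(sync, 286.4) == 41.0  # nearest
        assert amplitude_at(sync, 286.5) == 41.0  # tie -> lower wavelength

    def test_out_of_range_request_rejected(self):
        with pytest.raises(DataError):
            amplitude_at(make_sync(np.arange(10.0)), 500.0)

    def test_pse_only_trace_is_silent_at_286_and_linear_at_293(self, noiseless_eem):
        amps = {}
        for conc in (200.0, 400.0, 800.0):
            deriv = first_derivative(synchronous_scan(noiseless_eem(PSE=conc), 25.0), 5)
            amps[conc] = (amplitude_at(deriv, 286.0), amplitude_at(deriv, 293.0))
        scale = abs(amps[800.0][1])
        for conc, (at286, at293) in amps.items():
            assert abs(at286) < 1e-9 * scale  # zero crossing: FEX channel blind to PSE
            assert at293 == pytest.approx(amps[800.0][1] * conc / 800.0, rel=1e-9)


class TestZeroCrossingWavelengths:
    def test_each_analyte_read_at_the_interferents_band_maximum(self, pure_sync):
        wavelengths = locate_analytical_wavelengths(pure_sync)
        assert wavelengths == {"FEX": 286.0, "PSE": 293.0}


@pytest.fixture(scope="module")
def pure_eems(noiseless_eem):
    return {
        "FEX": (noiseless_eem(FEX=1000.0), 1000.0),
        "PSE": (noiseless_eem(PSE=800.0), 800.0),
    }


class TestOptimizeDeltaLambda:
    def test_chosen_offset_is_the_table_optimum(self, pure_eems):
        result = optimize_delta_lambda(pure_eems)
        feasible = result.table[result.table["feasible"]]
        assert result.chosen_nm == feasible.loc[feasible["score"].idxmax(), "delta_lambda_nm"]
        assert result.chosen_nm == 25.0
        assert result.analytical_wavelengths == {"FEX": 286.0, "PSE": 293.0}

    def test_singleton_candidate_returned_with_score(self, pure_eems):
        result = optimize_delta_lambda(pure_eems, candidates=[25.0])
        assert result.chosen_nm == 25.0
        assert result.score > 0

    def test_single_analyte_reduces_to_sensitivity_argmax(self, noiseless_eem):
        result = optimize_delta_lambda({"FEX": (noiseless_eem(FEX=1000.0), 1000.0)})
        best = result.table.loc[result.table["score"].idxmax()]
        assert result.chosen_nm == best["delta_lambda_nm"]

    def test_impossible_constraint_raises_diagnostic_error(self, pure_eems):
        with pytest.raises(DataError, match="cross-sensitivity"):
            optimize_delta_lambda(pure_eems, max_cross_fraction=1e-18)


class TestTransformLinearity:
    def test_synchronous_extraction_is_linear_in_the_eem(self, noiseless_eem):
        a = noiseless_eem(FEX=700.0)
        b = noiseless_eem(PSE=300.0)
        combined = ExcitationEmissionMatrix(
            a.ex_grid, a.em_grid, 2.0 * a.intensities + 0.5 * b.intensities
        )
        lhs = synchronous_scan(combined, 25.0).intensities
        rhs = (
            2.0 * synchronous_scan(a, 25.0).intensities
            + 0.5 * synchronous_scan(b, 25.0).intensities
        )
        np.testing.assert_allclose(lhs, rhs, rtol=1e-12)
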