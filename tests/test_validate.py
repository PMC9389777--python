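"""Recovery statistics, LOD/LOQ, method comparison, robustness."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from synchrofluor import (
    ConfigurationError,
    DataError,
    DegenerateDesignError,
    MethodSummary,
    RobustnessConfig,
    WavelengthGrid,
    compare_methods,
    compare_methods_raw,
    default_fluorophores,
    default_matrix,
    fit_calibration,
    lod_loq,
    percent_recovery,
    robustness,
    standard_addition,
    summarize_recoveries,
)


class TestPercentRecovery:
    @pytest.mark.parametrize(
        "added,found,expected",
        [(100.0, 100.94, 100.94), (150.0, 152.75, 101.83), (77.7, 77.7, 100.0)],
    )
    def test_recovery_values(self, added, found, expected):
        assert percent_recovery(added, found) == pytest.approx(expected, abs=5e-3)

    @pytest.mark.parametrize("added", [0.0, -10.0])
    def test_nonpositive_added_rejected(self, added):
        with pytest.raises(DataError):
            percent_recovery(added, 50.0)


class TestSummarizeRecoveries:
    def test_constant_recoveries_have_zero_rsd(self):
        summary = summarize_recoveries([(100.0, 99.0), (200.0, 198.0), (300.0, 297.0)])
        assert summary.mean_recovery == pytest.approx(99.0)
        assert summary.rsd == pytest.approx(0.0, abs=1e-12)

    def test_rsd_uses_sample_standard_deviation(self):
        rows = [(100.0, 98.0), (100.0, 102.0)]
        summary = summarize_recoveries(rows, round_decimals=None)
        # sample SD of {98, 102} is sqrt(8), not 2
        assert summary.rsd == pytest.approx(100.0 * np.sqrt(8.0) / 100.0)

    def test_single_row_rejected(self):
        with pytest.raises(DegenerateDesignError):
            summarize_recoveries([(100.0, 99.0)])


@pytest.fixture(scope="module")
def curve():
    return fit_calibration([0.0, 500.0, 1000.0], [1.0, 17.5, 34.0], "FEX", 286.0)


class TestLodLoq:
    def test_zero_sigma_gives_zero_limits(self, curve):
        assert lod_loq(curve, sigma=0.0) == (0.0, 0.0)

    def test_loq_lod_ratio_is_exactly_ten_over_threepointthree(self, curve):
        lod, loq = lod_loq(curve)
        if lod > 0:
            assert loq / lod == pytest.approx(10.0 / 3.3, rel=1e-12)

    def test_direct_arithmetic_example(self):
        curve = fit_calibration([0.0, 500.0, 1000.0], [0.0, 16.5, 33.0], "X", 286.0)
        assert curve.slope == pytest.approx(0.033)
        lod, loq = lod_loq(curve, sigma=0.33)
        assert lod == pytest.approx(33.0)
        assert loq == pytest.approx(100.0)


class TestCompareMethods:
    def test_identical_summaries_give_t_zero_f_one(self):
        s = MethodSummary(mean=99.5, rsd=1.0, n=5)
        result = compare_methods(s, s)
        assert result.t_statistic == pytest.approx(0.0)
        assert result.f_statistic == pytest.approx(1.0)
        assert not result.t_significant and not result.f_significant

    def test_critical_values_follow_degrees_of_freedom(self):
        a = MethodSummary(99.0, 1.0, 5)
        b = MethodSummary(100.0, 1.5, 5)
        result = compare_methods(a, b)
        assert result.t_critical == pytest.approx(2.306, abs=5e-4)
        assert result.f_critical == pytest.approx(6.388, abs=5e-3)

    def test_f_is_at_least_one_regardless_of_order(self):
        a = MethodSummary(99.0, 0.5, 5)
        b = MethodSummary(100.0, 1.5, 5)
        assert compare_methods(a, b).f_statistic == compare_methods(b, a).f_statistic
        assert compare_methods(a, b).f_statistic >= 1.0

    def test_zero_variance_in_both_rejected(self):
        s = MethodSummary(mean=100.0, rsd=0.0, n=5)
        with pytest.raises(DataError):
            compare_methods(s, s)

    @settings(derandomize=True, max_examples=25)
    @given(seed=st.integers(0, 2**16))
    def test_raw_vectors_equal_summary_route(self, seed):
        rng = np.random.default_rng(seed)
        a = 100.0 + rng.normal(0.0, 1.0, size=5)
        b = 99.0 + rng.normal(0.0, 1.5, size=6)
        via_raw = compare_methods_raw(a, b)
        mk = lambda v: MethodSummary(
            float(np.mean(v)),
            100.0 * float(np.std(v, ddof=1)) / float(np.mean(v)),
            len(v),
        )
        via_summary = compare_methods(mk(a), mk(b))
        assert via_raw.t_statistic == pytest.approx(via_summary.t_statistic, rel=1e-12)
        assert via_raw.f_statistic == pytest.approx(via_summary.f_statistic, rel=1e-12)

    def test_welch_variant_available(self):
        # balanced groups: identical statistic, reduced degrees of freedom
        a = MethodSummary(99.0, 0.5, 5)
        b = MethodSummary(100.0, 2.5, 5)
        pooled = compare_methods(a, b, t_variant="pooled")
        welch = compare_methods(a, b, t_variant="welch")
        assert welch.t_statistic == pytest.approx(pooled.t_statistic)
        assert welch.t_critical > pooled.t_critical
        # unbalanced, heteroscedastic groups: statistics differ
        c = MethodSummary(100.0, 2.5, 10)
        assert compare_methods(a, c, t_variant="welch").t_statistic != pytest.approx(
            compare_methods(a, c, t_variant="pooled").t_statistic
        )


class TestStandardAddition:
    def test_zero_noise_additions_recover_exactly(self):
        base = 150.0
        additions = [(100.0, 250.0), (200.0, 350.0), (300.0, 450.0)]
        summary = standard_addition(base, additions)
        assert summary.mean_recovery == pytest.approx(100.0)
        assert summary.rsd == pytest.approx(0.0, abs=1e-12)

    def test_negative_increment_reported_not_raised(self):
        summary = standard_addition(150.0, [(100.0, 140.0), (200.0, 360.0)])
        assert summary.rows[0][2] < 0


def small_robustness_config(noise=True):
    matrix = default_matrix("solvent")
    return RobustnessConfig(
        fluorophores=default_fluorophores(),
        matrix=matrix if noise else matrix.noiseless,
        ex_grid=WavelengthGrid(240.0, 320.0, 0.5),
        em_grid=WavelengthGrid(240.0, 320.0, 0.5),
        calibration_levels={"FEX": (100.0, 500.0, 1000.0), "PSE": (50.0, 400.0, 800.0)},
        n_replicates=3 if noise else 2,
        n_determinations=2,
    )


class TestRobustness:
    def test_unknown_perturbation_key_rejected(self):
        with pytest.raises(ConfigurationError):
            robustness(small_robustness_config(), perturbations=["not-a-knob"])
        with pytest.raises(ConfigurationError):
            robustness(
                small_robustness_config(), perturbations={"bad": {"voltage": 2.0}}
            )

    def test_null_perturbation_reproduces_unperturbed_run_exactly(self):
        cfg = small_robustness_config()
        alone = robustness(cfg, perturbations=["null"], seed=5)
        with_others = robustness(
            cfg, perturbations=["null", "ph:+0.1"], seed=5
        )
        null_entries = [e for e in with_others if e.perturbation == "null"]
        assert [(e.analyte, e.mean_recovery, e.rsd) for e in alone] == [
            (e.analyte, e.mean_recovery, e.rsd) for e in null_entries
        ]

    def test_enhancement_perturbation_shifts_recovery_linearly(self):
        # noiseless: a +2% enhancement must shift recovery by exactly +2%
        cfg = small_robustness_config(noise=False)
        entries = robustness(
            cfg,
            perturbations={"enh:+2%": {"enhancement_factor": 1.02}},
            seed=0,
        )
        for entry in entries:
            assert entry.mean_recovery == pytest.approx(102.0, abs=1e-6)

    def test_delta_lambda_shift_keeps_recoveries_in_band(self):
        # the +/-1 nm instrument-setting perturbation: recalibrated at the
        # shifted offset with re-located zero crossings, recoveries stay
        # within the 98-102% acceptance band
        entries = robustness(
            small_robustness_config(),
            perturbations=["delta_lambda:+1nm", "delta_lambda:-1nm"],
            seed=3,
        )
        for entry in entries:
            assert 98.0 < entry.mean_recovery < 102.0
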