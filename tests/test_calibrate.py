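"""Calibration tests: table I/O, fit behaviour, aggregation, sensitivity."""

import dataclasses

import numpy as np
import pytest

from denitvial import (
    DEFAULT_PARAMS,
    MeasuredTable,
    NoiseModel,
    aggregate_r,
    fit_r,
    generate_measured_table,
    sensitivity_O2_min,
)
from denitvial.calibrate import FitResult, _n2_sse


@pytest.fixture(scope="module")
def clean_table(calibration_treatment):
    """Noiseless synthetic gas table at the reference recruitment probability."""
    return generate_measured_table(
        calibration_treatment, DEFAULT_PARAMS, r_true=0.0052, noise=NoiseModel(cv=0.0)
    )


class TestMeasuredTable:
    def test_validation(self):
        with pytest.raises(ValueError):
            MeasuredTable(times=[1, 2], O2_hs_obs=[1.0], N2_obs=[0.0, 0.0])
        with pytest.raises(ValueError):
            MeasuredTable(times=[2, 1], O2_hs_obs=[1.0, 1.0], N2_obs=[0.0, 0.0])
        with pytest.raises(ValueError):
            MeasuredTable(times=[1, 2], O2_hs_obs=[1.0, np.nan], N2_obs=[0.0, 0.0])

    def test_csv_round_trip_bit_identical(self, tmp_path, clean_table):
        path = tmp_path / "table.csv"
        clean_table.to_csv(path)
        back = MeasuredTable.from_csv(path)
        assert np.array_equal(back.times, clean_table.times)
        assert np.array_equal(back.O2_hs_obs, clean_table.O2_hs_obs)
        assert np.array_equal(back.N2_obs, clean_table.N2_obs)

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("time_h,N2_molN\n1,0\n")
        with pytest.raises(ValueError, match="misses columns"):
            MeasuredTable.from_csv(path)


class TestFitR:
    def test_zero_noise_recovery_to_optimiser_tolerance(
        self, clean_table, calibration_treatment
    ):
        fit = fit_r(clean_table, calibration_treatment)
        assert fit.converged and not fit.at_bound
        assert fit.r_opt == pytest.approx(0.0052, abs=1e-4)

    def test_noisy_recovery_within_ten_percent(self, calibration_treatment):
        table = generate_measured_table(
            calibration_treatment, r_true=0.005, noise=NoiseModel(cv=0.02, seed=11)
        )
        fit = fit_r(table, calibration_treatment)
        assert abs(fit.r_opt - 0.005) / 0.005 < 0.10

    def test_all_zero_n2_hits_lower_bound_flagged(self, calibration_treatment, clean_table):
        table = MeasuredTable(
            times=clean_table.times,
            O2_hs_obs=clean_table.O2_hs_obs,
            N2_obs=np.zeros_like(clean_table.N2_obs),
        )
        fit = fit_r(table, calibration_treatment)
        assert fit.at_bound
        assert fit.r_opt < 2e-4

    def test_too_few_observations_rejected(self, calibration_treatment, clean_table):
        table = MeasuredTable(
            times=clean_table.times[:3],
            O2_hs_obs=clean_table.O2_hs_obs[:3],
            N2_obs=clean_table.N2_obs[:3],
        )
        with pytest.raises(ValueError, match="at least 5"):
            fit_r(table, calibration_treatment)

    def test_objective_unimodal_on_grid(self, clean_table, calibration_treatment):
        """Coarse grid scan: SSE decreases to a single minimum then increases."""
        grid = np.logspace(-4, 0, 25)
        sse = np.array(
            [_n2_sse(r, clean_table, calibration_treatment, DEFAULT_PARAMS) for r in grid]
        )
        k = int(np.argmin(sse))
        assert 0 < k < len(grid) - 1
        assert np.all(np.diff(sse[: k + 1]) <= 0)
        assert np.all(np.diff(sse[k:]) >= 0)

    def test_time_shift_invariance(self, calibration_treatment):
        """Shifting the sampling clock and the table together leaves r intact."""
        shifted_trt = dataclasses.replace(
            calibration_treatment,
            schedule=dataclasses.replace(calibration_treatment.schedule, first_time=4.0),
        )
        base = generate_measured_table(calibration_treatment, r_true=0.0052,
                                       noise=NoiseModel(cv=0.0))
        shifted = generate_measured_table(shifted_trt, r_true=0.0052,
                                          noise=NoiseModel(cv=0.0))
        r_base = fit_r(base, calibration_treatment).r_opt
        r_shift = fit_r(shifted, shifted_trt).r_opt
        assert r_shift == pytest.approx(r_base, rel=0.02)


class TestAggregate:
    def test_reference_per_batch_estimates_average(self):
        # the nine per-vial optimisation results reported for the
        # incubation experiment average to 0.0052 h^-1
        reference = [0.0066, 0.0059, 0.0029, 0.0033, 0.0062, 0.0020, 0.0018, 0.0117, 0.0066]
        fits = [FitResult(r_opt=v, sse=0.0, n_obs=20, converged=True) for v in reference]
        assert aggregate_r(fits) == pytest.approx(0.0052, abs=1e-4)

    def test_single_and_duplicates(self):
        one = FitResult(r_opt=0.004, sse=0.0, n_obs=10, converged=True)
        assert aggregate_r([one]) == 0.004
        assert aggregate_r([one, one, one]) == 0.004

    def test_empty_or_unconverged_rejected(self):
        with pytest.raises(ValueError):
            aggregate_r([])
        bad = FitResult(r_opt=0.004, sse=0.0, n_obs=10, converged=False)
        with pytest.raises(ValueError):
            aggregate_r([bad])


class TestO2MinSensitivity:
    def test_directional_response(self, clean_table, calibration_treatment):
        # a higher recruitment-arrest threshold narrows the window, which a
        # fit on the same data must compensate with a larger r
        up = sensitivity_O2_min([clean_table], [calibration_treatment], factor=10.0)
        down = sensitivity_O2_min([clean_table], [calibration_treatment], factor=0.1)
        assert up[0] > 0.0
        assert down[0] < 0.0

    def test_identity_factor(self, clean_table, calibration_treatment):
        change = sensitivity_O2_min([clean_table], [calibration_treatment], factor=1.0)
        assert change[0] == pytest.approx(0.0, abs=1e-9)

    def test_invalid_factor(self, clean_table, calibration_treatment):
        with pytest.raises(ValueError):
            sensitivity_O2_min([clean_table], [calibration_treatment], factor=0.0)
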