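"""Partition coefficient, Ve computation and steady-state detection."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from molliecv import (
    ECVConstants,
    InsufficientDataError,
    InvalidParameterError,
    KineticsConfig,
    ScanSeries,
    TissueT1Point,
    delta_r1,
    generate_cohort,
    generate_scan,
    lambda_from_ve,
    partition_coefficient,
    read_scan_csv,
    steady_state_window,
    ve_from_lambda,
    ve_series,
    write_scan_csv,
)


class TestDeltaR1:
    @pytest.mark.parametrize(
        "pre, post, expected",
        [
            (1000.0, 500.0, 0.001),
            (700.0, 700.0, 0.0),
            (1534.0, 309.0, 1 / 309.0 - 1 / 1534.0),  # ~0.0025845
        ],
    )
    def test_arithmetic(self, pre, post, expected):
        assert delta_r1(pre, post) == pytest.approx(expected, abs=1e-12)

    def test_blood_like_value(self):
        assert delta_r1(1534.0, 309.0) == pytest.approx(0.0025845, abs=1e-6)

    def test_nonpositive_t1(self):
        with pytest.raises(InvalidParameterError):
            delta_r1(-1.0, 500.0)


class TestPartitionCoefficient:
    def test_simple_ratio(self):
        assert partition_coefficient(0.001, 0.002) == pytest.approx(0.5)

    def test_equal_inputs(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert partition_coefficient(0.002, 0.002) == pytest.approx(1.0)

    def test_noiseless_series_recovers_truth_at_every_timepoint(self):
        scan = generate_scan(KineticsConfig(protocol="bolus", true_lambda=0.45, noise_frac=0.0))
        res = ve_series(scan)
        assert np.allclose(res.lambda_, 0.45, rtol=1e-12)

    def test_no_blood_contrast_effect(self):
        with pytest.raises(InvalidParameterError):
            partition_coefficient(0.001, 0.0)


class TestVeLambdaConversion:
    def test_reference_subject_value(self):
        # infusion row of the youngest reference subject
        assert ve_from_lambda(0.452, 0.477) == pytest.approx(0.2032, abs=5e-5)

    def test_zero_ve(self):
        lam0 = 0.045 / (1.05 * 0.6)
        assert ve_from_lambda(lam0, 0.40) == pytest.approx(0.0, abs=1e-12)

    def test_lambda_from_ve_value(self):
        assert lambda_from_ve(0.25, 0.40) == pytest.approx((0.25 + 0.045) / (1.05 * 0.6))

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(lam=st.floats(0.2, 0.7), hct=st.floats(0.15, 0.6))
    def test_round_trip_identity(self, lam, hct):
        assert lambda_from_ve(ve_from_lambda(lam, hct), hct) == pytest.approx(
            lam, abs=1e-12
        )

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(hct=st.floats(0.15, 0.55), dh=st.floats(0.01, 0.09))
    def test_monotonicity(self, hct, dh):
        # Ve decreasing in hct at fixed lambda; lambda increasing in hct at fixed Ve
        assert ve_from_lambda(0.45, hct + dh) < ve_from_lambda(0.45, hct)
        assert lambda_from_ve(0.25, hct + dh) > lambda_from_ve(0.25, hct)

    def test_constants_override(self):
        c = ECVConstants(rho=1.0, vp=0.0)
        assert ve_from_lambda(0.5, 0.5, c) == pytest.approx(0.25)

    def test_invalid_hematocrit(self):
        with pytest.raises(InvalidParameterError):
            lambda_from_ve(0.25, 1.2)


def _series(times, blood, myo, protocol="infusion", hct=0.40, pre_b=1500.0, pre_m=950.0):
    points = []
    for t, b, m in zip(times, blood, myo):
        points.append(TissueT1Point(time_min=t, tissue="blood", t1_msec=b))
        points.append(TissueT1Point(time_min=t, tissue="myocardium", t1_msec=m))
    return ScanSeries(
        subject_id="T",
        protocol=protocol,
        hematocrit=hct,
        pre_blood_t1_msec=pre_b,
        pre_myo_t1_msec=pre_m,
        points=points,
    )


class TestSteadyStateWindow:
    def test_constant_series_is_entirely_steady(self):
        times = [10.0, 20.0, 30.0, 40.0]
        s = _series(times, [400.0] * 4, [550.0] * 4)
        assert steady_state_window(s) == (10.0, 40.0)

    def test_drifting_blood_rejected(self):
        times = [10.0, 20.0, 30.0, 40.0]
        blood = [400.0 * 1.1**k for k in range(4)]  # +10% per point
        s = _series(times, blood, [550.0] * 4)
        assert steady_state_window(s) is None

    def test_infusion_fixture_plateau_detected_by_30_min(self):
        """An infusion plateauing at 25 min with 1% noise yields a window
        starting no later than 30 min."""
        cfg = KineticsConfig(protocol="infusion", plateau_time_min=25.0,
                             noise_frac=0.01, seed=0)
        w = steady_state_window(generate_scan(cfg))
        assert w is not None
        assert w[0] <= 30.0

    def test_requires_two_points(self):
        s = _series([15.0], [400.0], [550.0], protocol="bolus")
        with pytest.raises(InsufficientDataError):
            steady_state_window(s)


class TestVeSeries:
    def test_zero_noise_bolus_construction(self):
        scan = generate_scan(
            KineticsConfig(protocol="bolus", true_lambda=0.45, hematocrit=0.40, noise_frac=0.0)
        )
        res = ve_series(scan)
        expected = 0.45 * 1.05 * 0.6 - 0.045  # 0.2385
        assert np.allclose(res.ve, expected, atol=1e-12)
        assert res.sd_ve == pytest.approx(0.0, abs=1e-12)

    def test_ve_invariant_under_shared_clearance(self):
        """Blood and myocardial T1 both drift as contrast clears, but with a
        fixed lambda the Ve series stays exactly constant."""
        times = np.array([12.0, 20.0, 30.0, 40.0, 50.0])
        dr1_b = 0.002 * 0.5 ** (times / 90.0)
        lam = 0.42
        blood = 1.0 / (1.0 / 1500.0 + dr1_b)
        myo = 1.0 / (1.0 / 950.0 + lam * dr1_b)
        s = _series(list(times), list(blood), list(myo), protocol="bolus")
        res = ve_series(s)
        assert np.ptp(res.ve) == pytest.approx(0.0, abs=1e-12)

    def test_ve_invariant_under_common_dr1_rescaling(self):
        """Scaling blood and myocardial ΔR1 by the same factor (dose /
        clearance independence) leaves Ve unchanged."""
        for scale in (0.5, 2.0):
            dr1_b = 0.0015
            blood = 1.0 / (1.0 / 1500.0 + scale * dr1_b)
            myo = 1.0 / (1.0 / 950.0 + scale * 0.45 * dr1_b)
            s = _series([15.0, 25.0], [blood] * 2, [myo] * 2, protocol="bolus")
            res = ve_series(s)
            assert res.mean_ve == pytest.approx(0.45 * 1.05 * 0.6 - 0.045, abs=1e-12)

    def test_bolus_points_before_12_min_excluded(self):
        scan = generate_scan(
            KineticsConfig(
                protocol="bolus",
                noise_frac=0.0,
                sample_times_min=(5.0, 8.0, 15.0, 20.0, 30.0),
            )
        )
        res = ve_series(scan)
        assert res.time_min.min() >= 12.0
        assert res.n_points == 3

    def test_infusion_restricted_to_steady_state(self):
        scan = generate_scan(KineticsConfig(protocol="infusion", noise_frac=0.0))
        res = ve_series(scan)
        assert res.steady_state is not None
        assert res.time_min.min() == pytest.approx(res.steady_state[0])

    def test_no_qualifying_timepoints(self):
        scan = generate_scan(
            KineticsConfig(protocol="bolus", noise_frac=0.0, sample_times_min=(3.0, 6.0))
        )
        with pytest.raises(InsufficientDataError):
            ve_series(scan)

    def test_cohort_parameter_recovery(self):
        """With 1% T1 noise, per-subject mean Ve lands within 0.5 Ve
        percentage points of truth for at least 9 of 10 subjects, in the
        majority of replicate cohorts (the per-subject success rate is
        ~94%, so a single 10-subject cohort occasionally shows 8/10)."""
        cohort_ok = []
        for k in range(5):
            subjects = generate_cohort(6, 4, seed=20110304 + k, noise_frac=0.01)
            hits = 0
            for s in subjects:
                truth = ve_from_lambda(s.true_lambda, s.hematocrit_bolus)
                est = ve_series(s.bolus).mean_ve
                hits += abs(est - truth) * 100.0 <= 0.5
            cohort_ok.append(hits >= 9)
        assert sum(cohort_ok) >= 3


class TestScanSeriesValidation:
    def test_percent_hematocrit_autoconverted(self):
        with pytest.warns(UserWarning, match="percentage"):
            s = _series([15.0], [400.0], [550.0], protocol="bolus", hct=42.0)
        assert s.hematocrit == pytest.approx(0.42)

    def test_pre_must_exceed_post(self):
        with pytest.raises(InvalidParameterError):
            _series([15.0], [1600.0], [550.0], protocol="bolus")

    def test_unpaired_points_dropped_with_warning(self):
        s = _series([15.0, 25.0], [400.0, 410.0], [550.0, 560.0], protocol="bolus")
        s.points.append(TissueT1Point(time_min=35.0, tissue="blood", t1_msec=420.0))
        with pytest.warns(UserWarning, match="unpaired"):
            paired = s.paired()
        assert len(paired) == 2


class TestCSVRoundTrip:
    def test_write_read_round_trip(self, tmp_path):
        scan = generate_scan(KineticsConfig(protocol="infusion", noise_frac=0.01, seed=4))
        path = tmp_path / "scan.csv"
        write_scan_csv(scan, path)
        back = read_scan_csv(path)
        assert back.subject_id == scan.subject_id
        assert back.protocol == scan.protocol
        assert back.hematocrit == pytest.approx(scan.hematocrit)
        np.testing.assert_allclose(
            back.paired().to_numpy(), scan.paired().to_numpy(), rtol=1e-12
        )

    def test_phase_column_optional(self, tmp_path):
        import pandas as pd

        scan = generate_scan(KineticsConfig(protocol="bolus", noise_frac=0.0))
        path = tmp_path / "scan.csv"
        write_scan_csv(scan, path)
        df = pd.read_csv(path).drop(columns="phase")
        path2 = tmp_path / "scan2.csv"
        df.to_csv(path2, index=False)
        back = read_scan_csv(path2)
        assert back.pre_blood_t1_msec == pytest.approx(scan.pre_blood_t1_msec)
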