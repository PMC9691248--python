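import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ilextract import datasets
from ilextract.elisa import (
    AccuracyReport,
    CalibrationCurve,
    ReplicateSet,
    accuracy_comparison,
    analyze_plate,
    fit_calibration,
    four_pl,
    invert_calibration,
    read_plate,
    replicate_stats,
    round_half_up,
)
from ilextract.errors import ConvergenceError, RangeError, ValidationError
from ilextract.synthetic import ScenarioConfig, make_plate

TRUTH = dict(a_top=1.2, a_bottom=0.05, ic50=25.0, slope=1.0)
LEVELS = (0.0, 5.0, 10.0, 25.0, 50.0, 100.0)


def exact_standards(**params):
    p = {**TRUTH, **params}
    return [(c, four_pl(c, p["a_top"], p["a_bottom"], p["ic50"], p["slope"]))
            for c in LEVELS]


class TestFitCalibration:
    def test_recovers_exact_standards(self):
        curve = fit_calibration(exact_standards())
        assert curve.a_top == pytest.approx(1.2, rel=1e-6)
        assert curve.a_bottom == pytest.approx(0.05, rel=1e-4)
        assert curve.ic50 == pytest.approx(25.0, rel=1e-6)
        assert curve.slope == pytest.approx(1.0, rel=1e-6)

    def test_constant_absorbances_rejected(self):
        with pytest.raises(ValidationError):
            fit_calibration([(c, 0.5) for c in LEVELS])

    def test_increasing_absorbances_rejected(self):
        with pytest.raises(ValidationError, match="competitive"):
            fit_calibration([(c, 0.1 + 0.005 * c) for c in LEVELS])

    def test_too_few_standards_rejected(self):
        with pytest.raises(ValidationError):
            fit_calibration(exact_standards()[:3])

    def test_median_ic50_recovery_under_noise(self):
        # 5% replicate CV on standards: median IC50 error under 10%
        cfg = ScenarioConfig(seed=0)
        errors = []
        for rep in range(60):
            plate = make_plate(cfg, noise_cv=0.05, seed=9000 + rep)
            curve = fit_calibration(plate.standards)
            errors.append(abs(curve.ic50 - cfg.ic50) / cfg.ic50)
        assert np.median(errors) < 0.10


class TestInvertCalibration:
    @pytest.fixture
    def curve(self):
        return CalibrationCurve(standards=tuple(exact_standards()), **TRUTH)

    def test_midpoint_maps_to_ic50(self, curve):
        assert invert_calibration(curve, curve.forward(25.0)) == pytest.approx(25.0)

    def test_near_top_maps_to_near_zero(self, curve):
        c = invert_calibration(curve, curve.a_top - 1e-9)
        assert c < 1e-6

    def test_out_of_range_names_bound(self, curve):
        with pytest.raises(RangeError, match="below-range"):
            invert_calibration(curve, curve.a_top + 0.1)
        with pytest.raises(RangeError, match="above-range"):
            invert_calibration(curve, curve.a_bottom)

    def test_round_trip_on_thousand_concentrations(self, curve, rng):
        conc = rng.uniform(1.0, 100.0, 1000)
        back = np.array(
            [invert_calibration(curve, curve.forward(c)) for c in conc]
        )
        assert np.max(np.abs(back - conc) / conc) <= 1e-9

    @given(
        c=st.floats(0.01, 500.0),
        slope=st.floats(0.5, 3.0),
        ic50=st.floats(5.0, 80.0),
    )
    def test_inverse_is_identity_on_open_range(self, c, slope, ic50):
        curve = CalibrationCurve(
            a_top=1.2, a_bottom=0.05, ic50=ic50, slope=slope
        )
        assert invert_calibration(curve, curve.forward(c)) == pytest.approx(
            c, rel=1e-9
        )


class TestReplicateStats:
    @pytest.mark.parametrize(
        "concs,mean,sd,cv,rel_err",
        [
            ((21.904, 19.950, 22.971), 21.608, 1.532, 7.090, 8.04),
            ((20.515, 20.145, 19.287), 19.982, 0.630, 3.153, -0.09),
        ],
    )
    def test_reference_triplicates(self, concs, mean, sd, cv, rel_err):
        rep = ReplicateSet("ref", 20.0, np.array(concs))
        report = replicate_stats(rep)
        assert round_half_up(report.mean, 3) == mean
        assert round_half_up(report.sd, 3) == sd
        assert round_half_up(report.cv_percent, 3) == cv
        assert round_half_up(report.relative_error_percent, 2) == rel_err

    def test_identical_replicates_have_zero_spread(self):
        report = replicate_stats(ReplicateSet("c", 20.0, [5.0, 5.0, 5.0]))
        assert report.sd == 0.0
        assert report.cv_percent == 0.0

    def test_single_replicate_rejected(self):
        with pytest.raises(ValidationError):
            ReplicateSet("c", 20.0, [5.0])

    @given(
        alpha=st.floats(0.1, 100.0),
        c=st.lists(st.floats(1.0, 50.0), min_size=3, max_size=6),
    )
    def test_cv_is_scale_invariant(self, alpha, c):
        base = replicate_stats(ReplicateSet("a", 20.0, np.array(c)))
        scaled = replicate_stats(ReplicateSet("a", 20.0, alpha * np.array(c)))
        assert scaled.cv_percent == pytest.approx(base.cv_percent, rel=1e-9)

    def test_sample_sd_not_population_sd(self):
        # the n-1 denominator is what reproduces the reference 1.532
        c = np.array([21.904, 19.950, 22.971])
        assert round_half_up(float(np.std(c, ddof=1)), 3) == 1.532
        assert round_half_up(float(np.std(c, ddof=0)), 3) != 1.532


class TestAccuracyComparison:
    def _report(self, rel_err, cv=5.0):
        mean = 20.0 * (1 + rel_err / 100.0)
        return AccuracyReport(
            condition="x", nominal=20.0, mean=mean, sd=cv * mean / 100.0,
            cv_percent=cv, relative_error_percent=rel_err, n=3,
        )

    @pytest.mark.parametrize(
        "before,after,decrease",
        [(32.18, -0.09, 32.27), (16.23, 10.66, 5.57), (8.0, 8.0, 0.0)],
    )
    def test_decrease_in_relative_error(self, before, after, decrease):
        out = accuracy_comparison(self._report(before), self._report(after))
        assert out["decrease_points"] == pytest.approx(decrease)

    def test_mismatched_nominal_rejected(self):
        a = self._report(5.0)
        b = AccuracyReport("y", 10.0, 10.5, 0.5, 4.76, 5.0, 3)
        with pytest.raises(ValidationError):
            accuracy_comparison(a, b)

    def test_precision_flag(self):
        out = accuracy_comparison(
            self._report(10.0, cv=7.0), self._report(1.0, cv=3.0)
        )
        assert out["precision_improved"] and out["accuracy_improved"]


class TestPlatePipeline:
    def test_zero_noise_unbiased_plate_recovers_nominal(self):
        cfg = ScenarioConfig(seed=0)
        plate = make_plate(cfg, nominal=20.0, hemoglobin=0.0, noise_cv=0.0)
        report = analyze_plate(plate, nominal=20.0)
        assert report.mean == pytest.approx(20.0, rel=1e-6)
        assert report.sd == pytest.approx(0.0, abs=1e-8)

    def test_plate_csv_round_trip(self, tmp_path):
        cfg = ScenarioConfig(seed=4)
        plate = make_plate(cfg, hemoglobin=0.2, seed=8)
        f = tmp_path / "plate.csv"
        plate.frame.to_csv(f, index=False)
        back = read_plate(f)
        assert back.standards == plate.standards
        np.testing.assert_array_equal(
            back.samples["absorbance"].to_numpy(),
            plate.samples["absorbance"].to_numpy(),
        )

    def test_extraction_reduces_hemoglobin_bias(self):
        # end-to-end contrast: biased before, near-nominal after
        cfg = ScenarioConfig(seed=42)
        before = analyze_plate(
            make_plate(cfg, hemoglobin=0.2, extracted=False, seed=1), 20.0
        )
        after = analyze_plate(
            make_plate(cfg, hemoglobin=0.2, extracted=True, seed=2), 20.0
        )
        out = accuracy_comparison(before, after)
        assert out["accuracy_improved"]
        assert abs(before.relative_error_percent) > 15.0
        assert abs(after.relative_error_percent) < 10.0


def test_reference_dataset_consistency():
    # every embedded triplicate reproduces its published summary row
    for key, summary in datasets.COTININE_REFERENCE_SUMMARY.items():
        report = replicate_stats(datasets.cotinine_replicate_set(*key))
        assert round_half_up(report.mean, 3) == summary["mean"]
        re_value = (
            report.relative_error_percent
            if summary["re_signed"] > 0
            else report.abs_relative_error_percent
        )
        assert round_half_up(re_value, summary["re_decimals"]) == summary["re_printed"]
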