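"""Population AIF: biexponential curve, plasma conversion, calibration,
bolus-arrival detection."""

import warnings
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adnexal_dce.aif import (
    AIFModel,
    ConcentrationCurve,
    DegenerateCalibrationError,
    blood_to_plasma,
    calibrate_to_measured,
    detect_bolus_arrival,
    population_blood_curve,
    weinmann_aif,
)
from adnexal_dce.semiquant import EnhancementCurve


class TestPopulationBloodCurve:
    def test_zero_before_onset(self, aif_model, times):
        curve = population_blood_curve(aif_model, times)
        pre = times < aif_model.onset_time
        assert np.all(curve.values[pre] == 0.0)
        assert np.all(curve.values[~pre] > 0.0)

    def test_equal_components_collapse_to_single_exponential(self):
        model = AIFModel(a1=1.0, a2=1.0, m1=0.5, m2=0.5, dose=1.0,
                         onset_time=0.0)
        t = np.arange(0.0, 120.0, 7.6)
        curve = population_blood_curve(model, t)
        np.testing.assert_allclose(curve.values, 2.0 * np.exp(-0.5 * t / 60.0))
        assert np.all(np.diff(curve.values) < 0)

    def test_discrete_maximum_at_first_post_onset_frame(self, aif_model, times):
        # The biexponential decays from the bolus, so on the acquisition
        # grid the largest sample is the first frame at/after onset.
        curve = population_blood_curve(aif_model, times)
        expected = int(np.argmax(times >= aif_model.onset_time))
        assert int(np.argmax(curve.values)) == expected

    def test_rejects_non_increasing_grid(self, aif_model):
        with pytest.raises(ValueError):
            population_blood_curve(aif_model, np.array([0.0, 7.6, 7.6]))

    @given(scale=st.floats(0.1, 10.0), dose=st.floats(0.01, 1.0))
    @settings(max_examples=25, deadline=None)
    def test_nonnegative_and_linear_in_scale_dose(self, scale, dose):
        model = AIFModel(a1=3.99, a2=4.78, m1=0.144, m2=0.0111,
                         dose=dose, scale=scale, onset_time=10.0)
        t = np.arange(50) * 7.6
        base = population_blood_curve(replace(model, scale=1.0, dose=1.0), t)
        curve = population_blood_curve(model, t)
        assert np.all(curve.values >= 0)
        np.testing.assert_allclose(curve.values, scale * dose * base.values,
                                   rtol=1e-12)


class TestBloodToPlasma:
    def test_zero_hematocrit_is_identity(self, aif_model, times):
        cb = population_blood_curve(aif_model, times)
        cp = blood_to_plasma(cb, 0.0)
        np.testing.assert_array_equal(cp.values, cb.values)
        assert cp.compartment == "plasma"

    def test_default_hematocrit_scaling(self):
        t = np.arange(5.0)
        cb = ConcentrationCurve(times=t, values=np.ones(5), compartment="blood")
        np.testing.assert_allclose(blood_to_plasma(cb, 0.45).values, 0.55)

    def test_composition_of_scalings(self, aif_model, times):
        cb = population_blood_curve(aif_model, times)
        once = blood_to_plasma(cb, 0.45)
        twice = blood_to_plasma(
            ConcentrationCurve(times=times, values=once.values,
                               compartment="blood"), 0.45)
        np.testing.assert_allclose(twice.values, (1 - 0.45) ** 2 * cb.values)

    @given(a=st.floats(0.01, 100.0))
    @settings(max_examples=25, deadline=None)
    def test_linearity(self, a, aif_model):
        t = np.arange(50) * 7.6
        cb = population_blood_curve(aif_model, t)
        scaled = ConcentrationCurve(times=t, values=a * cb.values,
                                    compartment="blood")
        np.testing.assert_allclose(blood_to_plasma(scaled, 0.45).values,
                                   a * blood_to_plasma(cb, 0.45).values,
                                   rtol=1e-12)

    @pytest.mark.parametrize("hct", [-0.1, 1.0, 1.5])
    def test_invalid_hematocrit(self, hct, aif_model, times):
        cb = population_blood_curve(aif_model, times)
        with pytest.raises(ValueError):
            blood_to_plasma(cb, hct)

    def test_requires_blood_compartment(self, times):
        tissue = ConcentrationCurve(times=times, values=np.zeros_like(times),
                                    compartment="tissue")
        with pytest.raises(ValueError):
            blood_to_plasma(tissue, 0.45)


class TestCalibration:
    def _grid_onset_model(self, aif_model, times):
        # Onset aligned to the frame grid so frame-level arrival detection
        # is exact and the fixed-point example holds to the digit.
        onset = float(times[times >= aif_model.onset_time][0])
        return replace(aif_model, onset_time=onset)

    def test_fixed_point(self, aif_model, times):
        model = self._grid_onset_model(aif_model, times)
        measured = [population_blood_curve(model, times)]
        cal = calibrate_to_measured(model, measured)
        assert cal.scale == pytest.approx(1.0, abs=1e-6)
        assert cal.onset_time == pytest.approx(model.onset_time, abs=1e-3)

    @pytest.mark.parametrize("factor", [2.0, 0.5, 17.3])
    def test_exact_scaling_recovered(self, factor, aif_model, times):
        model = self._grid_onset_model(aif_model, times)
        base = population_blood_curve(model, times)
        measured = [ConcentrationCurve(times=times, values=factor * base.values,
                                       compartment="blood")]
        cal = calibrate_to_measured(model, measured)
        assert cal.scale == pytest.approx(factor, rel=1e-6)

    def test_recovers_scale_from_noisy_patient_aifs(self, aif_model, times, rng):
        # Ten patient curves = population curve x known factor with
        # multiplicative noise; the LS calibration should recover the factor.
        factor = 12.5
        base = population_blood_curve(aif_model, times).values * factor
        measured = []
        for _ in range(10):
            noisy = base * (1 + rng.normal(0, 0.05, base.shape))
            noisy[base == 0] = 0.0
            measured.append(ConcentrationCurve(times=times, values=noisy,
                                               compartment="blood"))
        cal = calibrate_to_measured(aif_model, measured)
        assert cal.scale == pytest.approx(factor, rel=0.05)

    def test_subframe_onset_refinement(self, aif_model, times):
        # True onset (10 s) lies between frames 7.6 and 15.2; refinement
        # should locate it to well under a frame interval.
        measured = [population_blood_curve(aif_model, times)]
        cal = calibrate_to_measured(aif_model, measured)
        assert cal.onset_time == pytest.approx(aif_model.onset_time, abs=0.5)
        assert cal.scale == pytest.approx(1.0, rel=0.05)

    def test_rss_non_increasing_vs_unit_scale(self, aif_model, times, rng):
        base = population_blood_curve(aif_model, times).values * 3.0
        noisy = base + rng.normal(0, 0.01, base.shape)
        noisy[base == 0] = 0.0
        measured = [ConcentrationCurve(times=times, values=noisy,
                                       compartment="blood")]
        cal = calibrate_to_measured(aif_model, measured)
        fitted = population_blood_curve(cal, times).values
        unit = population_blood_curve(
            replace(aif_model, scale=1.0, onset_time=cal.onset_time),
            times).values
        assert np.sum((noisy - fitted) ** 2) <= np.sum((noisy - unit) ** 2)

    def test_empty_list_rejected(self, aif_model):
        with pytest.raises(ValueError):
            calibrate_to_measured(aif_model, [])

    def test_all_zero_curves_degenerate(self, aif_model, times):
        zero = ConcentrationCurve(times=times, values=np.zeros_like(times),
                                  compartment="blood")
        with pytest.raises(DegenerateCalibrationError):
            calibrate_to_measured(aif_model, [zero, zero])


class TestBolusArrival:
    def test_unambiguous_step(self):
        curve = EnhancementCurve(times=np.array([0.0, 1.0, 2.0, 3.0]),
                                 signal=np.array([0.0, 0.0, 10.0, 10.0]),
                                 injection_time=1.5, frame_interval=1.0)
        assert detect_bolus_arrival(curve, 2) == 2.0

    def test_flat_curve_falls_back_to_injection_time(self):
        curve = EnhancementCurve(times=np.arange(10.0),
                                 signal=np.full(10, 7.0),
                                 injection_time=3.5, frame_interval=1.0)
        with pytest.warns(UserWarning):
            assert detect_bolus_arrival(curve, 3) == 3.5

    def test_noisy_curve_detected_within_one_frame(self, protocol, aif_model,
                                                   cp, rng):
        # SNR ~20 relative to baseline; arrival should land within one
        # frame of the first truly enhancing sample.
        from adnexal_dce.pk_model import PKParams, forward_extended_tofts

        t = protocol.times()
        truth = PKParams(ktrans=0.05, kep=2.0, vp=0.15, delta=0.0)
        ct = forward_extended_tofts(truth, cp, t)
        si0 = 100.0
        signal = si0 * (1.0 + 18.0 * ct.values) + rng.normal(0, si0 / 20, t.shape)
        curve = EnhancementCurve(times=t, signal=signal,
                                 injection_time=protocol.injection_time_s,
                                 frame_interval=protocol.frame_interval_s)
        detected = detect_bolus_arrival(curve, protocol.n_baseline_frames)
        first_enhancing = float(t[t >= aif_model.onset_time][0])
        assert abs(detected - first_enhancing) <= protocol.frame_interval_s

    def test_invalid_baseline_count(self):
        curve = EnhancementCurve(times=np.arange(5.0),
                                 signal=np.ones(5), injection_time=1.0,
                                 frame_interval=1.0)
        with pytest.raises(ValueError):
            detect_bolus_arrival(curve, 0)
        with pytest.raises(ValueError):
            detect_bolus_arrival(curve, 5)
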