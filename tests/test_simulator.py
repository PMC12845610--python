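"""Ground-truth simulator: determinism, analytic limits, round trips."""

import numpy as np
import pytest

from coilpilot import head_geometry as hg
from coilpilot import mep_analysis as ma
from coilpilot.contact_sensing import adjust, normalize
from coilpilot.exceptions import NoContactError
from coilpilot.simulator import (HeadModel, MepModel, SuspensionModel,
                                 rmt_pulse_callback, sample_landmarks,
                                 simulate_mep_amplitude, simulate_sensor_pair,
                                 simulate_study, simulate_trial,
                                 synthesize_emg_epoch)
from coilpilot.tilt_experiment import (balance_at_peak, peak_condition,
                                       summarize_study)


class TestLandmarkSampling:
    def test_neutral_pose_is_sagittally_symmetric(self):
        lm, truth = sample_landmarks(HeadModel(), 0.0, seed=0)
        assert lm.left_preauricular[0] == pytest.approx(
            -lm.right_preauricular[0])
        assert lm.nasion[0] == pytest.approx(0.0)
        assert truth["theta_deg"] == pytest.approx(0.0)

    def test_programmed_roll_appears_as_ear_axis_angle(self):
        lm, _ = sample_landmarks(HeadModel(roll=5.0), 0.0, seed=0)
        assert hg.ear_axis_angle(lm) == pytest.approx(5.0, abs=1e-9)

    def test_fixed_seed_reproducibility(self):
        a, _ = sample_landmarks(HeadModel(), 1.0, seed=42)
        b, _ = sample_landmarks(HeadModel(), 1.0, seed=42)
        assert np.array_equal(a.nasion, b.nasion)
        assert np.array_equal(a.left_preauricular, b.left_preauricular)

    def test_true_c3_lies_on_the_ellipsoid_surface(self):
        head = HeadModel(roll=3.0, pitch=2.0, center=(5.0, -4.0, 10.0))
        p = head.true_c3 - np.asarray(head.center)
        # undo the pose: the point must satisfy the ellipsoid equation
        a, b, c = head.semi_axes
        from coilpilot.simulator import _rotation
        local = _rotation(head.yaw, head.pitch, head.roll).T @ p
        assert (local[0] / a) ** 2 + (local[1] / b) ** 2 \
            + (local[2] / c) ** 2 == pytest.approx(1.0, abs=1e-12)


class TestSensorPair:
    def test_tangential_contact_is_exactly_balanced(self):
        model = SuspensionModel(noise_sd=0.0)
        raw = simulate_sensor_pair(0.0, 2.0, model, seed=0)
        ratio = normalize(adjust(raw, model.calibration))
        assert ratio.norm0 == pytest.approx(0.5, abs=1e-12)

    def test_positive_tilt_loads_the_upper_sensor(self):
        model = SuspensionModel(noise_sd=0.0)
        raw = simulate_sensor_pair(3.0, 2.0, model, seed=0)
        adj = adjust(raw, model.calibration)
        assert adj.adj0 > adj.adj1
        ratio = normalize(adj)
        assert ratio.norm0 - 0.5 > 0  # positive deviation convention

    def test_zero_depth_gives_no_contact_downstream(self):
        model = SuspensionModel(noise_sd=0.0)
        raw = simulate_sensor_pair(0.0, 0.0, model, seed=0)
        adj = adjust(raw, model.calibration)
        assert adj.total_load == 0.0
        with pytest.raises(NoContactError):
            normalize(adj)

    def test_compression_saturates_at_max_travel(self):
        model = SuspensionModel(noise_sd=0.0, max_compression=3.0)
        deep = simulate_sensor_pair(0.0, 10.0, model, seed=0)
        deeper = simulate_sensor_pair(0.0, 20.0, model, seed=0)
        assert deep.ch0 == deeper.ch0


class TestMepAmplitudeModel:
    MODEL = MepModel()

    def test_ideal_conditions_give_near_maximal_amplitude(self):
        amp = simulate_mep_amplitude(0.0, 2500.0, 1.2 * self.MODEL.rmt_true,
                                     self.MODEL, seed=0)
        assert amp == pytest.approx(
            self.MODEL.max_amplitude
            * self.MODEL.response_factor(1.2 * self.MODEL.rmt_true))
        assert amp > 0.99 * self.MODEL.max_amplitude

    def test_overload_reduces_amplitude(self):
        good = simulate_mep_amplitude(0.0, 2500.0, 66.0, self.MODEL, seed=0)
        bad = simulate_mep_amplitude(0.0, 7000.0, 66.0, self.MODEL, seed=0)
        assert bad < good
        assert bad == 0.0

    def test_subthreshold_intensity_yields_invalid_response(self):
        amp = simulate_mep_amplitude(0.0, 2500.0, 40.0, self.MODEL, seed=0)
        assert amp < 50.0

    def test_trapezoid_efficacy_shape(self):
        m = self.MODEL
        assert m.load_efficacy(700.0) == 0.0
        assert m.load_efficacy(1150.0) == pytest.approx(0.5)
        assert m.load_efficacy(2000.0) == 1.0
        assert m.load_efficacy(5000.0) == pytest.approx(0.5)
        assert m.load_efficacy(6500.0) == 0.0


class TestEmgSynthesis:
    def test_zero_amplitude_no_noise_is_flat_offset(self):
        ep = synthesize_emg_epoch(0.0, MepModel(emg_noise_sd=0.0), seed=0)
        assert np.allclose(ep.samples, 2.5)
        assert ep.samples.size == 800

    def test_round_trip_through_measurement_pipeline(self):
        ep = synthesize_emg_epoch(500.0, MepModel(emg_noise_sd=0.0), seed=0)
        m = ma.analyze_epoch(ep)
        assert m.amplitude == pytest.approx(500.0, abs=25.0)
        assert m.valid

    def test_fixed_seed_reproducibility(self):
        a = synthesize_emg_epoch(300.0, MepModel(emg_noise_sd=8.0), seed=9)
        b = synthesize_emg_epoch(300.0, MepModel(emg_noise_sd=8.0), seed=9)
        assert np.array_equal(a.samples, b.samples)


class TestTrialSimulation:
    def test_noiseless_trial_peaks_at_tangent_with_zero_deviation(self):
        trial, truth = simulate_trial(tangent_pitch=25.0, seed=0)
        peak = peak_condition(trial)
        assert peak.robot_pitch == 25.0
        dev, flag = balance_at_peak(trial)
        assert dev == pytest.approx(0.0, abs=1e-12)
        assert flag

    def test_fixed_seed_gives_identical_log(self, tmp_path):
        from coilpilot.io import write_trial_log
        susp = SuspensionModel(noise_sd=25.0)
        mep = MepModel(amplitude_noise_sd=120.0)
        paths = []
        for name in ("a.csv", "b.csv"):
            trial, _ = simulate_trial(suspension=susp, mep=mep,
                                      tangent_pitch=25.0, seed=7)
            p = tmp_path / name
            write_trial_log(trial, p)
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]

    def test_sensor_averaging_reduces_ratio_noise(self):
        susp = SuspensionModel(noise_sd=60.0)
        devs = {}
        for n in (1, 25):
            rng = np.random.default_rng(123)
            errs = []
            for _ in range(30):
                trial, _ = simulate_trial(suspension=susp,
                                          tangent_pitch=25.0, seed=rng,
                                          n_sensor_samples=n)
                at_tangent = [c for c in trial.conditions
                              if c.robot_pitch == 25.0][0]
                errs.append(abs(at_tangent.norm0 - 0.5))
            devs[n] = np.mean(errs)
        assert devs[25] < devs[1]

    def test_moderate_noise_study_mostly_balanced_at_peak(self):
        trials = simulate_study(15, seed=3)
        s = summarize_study(trials)
        assert s.n_trials == 15
        assert s.proportion_balanced >= 0.6
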