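"""Marker-level generator, event detection and the extraction round trip."""

import numpy as np
import pytest

from tripgait.body import BodyModel
from tripgait.events import EventDetectionError, GaitEvents, detect_gait_events
from tripgait.features import FEATURE_NAMES, extract_features
from tripgait.markers import MarkerTrajectorySet
from tripgait.synthetic import GaitTrialSpec, generate_marker_trial


class TestGaitTrialSpec:
    def test_rejects_nonpositive_quantities(self):
        with pytest.raises(ValueError):
            GaitTrialSpec(gait_speed=-1.0)
        with pytest.raises(ValueError):
            GaitTrialSpec(n_cycles=0)
        with pytest.raises(ValueError):
            GaitTrialSpec(noise_sd=-0.001)

    def test_step_length_defaults_to_kinematic_identity(self):
        spec = GaitTrialSpec(gait_speed=1.2, cadence=120.0)
        assert spec.step_length == pytest.approx(0.6)

    def test_inconsistent_step_length_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            GaitTrialSpec(gait_speed=1.2, cadence=120.0, step_length=0.8)

    def test_yaml_round_trip(self, tmp_path):
        spec = GaitTrialSpec(gait_speed=1.1, cadence=105.0, trunk_lean=4.0)
        path = tmp_path / "trial.yaml"
        spec.to_yaml(path)
        assert GaitTrialSpec.from_yaml(path) == spec


class TestEventDetection:
    def test_events_match_generator_ground_truth(self, clean_trial):
        _, traj, events = clean_trial
        truth = traj.meta["ground_truth"]["events"]
        for name in ("pre_TD", "LO", "post_TD", "next_TD"):
            assert abs(getattr(events, name) - truth[name]) <= 3, name

    def test_step_time_from_cadence(self, clean_trial, body_model):
        _, traj, events = clean_trial
        fv = extract_features(traj, events, body_model)
        assert fv["Step time"] == pytest.approx(0.5, abs=0.01)

    def test_constant_record_rejected(self):
        names = [f"{s}_{m}" for s in ("L", "R")
                 for m in ("heel", "toe", "ankle", "knee", "hip", "shoulder")]
        pos = np.tile(np.linspace(0, 1, len(names) * 3).reshape(1, len(names), 3),
                      (100, 1, 1))
        traj = MarkerTrajectorySet(marker_names=names, positions=pos)
        with pytest.raises(EventDetectionError, match="limb"):
            detect_gait_events(traj)

    def test_event_ordering_enforced(self):
        with pytest.raises(ValueError, match="ordered"):
            GaitEvents(pre_TD=10, LO=5, post_TD=20, next_TD=30)


class TestRoundTrip:
    """Noise-free trials must return their configured ground truth."""

    def test_gait_speed_recovered(self, clean_trial, body_model):
        spec, traj, events = clean_trial
        fv = extract_features(traj, events, body_model)
        assert fv["Gait speed in gait cycle"] == pytest.approx(1.2, abs=0.01)

    def test_toe_clearance_recovered(self, clean_trial, body_model):
        spec, traj, events = clean_trial
        fv = extract_features(traj, events, body_model)
        assert fv["Toe clearance"] == pytest.approx(0.16, abs=0.005)

    def test_trunk_angle_recovered(self, clean_trial, body_model):
        spec, traj, events = clean_trial
        fv = extract_features(traj, events, body_model)
        assert fv["Trunk angle at LO"] == pytest.approx(90 - spec.trunk_lean, abs=0.5)
        assert fv["Max trunk flexion in gait cycle"] == pytest.approx(87.0, abs=0.5)

    def test_vertical_trunk_scores_90(self, body_model):
        spec = GaitTrialSpec(trunk_lean=0.0, noise_sd=0.0)
        traj = generate_marker_trial(spec, seed=2)
        sh = 0.5 * (traj.marker("L_shoulder") + traj.marker("R_shoulder"))
        hp = 0.5 * (traj.marker("L_hip") + traj.marker("R_hip"))
        dx = sh[:, 0] - hp[:, 0]
        assert np.allclose(dx, 0.0, atol=1e-12)

    def test_step_length_recovered(self, clean_trial, body_model):
        spec, traj, events = clean_trial
        fv = extract_features(traj, events, body_model)
        assert fv["Step length"] == pytest.approx(spec.step_length, abs=0.01)

    @pytest.mark.parametrize("speed", [0.8, 1.4])
    def test_speed_sweep(self, speed, body_model):
        spec = GaitTrialSpec(gait_speed=speed, cadence=110.0, noise_sd=0.0)
        traj = generate_marker_trial(spec, seed=4)
        events = detect_gait_events(traj)
        fv = extract_features(traj, events, body_model)
        assert fv["Gait speed in gait cycle"] == pytest.approx(speed, abs=0.01)

    def test_knee_flexion_on_realistic_scale(self, clean_trial, body_model):
        """Swing-phase peak knee flexion lands on the scale seen in adult
        gait (Table-style values around 100-135 deg on this convention)."""
        _, traj, events = clean_trial
        fv = extract_features(traj, events, body_model)
        assert 90.0 < fv["Max knee flexion in swing phase"] < 140.0

    def test_deterministic_given_seed(self):
        spec = GaitTrialSpec(noise_sd=0.002)
        a = generate_marker_trial(spec, seed=11)
        b = generate_marker_trial(spec, seed=11)
        np.testing.assert_array_equal(a.positions, b.positions)

    def test_noise_does_not_break_detection(self, body_model):
        spec = GaitTrialSpec(noise_sd=0.003)
        traj = generate_marker_trial(spec, seed=12)
        events = detect_gait_events(traj)
        fv = extract_features(traj, events, body_model)
        assert fv["Gait speed in gait cycle"] == pytest.approx(1.05, abs=0.05)


class TestInvariances:
    def test_frame_rate_invariance(self, body_model):
        """Resampling 120 -> 240 Hz changes time-based features < 1%."""
        vals = {}
        for rate in (120.0, 240.0):
            spec = GaitTrialSpec(gait_speed=1.2, cadence=120.0,
                                 sampling_rate=rate, noise_sd=0.0)
            traj = generate_marker_trial(spec, seed=5)
            fv = extract_features(traj, detect_gait_events(traj), body_model)
            vals[rate] = fv
        for name in ("Step time", "Gait cycle time", "Swing time",
                     "Gait speed in gait cycle", "Toe clearance"):
            a, b = vals[120.0][name], vals[240.0][name]
            assert abs(a - b) / abs(a) < 0.01, name

    def test_translation_invariance(self, clean_trial, body_model):
        _, traj, events = clean_trial
        fv = extract_features(traj, events, body_model)
        shifted = MarkerTrajectorySet(
            marker_names=list(traj.marker_names),
            positions=traj.positions + np.array([3.0, 0.25, -1.0]),
            sampling_rate=traj.sampling_rate,
        )
        fv2 = extract_features(shifted, events, body_model)
        for name in FEATURE_NAMES:
            assert fv2[name] == pytest.approx(fv[name], abs=1e-8), name

    def test_swing_shorter_than_step(self, clean_trial, body_model):
        _, traj, events = clean_trial
        fv = extract_features(traj, events, body_model)
        assert fv["Swing time"] < fv["Step time"]


class TestMarkerCSV:
    def test_long_format_round_trip(self, tmp_path, clean_trial):
        _, traj, _ = clean_trial
        path = tmp_path / "markers.csv"
        traj.to_csv(path)
        back = MarkerTrajectorySet.from_csv(path)
        assert back.sampling_rate == pytest.approx(traj.sampling_rate)
        np.testing.assert_allclose(
            back.marker("L_toe"), traj.marker("L_toe"), atol=1e-6)

    def test_missing_required_marker_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            MarkerTrajectorySet(marker_names=["L_heel"],
                                positions=np.zeros((10, 1, 3)))

    def test_non_finite_rejected(self, clean_trial):
        _, traj, _ = clean_trial
        pos = traj.positions.copy()
        pos[0, 0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            MarkerTrajectorySet(marker_names=list(traj.marker_names),
                                positions=pos)
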