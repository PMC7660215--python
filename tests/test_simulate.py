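"""Synthetic study generation: design bookkeeping, determinism, error injection."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from tugkin.pipeline import study_error_table
from tugkin.roster import DEFAULT_ROSTER
from tugkin.simulate import (
    GRAVITY,
    ConfigurationError,
    MountingModel,
    StudyDesign,
    default_design,
    generate_study,
    synthesize_sensor_stream,
    zero_mounts,
)
from tugkin.trajectory import build_trajectory


class TestStudyDesign:
    def test_default_matches_study_bookkeeping(self):
        d = default_design()
        assert d.n_subjects == 7
        assert d.trials_per_subject == (3, 3, 3, 3, 3, 5, 5)
        assert d.n_trials == 25

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_subjects": 0, "trials_per_subject": ()},
            {"n_subjects": 2, "trials_per_subject": (3,)},
            {"n_subjects": 1, "trials_per_subject": (0,)},
            {"n_subjects": 1, "trials_per_subject": (1,), "imu_rate_hz": -60},
            {"n_subjects": 1, "trials_per_subject": (1,), "ref_noise_sd_deg": -1},
        ],
    )
    def test_invalid_designs_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            StudyDesign(**kwargs)

    def test_unknown_dropout_sensor_rejected(self):
        d = StudyDesign(n_subjects=1, trials_per_subject=(1,), dropout_sensors={"S01": {"Nose"}})
        with pytest.raises(ConfigurationError):
            d.dropout_for("S01", DEFAULT_ROSTER)


class TestGenerateStudy:
    def test_trial_metadata_and_dropout(self):
        design = StudyDesign(
            n_subjects=2,
            trials_per_subject=(2, 1),
            seed=5,
            dropout_sensors={"S01": {"Heel", "LPT"}},
        )
        trials = generate_study(design)
        assert [(t.subject, t.trial) for t in trials] == [
            ("S01", 1), ("S01", 2), ("S02", 1)
        ]
        assert "Heel" not in trials[0].sensor_streams
        assert "LPT" not in trials[1].sensor_streams
        assert "Heel" in trials[2].sensor_streams
        assert len(trials[2].sensor_streams) == 11

    def test_seed_determinism(self):
        design = StudyDesign(n_subjects=1, trials_per_subject=(2,), seed=42)
        a = generate_study(design)
        b = generate_study(design)
        for ta, tb in zip(a, b):
            assert ta.events == tb.events
            np.testing.assert_array_equal(
                ta.sensor_streams["MLT"].q, tb.sensor_streams["MLT"].q
            )
            np.testing.assert_array_equal(
                ta.ref_angles.to_numpy(), tb.ref_angles.to_numpy()
            )

    def test_different_seeds_differ(self):
        a = generate_study(StudyDesign(n_subjects=1, trials_per_subject=(1,), seed=1))
        b = generate_study(StudyDesign(n_subjects=1, trials_per_subject=(1,), seed=2))
        assert not np.array_equal(
            a[0].ref_angles.to_numpy(), b[0].ref_angles.to_numpy()
        )

    def test_quaternions_unit_norm_and_standing_start(self, clean_trial):
        for stream in clean_trial.sensor_streams.values():
            norms = np.linalg.norm(stream.q, axis=1)
            np.testing.assert_allclose(norms, 1.0, atol=1e-9)
        # all sensors report the same orientation at the upright start,
        # segments parallel (here: zero static offsets)
        q0 = clean_trial.sensor_streams["L4-L5"].q[0]
        for stream in clean_trial.sensor_streams.values():
            assert min(
                np.linalg.norm(stream.q[0] - q0), np.linalg.norm(stream.q[0] + q0)
            ) < 1e-9


class TestSynthesizeSensorStream:
    def test_static_pose_constant_stream_and_gravity_norm(self, rng):
        traj = build_trajectory()
        placement = DEFAULT_ROSTER.get("Shin")
        mount = MountingModel("Shin")
        stream, stand, seated = synthesize_sensor_stream(traj, placement, mount, 60.0, rng)
        # during the standing hold the orientation is constant
        hold = stream.timestamps < traj.stand_hold_s
        assert hold.sum() >= 2
        assert np.max(np.abs(stream.q[hold] - stream.q[0][None, :])) < 1e-12
        np.testing.assert_allclose(np.linalg.norm(stand, axis=1), GRAVITY, atol=1e-9)
        np.testing.assert_allclose(np.linalg.norm(seated, axis=1), GRAVITY, atol=1e-9)

    def test_standing_accel_is_gravity_in_sensor_frame(self, rng):
        traj = build_trajectory()
        placement = DEFAULT_ROSTER.get("LAT")
        mount = MountingModel("LAT", static_axis="ap", static_deg=30.0)
        stream, stand, _ = synthesize_sensor_stream(traj, placement, mount, 60.0, rng)
        # rotating the sensed vector by the frame-one orientation recovers
        # gravity in the world frame
        world = Rotation.from_quat(stream.q[0], scalar_first=True).apply(stand[0])
        np.testing.assert_allclose(world, [0, 0, -GRAVITY], atol=1e-9)

    def test_invalid_rate_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            synthesize_sensor_stream(
                build_trajectory(), DEFAULT_ROSTER.get("Shin"), MountingModel("Shin"), 0.0, rng
            )


class TestErrorInjection:
    def test_movement_offset_biases_only_affected_pairs(self):
        mounts = zero_mounts()
        mounts["DFoot"] = MountingModel("DFoot", offset_axis="ml", offset_deg=10.0)
        design = StudyDesign(
            n_subjects=1, trials_per_subject=(1,), seed=2,
            duration_jitter=0.0, ref_noise_sd_deg=0.0,
        )
        records = study_error_table(generate_study(design, mounts=mounts))
        affected = records[records.distal == "DFoot"]
        others = records[records.distal != "DFoot"]
        np.testing.assert_allclose(affected.bias_deg, 10.0, atol=1e-6)
        np.testing.assert_allclose(affected.rmse_deg, 10.0, atol=1e-6)
        assert others.rmse_deg.max() < 1e-6

    def test_offset_on_proximal_sensor_biases_negatively(self):
        mounts = zero_mounts()
        mounts["MLS"] = MountingModel("MLS", offset_axis="ml", offset_deg=10.0)
        design = StudyDesign(
            n_subjects=1, trials_per_subject=(1,), seed=2,
            duration_jitter=0.0, ref_noise_sd_deg=0.0,
        )
        records = study_error_table(generate_study(design, mounts=mounts))
        as_distal = records[records.distal == "MLS"]  # knee pairs
        as_prox = records[records.proximal == "MLS"]  # ankle pairs
        np.testing.assert_allclose(as_distal.bias_deg, 10.0, atol=1e-6)
        np.testing.assert_allclose(as_prox.bias_deg, -10.0, atol=1e-6)

    def test_constant_static_offset_cancels_exactly(self):
        """A fixed sensor-vs-segment mounting rotation is invisible: the
        two-pose calibration plus frame-one alignment remove it."""
        mounts = zero_mounts()
        mounts["LLT"] = MountingModel("LLT", static_axis="ml", static_deg=25.0)
        mounts["Heel"] = MountingModel("Heel", static_axis="si", static_deg=40.0)
        design = StudyDesign(
            n_subjects=1, trials_per_subject=(1,), seed=3,
            duration_jitter=0.0, ref_noise_sd_deg=0.0,
        )
        records = study_error_table(generate_study(design, mounts=mounts))
        assert records.rmse_deg.max() < 1e-6

    def test_sensors_with_different_static_offsets_track_identically(self):
        """Same segment motion, different mounts: identical orientation
        output after calibration and frame-one alignment."""
        from tugkin.pipeline import calibrate_trial, globalize_trial

        mounts = zero_mounts()
        mounts["LAT"] = MountingModel("LAT", static_axis="ml", static_deg=15.0)
        design = StudyDesign(
            n_subjects=1, trials_per_subject=(1,), seed=4,
            duration_jitter=0.0, ref_noise_sd_deg=0.0,
        )
        trial = generate_study(design, mounts=mounts)[0]
        series = globalize_trial(trial, calibrate_trial(trial))
        # LAT (offset 15 deg) and MLT (no offset) ride the same thigh
        np.testing.assert_allclose(series["LAT"].si, series["MLT"].si, atol=1e-9)
        np.testing.assert_allclose(series["LAT"].ap, series["MLT"].ap, atol=1e-9)
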