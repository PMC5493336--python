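import numpy as np
import pytest

from stepgaze import synthetic_data as sd
from stepgaze.gait_pipeline import (
    FilterSpec,
    GaitExtractionError,
    HEAD_EVENTS,
    assign_lead_trail,
    crossing_instant,
    detect_foot_contacts,
    extract_gait_parameters,
    foot_positions,
    head_flexion,
    horizontal_toe_velocity,
    lowpass,
    ml_bve,
    stride_lengths,
    toe_clearance,
)
from stepgaze.trial_io import StepGeometry, TrialBundle

from conftest import make_traj

NOFILT = FilterSpec(cutoff=None)


def line_traj(name, x0, x1, n, rate=100.0, z=0.0):
    x = np.linspace(x0, x1, n)
    return make_traj(name, np.column_stack([x, np.zeros(n), np.full(n, z)]), rate)


class TestLowpass:
    def test_constant_unchanged(self):
        traj = make_traj("a", np.ones((200, 3)))
        out = lowpass(traj, FilterSpec(cutoff=6.0))
        np.testing.assert_allclose(out.xyz, traj.xyz, atol=1e-9)

    def test_low_frequency_preserved(self):
        t = np.arange(1000) / 100.0
        sig = np.sin(2 * np.pi * 1.0 * t)
        traj = make_traj("a", np.column_stack([sig, sig, sig]))
        out = lowpass(traj, FilterSpec(cutoff=6.0))
        mid = slice(200, 800)
        ratio = np.abs(out.xyz[mid, 0]).max() / np.abs(traj.xyz[mid, 0]).max()
        assert ratio == pytest.approx(1.0, abs=0.01)

    def test_high_frequency_attenuated(self):
        t = np.arange(1000) / 100.0
        sig = np.sin(2 * np.pi * 30.0 * t)
        traj = make_traj("a", np.column_stack([sig, sig, sig]))
        out = lowpass(traj, FilterSpec(cutoff=6.0))
        mid = slice(200, 800)
        ratio = np.abs(out.xyz[mid, 0]).max() / np.abs(traj.xyz[mid, 0]).max()
        assert ratio < 0.10

    def test_cutoff_above_nyquist_rejected(self):
        traj = make_traj("a", np.zeros((100, 3)))
        with pytest.raises(ValueError):
            lowpass(traj, FilterSpec(cutoff=50.0))

    def test_none_cutoff_is_identity(self):
        traj = make_traj("a", np.random.default_rng(0).normal(size=(50, 3)))
        assert lowpass(traj, NOFILT) is traj


class TestCrossingInstant:
    def test_linear_case(self):
        toe = line_traj("toe", 0.0, 2.0, 201)  # 2 m over 2 s
        assert crossing_instant(toe, 1.0) == pytest.approx(1.0, abs=1e-9)

    def test_crossing_exactly_on_frame(self):
        toe = line_traj("toe", 0.0, 2.0, 201)
        edge = toe.x[150]
        assert crossing_instant(toe, edge) == pytest.approx(1.50, abs=1e-9)

    def test_no_crossing_raises(self):
        toe = line_traj("toe", 0.0, 0.5, 100)
        with pytest.raises(GaitExtractionError):
            crossing_instant(toe, 1.0)

    def test_synthetic_within_5ms(self, write_trial):
        bundle, gt = write_trial
        prefix = "l" if gt.lead_foot == "left" else "r"
        toe = bundle.markers[f"{prefix}_toe"]
        t = crossing_instant(toe, gt.edge_x)
        assert t == pytest.approx(gt.event_times["lead_crossing"], abs=0.005)


class TestToeClearance:
    def test_write_condition_group_mean(self):
        # toe at 0.217 m over a 0.075 m step -> 142 mm
        toe = make_traj("toe", [[4.0, 0.0, 0.217]] * 10)
        step = StepGeometry(edge_x=4.0)
        assert toe_clearance(toe, 0.05, step) == pytest.approx(142.0)

    def test_zero_clearance_at_step_height(self):
        toe = make_traj("toe", [[4.0, 0.0, 0.075]] * 10)
        assert toe_clearance(toe, 0.05, StepGeometry(edge_x=4.0)) == pytest.approx(0.0)

    def test_synthetic_within_2mm(self, no_phone_trial):
        bundle, gt = no_phone_trial
        prefix = "l" if gt.lead_foot == "left" else "r"
        toe = bundle.markers[f"{prefix}_toe"]
        t = crossing_instant(toe, gt.edge_x)
        clearance = toe_clearance(toe, t, bundle.step)
        assert clearance == pytest.approx(gt.gait["lead_clearance_mm"], abs=2.0)


class TestHorizontalToeVelocity:
    def test_constant_advance(self):
        toe = line_traj("toe", 0.0, 3.84, 101)  # 3.84 m/s over 1 s
        v = horizontal_toe_velocity(toe, 0.5, NOFILT)
        assert v == pytest.approx(3.84, abs=1e-9)

    def test_stationary_toe(self):
        toe = make_traj("toe", [[1.0, 0.0, 0.0]] * 100)
        assert horizontal_toe_velocity(toe, 0.5, NOFILT) == pytest.approx(0.0)

    def test_boundary_crossing_rejected(self):
        toe = line_traj("toe", 0.0, 1.0, 100)
        with pytest.raises(GaitExtractionError):
            horizontal_toe_velocity(toe, 0.005, NOFILT)


class TestFootContacts:
    def test_stationary_foot_single_stance(self, step):
        toe = make_traj("toe", [[1.0, 0.1, 0.0]] * 300)
        heel = make_traj("heel", [[0.82, 0.1, 0.0]] * 300)
        contacts = detect_foot_contacts(toe, heel, step, NOFILT, foot="left")
        assert len(contacts) == 1
        assert contacts[0].start_time == 0.0
        assert contacts[0].end_time == pytest.approx(3.0)

    def test_no_stance_raises(self, step):
        n = 500
        t = np.arange(n) / 100.0
        x = t * 2.0
        z = 0.2 + 0.05 * np.sin(t)  # always airborne
        toe = make_traj("toe", np.column_stack([x, np.zeros(n), z]))
        heel = make_traj("heel", np.column_stack([x - 0.18, np.zeros(n), z]))
        with pytest.raises(GaitExtractionError):
            detect_foot_contacts(toe, heel, step, NOFILT, foot="left")

    def test_stance_count_matches_generator(self):
        for seed in range(20):
            bundle, gt = sd.simulate_trial(
                sd.condition_presets("no_phone"), seed=seed, with_gaze=False
            )
            for side, prefix in (("left", "l"), ("right", "r")):
                contacts = detect_foot_contacts(
                    bundle.markers[f"{prefix}_toe"],
                    bundle.markers[f"{prefix}_calcaneus"],
                    bundle.step,
                    NOFILT,
                    foot=side,
                )
                assert len(contacts) == gt.n_stances[side]

    def test_contact_times_within_one_frame(self, write_trial):
        bundle, gt = write_trial
        prefix = {"left": "l", "right": "r"}
        lead_p = prefix[gt.lead_foot]
        contacts = detect_foot_contacts(
            bundle.markers[f"{lead_p}_toe"],
            bundle.markers[f"{lead_p}_calcaneus"],
            bundle.step,
            NOFILT,
            foot=gt.lead_foot,
        )
        landing = [c for c in contacts if c.toe_x > gt.edge_x][0]
        assert landing.time == pytest.approx(
            gt.event_times["lead_contact_after"], abs=0.010
        )


class TestLeadTrailAssignment:
    def _events(self, bundle):
        contacts = {}
        for side, prefix in (("left", "l"), ("right", "r")):
            contacts[side] = detect_foot_contacts(
                bundle.markers[f"{prefix}_toe"],
                bundle.markers[f"{prefix}_calcaneus"],
                bundle.step,
                NOFILT,
                foot=side,
            )
        return assign_lead_trail(contacts["left"], contacts["right"], bundle.step)

    def test_matches_generator_over_seeds(self):
        leads = set()
        for seed in range(40):
            bundle, gt = sd.simulate_trial(
                sd.condition_presets("talk"), seed=seed, with_gaze=False
            )
            events = self._events(bundle)
            assert events.lead_foot == gt.lead_foot
            leads.add(gt.lead_foot)
        assert leads == {"left", "right"}  # both assignments occur

    def test_event_ordering_invariant(self, write_trial):
        bundle, _ = write_trial
        params = extract_gait_parameters(bundle, NOFILT)
        assert params.flags == []

    def test_step_never_mounted_flagged(self, step):
        # both feet walk but stop short of the edge
        n = 600
        t = np.arange(n) / 100.0
        markers = {}
        for prefix, y in (("l", 0.1), ("r", -0.1)):
            x = np.minimum(t * 1.0, 3.0)
            xyz = np.column_stack([x, np.full(n, y), np.zeros(n)])
            markers[f"{prefix}_toe"] = make_traj(f"{prefix}_toe", xyz)
            xyz_h = xyz.copy()
            xyz_h[:, 0] -= 0.18
            markers[f"{prefix}_calcaneus"] = make_traj(f"{prefix}_calcaneus", xyz_h)
        bundle = TrialBundle(
            participant_id="P01",
            condition="no_phone",
            repetition=1,
            markers=markers,
            step=step,
        )
        params = extract_gait_parameters(bundle, NOFILT)
        assert any("never negotiated" in f for f in params.flags)


class TestFootPositionsAndStrides:
    def test_paper_lead_pre_example(self, write_trial):
        bundle, gt = write_trial
        params = extract_gait_parameters(bundle, NOFILT)
        # 0.22 m short of the edge reads as pre distance 0.22 m by convention
        assert params.lead_foot_pre == pytest.approx(gt.gait["lead_foot_pre"], abs=5e-3)

    def test_lead_stride_from_plants(self, no_phone_trial):
        bundle, gt = no_phone_trial
        params = extract_gait_parameters(bundle, NOFILT)
        assert params.lead_stride == pytest.approx(gt.gait["lead_stride"], abs=5e-3)
        assert params.trail_stride == pytest.approx(gt.gait["trail_stride"], abs=5e-3)

    def test_stride_is_landing_minus_floor_plant(self):
        # lead floor plant at 2.9 m, landing at 4.19 m -> 1.29 m stride
        from stepgaze.gait_pipeline import FootContact, GaitEvents

        events = GaitEvents(
            lead_foot="left",
            penultimate=FootContact("right", 0.0, 0.5, 2.6, 2.42, 0.0),
            final=FootContact("left", 0.5, 1.0, 2.9, 2.72, 0.0),
            lead_landing=FootContact("left", 1.5, 2.0, 4.19, 4.01, 0.075),
            trail_landing=FootContact("right", 2.0, 2.5, 4.8, 4.62, 0.075),
        )
        strides = stride_lengths(events)
        assert strides["lead_stride"] == pytest.approx(1.29)
        positions = foot_positions(events, edge_x=4.0)
        assert positions["lead_foot_pre"] == pytest.approx(1.1)
        assert positions["trail_foot_post"] == pytest.approx(0.8)
        signed = foot_positions(events, edge_x=4.0, signed=True)
        assert signed["lead_foot_pre"] == pytest.approx(-1.1)
        heel = foot_positions(events, edge_x=4.0, post_reference="heel")
        assert heel["trail_foot_post"] == pytest.approx(0.62)

    def test_landing_exactly_at_edge_is_zero(self):
        from stepgaze.gait_pipeline import FootContact, GaitEvents

        events = GaitEvents(
            lead_foot="left",
            penultimate=FootContact("right", 0.0, 0.5, 3.0, 2.82, 0.0),
            final=FootContact("left", 0.5, 1.0, 3.5, 3.32, 0.0),
            lead_landing=FootContact("left", 1.5, 2.0, 4.0, 3.82, 0.075),
            trail_landing=FootContact("right", 2.0, 2.5, 4.5, 4.32, 0.075),
        )
        assert foot_positions(events, edge_x=4.0)["lead_foot_post"] == pytest.approx(0.0)


class TestHeadFlexion:
    def _head_markers(self, pitch_deg, n=100):
        pitch = np.radians(pitch_deg)
        markers = {}
        fwd = np.array([0.1 * np.cos(pitch), 0.0, -0.1 * np.sin(pitch)])
        for name, sgn_f, sgn_y in (
            ("head_front_left", 1, 1),
            ("head_front_right", 1, -1),
            ("head_back_left", -1, 1),
            ("head_back_right", -1, -1),
        ):
            pos = np.tile(sgn_f * fwd + [0.0, sgn_y * 0.07, 1.7], (n, 1))
            markers[name] = make_traj(name, pos)
        return markers

    def test_identity_pose_is_zero(self):
        markers = self._head_markers(0.0)
        angles = head_flexion(markers, {"ev": 0.5})
        assert angles["ev"] == pytest.approx(0.0, abs=1e-9)

    def test_32_degrees_down(self):
        markers = self._head_markers(32.0)
        angles = head_flexion(markers, {"ev": 0.5})
        assert angles["ev"] == pytest.approx(32.0, abs=1e-9)

    def test_calibration_pose_subtracted(self):
        markers = self._head_markers(40.0)
        cal = {name: t.xyz[0] for name, t in self._head_markers(8.0).items()}
        angles = head_flexion(markers, {"ev": 0.5}, calibration=cal)
        assert angles["ev"] == pytest.approx(32.0, abs=1e-9)

    def test_synthetic_within_one_degree(self, write_trial):
        bundle, gt = write_trial
        params = extract_gait_parameters(bundle, NOFILT)
        for ev in HEAD_EVENTS:
            assert params.head_flexion[ev] == pytest.approx(gt.head[ev], abs=1.0)


class TestMlBve:
    def test_constant_is_zero(self):
        traj = make_traj("sternum", [[0.0, 0.3, 1.4]] * 50)
        assert ml_bve(traj) == pytest.approx(0.0)

    def test_alternating_unit(self):
        y = np.array([1.0, -1.0] * 25)
        traj = make_traj("sternum", np.column_stack([np.zeros(50), y, np.ones(50)]))
        assert ml_bve(traj, "rms") == pytest.approx(1.0)
        assert ml_bve(traj, "as_printed") == pytest.approx(1.0)

    def test_matches_two_pass_oracle(self, rng):
        for _ in range(30):
            y = rng.normal(size=200)
            traj = make_traj(
                "sternum", np.column_stack([np.zeros(200), y, np.ones(200)])
            )
            mean = sum(y) / len(y)
            msd = sum((v - mean) ** 2 for v in y) / len(y)
            assert ml_bve(traj, "as_printed") == pytest.approx(msd, abs=1e-12)
            assert ml_bve(traj, "rms") == pytest.approx(np.sqrt(msd), abs=1e-12)

    def test_translation_invariant_and_scaling(self, rng):
        y = rng.normal(size=100)
        base = make_traj("s", np.column_stack([np.zeros(100), y, np.ones(100)]))
        shifted = make_traj(
            "s", np.column_stack([np.zeros(100), y + 3.7, np.ones(100)])
        )
        scaled = make_traj(
            "s", np.column_stack([np.zeros(100), 2.5 * y, np.ones(100)])
        )
        assert ml_bve(shifted) == pytest.approx(ml_bve(base), abs=1e-12)
        assert ml_bve(scaled) == pytest.approx(2.5 * ml_bve(base), rel=1e-12)

    def test_too_short_rejected(self):
        traj = make_traj("sternum", [[0.0, 0.3, 1.4]])
        with pytest.raises(ValueError):
            ml_bve(traj)


class TestExtractGaitParameters:
    def test_noiseless_write_trial_recovers_all(self):
        bundle, gt = sd.simulate_trial(
            sd.condition_presets("write"), seed=5, sd_scale=0.0
        )
        params = extract_gait_parameters(bundle, NOFILT)
        assert params.flags == []
        assert params.lead_clearance_mm == pytest.approx(142.0, abs=2.0)
        assert params.trail_clearance_mm == pytest.approx(90.0, abs=2.0)
        assert params.lead_velocity == pytest.approx(2.32, abs=0.05)
        assert params.trail_velocity == pytest.approx(1.91, abs=0.05)
        assert params.lead_stride == pytest.approx(0.80, abs=0.005)
        assert params.ml_bve == pytest.approx(1.35, abs=1.35 * 0.05)
        for ev in HEAD_EVENTS:
            assert params.head_flexion[ev] == pytest.approx(gt.head[ev], abs=1.0)

    def test_missing_sternum_flags_bve_only(self, write_trial):
        bundle, _ = write_trial
        markers = {k: v for k, v in bundle.markers.items() if k != "sternum"}
        clone = TrialBundle(
            participant_id="P01",
            condition="write",
            repetition=1,
            markers=markers,
            step=bundle.step,
        )
        params = extract_gait_parameters(clone, NOFILT)
        assert params.ml_bve is None
        assert any("sternum" in f for f in params.flags)
        assert params.lead_stride is not None
        assert params.lead_clearance_mm is not None

    def test_translation_and_time_shift_invariance(self, no_phone_trial):
        bundle, _ = no_phone_trial
        base = extract_gait_parameters(bundle, NOFILT)
        # translate the whole lab frame along y; prepend a still second
        markers = {}
        for name, traj in bundle.markers.items():
            xyz = traj.xyz.copy()
            xyz[:, 1] += 0.4
            pad = np.tile(xyz[0], (100, 1))
            markers[name] = make_traj(name, np.vstack([pad, xyz]))
        clone = TrialBundle(
            participant_id="P01",
            condition="no_phone",
            repetition=1,
            markers=markers,
            step=bundle.step,
        )
        shifted = extract_gait_parameters(clone, NOFILT)
        for attr in (
            "lead_clearance_mm",
            "trail_clearance_mm",
            "lead_stride",
            "trail_stride",
            "lead_foot_pre",
            "trail_foot_post",
        ):
            assert getattr(shifted, attr) == pytest.approx(
                getattr(base, attr), abs=1e-6
            )
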