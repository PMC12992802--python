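"""Limb angles, rapid-motion selection, interlimb correlations, gait metrics."""

import numpy as np
import pytest

from cereb import kinematics as km
from cereb import synthdata


def _static_skeleton(n=100, limb_vec=(1.0, 0.0, 0.0)):
    """Skeleton with body along +x and all limb vectors set to ``limb_vec``."""
    t = np.arange(n) / km.FRAME_RATE
    xyz = np.zeros((n, 9, 3))
    pos = {  # trunk level so the body axis is exactly horizontal
        "anus": (8.0, 10.0, 2.5), "neck": (13.0, 10.0, 2.5),
        "chest": (11.0, 10.0, 2.5), "nose": (14.0, 10.0, 3.5),
        "tail_tip": (5.0, 10.0, 1.5),
    }
    for m, p in pos.items():
        xyz[:, km.MARKERS.index(m), :] = p
    for limb in km.LIMBS:
        origin = pos["chest" if "fore" in limb else "anus"]
        xyz[:, km.MARKERS.index(limb), :] = np.array(origin) + np.array(limb_vec)
    return km.Skeleton3D(t=t, xyz=xyz)


class TestLimbAngles:
    def test_parallel_limb_zero_angle(self):
        skel = _static_skeleton(limb_vec=(2.0, 0.0, 0.0))
        ang = km.limb_angle_series(skel)
        assert np.allclose(ang.angles["l_forepaw"], 0.0, atol=1e-9)

    def test_orthogonal_limb_ninety_degrees(self):
        skel = _static_skeleton(limb_vec=(0.0, 0.0, -2.0))
        ang = km.limb_angle_series(skel)
        assert np.allclose(ang.angles["r_hindpaw"], 90.0, atol=1e-9)

    def test_sinusoidal_angle_speed_amplitude_oracle(self):
        # 1-Hz, 20-deg angle swing in the horizontal plane; central
        # differences at 20 Hz attenuate the true 2*pi*f*A by sinc(2*pi*f*dt)
        n, f, amp = 400, 1.0, 20.0
        skel = _static_skeleton(n)
        # oscillate about 90 deg so the [0, 180] angle range never rectifies
        theta = np.radians(90.0 + amp * np.sin(2 * np.pi * f * skel.t))
        k = km.MARKERS.index("l_forepaw")
        skel.xyz[:, k, 0] = 11.0 + 2.0 * np.cos(theta)
        skel.xyz[:, k, 1] = 10.0 + 2.0 * np.sin(theta)
        skel.xyz[:, k, 2] = 2.5
        speeds = km.limb_angle_series(skel).speeds["l_forepaw"]
        assert speeds[20:-20].max() == pytest.approx(2 * np.pi * f * amp, rel=0.05)

    def test_zero_length_frames_interpolated(self):
        skel = _static_skeleton(limb_vec=(2.0, 0.0, 0.0))
        k = km.MARKERS.index("l_forepaw")
        skel.xyz[50, k, :] = skel.xyz[50, km.MARKERS.index("chest"), :]
        ang = km.limb_angle_series(skel)
        assert np.isfinite(ang.angles["l_forepaw"]).all()


class TestRapidMotionMask:
    def test_stationary_skeleton_empty_mask(self):
        skel = _static_skeleton()
        assert not km.rapid_motion_mask(skel).mask.any()

    def test_steady_translation_full_mask(self):
        skel = _static_skeleton(n=200)
        skel.xyz[:, :, 0] += (5.0 / km.FRAME_RATE) * np.arange(200)[:, None]
        # keep within arena: speed 5 cm/s for 10 s = 50 cm; recenter
        skel.xyz[:, :, 0] = np.mod(skel.xyz[:, :, 0], 15.0) + 2.0
        mask = km.rapid_motion_mask(skel).mask
        assert mask[2:-2].mean() > 0.95

    def test_matches_brute_force_and_excludes_rearing(self):
        truth = synthdata.GaitGroundTruth(
            rear_episodes=((30.0, 36.0),), lr_phase_mix=0.0
        )
        skel, _ = synthdata.gen_skeleton(truth, duration=120.0, seed=3)
        m = km.rapid_motion_mask(skel)
        sp = km.anus_speed(skel)
        lh = skel.pos("l_hindpaw")[:, 2]
        rh = skel.pos("r_hindpaw")[:, 2]
        lim = 2.576 * np.std(lh - rh)
        ref = np.maximum(lh, rh)
        oracle = (
            (sp > 2.0)
            & (skel.pos("l_forepaw")[:, 2] <= ref + lim)
            & (skel.pos("r_forepaw")[:, 2] <= ref + lim)
        )
        assert np.array_equal(m.mask, oracle)
        rearing = (skel.t > 31) & (skel.t < 35)
        assert not m.mask[rearing].any()


class TestLimbCorrelations:
    def test_matrix_symmetry_and_unit_diagonal(self, walking_skeleton):
        skel, _ = walking_skeleton
        c = km.limb_speed_correlations(
            km.limb_angle_series(skel), km.rapid_motion_mask(skel)
        )
        assert np.allclose(c.r, c.r.T)
        assert np.allclose(np.diag(c.r), 1.0)
        assert (np.abs(c.r) <= 1.0 + 1e-12).all()

    def test_lr_correlation_increases_with_phase_mix(self):
        vals = []
        for mix in (0.0, 0.25, 0.5, 0.75, 1.0):
            truth = synthdata.GaitGroundTruth(
                lr_phase_mix=mix, turning_profile=(20.0, -20.0, 0.0, 40.0)
            )
            skel, _ = synthdata.gen_skeleton(truth, duration=120.0, seed=42)
            c = km.limb_speed_correlations(
                km.limb_angle_series(skel), km.rapid_motion_mask(skel)
            )
            vals.append(c.pair("l_forepaw", "r_forepaw"))
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_too_few_frames_raises(self):
        skel = _static_skeleton(n=80)
        ang = km.limb_angle_series(skel)
        mask = km.rapid_motion_mask(skel)  # empty
        with pytest.raises(km.InsufficientDataError):
            km.limb_speed_correlations(ang, mask)


class TestSegmentation:
    def test_walk_then_still_single_boundary(self):
        truth = synthdata.GaitGroundTruth(turning_profile=(20.0, 0.0))
        skel, _ = synthdata.gen_skeleton(
            truth, duration=120.0, seed=7, speed_profile=(6.0, 0.0)
        )
        labels = km.segment_movements(skel)
        assert labels.n_segments == 2
        assert abs(labels.boundaries_s[0] - 60.0) <= 1.0

    def test_constant_behaviour_single_segment(self):
        # a resting animal: every movement feature is flat
        truth = synthdata.GaitGroundTruth(turning_profile=(0.0,))
        skel, _ = synthdata.gen_skeleton(
            truth, duration=60.0, seed=8, speed_profile=(0.0,)
        )
        assert km.segment_movements(skel).n_segments == 1

    def test_deterministic_labels(self):
        truth = synthdata.GaitGroundTruth(turning_profile=(20.0, 0.0))
        skel, _ = synthdata.gen_skeleton(
            truth, duration=120.0, seed=7, speed_profile=(6.0, 0.0)
        )
        a = km.segment_movements(skel)
        b = km.segment_movements(skel)
        assert np.array_equal(a.frame_segment, b.frame_segment)
        assert np.array_equal(a.segment_cluster, b.segment_cluster)

    def test_short_recording_rejected(self):
        truth = synthdata.GaitGroundTruth()
        skel, _ = synthdata.gen_skeleton(truth, duration=20.0, seed=1)
        with pytest.raises(km.InsufficientDataError):
            km.segment_movements(skel)


def _uniform_segments(skel, n_seg):
    seglen = skel.n_frames // n_seg
    frame_seg = np.minimum(np.arange(skel.n_frames) // seglen, n_seg - 1)
    return km.SegmentLabels(
        frame_segment=frame_seg,
        boundaries_s=np.empty(0),
        segment_cluster=np.zeros(n_seg, dtype=int),
    )


class TestPositiveCorrVsTurning:
    TURNS = tuple(np.tile([10.0, 40.0, 80.0, 120.0], 6))

    def test_monotone_construction_gives_nondecreasing_curve(self):
        mixes = tuple(min(1.0, tv / 120.0) for tv in self.TURNS)
        truth = synthdata.GaitGroundTruth(turning_profile=self.TURNS)
        skel, _ = synthdata.gen_skeleton(
            truth, duration=240.0, seed=9, mix_profile=mixes
        )
        curve = km.positive_corr_vs_turning(
            skel, _uniform_segments(skel, len(self.TURNS)), seed=1
        )
        assert np.all(np.diff(curve.p_positive) >= -1e-9)

    def test_pure_antiphase_probability_zero(self):
        truth = synthdata.GaitGroundTruth(
            lr_phase_mix=0.0, turning_profile=self.TURNS
        )
        skel, _ = synthdata.gen_skeleton(truth, duration=240.0, seed=10)
        curve = km.positive_corr_vs_turning(
            skel, _uniform_segments(skel, len(self.TURNS)), seed=1
        )
        assert np.all(curve.p_positive == 0.0)

    def test_mix_independent_of_turning_gives_flat_curve(self):
        truth = synthdata.GaitGroundTruth(
            lr_phase_mix=0.5, turning_profile=self.TURNS
        )
        skel, _ = synthdata.gen_skeleton(truth, duration=240.0, seed=12)
        curve = km.positive_corr_vs_turning(
            skel, _uniform_segments(skel, len(self.TURNS)), seed=1
        )
        grand = np.nanmean(curve.p_positive)
        for p, sem in zip(curve.p_positive, curve.sem):
            assert abs(p - grand) <= max(3 * sem, 0.25)

    def test_too_few_segments_rejected(self, walking_skeleton):
        skel, _ = walking_skeleton
        with pytest.raises(km.InsufficientDataError):
            km.positive_corr_vs_turning(skel, _uniform_segments(skel, 4), seed=0)


class TestGaitMetrics:
    def test_perfect_gait_has_no_variability(self):
        truth = synthdata.GaitGroundTruth(
            stride_frequency_Hz=2.5, marker_noise_sd=0.0, turning_profile=(0.0,)
        )
        skel, _ = synthdata.gen_skeleton(truth, duration=120.0, seed=1)
        gm = km.gait_metrics(skel)
        assert gm.stride_time_cv < 0.01
        assert gm.interlimb_phase_variance < 1e-3

    def test_stride_jitter_recovered(self):
        truth = synthdata.GaitGroundTruth(
            stride_frequency_Hz=2.0, turning_profile=(0.0,)
        )
        skel, _ = synthdata.gen_skeleton(
            truth, duration=300.0, seed=0, stride_jitter=0.10
        )
        assert km.gait_metrics(skel).stride_time_cv == pytest.approx(0.10, abs=0.02)

    def test_ataxia_index_increases_with_placement_noise(self):
        vals = []
        for sd in (0.05, 0.1, 0.2):
            truth = synthdata.GaitGroundTruth(
                marker_noise_sd=sd, stride_frequency_Hz=2.0, turning_profile=(0.0,)
            )
            skel, _ = synthdata.gen_skeleton(truth, duration=180.0, seed=3)
            vals.append(km.gait_metrics(skel).ataxia_index)
        assert vals[0] < vals[1] < vals[2]

    def test_insufficient_strides_raise(self):
        truth = synthdata.GaitGroundTruth(turning_profile=(0.0,))
        skel, _ = synthdata.gen_skeleton(truth, duration=31.0, seed=4, speed_profile=None)
        short = km.Skeleton3D(t=skel.t[:100], xyz=skel.xyz[:100])
        with pytest.raises(km.InsufficientDataError):
            km.gait_metrics(short)


class TestSkeletonIO:
    @pytest.mark.parametrize("ext", [".csv", ".h5"])
    def test_roundtrip(self, tmp_path, walking_skeleton, ext):
        skel, _ = walking_skeleton
        path = tmp_path / f"skel{ext}"
        km.save_skeleton(skel, path)
        back = km.load_skeleton(path)
        assert np.allclose(back.xyz, skel.xyz)
        assert np.allclose(back.t, skel.t)
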