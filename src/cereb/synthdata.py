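"""Synthetic inputs with attached ground truth.

Two generators emulate the raw data the analysis consumes, so every
downstream stage can be tested without recordings:

* :func:`gen_tonic_trace` — voltage-clamp holding-current traces with
  stepwise drug-induced baseline shifts (gradual wash-in), superimposed
  sIPSC transients and white noise;
* :func:`gen_skeleton` — 9-marker open-field pose at 20 Hz in a
  20 x 20 x 30 cm arena, with a controllable left-right limb phase mix,
  a prescribed turning profile and optional rearing episodes.

Both return the emitted object together with the unchanged ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .ephys import TraceRecording
from .kinematics import FRAME_RATE, MARKERS, Skeleton3D

__all__ = [
    "TraceGroundTruth",
    "GaitGroundTruth",
    "gen_tonic_trace",
    "gen_skeleton",
]


@dataclass
class TraceGroundTruth:
    """Generative parameters of one holding-current trace.

    ``component_shifts`` maps transition labels ("base->TTX", "TTX->GBZ", ...)
    to the true outward baseline shift in pA; IPSC times/amplitudes describe
    the injected transients.
    """

    baseline_pA: float = -120.0
    component_shifts: dict[str, float] = field(default_factory=dict)
    ipsc_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    ipsc_amplitudes: np.ndarray = field(default_factory=lambda: np.empty(0))
    noise_sd: float = 2.0

    def __post_init__(self) -> None:
        self.ipsc_times = np.asarray(self.ipsc_times, dtype=float)
        self.ipsc_amplitudes = np.asarray(self.ipsc_amplitudes, dtype=float)
        if len(self.ipsc_times) > 1 and np.any(np.diff(self.ipsc_times) <= 0):
            raise ValueError("ipsc_times must be strictly increasing")

    @property
    def total_tonic_pA(self) -> float:
        return float(sum(self.component_shifts.values()))


@dataclass
class GaitGroundTruth:
    """Generative parameters of one open-field recording.

    ``lr_phase_mix`` is the fraction of locomotor bouts in which the left and
    right limbs of each girdle move in phase (hopping/twist-turning style);
    the remaining bouts are pure antiphase (trot).  ``turning_profile`` is
    the signed heading angular velocity (deg/s) per equal-length segment.
    """

    stride_frequency_Hz: float = 2.0
    lr_phase_mix: float = 0.0
    turning_profile: tuple[float, ...] = (0.0,)
    rear_episodes: tuple[tuple[float, float], ...] = ()
    marker_noise_sd: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 <= self.lr_phase_mix <= 1.0:
            raise ValueError("lr_phase_mix must be in [0, 1]")
        if self.stride_frequency_Hz <= 0:
            raise ValueError("stride_frequency_Hz must be positive")
        eps = sorted(self.rear_episodes)
        for (a0, a1), (b0, b1) in zip(eps[:-1], eps[1:]):
            if b0 < a1:
                raise ValueError("rear episodes must not overlap")


# ---------------------------------------------------------------------------
# tonic current traces

#: Wash-in time constant of bath-applied drugs, seconds.
WASH_TAU_S = 10.0
#: IPSC decay time constant, seconds (instantaneous rise).
IPSC_TAU_S = 0.010


def _wash_profile(t: np.ndarray, t_event: float, tau: float = WASH_TAU_S) -> np.ndarray:
    """Causal wash-in: 0 before the event, truncated logistic after.

    Half-rise 2*tau after the event; renormalized so the profile starts at
    exactly 0 at the event and saturates at 1.
    """
    x = (t - t_event) / tau - 2.0
    s = 1.0 / (1.0 + np.exp(-x))
    s0 = 1.0 / (1.0 + np.exp(2.0))
    out = (s - s0) / (1.0 - s0)
    out[t < t_event] = 0.0
    return out


def gen_tonic_trace(
    protocol: tuple[str, ...],
    truth: TraceGroundTruth,
    duration: float = 420.0,
    rate: float = 200.0,
    seed: int = 0,
    event_times: tuple[float, ...] | None = None,
    meta: dict | None = None,
) -> tuple[TraceRecording, TraceGroundTruth]:
    """Emit a holding-current trace realizing the ground truth.

    ``protocol`` is the ordered drug list, e.g. ``("TTX", "GBZ")``; the
    transition labels in ``truth.component_shifts`` must match it exactly
    (``"base->TTX"``, ``"TTX->GBZ"``...).  Events default to evenly spaced
    times.  The trace is baseline + cumulative wash-in shifts + inward IPSC
    transients + white noise.
    """
    labels = ("base",) + tuple(protocol)
    expected = [f"{a}->{b}" for a, b in zip(labels[:-1], labels[1:])]
    if set(truth.component_shifts) != set(expected):
        raise ValueError(
            f"component_shifts labels {sorted(truth.component_shifts)} do not "
            f"match protocol transitions {expected}"
        )
    if rate < 100:
        raise ValueError("sampling rate must be >= 100 Hz")
    n_ev = len(protocol)
    if event_times is None:
        event_times = tuple(duration * (i + 1) / (n_ev + 1) for i in range(n_ev))
    if len(event_times) != n_ev or max(event_times) >= duration:
        raise ValueError("need one in-range event time per protocol drug")
    if len(truth.ipsc_times) and truth.ipsc_times.max() > duration:
        raise ValueError("ipsc_times must lie within the trace duration")

    dt = 1.0 / rate
    n = int(round(duration * rate))
    t = np.arange(n) * dt
    cur = np.full(n, truth.baseline_pA)
    for lab, t_ev in zip(expected, event_times):
        cur = cur + truth.component_shifts[lab] * _wash_profile(t, t_ev)
    if len(truth.ipsc_times):
        deltas = np.zeros(n)
        idx = np.minimum((truth.ipsc_times * rate).astype(int), n - 1)
        np.add.at(deltas, idx, truth.ipsc_amplitudes)
        decay = np.exp(-dt / IPSC_TAU_S)
        cur = cur - signal.lfilter([1.0], [1.0, -decay], deltas)
    if truth.noise_sd > 0:
        rng = np.random.default_rng(seed)
        cur = cur + rng.normal(0.0, truth.noise_sd, n)
    trace = TraceRecording(
        t=t,
        I=cur,
        events=list(zip(protocol, event_times)),
        meta={"synthetic": True, **(meta or {})},
    )
    return trace, truth


# ---------------------------------------------------------------------------
# gait skeletons

_ARENA = (20.0, 20.0, 30.0)
_BODY_LEN = 5.0  # anus->neck, cm
_TRUNK_Z = {"nose": 3.8, "neck": 3.2, "chest": 2.2, "anus": 2.6, "tail_tip": 1.8}


def _cycle_waveform(phase: np.ndarray, swing_frac: float = 0.2) -> np.ndarray:
    """Asymmetric stride cycle in [-1, 1]: fast swing, slow stance.

    The rectified derivative forms one pulse per cycle during swing, so
    antiphase limbs have anti-aligned speed pulses (negative correlation)
    while in-phase limbs are positively correlated — the signature the
    interlimb analysis measures.
    """
    ph = np.mod(phase, 2 * np.pi) / (2 * np.pi)
    out = np.empty_like(ph)
    sw = ph >= 1.0 - swing_frac  # swing ends exactly at the cycle boundary
    out[~sw] = 1.0 - 2.0 * ph[~sw] / (1.0 - swing_frac)
    out[sw] = -np.cos(np.pi * (ph[sw] - (1.0 - swing_frac)) / swing_frac)
    return out


def _swing_lift(phase: np.ndarray, swing_frac: float = 0.4) -> np.ndarray:
    """Paw elevation: raised cosine around swing (the paw unloads before the
    forward flick), 0 through mid-stance; one lift per stride cycle with a
    dominant fundamental at the stride frequency."""
    ph = np.mod(phase, 2 * np.pi) / (2 * np.pi)
    lift = np.zeros_like(ph)
    sw = ph >= 1.0 - swing_frac
    lift[sw] = 0.5 * (
        1 - np.cos(2 * np.pi * (ph[sw] - (1.0 - swing_frac)) / swing_frac)
    )
    return lift


def gen_skeleton(
    truth: GaitGroundTruth,
    duration: float = 120.0,
    seed: int = 0,
    speed_cm_s: float = 6.0,
    stride_jitter: float = 0.0,
    stride_amp_cm: float = 1.5,
    lift_cm: float = 1.0,
    bout_s: float = 1.0,
    mix_profile: tuple[float, ...] | None = None,
    speed_profile: tuple[float, ...] | None = None,
    meta: dict | None = None,
) -> tuple[Skeleton3D, GaitGroundTruth]:
    """Emit a 9-marker, 20-Hz open-field recording realizing the ground truth.

    The trunk follows a smooth 2D walk whose heading integrates the segment
    turning profile (with gentle wall-avoidance steering near the arena
    boundary); paws oscillate at the stride frequency, with each ``bout_s``
    locomotor bout drawn in-phase (left-right offset 0) with probability
    ``lr_phase_mix`` and antiphase (offset pi) otherwise; rearing raises the
    forepaws well above the hindpaws during the listed episodes.  ``stride_jitter``
    perturbs individual stride periods (fractional SD) for gait-variability
    studies.  ``mix_profile`` / ``speed_profile`` optionally override the
    in-phase bout probability / walking speed per turning-profile segment
    (e.g. to couple in-phase gait to turning, or to insert still periods —
    stride amplitude scales with speed).  All markers stay inside the
    20 x 20 x 30 cm arena.
    """
    if duration > 600.0:
        raise ValueError("recording duration is capped at 600 s (10-min session)")
    rng = np.random.default_rng(seed)
    fs = FRAME_RATE
    n = int(round(duration * fs))
    dt = 1.0 / fs
    t = np.arange(n) * dt

    # heading from the prescribed turning profile + wall avoidance
    seg = np.asarray(truth.turning_profile, dtype=float)
    seg_idx = np.minimum((t / duration * len(seg)).astype(int), len(seg) - 1)
    omega = np.radians(seg[seg_idx])
    if speed_profile is not None:
        if len(speed_profile) != len(seg):
            raise ValueError("speed_profile must match turning_profile length")
        speed = np.asarray(speed_profile, dtype=float)[seg_idx]
    else:
        speed = np.full(n, speed_cm_s)
    psi = np.empty(n)
    pos = np.empty((n, 2))
    psi[0] = rng.uniform(0, 2 * np.pi)
    pos[0] = (10.0, 10.0)
    margin, k_wall, max_steer = 6.5, 3.0, 2.5  # rad/s
    for i in range(1, n):
        p = pos[i - 1]
        steer = 0.0
        d_wall = min(p[0], p[1], _ARENA[0] - p[0], _ARENA[1] - p[1])
        if d_wall < margin:
            to_center = np.arctan2(10.0 - p[1], 10.0 - p[0])
            err = np.angle(np.exp(1j * (to_center - psi[i - 1])))
            steer = np.clip(k_wall * err * (1.0 - d_wall / margin),
                            -max_steer, max_steer)
        psi[i] = psi[i - 1] + (omega[i - 1] + steer) * dt
        pos[i] = p + speed[i - 1] * dt * np.array([np.cos(psi[i]), np.sin(psi[i])])
        pos[i] = np.clip(pos[i], 1.5, _ARENA[0] - 1.5)

    # stride phase, optionally with per-stride period jitter
    f0 = truth.stride_frequency_Hz
    if stride_jitter > 0:
        # slowly varying (AR(1)) cadence fluctuations: stride-to-stride
        # intervals then carry the full jitter SD for every limb phase
        n_strides = int(np.ceil(duration * f0 * 1.5)) + 2
        rho = 0.8
        eps = rng.standard_normal(n_strides)
        a = np.empty(n_strides)
        a[0] = eps[0]
        for k in range(1, n_strides):
            a[k] = rho * a[k - 1] + np.sqrt(1 - rho**2) * eps[k]
        periods = (1.0 / f0) * (1.0 + stride_jitter * a)
        periods = np.clip(periods, 0.3 / f0, 3.0 / f0)
        knots = np.concatenate([[0.0], np.cumsum(periods)])
        theta = 2 * np.pi * np.interp(t, knots, np.arange(len(knots), dtype=float))
    else:
        theta = 2 * np.pi * f0 * t

    h_hat = np.stack([np.cos(psi), np.sin(psi)], axis=1)
    n_hat = np.stack([-np.sin(psi), np.cos(psi)], axis=1)

    xyz = np.zeros((n, len(MARKERS), 3))

    def put(marker: str, xy: np.ndarray, z: np.ndarray) -> None:
        k = MARKERS.index(marker)
        xyz[:, k, :2] = xy
        xyz[:, k, 2] = z

    anus = pos
    neck = pos + _BODY_LEN * h_hat
    ones = np.ones(n)
    put("anus", anus, _TRUNK_Z["anus"] * ones)
    put("neck", neck, _TRUNK_Z["neck"] * ones)
    put("chest", pos + 0.7 * _BODY_LEN * h_hat, _TRUNK_Z["chest"] * ones)
    put("nose", neck + 1.5 * h_hat, _TRUNK_Z["nose"] * ones)
    put("tail_tip", pos - 3.0 * h_hat, _TRUNK_Z["tail_tip"] * ones)

    # rearing envelope: raised-cosine edged elevation of the forelimbs
    rear = np.zeros(n)
    for t0, t1 in truth.rear_episodes:
        ramp = 0.5
        up = np.clip((t - t0) / ramp, 0, 1)
        down = np.clip((t1 - t) / ramp, 0, 1)
        env = np.minimum(up, down)
        env[(t < t0) | (t > t1)] = 0.0
        rear = np.maximum(rear, env)
    rear_lift = 5.0 * rear  # up to 5 cm forepaw elevation

    # left-right phase offset switches between antiphase (pi) and in-phase (0)
    # in bouts; lr_phase_mix is the in-phase bout fraction.  Transitions are
    # smoothed over ~0.3 s so limb trajectories stay continuous.
    n_bouts = max(1, int(np.ceil(duration / bout_s)))
    if mix_profile is not None:
        if len(mix_profile) != len(seg):
            raise ValueError("mix_profile must match turning_profile length")
        bout_mid = (np.arange(n_bouts) + 0.5) * bout_s
        bout_seg = np.minimum(
            (bout_mid / duration * len(seg)).astype(int), len(seg) - 1
        )
        bout_prob = np.asarray(mix_profile, dtype=float)[bout_seg]
    else:
        bout_prob = np.full(n_bouts, truth.lr_phase_mix)
    in_phase = rng.random(n_bouts) < bout_prob
    bout_idx = np.minimum((t / bout_s).astype(int), n_bouts - 1)
    offset_t = np.pi * (1.0 - in_phase[bout_idx].astype(float))
    k = max(1, int(round(0.3 * fs)))
    offset_t = np.convolve(offset_t, np.ones(k) / k, mode="same")
    limb_phase = {
        "l_forepaw": np.zeros(n),
        "r_forepaw": offset_t,
        "l_hindpaw": offset_t,
        "r_hindpaw": np.zeros(n),
    }
    limb_attach = {
        "l_forepaw": (0.7 * _BODY_LEN, +1.2),
        "r_forepaw": (0.7 * _BODY_LEN, -1.2),
        "l_hindpaw": (0.0, +1.3),
        "r_hindpaw": (0.0, -1.3),
    }
    gait_gain = np.clip(speed / max(speed_cm_s, 1e-9), 0.0, 1.0)
    for limb, ph0 in limb_phase.items():
        fwd0, lat = limb_attach[limb]
        ph = theta + ph0
        excursion = stride_amp_cm * gait_gain * _cycle_waveform(ph)
        z = lift_cm * gait_gain * _swing_lift(ph)
        if limb.endswith("forepaw"):
            z = z + rear_lift
        xy = pos + (fwd0 + excursion)[:, None] * h_hat + lat * n_hat
        put(limb, xy, z)

    if truth.marker_noise_sd > 0:
        xyz = xyz + truth.marker_noise_sd * rng.standard_normal(xyz.shape)
    xyz[:, :, 0] = np.clip(xyz[:, :, 0], 0.0, _ARENA[0])
    xyz[:, :, 1] = np.clip(xyz[:, :, 1], 0.0, _ARENA[1])
    xyz[:, :, 2] = np.clip(xyz[:, :, 2], 0.0, _ARENA[2])
    skel = Skeleton3D(
        t=t, xyz=xyz, arena_cm=_ARENA, meta={"synthetic": True, **(meta or {})}
    )
    return skel, truth
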