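"""Interlimb coordination from 9-marker 3D pose at 20 Hz.

The pipeline mirrors open-field posture analysis of freely moving mice: limb
angles relative to the trunk, selection of rapid whole-body motion, Pearson
correlations of rectified limb angular speeds, feature-based motion
segmentation, the turning-speed dependence of positive left-right
correlations, and classical gait-regularity metrics.

Conventions fixed here (the source kinematic literature gives no formulas):
the body vector runs anus -> neck; forelimb vectors originate at the chest,
hindlimb vectors at the anus; heading is the horizontal azimuth of the body
vector.  Angular speeds are rectified central differences at the native 20 Hz
without pre-smoothing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from scipy import signal
from sklearn.cluster import KMeans

from . import spikestats

__all__ = [
    "MARKERS",
    "LIMBS",
    "Skeleton3D",
    "LimbAngleSeries",
    "MotionMask",
    "CorrelationMatrix",
    "GaitMetrics",
    "SegmentLabels",
    "InsufficientDataError",
    "limb_angle_series",
    "rapid_motion_mask",
    "limb_speed_correlations",
    "segment_movements",
    "positive_corr_vs_turning",
    "gait_metrics",
    "save_skeleton",
    "load_skeleton",
]

#: Fixed marker order for the wide CSV/HDF5 layout.
MARKERS = (
    "nose",
    "neck",
    "chest",
    "anus",
    "tail_tip",
    "l_forepaw",
    "r_forepaw",
    "l_hindpaw",
    "r_hindpaw",
)

#: Limb order used in the 4x4 correlation matrix.
LIMBS = ("l_forepaw", "r_forepaw", "l_hindpaw", "r_hindpaw")

FRAME_RATE = 20.0


class InsufficientDataError(ValueError):
    """Too few frames, segments or strides for the requested statistic."""

    def __init__(self, msg: str, n: int = 0):
        super().__init__(msg)
        self.n = n


@dataclass
class Skeleton3D:
    """9-marker 3D pose time series in cm, sampled at 20 Hz.

    ``xyz`` has shape ``(n_frames, 9, 3)`` with markers in :data:`MARKERS`
    order; coordinates are arena-frame cm with the origin at a floor corner
    and z up.
    """

    t: np.ndarray
    xyz: np.ndarray
    arena_cm: tuple[float, float, float] = (20.0, 20.0, 30.0)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.shape != (len(self.t), len(MARKERS), 3):
            raise ValueError("xyz must have shape (n_frames, 9, 3)")
        if len(self.t) > 2:
            dt = np.diff(self.t)
            if abs(dt.mean() - 1.0 / FRAME_RATE) > 1e-6:
                raise ValueError("skeleton must be sampled at 20 Hz")

    def pos(self, marker: str) -> np.ndarray:
        return self.xyz[:, MARKERS.index(marker), :]

    @property
    def n_frames(self) -> int:
        return len(self.t)


@dataclass
class LimbAngleSeries:
    """Per-limb angle (deg, in [0, 180]) and rectified angular speed (deg/s)."""

    t: np.ndarray
    angles: dict[str, np.ndarray]
    speeds: dict[str, np.ndarray]


@dataclass
class MotionMask:
    """Boolean rapid-motion mask with the selection criteria recorded."""

    mask: np.ndarray
    speed_threshold_cm_s: float
    height_limit_multiplier: float
    height_limit_cm: float


@dataclass
class CorrelationMatrix:
    """4x4 Pearson correlations of limb angular speeds (LF, RF, LH, RH)."""

    r: np.ndarray
    n_frames: int
    limbs: tuple[str, ...] = LIMBS

    def pair(self, a: str, b: str) -> float:
        return float(self.r[self.limbs.index(a), self.limbs.index(b)])


@dataclass
class GaitMetrics:
    stride_time_cv: float
    step_width_cv: float
    ataxia_index: float
    interlimb_phase_variance: float
    n_strides: int


@dataclass
class SegmentLabels:
    """Contiguous motion segments and their behavioural cluster ids."""

    frame_segment: np.ndarray  # segment index per frame
    boundaries_s: np.ndarray  # change-point times, seconds
    segment_cluster: np.ndarray  # cluster id per segment

    @property
    def n_segments(self) -> int:
        return int(self.frame_segment.max()) + 1

    def intervals(self, t: np.ndarray) -> list[tuple[int, int]]:
        """Frame index ranges [start, stop) of each segment."""
        out = []
        for s in range(self.n_segments):
            idx = np.flatnonzero(self.frame_segment == s)
            out.append((int(idx[0]), int(idx[-1]) + 1))
        return out


# ---------------------------------------------------------------------------
# limb angles


def _central_diff(x: np.ndarray, dt: float) -> np.ndarray:
    d = np.empty_like(x)
    d[1:-1] = (x[2:] - x[:-2]) / (2 * dt)
    d[0] = (x[1] - x[0]) / dt
    d[-1] = (x[-1] - x[-2]) / dt
    return d


#: Limb attachment points: limb vector = attachment -> paw.
_LIMB_ORIGIN = {
    "l_forepaw": "chest",
    "r_forepaw": "chest",
    "l_hindpaw": "anus",
    "r_hindpaw": "anus",
}


def limb_angle_series(skel: Skeleton3D) -> LimbAngleSeries:
    """Angle between each limb vector and the body (anus->neck) vector.

    Frames with a numerically zero-length vector are flagged and linearly
    interpolated before differencing.  Angular speed is the rectified central
    difference of the angle.
    """
    dt = 1.0 / FRAME_RATE
    body = skel.pos("neck") - skel.pos("anus")
    nb = np.linalg.norm(body, axis=1)
    angles: dict[str, np.ndarray] = {}
    speeds: dict[str, np.ndarray] = {}
    for limb in LIMBS:
        vec = skel.pos(limb) - skel.pos(_LIMB_ORIGIN[limb])
        nv = np.linalg.norm(vec, axis=1)
        ok = (nb > 1e-9) & (nv > 1e-9)
        cosang = np.full(len(nb), np.nan)
        cosang[ok] = np.einsum("ij,ij->i", body[ok], vec[ok]) / (nb[ok] * nv[ok])
        ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
        if not ok.all():
            idx = np.arange(len(ang))
            ang = np.interp(idx, idx[ok], ang[ok])
        angles[limb] = ang
        speeds[limb] = np.abs(_central_diff(ang, dt))
    return LimbAngleSeries(t=skel.t, angles=angles, speeds=speeds)


# ---------------------------------------------------------------------------
# rapid-motion selection


def anus_speed(skel: Skeleton3D) -> np.ndarray:
    """Speed of the anus marker (cm/s, central differences)."""
    dt = 1.0 / FRAME_RATE
    p = skel.pos("anus")
    v = np.stack([_central_diff(p[:, k], dt) for k in range(3)], axis=1)
    return np.linalg.norm(v, axis=1)


def heading(skel: Skeleton3D) -> np.ndarray:
    """Horizontal azimuth of the anus->neck body vector, radians, unwrapped."""
    body = skel.pos("neck") - skel.pos("anus")
    return np.unwrap(np.arctan2(body[:, 1], body[:, 0]))


def turning_speed(skel: Skeleton3D) -> np.ndarray:
    """Rectified heading angular speed, deg/s."""
    return np.abs(np.degrees(_central_diff(heading(skel), 1.0 / FRAME_RATE)))


def rapid_motion_mask(
    skel: Skeleton3D,
    speed_threshold: float = 2.0,
    height_multiplier: float = 2.576,
) -> MotionMask:
    """Frames of rapid whole-body motion.

    A frame is included iff the anus speed exceeds ``speed_threshold`` (cm/s)
    AND each forepaw z stays at or below the per-frame hindpaw reference (max
    of the two hindpaw z) plus ``height_multiplier`` times the recording-wide
    SD of the left-right hindpaw vertical distance.  The height limit removes
    rearing, in which both forelimbs rise together.
    """
    sp = anus_speed(skel)
    lhz = skel.pos("l_hindpaw")[:, 2]
    rhz = skel.pos("r_hindpaw")[:, 2]
    sd = float(np.std(lhz - rhz))
    limit = height_multiplier * sd
    ref = np.maximum(lhz, rhz)
    fl = skel.pos("l_forepaw")[:, 2]
    fr = skel.pos("r_forepaw")[:, 2]
    mask = (sp > speed_threshold) & (fl <= ref + limit) & (fr <= ref + limit)
    return MotionMask(
        mask=mask,
        speed_threshold_cm_s=speed_threshold,
        height_limit_multiplier=height_multiplier,
        height_limit_cm=limit,
    )


def limb_speed_correlations(
    angles: LimbAngleSeries,
    mask: MotionMask | np.ndarray | None = None,
    min_frames: int = 50,
) -> CorrelationMatrix:
    """Pearson correlations of limb angular speeds over masked frames."""
    m = mask.mask if isinstance(mask, MotionMask) else mask
    if m is None:
        m = np.ones(len(angles.t), dtype=bool)
    n = int(m.sum())
    if n < min_frames:
        raise InsufficientDataError(
            f"only {n} rapid-motion frames (< {min_frames})", n=n
        )
    X = np.stack([angles.speeds[limb][m] for limb in LIMBS])
    r = np.corrcoef(X)
    return CorrelationMatrix(r=r, n_frames=n)


# ---------------------------------------------------------------------------
# segmentation


@dataclass
class SegmentationConfig:
    k_clusters: int = 8
    window_stride_s: float = 0.25
    feature_windows_s: tuple[float, ...] = (0.5, 1.0, 2.0)
    stride_band_Hz: tuple[float, float] = (1.5, 4.0)
    min_segment_s: float = 2.0
    penalty: float = 25.0
    seed: int = 0


def _rolling_mean(x: np.ndarray, w: int) -> np.ndarray:
    if w <= 1:
        return x.copy()
    kernel = np.ones(w) / w
    pad = np.pad(x, (w // 2, w - 1 - w // 2), mode="edge")
    return np.convolve(pad, kernel, mode="valid")


def _movement_features(skel: Skeleton3D, cfg: SegmentationConfig) -> tuple[np.ndarray, np.ndarray]:
    """Multiscale features on a window-stride grid: (grid frame idx, features)."""
    fs = FRAME_RATE
    sp = anus_speed(skel)
    ts = turning_speed(skel)
    paw_h = np.mean([skel.pos(l)[:, 2] for l in LIMBS], axis=0)
    # stride-band power of mean paw height at several window lengths
    sos = signal.butter(
        2, cfg.stride_band_Hz, btype="bandpass", fs=fs, output="sos"
    )
    band = signal.sosfiltfilt(sos, paw_h - paw_h.mean())
    cols = []
    for w_s in cfg.feature_windows_s:
        w = max(1, int(round(w_s * fs)))
        cols.append(_rolling_mean(sp, w))
        cols.append(_rolling_mean(ts, w))
        cols.append(_rolling_mean(paw_h, w))
        cols.append(np.sqrt(_rolling_mean(band**2, w)))
    F = np.stack(cols, axis=1)
    stride = max(1, int(round(cfg.window_stride_s * fs)))
    grid = np.arange(0, len(F), stride)
    return grid, F[grid]


def _binary_segmentation(Z: np.ndarray, min_len: int, penalty: float) -> list[int]:
    """Recursive mean-shift change points on z-scored features (SSE gain)."""

    def best_split(lo: int, hi: int) -> tuple[float, int]:
        seg = Z[lo:hi]
        n = len(seg)
        if n < 2 * min_len:
            return 0.0, -1
        csum = np.cumsum(seg, axis=0)
        csq = np.cumsum((seg**2).sum(axis=1))
        total = csq[-1] - (csum[-1] ** 2).sum() / n
        best_gain, best_k = 0.0, -1
        for k in range(min_len, n - min_len + 1):
            left = csq[k - 1] - (csum[k - 1] ** 2).sum() / k
            right = (csq[-1] - csq[k - 1]) - (
                (csum[-1] - csum[k - 1]) ** 2
            ).sum() / (n - k)
            gain = total - left - right
            if gain > best_gain:
                best_gain, best_k = gain, lo + k
        return best_gain, best_k

    cps: list[int] = []
    stack = [(0, len(Z))]
    while stack:
        lo, hi = stack.pop()
        gain, k = best_split(lo, hi)
        if k >= 0 and gain > penalty:
            cps.append(k)
            stack.append((lo, k))
            stack.append((k, hi))
    return sorted(cps)


def segment_movements(
    skel: Skeleton3D, config: SegmentationConfig | None = None
) -> SegmentLabels:
    """Change-point segmentation of movement features, then k-means clustering.

    Features (translational speed, turning speed, mean paw height and
    stride-band power at 0.5/1/2-s windows) are z-scored on a 0.25-s grid;
    change points come from recursive binary segmentation of the summed
    squared error, and segment-mean features are clustered with seeded
    k-means into at most ``k_clusters`` groups.  A recording with constant
    behaviour yields a single segment.
    """
    cfg = config or SegmentationConfig()
    if skel.t[-1] - skel.t[0] < 30.0 - 1e-9:
        raise InsufficientDataError("recording must be at least 30 s for segmentation")
    grid, F = _movement_features(skel, cfg)
    sd = F.std(axis=0)
    keep = sd > 1e-9
    if not keep.any():  # fully constant features
        frame_segment = np.zeros(skel.n_frames, dtype=int)
        return SegmentLabels(frame_segment, np.empty(0), np.zeros(1, dtype=int))
    Z = (F[:, keep] - F[:, keep].mean(axis=0)) / sd[keep]
    min_len = max(2, int(round(cfg.min_segment_s / cfg.window_stride_s)))
    cps = _binary_segmentation(Z, min_len, cfg.penalty * Z.shape[1])
    bounds = [0] + cps + [len(grid)]
    frame_segment = np.zeros(skel.n_frames, dtype=int)
    for si in range(len(bounds) - 1):
        f0 = grid[bounds[si]]
        f1 = grid[bounds[si + 1]] if bounds[si + 1] < len(grid) else skel.n_frames
        frame_segment[f0:f1] = si
    seg_means = np.stack(
        [Z[bounds[i] : bounds[i + 1]].mean(axis=0) for i in range(len(bounds) - 1)]
    )
    k = min(cfg.k_clusters, len(seg_means))
    if k > 1:
        km = KMeans(n_clusters=k, n_init=10, random_state=cfg.seed)
        clusters = km.fit_predict(seg_means)
    else:
        clusters = np.zeros(len(seg_means), dtype=int)
    boundary_t = skel.t[grid[np.array(cps, dtype=int)]] if cps else np.empty(0)
    return SegmentLabels(frame_segment, boundary_t, clusters)


# ---------------------------------------------------------------------------
# turning-speed dependence


@dataclass
class PositiveCorrCurve:
    bin_edges_deg_s: np.ndarray
    bin_centers_deg_s: np.ndarray
    p_positive: np.ndarray
    sem: np.ndarray
    n_segments: np.ndarray
    segment_turning_deg_s: np.ndarray
    segment_corr: np.ndarray


def positive_corr_vs_turning(
    skel: Skeleton3D,
    segments: SegmentLabels,
    limb_pair: tuple[str, str] = ("l_forepaw", "r_forepaw"),
    n_bins: int = 4,
    min_frames: int = 20,
    n_boot: int = 1000,
    seed: int = 0,
) -> PositiveCorrCurve:
    """P(positive limb-pair correlation) as a function of segment turning speed.

    Per segment the limb-pair angular-speed correlation (rapid-motion frames
    only) and the mean rectified turning speed are computed; segments are
    binned into ``n_bins`` equal-count turning-speed bins, and within each bin
    the fraction of segments with positive correlation is reported with a
    bootstrap s.e.m.  Empty or underpopulated segments are dropped, not
    interpolated.
    """
    angles = limb_angle_series(skel)
    mask = rapid_motion_mask(skel).mask
    ts = turning_speed(skel)
    a, b = limb_pair
    seg_turn, seg_corr = [], []
    for f0, f1 in segments.intervals(skel.t):
        m = mask[f0:f1]
        if m.sum() < min_frames:
            continue
        xa = angles.speeds[a][f0:f1][m]
        xb = angles.speeds[b][f0:f1][m]
        if xa.std() < 1e-12 or xb.std() < 1e-12:
            continue
        seg_corr.append(float(np.corrcoef(xa, xb)[0, 1]))
        seg_turn.append(float(ts[f0:f1][m].mean()))
    seg_turn = np.asarray(seg_turn)
    seg_corr = np.asarray(seg_corr)
    if len(seg_turn) < 10:
        raise InsufficientDataError(
            f"only {len(seg_turn)} usable segments (< 10)", n=len(seg_turn)
        )
    qs = np.linspace(0, 1, n_bins + 1)
    edges = np.quantile(seg_turn, qs)
    edges[-1] += 1e-9
    p = np.full(n_bins, np.nan)
    sem = np.full(n_bins, np.nan)
    counts = np.zeros(n_bins, dtype=int)
    centers = np.full(n_bins, np.nan)
    for i in range(n_bins):
        sel = (seg_turn >= edges[i]) & (seg_turn < edges[i + 1])
        counts[i] = sel.sum()
        if counts[i] == 0:
            continue
        pos = (seg_corr[sel] > 0).astype(float)
        p[i] = pos.mean()
        centers[i] = seg_turn[sel].mean()
        if counts[i] >= 2:
            sem[i] = spikestats.bootstrap_sem(
                pos, np.mean, n_iter=n_boot, seed=seed + i
            ).sem
    return PositiveCorrCurve(
        bin_edges_deg_s=edges,
        bin_centers_deg_s=centers,
        p_positive=p,
        sem=sem,
        n_segments=counts,
        segment_turning_deg_s=seg_turn,
        segment_corr=seg_corr,
    )


# ---------------------------------------------------------------------------
# classical gait metrics


def _refine_peak(x: np.ndarray, p: int) -> float:
    """Sub-sample peak location by parabolic interpolation."""
    if p <= 0 or p >= len(x) - 1:
        return float(p)
    denom = x[p - 1] - 2 * x[p] + x[p + 1]
    if abs(denom) < 1e-12:
        return float(p)
    return p + 0.5 * (x[p - 1] - x[p + 1]) / denom


def _stride_peaks(fwd: np.ndarray, fs: float) -> np.ndarray:
    """Stride event times (s) from a paw's body-frame forward position."""
    x = fwd - _rolling_mean(fwd, int(fs))
    # dominant cadence from the spectrum, searched in the 1-6 Hz gait band
    f, p = signal.periodogram(x, fs=fs)
    band = (f >= 1.0) & (f <= 6.0)
    if not band.any() or p[band].max() <= 0:
        return np.empty(0)
    f0 = f[band][np.argmax(p[band])]
    dist = max(2, int(round(0.6 * fs / f0)))
    peaks, _ = signal.find_peaks(x, distance=dist, prominence=0.25 * x.std())
    return np.array([_refine_peak(x, pk) for pk in peaks]) / fs


def gait_metrics(skel: Skeleton3D, min_strides: int = 20) -> GaitMetrics:
    """Classical gait-regularity metrics from hindpaw stride cycles.

    Strides are peaks of the hindpaw forward position in the body frame
    (sub-sample refined).  ``stride_time_cv`` is SD/mean of left-hindpaw
    inter-stride intervals; ``step_width_cv`` the CV of the lateral hindpaw
    separation at mid-stance; ``ataxia_index`` the mean lateral deviation of
    hindpaw placements from each side's track line parallel to the body axis,
    normalized by body length;
    ``interlimb_phase_variance`` the circular variance of the left-forepaw /
    right-hindpaw phase lag across strides.  These definitions follow common
    mouse-gait conventions and are validated against the synthetic generator.
    """
    fs = FRAME_RATE
    body = skel.pos("neck") - skel.pos("anus")
    bh = body[:, :2]
    nb = np.linalg.norm(bh, axis=1)
    nb[nb < 1e-9] = 1.0
    h_hat = bh / nb[:, None]  # horizontal body axis
    n_hat = np.stack([-h_hat[:, 1], h_hat[:, 0]], axis=1)  # left normal
    body_len = float(np.median(np.linalg.norm(body, axis=1)))

    def fwd_lat(marker: str) -> tuple[np.ndarray, np.ndarray]:
        rel = (skel.pos(marker) - skel.pos("anus"))[:, :2]
        return np.einsum("ij,ij->i", rel, h_hat), np.einsum("ij,ij->i", rel, n_hat)

    lh_f, lh_l = fwd_lat("l_hindpaw")
    rh_f, rh_l = fwd_lat("r_hindpaw")
    lf_f, _ = fwd_lat("l_forepaw")

    t_lh = _stride_peaks(lh_f, fs)
    t_rh = _stride_peaks(rh_f, fs)
    t_lf = _stride_peaks(lf_f, fs)
    if len(t_lh) < min_strides + 1:
        raise InsufficientDataError(
            f"only {len(t_lh)} strides detected (< {min_strides})", n=len(t_lh)
        )
    intervals = np.diff(t_lh)
    stride_time_cv = float(intervals.std() / intervals.mean())

    # mid-stance = halfway between consecutive swing peaks
    mid = ((t_lh[:-1] + t_lh[1:]) / 2 * fs).astype(int)
    mid = mid[mid < skel.n_frames]
    widths = np.abs(lh_l[mid] - rh_l[mid])
    step_width_cv = float(widths.std() / widths.mean()) if widths.mean() > 0 else 0.0

    # lateral deviation of placements from each side's own track line
    dev_l = np.abs(lh_l[mid] - lh_l[mid].mean())
    dev_r = np.abs(rh_l[mid] - rh_l[mid].mean())
    ataxia_index = float(np.concatenate([dev_l, dev_r]).mean() / body_len)

    # LF-RH phase lag per left-forepaw stride cycle
    phases = []
    for k in range(len(t_lf) - 1):
        t0, t1 = t_lf[k], t_lf[k + 1]
        inside = t_rh[(t_rh >= t0) & (t_rh < t1)]
        if len(inside):
            phases.append(2 * np.pi * (inside[0] - t0) / (t1 - t0))
    if phases:
        z = np.exp(1j * np.asarray(phases))
        phase_var = float(1.0 - np.abs(z.mean()))
    else:
        phase_var = float("nan")
    return GaitMetrics(
        stride_time_cv=stride_time_cv,
        step_width_cv=step_width_cv,
        ataxia_index=ataxia_index,
        interlimb_phase_variance=phase_var,
        n_strides=len(intervals),
    )


# ---------------------------------------------------------------------------
# I/O


def save_skeleton(skel: Skeleton3D, path: str | Path) -> None:
    """Wide CSV (t_s then x/y/z per marker, fixed order) or HDF5 mirror."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            f.create_dataset("t_s", data=skel.t)
            f.create_dataset("xyz_cm", data=skel.xyz)
            f.attrs["markers"] = json.dumps(list(MARKERS))
            f.attrs["arena_cm"] = list(skel.arena_cm)
            f.attrs["meta"] = json.dumps(skel.meta)
    else:
        data = {"t_s": skel.t}
        for i, m in enumerate(MARKERS):
            for j, ax in enumerate("xyz"):
                data[f"{m}_{ax}"] = skel.xyz[:, i, j]
        pd.DataFrame(data).to_csv(path, index=False)


def load_skeleton(path: str | Path, arena_cm=(20.0, 20.0, 30.0)) -> Skeleton3D:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            t = f["t_s"][:]
            xyz = f["xyz_cm"][:]
            arena = tuple(f.attrs["arena_cm"])
            meta = json.loads(f.attrs["meta"])
        return Skeleton3D(t=t, xyz=xyz, arena_cm=arena, meta=meta)
    df = pd.read_csv(path)
    t = df["t_s"].to_numpy()
    xyz = np.stack(
        [
            np.stack([df[f"{m}_{ax}"].to_numpy() for ax in "xyz"], axis=1)
            for m in MARKERS
        ],
        axis=1,
    )
    return Skeleton3D(t=t, xyz=xyz, arena_cm=arena_cm)
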