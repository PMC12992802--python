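"""Pharmacological decomposition of tonic GABA_A currents.

Whole-cell holding-current traces from cerebellar granule cells are decomposed
into pharmacologically defined components: the tonic current is the baseline
shift upon gabazine (GBZ), and the TTX-sensitive (spillover) vs TTX-insensitive
(nonsynaptic) parts are read off the sequential drug applications
(TTX -> GBZ, optionally preceded by the GAT blocker NPA).

Sign convention: holding current is inward-negative; blocking an inward tonic
current shifts the baseline in the positive (outward) direction, and that
positive shift is reported as the tonic-current magnitude.

Baselines are estimated as the mode of a Gaussian fitted to the all-point
histogram of a window, which is robust against the inward sIPSC transients
riding on the trace.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd
from scipy import ndimage, optimize, signal, stats

__all__ = [
    "TraceRecording",
    "TonicDecomposition",
    "IPSCEventSet",
    "ReversalEstimate",
    "WindowingError",
    "ProtocolError",
    "drug_shift",
    "decompose_tonic",
    "detect_ipscs",
    "fit_freq_current_regression",
    "reversal_from_iv",
    "estimate_exgaba",
    "save_trace",
    "load_trace",
    "PROTOCOLS",
]

#: Settling margin after each drug application, seconds.  Wash-in of a bath
#: drug is gradual; baselines are only read this long after an event.
DEFAULT_SETTLE_S = 60.0
#: Default baseline window length, seconds.
DEFAULT_WINDOW_S = 30.0

#: Ordered drug events per named protocol.  The first transition label always
#: starts from "base".
PROTOCOLS = {
    "ttx-gbz": ("TTX", "GBZ"),
    "npa-ttx-gbz": ("NPA", "TTX", "GBZ"),
}


class WindowingError(ValueError):
    """A baseline window overlaps a drug event or leaves the trace."""


class ProtocolError(ValueError):
    """Trace events do not match the requested protocol."""


@dataclass
class TraceRecording:
    """A sampled holding-current trace with drug-application annotations.

    Attributes
    ----------
    t : array of float
        Sample times in seconds, uniformly spaced.
    I : array of float
        Holding current in pA (inward currents negative).
    events : list of (label, time) tuples
        Drug applications, sorted by time, labels unique.
    meta : dict
        Free-form condition labels (age, genotype, protocol...).
    """

    t: np.ndarray
    I: np.ndarray
    events: list[tuple[str, float]] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.I = np.asarray(self.I, dtype=float)
        if self.t.ndim != 1 or self.t.shape != self.I.shape:
            raise ValueError("t and I must be 1-D arrays of equal length")
        if len(self.t) > 2:
            dt = np.diff(self.t)
            if dt.min() <= 0:
                raise ValueError("t must be strictly increasing")
            if (dt.max() - dt.min()) > 1e-6 * dt.mean():
                raise ValueError("t must be uniform to within 1 ppm")
        times = [tv for _, tv in self.events]
        labels = [lb for lb, _ in self.events]
        if sorted(times) != times:
            raise ValueError("events must be sorted by time")
        if len(set(labels)) != len(labels):
            raise ValueError("event labels must be unique")

    @property
    def rate(self) -> float:
        """Sampling rate, Hz."""
        return 1.0 / (self.t[1] - self.t[0])

    def event_time(self, label: str) -> float:
        for lb, tv in self.events:
            if lb == label:
                return tv
        raise ProtocolError(f"no event labelled {label!r} in trace")


@dataclass
class TonicDecomposition:
    """Tonic-current components of one trace, all in pA.

    ``ttx_sensitive_pA + ttx_insensitive_pA == total_tonic_pA`` holds exactly
    by construction.  ``ttx_sensitive_fraction`` is NaN (and ``fraction_defined``
    False) when the total is not positive.  Negative components are reported
    as-is with ``negative_components`` listing them; near-zero TTX shifts do
    occur in adult recordings and clipping them would bias group means.
    """

    shifts: dict[str, float]
    total_tonic_pA: float
    ttx_sensitive_pA: float
    ttx_insensitive_pA: float
    ttx_sensitive_fraction: float
    fraction_defined: bool
    negative_components: tuple[str, ...] = ()

    def to_row(self) -> dict:
        row = dict(self.shifts)
        row.update(
            total_tonic_pA=self.total_tonic_pA,
            ttx_sensitive_pA=self.ttx_sensitive_pA,
            ttx_insensitive_pA=self.ttx_insensitive_pA,
            ttx_sensitive_fraction=self.ttx_sensitive_fraction,
        )
        return row


@dataclass
class IPSCEventSet:
    """Detected spontaneous IPSCs: times (s) and positive amplitudes (pA)."""

    times: np.ndarray
    amplitudes: np.ndarray
    frequency_Hz: float
    mean_amplitude_pA: float


@dataclass
class ReversalEstimate:
    """Extrasynaptic GABA_A reversal from cell-attached measurements.

    Convention: ``DF == Vm - E`` (a depolarizing driving force is positive),
    so ``E_xGABA = Vm - DF``.
    """

    Vm_mV: float
    DF_mV: float
    E_xGABA_mV: float


# ---------------------------------------------------------------------------
# baseline estimation


def _gaussian_mode(x: np.ndarray) -> float:
    """Mode of a Gaussian fitted to the all-point histogram of ``x``.

    Falls back to the median for (near-)constant windows where a fit is
    degenerate.
    """
    x = np.asarray(x, dtype=float)
    med = np.median(x)
    mad = stats.median_abs_deviation(x)
    if mad < 1e-12:
        return float(med)
    sd0 = 1.4826 * mad
    lo, hi = med - 5 * sd0, med + 5 * sd0
    nbins = 80
    counts, edges = np.histogram(x[(x >= lo) & (x <= hi)], bins=nbins)
    centers = 0.5 * (edges[:-1] + edges[1:])

    def gauss(v, a, mu, s):
        return a * np.exp(-0.5 * ((v - mu) / s) ** 2)

    p0 = (counts.max(), centers[np.argmax(counts)], sd0)
    try:
        popt, _ = optimize.curve_fit(gauss, centers, counts, p0=p0, maxfev=2000)
        mu = float(popt[1])
    except RuntimeError:  # pragma: no cover - pathological windows
        mu = float(med)
    if not (lo <= mu <= hi):
        mu = float(med)
    return mu


def _window_slice(trace: TraceRecording, start: float, stop: float) -> np.ndarray:
    if start < trace.t[0] - 1e-9 or stop > trace.t[-1] + 1e-9:
        raise WindowingError(
            f"window [{start:.1f}, {stop:.1f}] s extends past the trace"
        )
    for lb, tv in trace.events:
        if start < tv < stop:
            raise WindowingError(
                f"window [{start:.1f}, {stop:.1f}] s overlaps event {lb!r} at {tv:.1f} s"
            )
    i0, i1 = np.searchsorted(trace.t, [start, stop])
    return trace.I[i0:i1]


def drug_shift(
    trace: TraceRecording,
    transition: tuple[str, str] | str,
    pre_window: float = DEFAULT_WINDOW_S,
    post_window: float = DEFAULT_WINDOW_S,
    settle: float = DEFAULT_SETTLE_S,
) -> float:
    """Baseline shift (pA) across one drug application.

    ``transition`` is a ``(from, to)`` label pair (or ``"from->to"`` string);
    the shift is measured at the event introducing the ``to`` drug.  The pre
    window is the ``pre_window`` seconds immediately before that event (it must
    start at least ``settle`` seconds after the previous event), the post
    window starts ``settle`` seconds after the event.  Returns
    ``baseline(post) - baseline(pre)``, positive for an outward shift.
    """
    if isinstance(transition, str):
        pre_label, post_label = transition.split("->")
    else:
        pre_label, post_label = transition
    t_ev = trace.event_time(post_label)
    if pre_label == "base":
        t_prev = trace.t[0]
        pre_start_min = t_prev
    else:
        t_prev = trace.event_time(pre_label)
        pre_start_min = t_prev + settle
    pre_stop = t_ev
    pre_start = pre_stop - pre_window
    if pre_start < pre_start_min - 1e-9:
        raise WindowingError(
            f"pre window for {pre_label}->{post_label} would enter the settling "
            f"margin of the previous event"
        )
    post_start = t_ev + settle
    post_stop = post_start + post_window
    later = [tv for _, tv in trace.events if tv > t_ev]
    if later and post_stop > min(later):
        raise WindowingError(
            f"post window for {pre_label}->{post_label} overlaps the next event"
        )
    pre = _gaussian_mode(_window_slice(trace, pre_start, pre_stop))
    post = _gaussian_mode(_window_slice(trace, post_start, post_stop))
    return float(post - pre)


def decompose_tonic(
    trace: TraceRecording,
    protocol: str = "ttx-gbz",
    pre_window: float = DEFAULT_WINDOW_S,
    post_window: float = DEFAULT_WINDOW_S,
    settle: float = DEFAULT_SETTLE_S,
) -> TonicDecomposition:
    """Decompose a trace into TTX-sensitive and TTX-insensitive tonic current.

    For ``"ttx-gbz"`` the TTX-sensitive component is the base->TTX shift and
    the TTX-insensitive component the TTX->GBZ shift; for ``"npa-ttx-gbz"``
    the same two transitions are read under NPA (the base->NPA shift is also
    reported in ``shifts`` but the tonic current under GAT blockade is
    NPA->GBZ).  The total is the sum of the two components, so additivity is
    exact by construction.
    """
    if protocol not in PROTOCOLS:
        raise ProtocolError(f"unknown protocol {protocol!r}; use one of {list(PROTOCOLS)}")
    drugs = PROTOCOLS[protocol]
    present = [lb for lb, _ in trace.events]
    if [d for d in drugs if d in present] != list(drugs):
        raise ProtocolError(
            f"protocol {protocol!r} requires events {drugs} in order; trace has {present}"
        )
    labels = ("base",) + drugs
    shifts: dict[str, float] = {}
    for a, b in zip(labels[:-1], labels[1:]):
        shifts[f"{a}->{b}"] = drug_shift(
            trace, (a, b), pre_window, post_window, settle
        )
    if protocol == "ttx-gbz":
        sens = shifts["base->TTX"]
        insens = shifts["TTX->GBZ"]
    else:
        sens = shifts["NPA->TTX"]
        insens = shifts["TTX->GBZ"]
    total = sens + insens
    negative = tuple(
        name
        for name, val in (("ttx_sensitive", sens), ("ttx_insensitive", insens))
        if val < 0
    )
    defined = total > 0
    frac = sens / total if defined else float("nan")
    return TonicDecomposition(
        shifts=shifts,
        total_tonic_pA=total,
        ttx_sensitive_pA=sens,
        ttx_insensitive_pA=insens,
        ttx_sensitive_fraction=frac,
        fraction_defined=bool(defined),
        negative_components=negative,
    )


# ---------------------------------------------------------------------------
# sIPSC detection


def detect_ipscs(
    trace: TraceRecording,
    window: tuple[float, float] | None = None,
    tau_ms: float = 10.0,
    threshold_mad: float = 4.5,
    merge_ms: float = 5.0,
) -> IPSCEventSet:
    """Detect spontaneous IPSCs by matched filtering.

    The trace (restricted to ``window``, which must end before any GABA_A
    blockade) is high-pass detrended and convolved with the canonical IPSC
    template (instantaneous rise, single-exponential decay ``tau_ms``).
    Detections exceed ``threshold_mad`` robust SDs of the filtered signal and
    are merged when closer than ``merge_ms``.  Amplitudes are the peak inward
    deviation from the local baseline, reported positive.
    """
    gbz = [tv for lb, tv in trace.events if lb == "GBZ"]
    if window is None:
        stop = min(gbz) if gbz else trace.t[-1]
        window = (trace.t[0], stop)
    if gbz and window[1] > min(gbz) + 1e-9:
        raise ProtocolError("IPSC window must precede GABA_A blockade (GBZ)")
    i0, i1 = np.searchsorted(trace.t, window)
    t = trace.t[i0:i1]
    x = trace.I[i0:i1]
    if len(x) < 10:
        return IPSCEventSet(np.empty(0), np.empty(0), 0.0, float("nan"))
    dt = t[1] - t[0]
    # remove slow baseline (drug steps, drift) with a long median filter
    k = int(round(1.0 / dt)) | 1
    base = ndimage.median_filter(x, size=min(k, len(x)), mode="nearest")
    r = x - base
    # matched filter: template is the inward (negative) IPSC shape
    n_tpl = max(3, int(round(5 * tau_ms / 1000.0 / dt)))
    tpl = -np.exp(-np.arange(n_tpl) * dt / (tau_ms / 1000.0))
    tpl /= np.linalg.norm(tpl)
    # cross-correlation aligned so score[i] scores an event with onset at i
    score = signal.fftconvolve(r, tpl[::-1], mode="full")[n_tpl - 1 : n_tpl - 1 + len(r)]
    mad = stats.median_abs_deviation(score)
    if mad < 1e-12:
        return IPSCEventSet(np.empty(0), np.empty(0), 0.0, float("nan"))
    thr = np.median(score) + threshold_mad * 1.4826 * mad
    min_dist = max(1, int(round(merge_ms / 1000.0 / dt)))
    peaks, _ = signal.find_peaks(score, height=thr, distance=min_dist)
    # the running-median baseline is ill-defined within half a kernel of the
    # window edges; detections there are unreliable and dropped
    guard = k // 2
    peaks = peaks[(peaks >= guard) & (peaks < len(r) - guard)]
    if len(peaks) == 0:
        return IPSCEventSet(np.empty(0), np.empty(0), 0.0, float("nan"))
    # amplitude: most-negative residual within one tau around the peak
    half = max(1, int(round(tau_ms / 1000.0 / dt)))
    amps = np.empty(len(peaks))
    times = np.empty(len(peaks))
    for j, p in enumerate(peaks):
        lo = max(0, p - half)
        hi = min(len(r), p + half + 1)
        i_min = lo + int(np.argmin(r[lo:hi]))
        amps[j] = -r[i_min]
        times[j] = t[i_min]
    times, uniq = np.unique(times, return_index=True)
    amps = amps[uniq]
    dur = window[1] - window[0]
    return IPSCEventSet(
        times=times,
        amplitudes=amps,
        frequency_Hz=len(times) / dur,
        mean_amplitude_pA=float(amps.mean()),
    )


# ---------------------------------------------------------------------------
# regression and reversal


def fit_freq_current_regression(
    points: Sequence[tuple[float, float]],
) -> tuple[float, float, float, float]:
    """OLS of baseline shift (pA) on sIPSC frequency (Hz).

    Returns ``(slope, intercept, r_squared, p)`` with a two-sided p-value for
    the zero-slope null.  Raises ``ValueError`` for fewer than 3 points or a
    degenerate (constant) predictor.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or len(pts) < 3:
        raise ValueError("need at least 3 (frequency, shift) points")
    x, y = pts[:, 0], pts[:, 1]
    if np.ptp(x) == 0:
        raise ValueError("degenerate regression: all frequencies equal")
    if np.ptp(y) == 0:  # constant response: no variance to explain
        return 0.0, float(y[0]), 0.0, 1.0
    res = stats.linregress(x, y)
    return (
        float(res.slope),
        float(res.intercept),
        float(res.rvalue**2),
        float(res.pvalue),
    )


def reversal_from_iv(iv: Sequence[tuple[float, float]]) -> float:
    """Zero-crossing potential (mV) of a sampled I-V relation.

    Linear interpolation between the samples bracketing the sign change; with
    multiple crossings (noise) the one nearest the median sampled potential is
    used.  Raises ``ValueError`` if the current never changes sign.
    """
    arr = np.asarray(iv, dtype=float)
    order = np.argsort(arr[:, 0])
    v, i = arr[order, 0], arr[order, 1]
    s = np.sign(i)
    crossings = []
    for k in range(len(v) - 1):
        if s[k] == 0:
            crossings.append(v[k])
        elif s[k] * s[k + 1] < 0:
            frac = i[k] / (i[k] - i[k + 1])
            crossings.append(v[k] + frac * (v[k + 1] - v[k]))
    if s[-1] == 0:
        crossings.append(v[-1])
    if not crossings:
        raise ValueError("current does not change sign over the sampled range")
    v_med = np.median(v)
    return float(min(crossings, key=lambda c: abs(c - v_med)))


def estimate_exgaba(
    Vm_mV: float, DF_mV: float, df_convention: str = "vm_minus_e"
) -> ReversalEstimate:
    """Combine resting potential and THIP driving force into E_xGABA.

    The default convention is ``DF == Vm - E`` (depolarizing driving force
    positive), giving ``E = Vm - DF``.  Pass ``df_convention="e_minus_vm"``
    if the driving force was tabulated with the opposite sign.
    """
    if not (np.isfinite(Vm_mV) and np.isfinite(DF_mV)):
        raise ValueError("Vm and DF must be finite")
    if df_convention == "vm_minus_e":
        e = Vm_mV - DF_mV
    elif df_convention == "e_minus_vm":
        e = Vm_mV + DF_mV
    else:
        raise ValueError("df_convention must be 'vm_minus_e' or 'e_minus_vm'")
    return ReversalEstimate(Vm_mV=float(Vm_mV), DF_mV=float(DF_mV), E_xGABA_mV=float(e))


# ---------------------------------------------------------------------------
# I/O


def save_trace(trace: TraceRecording, path: str | Path) -> None:
    """Write a trace as CSV (t_s, I_pA) + sidecar JSON, or as HDF5 (.h5)."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            f.create_dataset("t_s", data=trace.t)
            f.create_dataset("I_pA", data=trace.I)
            ev = f.create_group("events")
            ev.attrs["labels"] = json.dumps([lb for lb, _ in trace.events])
            ev.create_dataset("times", data=np.array([tv for _, tv in trace.events]))
            f.attrs["meta"] = json.dumps(trace.meta)
    else:
        pd.DataFrame({"t_s": trace.t, "I_pA": trace.I}).to_csv(path, index=False)
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(
            json.dumps({"events": trace.events, "meta": trace.meta}, indent=1)
        )


def load_trace(path: str | Path) -> TraceRecording:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            t = f["t_s"][:]
            cur = f["I_pA"][:]
            labels = json.loads(f["events"].attrs["labels"])
            times = f["events"]["times"][:]
            meta = json.loads(f.attrs["meta"])
        events = list(zip(labels, times.tolist()))
    else:
        df = pd.read_csv(path)
        t, cur = df["t_s"].to_numpy(), df["I_pA"].to_numpy()
        sidecar = path.with_suffix(path.suffix + ".json")
        events, meta = [], {}
        if sidecar.exists():
            side = json.loads(sidecar.read_text())
            events = [tuple(e) for e in side.get("events", [])]
            meta = side.get("meta", {})
    return TraceRecording(t=t, I=cur, events=events, meta=meta)
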