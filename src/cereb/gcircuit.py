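"""Condition parameter sets and the stochastic GoC->GC inhibitory synapse.

The four experimental conditions (age x genotype) are encoded as canonical
parameter sets: GoC->GC convergence, per-synapse release rates, the
activity-independent (Best1-like) tonic conductance, the spillover gain and
the extrasynaptic reversal potential.  The synapse model releases
probabilistically on presynaptic spikes and adds an independent Poisson
miniature process; every release event feeds a slowly decaying spillover
conductance on top of the constant tonic term (the two-source tonic model).

The convergence-estimation procedure inverts the model: it finds the smallest
number of synapses whose simulated mean tonic current in a voltage-clamped GC
reaches an experimentally measured target.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np
from scipy import signal

from . import params

__all__ = [
    "ConditionConfig",
    "ReleaseTrain",
    "ConfigurationError",
    "ConvergenceError",
    "condition_config",
    "condition_names",
    "sample_goc_gc_release",
    "tonic_conductance_trace",
    "mean_tonic_conductance",
    "estimate_required_convergence",
    "YOUNG_WT_TTX_INSENSITIVE_PA",
    "YOUNG_KO_TTX_INSENSITIVE_PA",
]

#: Printed group means of the TTX-insensitive tonic current (pA), young WT vs
#: young Best1-KO; their ratio fixes the KO's residual activity-independent
#: conductance (a ~75.4% loss).
YOUNG_WT_TTX_INSENSITIVE_PA = 8.16
YOUNG_KO_TTX_INSENSITIVE_PA = 2.01


class ConfigurationError(ValueError):
    pass


class ConvergenceError(RuntimeError):
    pass


@dataclass(frozen=True)
class ConditionConfig:
    """One age x genotype parameter set for granule-cell inhibition."""

    name: str
    age: str  # "young" | "adult"
    genotype: str  # "WT" | "Best1KO"
    goc_convergence_mean: float  # mean GoC inputs per GC
    spont_release_rate_Hz: float  # per-synapse miniature rate
    evoked_release_prob: float  # release probability per presynaptic spike
    g_tonic_const_nS: float  # activity-independent (Best1-like) conductance
    spill_gain_nS_per_event: float  # spillover increment per release
    spill_tau_ms: float  # spillover decay
    E_xGABA_mV: float  # extrasynaptic GABA_A reversal
    k_current_gain: float  # homeostatic outward-K+ leak scale (>= 1)
    background_goc_rate_Hz: float  # GoC rate assumed for calibration


@dataclass
class ReleaseTrain:
    """GABA release events: sorted times (s) and source synapse indices."""

    times: np.ndarray
    source_synapse: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.source_synapse = np.asarray(self.source_synapse, dtype=np.int64)
        if np.any(np.diff(self.times) < 0):
            raise ValueError("release times must be sorted")


def _load_table() -> dict:
    with resources.files("cereb.data").joinpath("conditions.json").open() as f:
        return json.load(f)


_TABLE = _load_table()


def condition_names() -> tuple[str, ...]:
    return tuple(_TABLE["conditions"])


def mean_tonic_conductance(cfg: ConditionConfig, goc_rate_Hz: float | None = None) -> float:
    """Expected tonic conductance (nS): constant term + stationary spillover.

    By Campbell's theorem the spillover mean is
    N * (spont + goc_rate * p_release) * gain * tau.
    """
    rate = cfg.background_goc_rate_Hz if goc_rate_Hz is None else goc_rate_Hz
    lam = cfg.goc_convergence_mean * (
        cfg.spont_release_rate_Hz + rate * cfg.evoked_release_prob
    )
    return cfg.g_tonic_const_nS + lam * cfg.spill_gain_nS_per_event * (
        cfg.spill_tau_ms / 1000.0
    )


def condition_config(age: str, genotype: str) -> ConditionConfig:
    """Canonical parameter set for one condition.

    ``age`` is ``young`` or ``adult``; ``genotype`` ``WT`` or ``Best1KO``
    (``KO`` accepted).  The homeostatic K+ gain of the KO configs is
    calibrated at load so the GC rheobase matches the same-age WT.
    """
    genotype = {"ko": "Best1KO", "best1ko": "Best1KO", "wt": "WT"}.get(
        genotype.lower(), genotype
    )
    name = f"{age}-{'ko' if genotype == 'Best1KO' else 'wt'}".lower()
    if name not in _TABLE["conditions"] or age not in ("young", "adult"):
        raise ConfigurationError(
            f"unknown condition {age!r}/{genotype!r}; known: {condition_names()}"
        )
    shared = _TABLE["shared"]
    raw = _TABLE["conditions"][name]

    def build(nm: str, k_gain: float) -> ConditionConfig:
        r = _TABLE["conditions"][nm]
        return ConditionConfig(
            name=nm,
            age=r["age"],
            genotype=r["genotype"],
            goc_convergence_mean=float(r["goc_convergence_mean"]),
            spont_release_rate_Hz=float(r["spont_release_rate_Hz"]),
            evoked_release_prob=float(shared["evoked_release_prob"]),
            g_tonic_const_nS=float(r["g_tonic_const_nS"]),
            spill_gain_nS_per_event=float(shared["spill_gain_nS_per_event"]),
            spill_tau_ms=float(shared["spill_tau_ms"]),
            E_xGABA_mV=float(r["E_xGABA_mV"]),
            k_current_gain=k_gain,
            background_goc_rate_Hz=float(shared["background_goc_rate_Hz"]),
        )

    if raw["genotype"] == "WT":
        return build(name, 1.0)
    wt = build(f"{age}-wt", 1.0)
    ko = build(name, 1.0)
    k = params.homeostatic_k_gain(
        mean_tonic_conductance(wt), mean_tonic_conductance(ko), ko.E_xGABA_mV
    )
    return build(name, max(1.0, k))


def sample_goc_gc_release(
    presyn_spikes: list[np.ndarray],
    cfg: ConditionConfig,
    duration: float,
    seed: int = 0,
) -> ReleaseTrain:
    """Stochastic release from a set of GoC->GC synapses onto one GC.

    Each presynaptic spike releases independently with
    ``cfg.evoked_release_prob``; an independent homogeneous Poisson process at
    ``cfg.spont_release_rate_Hz`` per synapse adds miniature events.  The
    union is returned sorted by time.
    """
    rng = np.random.default_rng(seed)
    times: list[np.ndarray] = []
    srcs: list[np.ndarray] = []
    for s, spk in enumerate(presyn_spikes):
        spk = np.asarray(spk, dtype=float)
        if len(spk) and (spk.min() < 0 or spk.max() > duration):
            raise ValueError("presynaptic spikes must lie within the duration")
        if cfg.evoked_release_prob > 0 and len(spk):
            keep = rng.random(len(spk)) < cfg.evoked_release_prob
            times.append(spk[keep])
            srcs.append(np.full(int(keep.sum()), s, dtype=np.int64))
        n_mini = rng.poisson(cfg.spont_release_rate_Hz * duration)
        if n_mini:
            times.append(rng.uniform(0.0, duration, n_mini))
            srcs.append(np.full(n_mini, s, dtype=np.int64))
    if not times:
        return ReleaseTrain(np.empty(0), np.empty(0, dtype=np.int64))
    t = np.concatenate(times)
    s_idx = np.concatenate(srcs)
    order = np.argsort(t, kind="stable")
    return ReleaseTrain(t[order], s_idx[order])


def tonic_conductance_trace(
    releases: ReleaseTrain,
    cfg: ConditionConfig,
    dt_ms: float,
    duration: float,
) -> np.ndarray:
    """Tonic conductance g(t) in nS on a uniform grid of step ``dt_ms``.

    g(t) = g_const + sum over release events of gain * exp(-(t - t_e)/tau).
    Events are binned to the grid (an event contributes from the start of its
    bin), so ``dt_ms`` must be at most tau/10.
    """
    if dt_ms > cfg.spill_tau_ms / 10.0 + 1e-12:
        raise ValueError("dt must be <= spill_tau/10")
    dt_s = dt_ms / 1000.0
    n = int(round(duration / dt_s))
    idx = np.minimum((releases.times / dt_s).astype(np.int64), n - 1)
    counts = np.bincount(idx, minlength=n).astype(float)
    decay = np.exp(-dt_ms / cfg.spill_tau_ms)
    spill = signal.lfilter([cfg.spill_gain_nS_per_event], [1.0, -decay], counts)
    return cfg.g_tonic_const_nS + spill


def _mean_tonic_current_sim(
    cfg: ConditionConfig,
    n_syn: int,
    holding_mV: float,
    seed: int,
    duration: float,
    goc_rate_Hz: float,
    dt_ms: float = 10.0,
) -> float:
    """Simulated mean GBZ-sensitive current (pA) for one synapse count."""
    rng = np.random.default_rng([seed, n_syn])
    presyn = []
    for _ in range(n_syn):
        n_spk = rng.poisson(goc_rate_Hz * duration)
        presyn.append(np.sort(rng.uniform(0.0, duration, n_spk)))
    rel = sample_goc_gc_release(
        presyn, cfg, duration, seed=int(rng.integers(2**31))
    )
    g = tonic_conductance_trace(rel, cfg, dt_ms, duration)
    burn = int(5 * cfg.spill_tau_ms / dt_ms)
    df = holding_mV - cfg.E_xGABA_mV
    return float(g[burn:].mean() * df)


def estimate_required_convergence(
    cfg: ConditionConfig,
    target_tonic_pA: float,
    holding_mV: float,
    seed: int = 0,
    duration: float = 300.0,
    goc_rate_Hz: float | None = None,
    n_max: int = 1024,
) -> int:
    """Smallest synapse count whose mean tonic current reaches a target.

    A single voltage-clamped GC at ``holding_mV`` receives N stochastic
    synapses driven by GoCs firing at the background rate; the mean
    GBZ-sensitive current is ``mean(g) * (holding - E_xGABA)``.  The search
    doubles N until the target is reached, then bisects.  The per-N estimate
    is deterministic in ``(seed, N)`` so repeated queries are consistent.
    ``cfg.goc_convergence_mean`` is ignored — it is the answer being sought.
    """
    if target_tonic_pA <= 0:
        raise ValueError("target current must be positive")
    df = holding_mV - cfg.E_xGABA_mV
    if df <= 0:
        raise ConvergenceError(
            f"no outward tonic current at {holding_mV} mV with E_xGABA = "
            f"{cfg.E_xGABA_mV} mV"
        )
    rate = cfg.background_goc_rate_Hz if goc_rate_Hz is None else goc_rate_Hz

    def mean_current(n: int) -> float:
        return _mean_tonic_current_sim(cfg, n, holding_mV, seed, duration, rate)

    if mean_current(1) >= target_tonic_pA:
        return 1
    lo, hi = 1, 2
    while mean_current(hi) < target_tonic_pA:
        lo, hi = hi, hi * 2
        if hi > n_max:
            raise ConvergenceError(
                f"target {target_tonic_pA} pA unreachable with <= {n_max} synapses"
            )
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if mean_current(mid) >= target_tonic_pA:
            hi = mid
        else:
            lo = mid
    return hi
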