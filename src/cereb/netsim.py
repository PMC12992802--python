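"""Density-faithful, size-scalable granular-layer network simulation.

The full-scale sheet is a 1.5 mm x 0.7 mm region of granular layer holding
~0.8 million granule cells (GCs), 2000 Golgi cells (GoCs) and 2000 mossy
fiber (MF) glomeruli.  A linear ``scale`` shrinks the sheet; counts scale
with area.  GCs are conductance-based leaky integrate-and-fire cells with
excitatory MF synapses, stochastic GoC inhibition (phasic + spillover tonic,
see :mod:`cereb.gcircuit`) and a condition-dependent tonic conductance; GoCs
are intrinsic pacemakers excited by parallel fibers (PFs).  Rate-modulated
MF input is delivered to a spatial zone, driving an ON cluster of GCs whose
PF feedback onto GoCs both patterns OFF-zone GCs and generates fast network
oscillations.

Integration is exponential-Euler at 0.05 ms with a single seeded RNG stream
and a fixed cell iteration order inside one compiled kernel, so rasters are
bit-reproducible per seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.spatial import cKDTree

from . import params
from .gcircuit import ConditionConfig, condition_config

log = logging.getLogger(__name__)

__all__ = [
    "FULL_DIMS_MM",
    "FULL_COUNTS",
    "NetworkGeometry",
    "Connectivity",
    "InputProtocol",
    "SpikeData",
    "SimResult",
    "GeometryError",
    "ConnectivityError",
    "IntegrationError",
    "build_geometry",
    "build_connectivity",
    "make_mf_input",
    "default_protocol",
    "simulate",
    "run_condition",
    "rheobase_current",
    "first_spike_latency",
]

FULL_DIMS_MM = (1.5, 0.7)
FULL_COUNTS = {"GC": 800_000, "GoC": 2000, "MF": 2000}
#: Minimum GoC/MF populations at small scales: area scaling alone would leave
#: too few cells to sustain the feedback loop or structure the input zone, so
#: their density is boosted to keep at least this many (logged when applied).
#: The MF floor also keeps the shot noise of the pooled input drive small
#: relative to network-generated rate fluctuations.
MIN_COUNTS = {"GoC": 50, "MF": 500}


class GeometryError(ValueError):
    pass


class ConnectivityError(ValueError):
    pass


class IntegrationError(RuntimeError):
    pass


@dataclass
class NetworkGeometry:
    """Cell positions (mm) on the scaled granular-layer sheet."""

    dims_mm: tuple[float, float]
    scale: float
    gc_pos: np.ndarray
    goc_pos: np.ndarray
    mf_pos: np.ndarray

    @property
    def n_gc(self) -> int:
        return len(self.gc_pos)

    @property
    def n_goc(self) -> int:
        return len(self.goc_pos)

    @property
    def n_mf(self) -> int:
        return len(self.mf_pos)

    @property
    def counts(self) -> dict[str, int]:
        return {"GC": self.n_gc, "GoC": self.n_goc, "MF": self.n_mf}


@dataclass
class Connectivity:
    """Edge lists (target-major pairs of index arrays) plus PF delays (ms)."""

    mf_to_gc: tuple[np.ndarray, np.ndarray]  # (gc_idx, mf_idx)
    goc_to_gc: tuple[np.ndarray, np.ndarray]  # (gc_idx, goc_idx)
    gc_to_goc: tuple[np.ndarray, np.ndarray]  # (goc_idx, gc_idx)
    pf_delay_ms: np.ndarray  # per gc_to_goc edge
    geometry: NetworkGeometry

    def mean_goc_in_degree(self) -> float:
        return len(self.goc_to_gc[0]) / self.geometry.n_gc


@dataclass
class InputProtocol:
    """Localized rate-modulated MF drive.

    In-zone MFs fire as an inhomogeneous Poisson process with
    r(t) = baseline * (1 + depth * sin(2 pi f t)); out-of-zone MFs fire
    homogeneously at the baseline rate.
    """

    zone: tuple[tuple[float, float], tuple[float, float]]  # ((x0,x1),(y0,y1)) mm
    baseline_rate_Hz: float = 20.0
    modulation_depth: float = 0.8
    modulation_freq_Hz: float = 2.0
    duration: float = 10.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.modulation_depth <= 1.0:
            raise ValueError("modulation depth must be in [0, 1]")


@dataclass
class SpikeData:
    """Spike events of one population, sorted by time."""

    cells: np.ndarray
    times: np.ndarray
    n_cells: int
    duration: float
    population: str = ""

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype=np.int64)
        self.times = np.asarray(self.times, dtype=float)
        if len(self.times) and (self.times.min() < 0 or self.times.max() > self.duration + 1e-9):
            raise ValueError("spike times must lie within [0, duration]")

    def for_cell(self, i: int) -> np.ndarray:
        return np.sort(self.times[self.cells == i])

    def rate_per_cell_Hz(self) -> float:
        return len(self.times) / (self.n_cells * self.duration)


@dataclass
class SimResult:
    gc: SpikeData
    goc: SpikeData
    mf: SpikeData
    geometry: NetworkGeometry
    conn: Connectivity
    protocol: InputProtocol
    cfg: ConditionConfig
    duration: float
    meta: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# geometry & connectivity


def build_geometry(scale: float, seed: int = 0) -> NetworkGeometry:
    """Scaled sheet with uniformly placed cells; counts scale with area."""
    if not 0 < scale <= 1:
        raise ValueError("scale must be in (0, 1]")
    dims = (FULL_DIMS_MM[0] * scale, FULL_DIMS_MM[1] * scale)
    counts = {}
    for pop, full in FULL_COUNTS.items():
        c = int(round(full * scale**2))
        if pop in MIN_COUNTS and c < MIN_COUNTS[pop]:
            boosted = min(MIN_COUNTS[pop], full)
            log.info(
                "%s count %d at scale %.3g below floor; density-boosted to %d",
                pop, c, scale, boosted,
            )
            c = boosted
        counts[pop] = c
    if min(counts.values()) < 10:
        raise GeometryError(f"degenerate geometry at scale {scale}: counts {counts}")
    rng = np.random.default_rng(seed)
    pos = {
        pop: rng.uniform([0, 0], dims, size=(counts[pop], 2))
        for pop in ("GC", "GoC", "MF")
    }
    return NetworkGeometry(
        dims_mm=dims, scale=scale,
        gc_pos=pos["GC"], goc_pos=pos["GoC"], mf_pos=pos["MF"],
    )


def build_connectivity(
    geom: NetworkGeometry,
    cfg: ConditionConfig,
    seed: int = 0,
    dendritic_radius_mm: float = 0.05,
    goc_axon_sigma_mm: float = 0.1,
    pf_reach_mm: float = 0.03,
) -> Connectivity:
    """Wire the network.

    MF->GC: each GC takes its 4 nearest distinct glomeruli, all of which must
    lie within the dendritic radius.  GoC->GC: each GC draws a
    Poisson(convergence) number of presynaptic GoCs without replacement,
    weighted by a Gaussian of somatic distance.  GC->GoC (PF): a GC contacts
    every GoC whose sagittal band its parallel fiber crosses, with a
    conduction delay growing with mediolateral distance.
    """
    rng = np.random.default_rng(seed)
    n_gc, n_goc = geom.n_gc, geom.n_goc

    tree = cKDTree(geom.mf_pos)
    dist, mf_idx = tree.query(geom.gc_pos, k=4)
    if np.any(dist[:, -1] > dendritic_radius_mm):
        bad = int(np.argmax(dist[:, -1]))
        raise ConnectivityError(
            f"GC {bad} cannot reach 4 glomeruli within {dendritic_radius_mm} mm"
        )
    mf_gc = (np.repeat(np.arange(n_gc), 4), mf_idx.ravel().astype(np.int64))

    # GoC -> GC, proximity-weighted sampling without replacement
    d2 = (
        (geom.gc_pos[:, None, :] - geom.goc_pos[None, :, :]) ** 2
    ).sum(axis=2)
    w = np.exp(-d2 / (2 * goc_axon_sigma_mm**2))
    k_draw = np.minimum(rng.poisson(cfg.goc_convergence_mean, size=n_gc), n_goc)
    gc_list, goc_list = [], []
    for i in range(n_gc):
        k = k_draw[i]
        if k == 0:
            continue
        p = w[i] / w[i].sum()
        pres = rng.choice(n_goc, size=k, replace=False, p=p)
        gc_list.append(np.full(k, i, dtype=np.int64))
        goc_list.append(pres.astype(np.int64))
    goc_gc = (np.concatenate(gc_list), np.concatenate(goc_list))

    # PF: sagittal band crossing, mediolateral conduction delay
    dy = np.abs(geom.gc_pos[:, 1][:, None] - geom.goc_pos[:, 1][None, :])
    hit = dy <= pf_reach_mm
    gc_e, goc_e = np.nonzero(hit)
    dx = np.abs(geom.gc_pos[gc_e, 0] - geom.goc_pos[goc_e, 0])
    delay = params.DELAYS.synaptic_ms + dx / params.DELAYS.pf_velocity_m_s
    return Connectivity(
        mf_to_gc=mf_gc,
        goc_to_gc=goc_gc,
        gc_to_goc=(goc_e.astype(np.int64), gc_e.astype(np.int64)),
        pf_delay_ms=delay,
        geometry=geom,
    )


def default_protocol(geom: NetworkGeometry, duration: float = 10.0) -> InputProtocol:
    """Central mediolateral strip (20% of the sheet) as the input zone."""
    lx, ly = geom.dims_mm
    return InputProtocol(
        zone=((0.4 * lx, 0.6 * lx), (0.0, ly)), duration=duration
    )


def make_mf_input(geom: NetworkGeometry, protocol: InputProtocol, seed: int = 0) -> SpikeData:
    """Inhomogeneous-Poisson MF spikes (thinning), homogeneous out of zone."""
    (x0, x1), (y0, y1) = protocol.zone
    if not (0 <= x0 <= x1 <= geom.dims_mm[0] and 0 <= y0 <= y1 <= geom.dims_mm[1]):
        raise ValueError("input zone must lie inside the sheet")
    rng = np.random.default_rng(seed)
    in_zone = (
        (geom.mf_pos[:, 0] >= x0) & (geom.mf_pos[:, 0] <= x1)
        & (geom.mf_pos[:, 1] >= y0) & (geom.mf_pos[:, 1] <= y1)
    )
    r0 = protocol.baseline_rate_Hz
    depth = protocol.modulation_depth
    f = protocol.modulation_freq_Hz
    T = protocol.duration
    cells, times = [], []
    rmax = r0 * (1 + depth)
    for m in range(geom.n_mf):
        if r0 <= 0:
            continue
        if in_zone[m] and depth > 0:
            n_cand = rng.poisson(rmax * T)
            cand = rng.uniform(0, T, n_cand)
            accept = rng.random(n_cand) < (
                r0 * (1 + depth * np.sin(2 * np.pi * f * cand)) / rmax
            )
            spk = cand[accept]
        else:
            spk = rng.uniform(0, T, rng.poisson(r0 * T))
        cells.append(np.full(len(spk), m, dtype=np.int64))
        times.append(spk)
    if cells:
        c = np.concatenate(cells)
        t = np.concatenate(times)
        order = np.argsort(t, kind="stable")
        c, t = c[order], t[order]
    else:
        c, t = np.empty(0, dtype=np.int64), np.empty(0)
    return SpikeData(cells=c, times=t, n_cells=geom.n_mf, duration=T, population="MF")


# ---------------------------------------------------------------------------
# integration kernel


@njit(fastmath=True)
def _run_kernel(
    n_steps, dt,
    V, gexc, ginh, gspill, refrac,
    C, gL, EL, Vth, Vres, ref_steps,
    E_exc, E_syn, E_ton, g_const, k_leak,
    dec_exc, dec_inh, dec_spill,
    w_mf, w_inh, w_spill,
    exc_step, exc_gc,
    mini_step, mini_gc,
    gocgc_ptr, gocgc_tgt, p_rel, rel_delay,
    gcgoc_ptr, gcgoc_tgt, gcgoc_del,
    w_pf, dec_pf,
    Vq, gpf, ga, refq,
    Cq, gLq, ELq, Vthq, Vresq, refq_steps, I_pace, E_exc_q,
    dec_adapt, w_adapt, E_K,
    rb_rel, rb_pf,
    seed,
    gc_sp_step, gc_sp_id, goc_sp_step, goc_sp_id,
):
    np.random.seed(seed)
    nG = V.shape[0]
    nQ = Vq.shape[0]
    L_rel = rb_rel.shape[0]
    L_pf = rb_pf.shape[0]
    pe = 0
    pm = 0
    cg = 0
    cq = 0
    n_exc = exc_step.shape[0]
    n_min = mini_step.shape[0]
    cap_g = gc_sp_step.shape[0]
    cap_q = goc_sp_step.shape[0]
    for s in range(n_steps):
        row = s % L_rel
        for i in range(nG):
            c = rb_rel[row, i]
            if c != 0.0:
                ginh[i] += c * w_inh
                gspill[i] += c * w_spill
                rb_rel[row, i] = 0.0
        rowp = s % L_pf
        for q in range(nQ):
            c = rb_pf[rowp, q]
            if c != 0.0:
                gpf[q] += c
                rb_pf[rowp, q] = 0.0
        while pe < n_exc and exc_step[pe] == s:
            gexc[exc_gc[pe]] += w_mf
            pe += 1
        while pm < n_min and mini_step[pm] == s:
            i = mini_gc[pm]
            ginh[i] += w_inh
            gspill[i] += w_spill
            pm += 1
        for i in range(nG):
            if refrac[i] > 0:
                refrac[i] -= 1
                V[i] = Vres
            else:
                gton = gspill[i] + g_const
                gt = gL * k_leak + gexc[i] + ginh[i] + gton
                vinf = (
                    gL * k_leak * EL + gexc[i] * E_exc + ginh[i] * E_syn + gton * E_ton
                ) / gt
                V[i] = vinf + (V[i] - vinf) * np.exp(-dt * gt / C)
                if V[i] >= Vth:
                    if cg < cap_g:
                        gc_sp_step[cg] = s
                        gc_sp_id[cg] = i
                    cg += 1
                    V[i] = Vres
                    refrac[i] = ref_steps
                    for e in range(gcgoc_ptr[i], gcgoc_ptr[i + 1]):
                        rb_pf[(s + gcgoc_del[e]) % L_pf, gcgoc_tgt[e]] += w_pf
            gexc[i] *= dec_exc
            ginh[i] *= dec_inh
            gspill[i] *= dec_spill
        for q in range(nQ):
            if refq[q] > 0:
                refq[q] -= 1
                Vq[q] = Vresq
            else:
                gt = gLq + gpf[q] + ga[q]
                vinf = (gLq * ELq + gpf[q] * E_exc_q + ga[q] * E_K + I_pace) / gt
                Vq[q] = vinf + (Vq[q] - vinf) * np.exp(-dt * gt / Cq)
                if Vq[q] >= Vthq:
                    if cq < cap_q:
                        goc_sp_step[cq] = s
                        goc_sp_id[cq] = q
                    cq += 1
                    Vq[q] = Vresq
                    refq[q] = refq_steps
                    ga[q] += w_adapt
                    for e in range(gocgc_ptr[q], gocgc_ptr[q + 1]):
                        if np.random.random() < p_rel:
                            rb_rel[(s + rel_delay) % L_rel, gocgc_tgt[e]] += 1.0
            gpf[q] *= dec_pf
            ga[q] *= dec_adapt
    return cg, cq


def _edges_to_csr(src: np.ndarray, dst: np.ndarray, n_src: int,
                  extra: np.ndarray | None = None):
    order = np.argsort(src, kind="stable")
    s, d = src[order], dst[order]
    ptr = np.zeros(n_src + 1, dtype=np.int64)
    np.add.at(ptr[1:], s, 1)
    ptr = np.cumsum(ptr)
    if extra is None:
        return ptr, d
    return ptr, d, extra[order]


def simulate(
    geom: NetworkGeometry,
    conn: Connectivity,
    cfg: ConditionConfig,
    mf_spikes: SpikeData,
    duration: float,
    dt_ms: float = 0.05,
    seed: int = 0,
    max_rate_Hz: float = 400.0,
) -> SpikeData:
    """Run the network and return GC spikes (GoC spikes in ``.meta['goc']``).

    Most users should call :func:`run_condition` instead, which also builds
    the geometry, wiring and input and returns a full :class:`SimResult`.
    """
    if dt_ms > 0.1:
        raise ValueError("dt must be <= 0.1 ms")
    gc_p, goc_p = params.GC, params.GOC
    n_gc, n_goc = geom.n_gc, geom.n_goc
    dt = dt_ms
    n_steps = int(round(duration * 1000.0 / dt_ms))
    rng = np.random.default_rng(seed)

    syn_delay_steps = int(round(params.DELAYS.synaptic_ms / dt_ms))

    # MF release -> GC excitatory events (synaptic delay baked in)
    mf_ptr, mf_tgt = _edges_to_csr(
        conn.mf_to_gc[1], conn.mf_to_gc[0], geom.n_mf
    )
    outdeg = np.diff(mf_ptr)
    spike_mf = mf_spikes.cells
    spike_step = (mf_spikes.times * 1000.0 / dt_ms).astype(np.int64) + syn_delay_steps
    reps = outdeg[spike_mf]
    exc_step = np.repeat(spike_step, reps)
    gather = np.concatenate(
        [mf_tgt[mf_ptr[m]:mf_ptr[m + 1]] for m in spike_mf]
    ) if len(spike_mf) else np.empty(0, dtype=np.int64)
    order = np.argsort(exc_step, kind="stable")
    exc_step, exc_gc = exc_step[order], gather[order]
    keep = exc_step < n_steps
    exc_step, exc_gc = exc_step[keep], exc_gc[keep]

    # miniature release events per GC at (in-degree x per-synapse rate)
    indeg = np.bincount(conn.goc_to_gc[0], minlength=n_gc)
    lam = indeg * cfg.spont_release_rate_Hz * duration
    n_mini = rng.poisson(lam)
    mini_gc = np.repeat(np.arange(n_gc, dtype=np.int64), n_mini)
    mini_step = rng.integers(0, n_steps, size=len(mini_gc))
    order = np.argsort(mini_step, kind="stable")
    mini_step, mini_gc = mini_step[order], mini_gc[order]

    gocgc_ptr, gocgc_tgt = _edges_to_csr(
        conn.goc_to_gc[1], conn.goc_to_gc[0], n_goc
    )
    pf_del_steps = np.round(conn.pf_delay_ms / dt_ms).astype(np.int64)
    gcgoc_ptr, gcgoc_tgt, gcgoc_del = _edges_to_csr(
        conn.gc_to_goc[1], conn.gc_to_goc[0], n_gc, extra=pf_del_steps
    )

    L_rel = syn_delay_steps + 1
    L_pf = int(pf_del_steps.max()) + 1 if len(pf_del_steps) else 1

    cap_g = int(n_gc * duration * max_rate_Hz)
    cap_q = int(n_goc * duration * max_rate_Hz)
    gc_sp_step = np.empty(cap_g, dtype=np.int64)
    gc_sp_id = np.empty(cap_g, dtype=np.int32)
    goc_sp_step = np.empty(cap_q, dtype=np.int64)
    goc_sp_id = np.empty(cap_q, dtype=np.int32)

    V = np.full(n_gc, gc_p.EL_mV)
    Vq = np.full(n_goc, goc_p.EL_mV + rng.uniform(0, 9.5, n_goc))  # desynchronize
    state = dict(
        gexc=np.zeros(n_gc), ginh=np.zeros(n_gc), gspill=np.zeros(n_gc),
        refrac=np.zeros(n_gc, dtype=np.int64),
        gpf=np.zeros(n_goc), ga=np.zeros(n_goc),
        refq=np.zeros(n_goc, dtype=np.int64),
    )
    kernel_seed = int(rng.integers(2**31))
    cg, cq = _run_kernel(
        n_steps, dt,
        V, state["gexc"], state["ginh"], state["gspill"], state["refrac"],
        gc_p.C_pF, gc_p.gL_nS, gc_p.EL_mV, gc_p.Vth_mV, gc_p.Vreset_mV,
        int(round(gc_p.refrac_ms / dt_ms)),
        gc_p.E_exc_mV, gc_p.E_syn_mV, cfg.E_xGABA_mV, cfg.g_tonic_const_nS,
        cfg.k_current_gain,
        np.exp(-dt_ms / gc_p.tau_exc_ms), np.exp(-dt_ms / gc_p.tau_inh_ms),
        np.exp(-dt_ms / cfg.spill_tau_ms),
        gc_p.w_mf_nS, gc_p.w_inh_nS, cfg.spill_gain_nS_per_event,
        exc_step, exc_gc.astype(np.int64),
        mini_step.astype(np.int64), mini_gc,
        gocgc_ptr, gocgc_tgt, cfg.evoked_release_prob, syn_delay_steps,
        gcgoc_ptr, gcgoc_tgt, gcgoc_del,
        goc_p.w_pf_nS, np.exp(-dt_ms / goc_p.tau_pf_ms),
        Vq, state["gpf"], state["ga"], state["refq"],
        goc_p.C_pF, goc_p.gL_nS, goc_p.EL_mV, goc_p.Vth_mV, goc_p.Vreset_mV,
        int(round(goc_p.refrac_ms / dt_ms)), params.goc_pacemaker_bias(goc_p),
        goc_p.E_exc_mV,
        np.exp(-dt_ms / goc_p.tau_adapt_ms), goc_p.w_adapt_nS, goc_p.E_K_mV,
        np.zeros((L_rel, n_gc)), np.zeros((L_pf, n_goc)),
        kernel_seed,
        gc_sp_step, gc_sp_id, goc_sp_step, goc_sp_id,
    )
    if not (np.isfinite(V).all() and np.isfinite(Vq).all()):
        bad = int(np.flatnonzero(~np.isfinite(np.concatenate([V, Vq])))[0])
        raise IntegrationError(f"non-finite membrane potential (cell {bad})")
    if cg > cap_g or cq > cap_q:
        raise IntegrationError(
            f"spike capacity exceeded ({cg} GC / {cq} GoC spikes); "
            "raise max_rate_Hz"
        )
    gc = SpikeData(
        cells=gc_sp_id[:cg].astype(np.int64),
        times=gc_sp_step[:cg] * dt_ms / 1000.0,
        n_cells=n_gc, duration=duration, population="GC",
    )
    goc = SpikeData(
        cells=goc_sp_id[:cq].astype(np.int64),
        times=goc_sp_step[:cq] * dt_ms / 1000.0,
        n_cells=n_goc, duration=duration, population="GoC",
    )
    gc.__dict__["goc"] = goc  # convenience backref
    return gc


def run_condition(
    age: str,
    genotype: str,
    scale: float = 0.05,
    duration: float = 10.0,
    seed: int = 0,
    protocol: InputProtocol | None = None,
    dt_ms: float = 0.05,
) -> SimResult:
    """Build and simulate one condition end to end.

    The geometry seed depends only on ``seed`` (not the condition), so runs
    of different conditions at the same seed share cell placements and are
    directly comparable.
    """
    cfg = condition_config(age, genotype)
    geom = build_geometry(scale, seed=seed)
    conn = build_connectivity(geom, cfg, seed=seed + 1)
    proto = protocol or default_protocol(geom, duration)
    mf = make_mf_input(geom, proto, seed=seed + 2)
    gc = simulate(geom, conn, cfg, mf, duration, dt_ms=dt_ms, seed=seed + 3)
    return SimResult(
        gc=gc, goc=gc.__dict__["goc"], mf=mf, geometry=geom, conn=conn,
        protocol=proto, cfg=cfg, duration=duration,
    )


# ---------------------------------------------------------------------------
# single-cell utilities (rheobase / homeostatic contract)


def rheobase_current(cfg: ConditionConfig) -> float:
    """Analytic GC rheobase (pA) under the condition's mean tonic conductance."""
    from .gcircuit import mean_tonic_conductance

    return params.gc_rheobase(
        mean_tonic_conductance(cfg), cfg.E_xGABA_mV, cfg.k_current_gain
    )


def first_spike_latency(
    cfg: ConditionConfig,
    I_pA: float,
    duration_ms: float = 500.0,
    dt_ms: float = 0.05,
) -> float | None:
    """First-spike latency (ms) of a single GC under a step current.

    The tonic conductance is held at its condition mean; returns None if the
    cell stays below threshold.  Uses the same exponential-Euler update as
    the network kernel.
    """
    from .gcircuit import mean_tonic_conductance

    p = params.GC
    g_t = mean_tonic_conductance(cfg)
    g_leak = p.gL_nS * cfg.k_current_gain
    gt = g_leak + g_t
    vinf = (g_leak * p.EL_mV + g_t * cfg.E_xGABA_mV + I_pA) / gt
    decay = np.exp(-dt_ms * gt / p.C_pF)
    v = p.EL_mV
    n = int(round(duration_ms / dt_ms))
    for s in range(n):
        v = vinf + (v - vinf) * decay
        if v >= p.Vth_mV:
            return (s + 1) * dt_ms
    return None
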