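"""Point-neuron and synapse parameters for the granular-layer network.

Conductance-based leaky integrate-and-fire cells stand in for detailed
multicompartmental models: the variables that the experiments constrain
(GoC->GC convergence, release rates, tonic conductance, E_xGABA, the KO
potassium-current gain) are carried by the condition configs, while the
membrane scaffolding below is fixed across conditions.

Units: pF, nS, mV, ms, pA throughout (pA/pF = mV/ms).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class GCParams:
    """Granule cell: small, electrotonically compact."""

    C_pF: float = 3.0
    gL_nS: float = 1.5
    EL_mV: float = -80.0
    Vth_mV: float = -40.0
    Vreset_mV: float = -75.0
    refrac_ms: float = 2.0
    E_exc_mV: float = 0.0
    tau_exc_ms: float = 3.0
    w_mf_nS: float = 2.0
    tau_inh_ms: float = 20.0
    w_inh_nS: float = 0.2
    #: synaptic GABA_A reversal (condition-independent); the age-dependent
    #: E_xGABA from cell-attached THIP recordings applies to the
    #: extrasynaptic (tonic + spillover) conductance only
    E_syn_mV: float = -80.0


@dataclass(frozen=True)
class GoCParams:
    """Golgi cell: intrinsic pacemaker near 8 Hz, PF-driven."""

    C_pF: float = 40.0
    gL_nS: float = 2.0
    EL_mV: float = -60.0
    Vth_mV: float = -50.0
    Vreset_mV: float = -60.0
    refrac_ms: float = 2.0
    E_exc_mV: float = 0.0
    tau_pf_ms: float = 2.0
    w_pf_nS: float = 0.05
    pacemaker_rate_Hz: float = 2.0
    # slow AHP / spike-frequency adaptation: sets the network rhythm period
    tau_adapt_ms: float = 100.0
    w_adapt_nS: float = 3.0
    E_K_mV: float = -90.0


@dataclass(frozen=True)
class SynapseDelays:
    synaptic_ms: float = 1.0
    pf_velocity_m_s: float = 0.5


GC = GCParams()
GOC = GoCParams()
DELAYS = SynapseDelays()


def goc_pacemaker_bias(p: GoCParams = GOC) -> float:
    """Constant bias current (pA) giving the target pacemaker rate.

    Closed form for a leaky integrate-and-fire cell:
    T = refrac + tau * ln((Vinf - Vreset)/(Vinf - Vth)).
    """
    tau = p.C_pF / p.gL_nS
    T = 1000.0 / p.pacemaker_rate_Hz
    L = (T - p.refrac_ms) / tau
    eL = np.exp(L)
    v_inf = (p.Vreset_mV - p.Vth_mV * eL) / (1.0 - eL)
    return float(p.gL_nS * (v_inf - p.EL_mV))


def gc_rheobase(mean_tonic_nS: float, E_xGABA_mV: float, k_leak: float = 1.0,
                p: GCParams = GC) -> float:
    """Rheobase (pA) of a GC with tonic conductance and scaled leak.

    Steady state must reach threshold:
    I = k*gL*(Vth - EL) + g_tonic*(Vth - E_xGABA).
    """
    return float(
        k_leak * p.gL_nS * (p.Vth_mV - p.EL_mV)
        + mean_tonic_nS * (p.Vth_mV - E_xGABA_mV)
    )


def homeostatic_k_gain(
    mean_tonic_wt_nS: float,
    mean_tonic_ko_nS: float,
    E_xGABA_mV: float,
    p: GCParams = GC,
) -> float:
    """Leak/outward-current scale factor matching the KO rheobase to WT.

    Best1 loss lowers the tonic conductance; a compensatory increase of the
    outward K+ current keeps the rheobase unchanged.  Matching the two
    rheobase expressions gives
    k = 1 + (g_wt - g_ko) * (Vth - E_xGABA) / (gL * (Vth - EL)).
    """
    k = 1.0 + (mean_tonic_wt_nS - mean_tonic_ko_nS) * (
        p.Vth_mV - E_xGABA_mV
    ) / (p.gL_nS * (p.Vth_mV - p.EL_mV))
    return float(k)
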