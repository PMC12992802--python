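{
  "version": 1,
  "comment": "Canonical age x genotype parameter sets for granule-cell inhibition. Convergence and rate ratios follow the measured constraints (adult convergence 8; young WT/KO need 4x/3x more; per-synapse miniature rate drops to 1/3 (WT) and 1/2 (KO) with age; E_xGABA -65 mV young, -80 mV adult). Conductances convert measured tonic currents at -60 mV holding with symmetric chloride (60 mV driving force); the adult-KO activity-independent conductance (50% of adult WT) and the free calibration constants in 'shared' are declared defaults, not measured values.",
  "shared": {
    "evoked_release_prob": 0.5,
    "spill_tau_ms": 100.0,
    "spill_gain_nS_per_event": 0.0185,
    "background_goc_rate_Hz": 8.0
  },
  "conditions": {
    "young-wt": {
      "age": "young",
      "genotype": "WT",
      "goc_convergence_mean": 32,
      "spont_release_rate_Hz": 0.3,
      "g_tonic_const_nS": 0.136,
      "E_xGABA_mV": -65.0
    },
    "young-ko": {
      "age": "young",
      "genotype": "Best1KO",
      "goc_convergence_mean": 24,
      "spont_release_rate_Hz": 0.3,
      "g_tonic_const_nS": 0.0335,
      "E_xGABA_mV": -65.0
    },
    "adult-wt": {
      "age": "adult",
      "genotype": "WT",
      "goc_convergence_mean": 8,
      "spont_release_rate_Hz": 0.1,
      "g_tonic_const_nS": 0.2884,
      "E_xGABA_mV": -80.0
    },
    "adult-ko": {
      "age": "adult",
      "genotype": "Best1KO",
      "goc_convergence_mean": 8,
      "spont_release_rate_Hz": 0.15,
      "g_tonic_const_nS": 0.1442,
      "E_xGABA_mV": -80.0
    }
  }
}
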