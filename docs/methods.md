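# Methods

This note documents the models and procedures implemented in `cereb`, the
parameter values they use and where those values come from, the design
choices made where the design was genuinely open, and what the synthetic-data
generators do and do not emulate.  Units throughout: pA, nS, mV, pF, ms (so
pA/pF = mV/ms); positions in mm (network) or cm (behaviour).

## 1. Tonic-current decomposition (`cereb.ephys`)

**Measurement model.** A whole-cell holding-current trace at −60 mV carries a
persistent inward tonic GABA_A current, transient inward sIPSCs and white
recording noise.  Blocking GABA_A receptors with gabazine (GBZ) shifts the
baseline outward by the tonic-current magnitude; applying TTX first removes
the action-potential-dependent (spillover) part, so the base→TTX shift is the
TTX-sensitive component and TTX→GBZ the TTX-insensitive one.  Under the GAT
blocker NPA the same two transitions are read starting from the NPA baseline.
By construction `ttx_sensitive + ttx_insensitive == total` exactly.  Negative
estimated components are reported as-is and flagged, never clipped — adult
recordings genuinely show near-zero TTX shifts, and clipping would bias group
means.

**Baseline estimator.** Each baseline is the mode of a Gaussian fitted to the
all-point histogram of a window (default 30 s), the standard robust reading
for traces contaminated by synaptic transients: the inward sIPSC tail skews
the mean but barely moves the histogram peak.  Degenerate (near-constant)
windows fall back to the median.  Windows observe a settling margin (default
60 s) after every drug event; the pre-window ends at the event, the
post-window starts one margin after it.

**Wash-in.** Bath-applied drugs act gradually.  The synthetic generator
renders each transition as a causal truncated logistic with a 10-s time
constant and half-rise 20 s after the event — zero before the event (the drug
cannot act before it arrives) and >98% complete at the 60-s margin.  The
residual ~2% settling error is the dominant term in the recovery error budget
(mean absolute component error ≈ 0.06 pA at 2-pA noise, far inside the 0.5-pA
tolerance used in tests).

**sIPSC detection.** Matched filter: the trace is detrended with a 1-s running
median (edge-guarded), correlated with the canonical IPSC template
(instantaneous rise, 10-ms exponential decay), and thresholded at 4.5 robust
(MAD-based) standard deviations of the filter output; detections closer than
5 ms are merged and duplicates removed.  The threshold was set from the
measured false-positive rate of the filter output, whose tail is slightly
heavier than Gaussian; at the study's signal-to-noise (30-pA events on 2-pA
noise) the true-event score sits ~19σ above threshold, so sensitivity is
unaffected.  Both τ and the threshold are arguments.

**Reversal potential.** `E_xGABA = V_m − DF_THIP` under the convention
DF ≡ V_m − E (depolarizing driving force positive); the opposite tabulation
is available via `df_convention="e_minus_vm"`.  The I–V zero crossing uses
linear interpolation between the bracketing samples; with multiple crossings
(noise) the one nearest the median sampled potential wins — crossings near
the extremes of the ramp are the ones most likely produced by noise.

## 2. Condition parameter sets (`cereb.gcircuit`)

The four canonical configurations encode the measured structure:

| | young-WT | young-KO | adult-WT | adult-KO |
|---|---|---|---|---|
| GoC→GC convergence | 32 | 24 | 8 | 8 |
| per-synapse mini rate (Hz) | 0.3 | 0.3 | 0.1 | 0.15 |
| g_tonic_const (nS) | 0.136 | 0.0335 | 0.288 | 0.144 |
| E_xGABA (mV) | −65 | −65 | −80 | −80 |
| K⁺ gain k | 1 | 1.069 | 1 | 1.096 |

Fixed by measurement: adult convergence 8 with young WT/KO requiring 4×/3×
more; the per-synapse miniature rate falling to 1/3 (WT) and 1/2 (KO) of the
young value with age; E_xGABA −65 → −80 mV.  (The miniature-rate constraint
is stated here per synapse; since the convergence changes 4× simultaneously,
the per-cell miniature frequency changes by a different factor — the
per-synapse reading is the one the model uses.)

Conductances convert measured currents at −60 mV holding with symmetric
chloride (60 mV driving force).  The young-WT TTX-insensitive mean of 8.16 pA
gives 0.136 nS; the young-KO residual of 2.01 pA (a 75.4% loss) gives
0.0335 nS; the adult-WT value follows from the unchanged total tonic current
and the 22.6% adult TTX-sensitive fraction; the adult-KO retention (50% of
adult WT) is a declared default — the measurement shows a significant
Best1-independent residual in adults without quantifying it as a group mean
usable here.

**Two-source tonic conductance.** `g(t) = g_const + Σ_k g_spill·exp(−(t−t_k)/τ_spill)`
over all release events (evoked and miniature), with τ_spill = 100 ms and
g_spill = 0.0185 nS per event.  The gain is derived by inverting Campbell's
theorem for the young-WT TTX-sensitive component: mean spillover =
N·λ_evoked·g_spill·τ with N = 32, λ_evoked = 8 Hz background GoC rate × 0.5
release probability, matched to 14.2 pA at 60 mV driving force.  Free
calibration constants (release probability 0.5, τ_spill 100 ms, background
GoC rate 8 Hz) are declared in `data/conditions.json`, not measured.

**Stochastic synapse.** Each presynaptic spike releases independently with
probability 0.5; an independent homogeneous Poisson process per synapse adds
miniature events.  Releases feed both the phasic IPSC conductance and the
spillover term.

**Homeostatic K⁺ gain.** Best1 loss lowers the tonic conductance; the
constitutive KO compensates by raising the outward K⁺ (leak) current such
that the rheobase is unchanged.  For the point GC the rheobase is analytic,
`I_rh = k·g_L(V_th−E_L) + ḡ_tonic(V_th−E_xGABA)`, and matching WT and KO
gives `k = 1 + (ḡ_WT − ḡ_KO)(V_th−E_xGABA)/(g_L(V_th−E_L))`, evaluated with
the Campbell-mean tonic conductance at the background GoC rate.  In the adult
conditions (E_xGABA = E_L = −80 mV) this also equalizes the total resting
conductance, so the f–I curve above rheobase remains steeper in the KO — the
compensation restores the threshold, not the gain.

**Convergence estimation.** `estimate_required_convergence` simulates a
voltage-clamped GC receiving N stochastic synapses (GoCs at the background
rate), computes the mean GBZ-sensitive current `mean(g)·(V_hold − E_xGABA)`
over 300 s after a 0.5-s burn-in, and returns the smallest N reaching the
target by doubling then bisection.  The per-N estimate is seeded by
(seed, N), so repeated queries are consistent and the search is monotone in
the target up to ~1% simulation noise (the spacing between adjacent N is
~12% at N = 8).

## 3. Granular-layer network (`cereb.netsim`)

**Geometry.** The full sheet is 1.5 mm × 0.7 mm with 0.8 M GCs, 2000 GoCs and
2000 MF glomeruli; a linear `scale` shrinks the sheet and counts scale with
area.  At small scales two floors apply (and are logged): GoCs are kept at
≥50 so the feedback loop has a functional population, and MF glomeruli at
≥500 so the shot noise of the pooled input drive stays small compared with
network-generated rate fluctuations (with ~10 in-zone fibers the common input
noise dominates the oscillation band and masks network activity).  Geometry
is degenerate (error) if any population would fall below 10.

**Wiring.** MF→GC: each GC takes its 4 nearest distinct glomeruli (all must
lie within a 50-µm dendritic radius).  GoC→GC: each GC draws
Poisson(convergence) presynaptic GoCs without replacement, weighted by a
Gaussian of somatic distance (σ = 100 µm); the sampled mean in-degree matches
the configured convergence to <2%.  GC→GoC: a parallel fiber runs
mediolaterally and contacts every GoC whose sagittal band (±30 µm) it
crosses, with delay 1 ms + distance/0.5 m s⁻¹.

**Neurons.** Conductance-based leaky integrate-and-fire point cells replace
detailed multicompartmental models; the experimentally constrained variables
(convergence, release rates, tonic conductance, E_xGABA, K⁺ gain) are carried
by the condition configs and the rest is scaffolding, fixed across
conditions:

* GC: C = 3 pF, g_L = 1.5 nS, E_L = −80 mV, V_th = −40 mV, V_reset = −75 mV,
  refractory 2 ms; MF synapse w = 2 nS, τ = 3 ms, E = 0 mV (an effective
  AMPA+NMDA lump sized so that ON cells are mean-driven at peak input);
  GoC IPSC w = 0.2 nS, τ = 20 ms (granule-cell IPSCs are slow).
* GoC: C = 40 pF, g_L = 2 nS, E_L = −60, V_th = −50, V_reset = −60 mV;
  PF synapse w = 0.05 nS, τ = 2 ms; a weak intrinsic pacemaker bias (2 Hz in
  isolation, solved in closed form) plus a slow spike-frequency-adaptation
  (AHP) conductance: +3 nS per spike, τ = 100 ms, E_K = −90 mV.  In the
  network, PF drive brings GoCs to ~8–15 Hz.

The GoC adaptation is the rhythmogenic element of the model.  Golgi cells
express prominent slow AHPs, and in the reduced network the adaptation turns
the GC→GoC→GC loop into a slow (≈10–20 Hz) population rhythm: a granule-cell
volley drives the Golgi population, the ensuing inhibition (slow IPSC decay)
silences the granule layer, and recovery is paced by the AHP.  Without it the
reduced network relaxes to an asynchronous state with no collective
oscillation at any loop gain we explored, and the age comparison of
oscillation power is meaningless.  The oscillation amplitude inherits the
condition structure through the per-volley inhibitory conductance
(convergence × release probability × IPSC weight), which is 4× larger in
young-WT than in adults.

**Reversal potentials.** The age-dependent E_xGABA applies to the
extrasynaptic conductance (g_const + spillover) only — the measurement uses
THIP, selective for δ-subunit extrasynaptic receptors.  Phasic synaptic
IPSCs use a fixed synaptic chloride reversal of −80 mV in all conditions.
This distinction matters: near spike threshold the driving force of a
−65-mV-reversal conductance is small, and applying E_xGABA to the synaptic
events would nearly cancel the measured 4× convergence difference in
effective synaptic current.

**Input protocol.** A central mediolateral strip covering 20% of the sheet
receives inhomogeneous-Poisson MF spikes with rate
`r(t) = 20·(1 + 0.8·sin(2π·2t))` Hz (thinning algorithm); out-of-zone fibers
fire homogeneously at 20 Hz.  Baseline, depth and frequency are declared
defaults — the underlying recordings do not print them — and are arguments of
`InputProtocol`.

**Integration.** Exponential Euler at dt = 0.05 ms (dt ≤ 0.1 ms enforced).
MF release and miniature events are precomputed event streams; evoked release
and PF volleys use ring buffers for their synaptic/conduction delays.  The
whole update runs in one compiled (numba) kernel with a single seeded RNG and
a fixed cell iteration order, so rasters are reproducible bit-for-bit per
seed.  Geometry is seeded independently of condition, so the four conditions
at one seed share cell placements and are directly comparable.

**Problem sizes.** Analyses use scale 0.05 (≈2,000 GCs) with 10–15 s of
biological time per run and 5 seeds shared across the four conditions; a
four-condition battery takes ~3 minutes on one CPU.  Full-scale geometry is
supported; full-scale simulation is out of scope.

## 4. Spike statistics (`cereb.spikestats`)

Population rates: per-1-ms-bin counts / (cells × bin), convolved with a
unit-area Gaussian (σ = 20 ms default) truncated at ±4σ and edge-renormalized
by the kernel mass inside the window, conserving total spike count to <1%.

ON cells are GCs with ≥1 MF input from an in-zone glomerulus.  Input–output
correlation is Pearson's r between rate series on a shared grid, excluding a
200-ms onset transient; zero-variance series yield NaN with a warning.

Power split: Welch periodogram (4-s Hann segments, 50% overlap) of the
mean-subtracted rate.  `P_input` integrates f_input ± 0.5 Hz; `P_osc`
integrates the network-oscillation band, default 10–50 Hz.  If a spectral
peak at least 3× the in-band mean appears above the band, the band widens
upward to include it (logged).  The band floor never moves down: below it the
spectrum is input-driven by construction (slow drive fluctuations and
harmonics of the rate response to the f_input modulation), and counting that
as "network oscillation" would invert the comparison between strongly and
weakly coupled networks.

Bootstrap: resample with replacement `n_iter = 1000` times; s.e.m. is the SD
of the bootstrap distribution, CI95 its 2.5/97.5 percentiles; seeded.

## 5. Gait kinematics (`cereb.kinematics`)

**Conventions** (the source kinematic literature gives no formulas; these are
fixed here and validated against the generator): body vector = anus→neck;
forelimb vectors originate at the chest, hindlimb vectors at the anus; limb
angle = arccos of the normalized dot product (range [0, 180]°); angular speed
= rectified central difference at the native 20 Hz, no pre-smoothing (an
optional low-pass exists but is off).  Central differencing attenuates a
sinusoidal angle's speed amplitude by sinc(2πf·dt) — 1.6% at 1 Hz, 6.5% at
2 Hz.  Heading is the horizontal azimuth of the body vector.

**Rapid-motion selection.** A frame qualifies iff anus speed > 2 cm/s AND
each forepaw z ≤ (per-frame max of the two hindpaw z) + 2.576 × SD of the
left–right hindpaw vertical distance, the SD taken over the whole recording.
The 2.576 multiplier is the two-sided 99% normal quantile; a direct
percentile variant of the height limit can be had by passing a different
multiplier.  The implementation is verified against an independent per-frame
brute-force evaluation.

**Interlimb correlations.** 4×4 Pearson matrix of rectified angular speeds
(LF, RF, LH, RH) over masked frames (≥50 required).  Note that for *rectified*
speeds a constant left–right phase offset is not monotonically ordered:
pure antiphase limbs have anti-aligned swing pulses (negative correlation),
but a quarter-cycle offset is *more* negative than antiphase because the
rectified waveform is dominated by its second harmonic.  The generator's
`lr_phase_mix` is therefore defined as the *fraction of locomotor bouts*
(1-s bouts, smoothly switched) in which the girdle moves in phase, which
makes the measured correlation increase monotonically from ≈ −0.23 (pure
trot) to ≈ +0.99 (pure in-phase) and is also the biologically natural
reading — animals mix discrete gaits rather than dialling a phase.

**Segmentation.** Movement features on a 0.25-s grid — translational speed,
rectified turning speed, mean paw height, and stride-band (1.5–4 Hz) power —
each averaged at 0.5/1/2-s windows; z-scored; change points by recursive
binary segmentation of the summed squared error with a per-dimension penalty
and 2-s minimum segment; segment-mean features clustered by seeded k-means
(k ≤ 8).  Constant recordings give one segment.

**Turning-speed dependence.** Per segment (rapid-motion frames only, ≥20):
the limb-pair correlation and the mean rectified turning speed; segments are
binned into equal-count turning bins; the fraction of segments with positive
correlation is reported with a bootstrap s.e.m.  Empty bins are flagged NaN,
never interpolated.

**Gait metrics** (common mouse-gait conventions, validated against the
generator): strides are sub-sample-refined peaks of the hindpaw forward
position in the body frame, with the cadence taken from the 1–6-Hz spectral
peak; stride-time CV = SD/mean of inter-stride intervals; step-width CV over
the lateral hindpaw separation at mid-stance; ataxia index = mean lateral
deviation of hindpaw placements from each side's own track line, normalized
by body length (a dispersion, so it responds monotonically to placement
noise); interlimb phase variance = circular variance of the LF–RH phase lag
across strides.

## 6. Synthetic data (`cereb.synthdata`)

**Traces** are baseline + causal wash-in shifts + inward IPSC transients
(instant rise, 10-ms decay) + white Gaussian noise, with the ground truth
(shift per transition, event times/amplitudes, noise SD) attached.

**Skeletons** are 9 markers at 20 Hz in a 20 × 20 × 30 cm arena: the trunk
follows a smooth 2D walk integrating a per-segment turning profile with
gentle wall-avoidance steering; paws oscillate with an asymmetric
swing/stance cycle (20% swing) and per-stride elevation; rearing episodes
raise the forepaws ~5 cm; stride-period jitter is a slowly varying AR(1)
(ρ = 0.8) cadence fluctuation so that measured inter-stride intervals carry
the nominal CV at every limb phase; marker noise is isotropic Gaussian.
Walking speed defaults to 6 cm/s; arena-floor friction and the speed
distribution of real mice are not modelled — defaults are plausible, not fit.

**What passing tests do and do not show.**  The generators realize exactly
the statistical structure the analysis assumes: white recording noise,
Poisson synaptic events, Poisson spiking, Gaussian marker noise, and gait
built from the same angle conventions the analysis measures.  Recovery
results therefore validate the *implementation* (estimators are unbiased and
correctly wired), not robustness to real-data pathologies: pink noise and
electrode drift, bursty or correlated synaptic release, pose-estimation
outliers and identity swaps, or gait structure beyond two alternating phase
modes.  Likewise the network results are statements about the reduced-scale
model (with its density floors and point neurons), not about the full-scale
circuit.

## 7. Known limitations

* The network is run at 1/20 linear scale with density-boosted GoC/MF
  populations; oscillation frequencies and power ratios are not calibrated to
  in-vivo values, only their ordering across conditions is used.
* Golgi–Golgi gap junctions, Purkinje/stellate/basket cells and reverse-mode
  GAT transport are not modelled (the latter was experimentally excluded).
* The tonic calibration treats the TTX-insensitive current as purely
  activity-independent, absorbing the small miniature-spillover contribution
  into g_const.
* Liquid-junction-potential correction and series-resistance compensation
  are out of scope, as in the underlying recordings.
* The adult-KO residual tonic conductance (50% of adult WT) is a declared
  default, not a measured group mean.
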