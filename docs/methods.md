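# Methods

## Neuron model

The simulator is a single-compartment exponential integrate-and-fire
(EIF) neuron with two first-order gated conductances, integrated by
forward Euler at dt = 0.025 ms:

    Cm dV/dt = −gL (V − EL) + gL ΔT exp((V − VT)/ΔT)
               − gh h (V − Eh) − gD a b (V − EK)
               + I_cmd(t) + I_hold + I_noise(t)

    dx/dt = (x_inf(V) − x)/τ_x          for x ∈ {h, a, b}

- **h** is the h-current activation gate: sigmoidal, half-activation
  −80 mV, slope 8 mV (activating with hyperpolarization), τ = 80 ms,
  reversal −30 mV. It produces the depolarizing "sag" on
  hyperpolarizing steps.
- **a·b** gates the D-type (Kv1.1-like) K⁺ current: fast activation
  (half −47 mV, slope 8 mV, τ = 6 ms) times slow inactivation (half
  −55 mV, slope 7 mV, τ = 600 ms), reversal −90 mV. The overlap of the
  two curves near the −60 mV holding potential leaves a small standing
  conductance (so increasing g_D lowers the measured input resistance),
  while the slow inactivation delays spike onset on depolarizing steps.
- When V crosses 0 mV the sample is recorded at +35 mV and V resets to
  −60 mV for a 2-ms refractory period. The EIF upstroke is smooth and
  well resolved at dt = 0.025 ms, so dV/dt-based spike detection sees a
  realistic trajectory (detected thresholds ≈ −41 mV, spike amplitudes
  ≈ 75 mV).
- Background synaptic bombardment is an Ornstein–Uhlenbeck current
  (τ = 3 ms) whose magnitude is solved analytically so the stationary
  V_m fluctuation is `noise_sd` (default 2.0 mV, giving V_m variances
  of a few mV², in the range of in vivo recordings). Band-limited
  noise matters: white voltage noise would trip the 10 V/s spike
  criterion.
- Holding at −60 mV uses a bias current solved from the steady-state
  current balance at initialization. Sweeps start from that steady
  state; the 1.5-s inter-sweep interval exceeds every model time
  constant, so no state carries between sweeps. Liquid-junction
  potential is not modelled; all voltages are pipette-referenced.

Default passive/conductance values (Cm 200 pF, gL 13.5 nS, gh 8 nS, gD
30 nS) were calibrated once so the model's measured properties sit in
the reported in vivo range: input resistance ≈ 48 MΩ, sag ratio ≈
0.8, first-spike latency near rheobase tens of ms, and 100-Hz burst
entrainment at EPSC amplitudes around 1.2 nA.

Voltage-dependent terms are tabulated on a 0.05-mV grid and linearly
interpolated inside the (numba-compiled) integration loop; this is ~5×
faster than evaluating the exponentials per step and accurate to <1e−4
on the gates. Randomness comes from counter-based Philox generators
seeded per cell via `numpy.random.SeedSequence`, so every simulation is
bit-reproducible given its seed.

## Induction protocol and plasticity rule

The theta-burst stimulus is 10 EPSC-shaped current pulses
(difference-of-exponentials, rise 0.5 ms, decay 3 ms) at 100 Hz,
repeated 10× at 5 Hz, in 3 series separated by 15 s. Only the series
periods are integrated; the 15-s gaps exceed all time constants and
are skipped with a steady-state reset. Evoked spikes are counted by
the simulator's reset events and cross-checked against the dV/dt
detector in the tests.

The plasticity rule is phenomenological: after an induction that
evokes n spikes,

    gD ← gD · (1 + min(α_D n, cap_D)),   α_D = 0.0028/spike, cap 1.2
    gh ← gh · (1 − min(α_h n, cap_h)),   α_h = 0.001/spike, cap 0.35

with 70% of the change expressed at 10 min and 100% from 20 min. No
quantitative spike-count → conductance transfer function is available
from experiments; these rates were calibrated once so that a
fully-entrained induction (≈300 spikes) reproduces the reported
group-level effect sizes (firing change ≈ −20 to −30% on the maximal
step, R_in ≈ −10%, latency roughly doubled, sag ratio slightly
increased), and they are a stand-in for an unknown mechanism, not a
model of one.

## Cohorts and condition regimes

Cells are drawn with 10% CV log-normal jitter on Cm, gL, gh and gD.
Each cell's depolarizing step range is placed around its rheobase with
a coarse random offset (−50/0/+50 pA), spacing (40–75 pA) and step
count (4–6) — emulating how experimenters adjust step ranges by eye.
This placement variability is deliberate: it gives the pooled
normalized input–output curves realistic between-cell scatter, which
is what makes the intercept shift detectable while the slope (gain)
comparison stays non-significant, the regime the analysis is designed
for. With exactly rheobase-locked grids the simulated population is
unrealistically homogeneous and the slope test rejects in every
replicate; the balanced offset mix also keeps the lowest step equally
likely to sit just below or just above rheobase, so floor effects at
the bottom of the curve do not bias the pooled slope in either
direction. The burst EPSC amplitude is log-normal per cell (mean
1050 pA, 35% CV), spreading evoked spike counts over ≈70–300 (about a
third of cells exceed 250) and driving the spike-count/effect-size
correlation; a per-cell log-normal jitter (σ = 0.60) on the plasticity
rates supplies the residual effect-size heterogeneity seen in the
group SEMs (simulated firing-change SEM ≈ 6–7% at n = 16).

Condition labels map to parameter regimes: `control` (no induction),
`TBS` (full rule), `BAPTA` (induction but rule silenced — calcium
chelation), `MK801` (full rule — NMDA-receptor block does not affect
this plasticity), `ZD` (gh = 0 — h-current block), `DTX` (gD and α_D
at 40% — partial Kv1.1 block; these cells fire more during induction,
and comparisons use only cells with ≥250 evoked spikes).

## Feature extraction choices

- R_in and sag ratio are computed on the **mean trace per amplitude**
  (repeats averaged before taking the within-window minimum), then the
  median across amplitudes. With in vivo-scale noise the per-sweep
  minimum is an extreme-value statistic whose bias scales with the
  noise-to-deflection ratio; computing it on averaged traces removes
  most of that bias (and is how example traces are presented in the
  experimental literature). A `average_repeats=False` switch restores
  the per-sweep mode.
- Sag ratio uses baseline-subtracted deflections, so it is invariant
  to constant voltage offsets and approaches 1 from below as g_h → 0.
- The spike detector requires, in addition to the 10 V/s dV/dt
  criterion, that the candidate's local maximum exceed −20 mV; fast
  subthreshold transients (EPSC onsets at ≥2 nA can exceed 10 V/s on a
  200-pF cell) are otherwise counted as spikes. `peak_min_mV=-inf`
  restores the pure slope rule.
- The baseline window is the 50 ms before step onset. Aggregations:
  threshold = median of first-spike thresholds across depolarizing
  sweeps; AHP = mean over eligible spikes; latency = mean over maximal
  steps with ≥1 spike; burst index = per-sweep fractions averaged per
  amplitude (a pooled-spikes mode is available), maximum over
  amplitudes with mean count ≥ 5; V_m variance = median over 5-s
  segments with ±5 ms blanked around spike peaks.
- "Firing rate" for change statistics is the mean spike count on the
  cell's maximal current step.

## Statistics

Within-group comparisons are paired t-tests on pre vs post values;
between-group comparisons are two-tailed two-sample t-tests on per-cell
percent changes (100·(post−pre)/pre). The input–output comparison pools
every cell's normalized points per timepoint and fits
`count ~ current × timepoint`; the timepoint main effect tests the
intercept, the interaction tests the slope. Because each cell's points
deviate from the population line together, the coefficient covariance
is cluster-robust with the cell as the cluster — with iid standard
errors the slope test's false-rejection rate is several times its
nominal level on replicate cohorts. Spike-count correlations
are ordinary least squares (R², slope p). No multiple-testing
correction is applied by default, matching standard practice for these
designs; a Holm option is available through the statistics API.

## Place-cell sessions and drift analysis

The virtual animal runs a 200-cm track at 20 cm/s; a session is one
running direction (30 laps by default — real sessions of 15–20 min
yield comparable lap counts, and each direction is analyzed
independently). Spiking is an inhomogeneous Poisson process: a
truncated-Gaussian field (center 100 cm, width 40 cm, σ = width/4, peak
8 Hz) on a uniform 1.6-Hz out-of-field baseline; the two components
scale geometrically per lap (`in_field_gain_per_lap`,
`drift_per_lap`). Analysis uses 2-cm bins, field = the contiguous run
of bins ≥20% of the peak containing the peak (a conventional
criterion; configurable), Skaggs bits/spike for spatial information,
inclusion at stability and information > 0.1, thirds split by session
duration with boundary laps to the earlier third, and per-lap rates
using occupancy time as denominator.

The center of the lap-correlation distribution is tested one-tailed
(t-test if Shapiro–Wilk accepts normality at α = 0.05, else a sign
test). The tail direction is fixed a priori per metric — decrease for
out-of-field firing, increase for in-field firing — because choosing
the tail from the sample mean doubles the type-I rate and breaks the
5% null calibration; the data-driven choice remains available
explicitly.

## What the synthetic data does and does not show

The generator reproduces the statistical structure the analysis
assumes: step-protocol sweeps with sag and delayed firing, burst
entrainment with edge failures, spike-count-coupled depression, and
lap-wise multiplicative rate drift. It does not emulate electrode
drift, seal degradation, anesthesia-state fluctuations, theta
modulation, behavioral variability in running speed, or heterogeneous
per-cell drift — so passing tests validate the *analysis chain* and
the qualitative induction phenomenology, not any biophysical claim
about Kv1.1 gating, and real-data effect sizes need not match the
simulated ones. Simulated drift populations are cleaner than real ones
(ANOVA F values far exceed those from tetrode data at the same drift
rate).

## Problem sizes in the test suite

Monte-Carlo acceptance checks use the study's group sizes (16 vs 11
cells, blocker groups of 7–9, place populations of 171 cells × 30
laps) with replicate counts chosen for a fast suite: 20 replicate
cohort sets for the parameter-recovery and pharmacology checks, 300
null populations for the type-I calibration (the ±2% band is widened
by two binomial standard errors of that count), and 40 drifting
populations for the detection-power check. Thresholds keep the same
success fractions (≥90%, ≥80%, 5% ± 2%) as the full-size versions.

## Known limitations

- The plasticity transfer function is linear-with-saturation by
  assumption; only its endpoints are constrained by data.
- Series resistance is not part of the electrical model (R_s ≈ 0 in
  simulated sweeps); the R_s estimator is validated on analytic
  two-compartment traces instead.
- Forward Euler at 0.025 ms biases passive steady states by ~0.2% and
  spike times by less than one sample; halving dt halves the bias.
- The EIF reset caricatures spike repolarization: AHP shape is set by
  `Vreset` and the subthreshold currents, so absolute AHP values are
  less meaningful than their changes.
- Lap segmentation assumes clean monotone runs between turnarounds
  (the simulator's trajectories are noise-free); real position data may
  need smoothing before `segment_laps`.
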