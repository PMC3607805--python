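# Methods

## Model overview and assumptions

The network couples 1600 excitatory and 400 inhibitory single-compartment
conductance-based neurons.  Both classes share all channel parameters
(g_K = 4.74 µS, g_Na = 12.5 µS, g_L = 0.025 µS; V_K = −80 mV,
V_Na = 40 mV, V_L = −65 mV; T = 34 °C so φ = 3^((34−6.3)/10) ≈ 21) and
differ only in capacitance: C_m = 0.25 nF (excitatory, τ_m = 10 ms) versus
0.125 nF (inhibitory, τ_m = 5 ms).  Sodium activation is slaved to its
steady state m∞(V) = α_m/(α_m + β_m); the remaining gates obey
dx/dt = φ[α_x(V)(1−x) − β_x(V)x].  With these parameters both classes are
type I: firing emerges through a saddle-node-on-invariant-circle
bifurcation at the same rheobase (measured ≈ 0.711 nA by bisection), with
continuous frequency onset and a purely phase-advancing response to brief
depolarizing pulses.  Units are fixed to mV/ms/nA/µS/nF throughout, so
conductances quoted in nS are converted internally.

Assumptions inherited from the model class: point neurons (no morphology),
chemical synapses only (no gap junctions, no NMDA, no plasticity),
homogeneous parameters within a population, and an external drive that is
statistically identical for every cell (shared rate, independent Poisson
realizations).

## Network and drive

Connectivity is an independent-Bernoulli digraph: each ordered pair is
connected with p = 0.1 (mean out-degree 200 of 2000, targets in both
populations, no self-connections — excluded as standard practice, the
difference is negligible at this density).  Per-edge delays are gamma
distributed with mean 2 ms and variance 4 ms² (moment-matched shape 1,
scale 2 ms) and apply to recurrent synapses only; external events arrive
undelayed.  Delays snap to the integration grid (fixed-step integrator).

Each synaptic contact adds a double-exponential conductance transient
g′/(τ_d−τ_r)[e^(−t/τ_d) − e^(−t/τ_r)] and a current −g_syn(V − E_syn) into
the membrane equation; this sign convention makes AMPA (E = 0 mV)
depolarizing and GABA (E = −70 mV) hyperpolarizing from rest.  The sum
over arrival times is integrated exactly by one rise and one decay
accumulator per synapse type per neuron, each decaying as e^(−dt/τ) and
incremented by the number of events arriving at a step — an isolated event
reproduces the closed form to machine precision (tested at < 1e−10).

The external drive of every neuron is an inhomogeneous Poisson train with
shared rate λ(t) = mean + x(t), where x is a zero-mean Ornstein–Uhlenbeck
process (σ = 0.6 spikes/s, τ = 16 ms, spectral corner 1/(2πτ) ≈ 9.9 Hz)
advanced by the stochastic Heun scheme (same Wiener increment in predictor
and corrector) and clipped at zero rate.  Event counts per dt bin are
drawn per neuron as Poisson(λ·dt), which makes counts over any window
exactly Poisson with the integrated rate; at the default operating point
λ·dt ≈ 0.43, so a Bernoulli (at most one event per bin) thinning would
distort the event statistics and is not used.  The printed σ is tiny
relative to the mean (0.6 vs 8500 spikes/s); the config exposes a
`sigma_scale` multiplier (default 1) so that regimes with visible
external-rate fluctuations — needed to demonstrate the rate code — can be
produced without reinterpreting the printed constant.

## Integration, detection, initial conditions

The coupled neuron equations advance with the Heun (explicit trapezoid)
predictor–corrector at dt = 0.05 ms; synaptic conductances are evaluated
at both step endpoints from the exactly decayed accumulators.  Spikes are
detected as upward crossings of 0 mV with a 2 ms lockout — unambiguous for
full-amplitude action potentials.  Initial conditions per trial: V
uniformly jittered in [V_L − 5, V_L] mV with gates at steady state of the
initial voltage; connectivity, jitter, OU path and Poisson realizations
derive from a single trial seed via independent child generators, making
trials bitwise reproducible.

Numerical caveats, measured: φ = 21 makes the gating kinetics stiff (the
h-gate time constant reaches ≈ 0.05 ms near the spike peak).  At
dt = 0.05 ms the excitatory tonic period is ≈ 1% short of its converged
value, and the inhibitory cell's discretized limit cycle carries ≈ 2% ISI
jitter; the clean second-order error scaling appears below
dt ≈ 0.0125 ms and is verified on subthreshold trajectories.  The network
keeps the working step of 0.05 ms; single-cell PRC characterization uses
0.025 ms, where the inhibitory cycle is regular to machine precision.
Because the currents that drove the printed PRC periods (8.09 ms
excitatory, 6.00 ms inhibitory) are not part of the parameter set, the
drive is bisected until the measured tonic period matches the target to
0.01 ms, and the PRC is computed at that operating point with pulse phases
strictly inside the cycle; the unperturbed reference interval is measured
on the same grid as the perturbed ones so spike-detection quantization
cancels in the phase shift.

## Observables

The LFP proxy is R_e⟨|I_AMPA| + |I_GABA|⟩ averaged over excitatory
neurons, with I_AMPA including the external train; |·| is applied per
neuron before averaging (reading the population bracket literally).  It is
accumulated on the integration grid and averaged into 1 ms bins, so a
500 ms analysis window is 500 samples and zero-padding to 512 gives the
intended frequency oversampling.  The population rate is the 1 ms spike
histogram divided by bin width and population size.  The embedded f-I
scatter pairs each ISI's instantaneous rate with the net input current
averaged over the open interval between the two spikes, blanking ±1 ms
around each spike so intrinsic spike currents do not contaminate the drive
estimate.

## Spectral estimation

Multitaper PSD per the Thomson recipe: 500 ms sliding windows with 50 ms
overlap (450 ms hop, following the stated overlap literally; the hop is
configurable), per-window mean removal (no prewhitening), K = 5 unit-energy
Slepian tapers, zero-padding to 512 samples, plain average over tapers,
windows, then trials.  NW = 3 is implied jointly by K = 5 = 2NW − 1 and
the stated ±6 Hz = NW/0.5 s resolution.  Integrated PSD matches signal
variance within 5% (Parseval check), and the estimate agrees with an
independent multitaper implementation to ≈ 1% at the peak (the residual is
that implementation's eigenvalue weighting of tapers).

Band-limited peaks are reported as the arg-max within 30–90 Hz, flagged as
a true oscillatory peak only when interior, locally maximal, and exceeding
by a factor 2 a power-law trend fitted in log-log space to the band's
flanks (10–30 and 90–200 Hz).  The factor-2 rule holds the false-positive
rate below 5% on pure 1/f² noise (100-seed Monte Carlo in the suite) while
detecting the default network's gamma line at trend ratios > 20.

Band-pass filtering uses a 4th-order Butterworth applied
forward–backward (zero phase) by default so spike–phase relations are not
displaced; a one-pass mode with its group delay is available for strict
replication of single-pass conventions.  Instantaneous phase is the angle
of the analytic signal of the filtered LFP: 0 at peaks, π at troughs;
spike phases interpolate the unwrapped phase linearly.

## Firing-mode analysis

The slow/fast frontier is the minimum of a Silverman-bandwidth Gaussian
KDE of pooled log instantaneous rates, between the two highest density
modes.  The log axis is used because the modes sit roughly a decade apart
and the slow mode is heavily right-skewed on the linear axis.  A dip test
of unimodality gates the procedure (no frontier is reported for unimodal
samples).  The dip statistic is computed exactly via a band-feasibility
reduction — for each candidate mode position, the minimal sup-distance to
a convex–concave CDF is half the maximal deviation of the empirical CDF
from the appropriate hull, minimized over mode positions by bisection —
and is validated in the suite against a brute-force linear-programming
oracle on small samples.  P-values are Monte Carlo against uniform samples
of the same size (the least favorable unimodal null), with samples above
2000 points subsampled for speed.

Classification: an ISI shorter than the frontier interval marks both
flanking spikes fast; a fast spike whose preceding ISI is slow or absent
opens a burst (burst-first); spikes flanking only slow ISIs are slow;
spikes without any ISI stay unclassified.  Spike-triggered averages use a
[−50, +20] ms window, only spikes whose same-neuron predecessor is ≥ 50 ms
older, and — for the local inhibition variant — the spiking neuron's own
recorded GABA current.  Phase histograms count, per population and mode,
only the first spikes of short (burst-first) and long ISIs, normalized per
mode.  The forbidden-gap width is the extent of the KDE region around the
frontier where density stays below half the lower mode peak, reported on
the period (ISI) axis in ms: the depression that creates the gap lasts a
duration set by the inhibitory decay time, so in period units the band
widens with slower GABA even as its location slides to lower rates.

## What the synthetic fixtures emulate

The fixtures generate (a) a 1/f² background with an optional sinusoidal
gamma line, (b) von-Mises phase-locked inhomogeneous Poisson trains with
the exact oscillation phase returned alongside, (c) ISI sequences from a
two-component lognormal mixture whose rate-axis density minimum is
computed analytically, and (d) OU-rate Poisson trains.  Each returns its
own ground truth, so analysis tests assert recovery.  They emulate the
*statistics* the estimators consume, not conductance dynamics: passing
recovery tests shows the estimators are calibrated, not that the network
is biologically faithful.  The network trials themselves are the only
evidence for the emergent claims (gamma peak, bimodality, phase coding).

## Scale of the shipped analyses

Pooled statistics (frontier, slow-ISI fraction) use five 3-second trials;
single-trial analyses (frontier of one trial, STA, phase histograms) use
one; the GABA decay-time sweep uses one trial per τ_d ∈ {2.5, 5, 10, 30} ms
and the low-drive control (5000 spikes/s) one trial.  Twenty-trial
averaging sharpens the histograms but does not move the headline numbers
outside the tolerances used in the tests.

## Measured calibration values

Single-event PSPs onto a resting cell, from the printed parameters: EPSP
peaks 0.429 (2.5 nS → exc), 0.549 (3.2 nS → exc), 0.690 (2.5 nS → inh),
0.881 mV (3.2 nS → inh); IPSP peaks 1.714 (exc) and 2.126 mV (inh).  The
within-population EPSP ratio equals the conductance ratio 3.2/2.5 exactly
(the synapse is far below the shunting regime); the across-population
ratio follows from the halved capacitance at equal leak.  The upper ends
exceed the commonly quoted physiological ranges by 6–13%; freezing the
gates or linearizing the driving force changes these values by < 0.1%, so
they are a direct consequence of the printed parameter set.

## Known limitations

No biophysical forward model of the extracellular potential (the LFP is a
current-sum proxy); no gap junctions, NMDA or plasticity; no bifurcation
continuation (rheobase is found by simulation-based bisection); the dip
test subsamples very large pools; single-trial frontier estimates wander
by ±10 spikes/s across seeds because the inter-mode valley is broad and
shallow.
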