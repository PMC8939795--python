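# Methods

## The circuit model

The model describes the mean membrane voltage of nine neuronal populations
grouped into six sources of the cortico-basal ganglia-thalamic circuit.
Motor cortex (M2) is a laminar microcircuit — superficial (SP), middle (MP)
and deep (DP) pyramidal layers plus inhibitory interneurons (II) — while
striatum (STR), external and internal pallidum (GPe/GPi), subthalamic
nucleus (STN) and ventrolateral thalamus (Thal) are single populations.

Each population is a damped second-order kernel,

    v'' = (H / tau) p - (2 / tau) v' - v / tau**2,

equivalent to the voltage response of an alpha-function synapse with gain
`H` (mV) and time constant `tau` (s).  Population output is a normalised
rate `S(v) = 1 / (1 + exp(-R v))`, with per-population slope `R`
(mV^-1) standing in for the spread of firing thresholds.  Long-range
connections carry strictly positive axonal delays `D` (s) and signed
weights `w` (negative for GABAergic sources: STR, GPe, GPi, and
intracortically II and the self-inhibition terms).  The nine coupled
second-order stochastic delay-differential equations are separated into 18
first-order equations and advanced by Euler-Maruyama at `dt = 0.5 ms`;
the stochastic input (standard deviation `noise_sd`, applied to the
subcortical populations and MP) enters the rate equation scaled by
`sqrt(dt)`.  A 2-s burn-in is discarded and the observed population
voltages (SP for M2, the single population elsewhere) are decimated to
250 Hz with a zero-phase FIR anti-alias filter.  Delays are rounded to
integration steps with a one-step minimum; a guard aborts with the
offending population's name if any |v| exceeds 1e5.

### Microcircuit wiring

Thal->MP, MP->SP, SP->DP, SP<->II; DP is the output layer projecting to
striatum and STN.  Every pyramidal layer carries self-inhibition, and II
does as well: each cortical population's self-inhibition is matched to its
excitatory input so that its operating point stays near the sensitive part
of the sigmoid (without the II term the interneuron population saturates
and the cortical loop loses its gain).

### The shipped default parameterization

The packaged `default_circuit.yaml` is a *fitted surrogate*: a parameter
set tuned to the qualitative regime of the Parkinsonian (6-OHDA rodent
model) state rather than a posterior fitted to empirical recordings (no
empirical data ship with the package).  Tuning was done by linearized
loop-gain analysis followed by simulation scans, with three goals, all
checked by the test suite:

1. **Lower-beta STN resonance.**  The STN/GPe loop (weights +-12, 3-ms
   delays, taus 4 and 5 ms) crosses its phase condition near 17 Hz, giving
   a dominant STN spectral peak inside 14-21 Hz across seeds.
2. **Pathway dose-response.**  STN beta power grows monotonically with the
   pallido-subthalamic (PS) weight — doubling at a multiplier near 2 — and
   with the hyperdirect (HD) weight — doubling near 1.8 — so that both
   Up-states can be calibrated by bisection inside the multiplier bracket
   [1, 6].  Down-states use the fixed multiplier 0.30.
3. **Cortically coherent beta.**  Cortical noise (MP, sd 0.3) dominates the
   subcortical noise sources (sd 0.1), which seeds the subcortical
   resonance from cortex and yields strong M2-STN beta coherence, matching
   the subthalamo-cortical coupling seen in 6-OHDA recordings.  It also gives
   phase-locked cortical stimulation a coherent pathway into the STN.

With this surrogate set the 12-phase amplitude response curve of STN
lower-beta power is sinusoidal with amplifying and suppressing phases
~180 degrees apart, but its magnitude (a few percent) is much smaller
than what a parameter set fitted to empirical recordings can produce;
matching empirical effect magnitudes is out of scope here, and the
closed-loop checks are therefore qualitative (sign and phase ordering,
not effect size).

## Closed-loop stimulation

The controller mirrors an implantable device loop running on the 250-Hz
observed signal.  Every 25 ms it takes the trailing 3 s of the sensed STN
voltage, zero-pads 1 s on each side, applies a zero-phase 4th-order
Butterworth band-pass (14-21 Hz) and a Hilbert transform.  The envelope is
read 25 ms before the window end to avoid the filter's edge transient; the
phase is extrapolated from the most recent positive zero-crossing before
that point, assuming a fixed 18 Hz.  For a true frequency off by `df` the
extrapolated phase accrues at most `|df| / 18 * 360` degrees of error over
one assumed period — 40 degrees at the +-2 Hz deviations typical of beta.

Stimulation starts when the gated envelope strictly exceeds the 75th
percentile of the *baseline* (unstimulated, same noise realization)
envelope and no stimulation occurred within the previous
`stim_duration + refractory` (0.5 s + 0.5 s), runs for 500 ms with the
phase re-estimated every 25 ms, and injects
`A sin(2 pi 18 (t - t_cross) + dphi_shift)` into the SP population's input.
The amplitude is `amplitude_ratio` (default 1/4, configurable) times the
intrinsic noise SD of the stimulated population; SP itself is noise-free,
so the reference falls back to the cortical (MP) noise SD.  Control policies: `fixed`
(18 Hz sinusoid, gated but not phase-tracked, random starting phase) and
`playback` (replay of a recorded waveform into a different noise
realization) are provided as non-phase-specific controls.

Amplitude response curves compare band power inside delivered stimulation
epochs against the *identical* time windows of the baseline run — the
baseline shares the noise realization, so epochs are duration-matched by
construction and the comparison is paired.

## Burst and synchronization analysis

Bursts: zero-phase 4th-order Butterworth at beta1 (14-21 Hz) or beta2
(21-30 Hz), Hilbert envelope, threshold at the linear-interpolated 75th
percentile of the full envelope of the run under analysis (state-specific
thresholds), minimum duration one cycle of the band's lower cut-off.
"Within-burst" always means network-wide samples inside STN burst windows.
PLV is the magnitude of the mean unit phasor of the phase difference; the
surrogate null redraws out-of-burst segments matched in number and
duration, shuffles the segment pairing between channels (truncating each
pair to the shorter segment), and takes the 95th percentile of 500
permutations.  Time-resolved traces use 200-ms windows at 95% overlap (a
10-ms hop; window starts are rounded per window so the non-integer hop of
2.5 samples at 250 Hz is honoured on average).  Relative phase stability
(RPS) is the mean absolute circular finite difference of the M2-STN phase
difference over 0-500 ms from burst onset (the window is configurable,
e.g. to 0-750 ms).

A calibration note: the beta-limited envelope has a correlation time of
roughly the inverse band width (~140 ms for beta1), so percentile-threshold
crossings on pure noise routinely outlast the one-cycle minimum — burst
counts on noise are governed by the threshold, not the duration rule.
Consequently the burst detector's false-alarm behaviour is validated
against amplitude ground truth in the fixtures, not against a
no-crossings expectation.

## Spectra, directionality, smoothing

Preprocessing standardises each channel (mean removal, zero-lag two-pass
FIR band-pass 4-100 Hz, z-score), cuts 1-s epochs and drops any epoch with
|z| above `artifact_z` (default 6).  Spectra are mean Hann periodograms
over the epochs (1-Hz resolution); the 1/f background is removed by a
log-log linear regression over 4-48 Hz, returning residual log10 power.
Non-parametric directionality prewhitens a channel pair via its coherency
`Sxy / sqrt(Sxx Syy)`, transforms to the lag domain, splits the energy over
positive / zero / negative lags (the ambiguous +-n/2 lag of the even-length
FFT is split evenly so that swapping the pair maps forward to reverse
exactly) and returns the three directional spectra; their
frequency-integrated sum reconstructs the integrated squared coherency.
Feature curves can be smoothed by the adjusted-R2-best sum of up to three
Gaussians; ties prefer the lower order since perfect fits make the
criterion float-noise.

## Fingerprints and pooled R2

A fingerprint is (a) per-source within-burst spectra (1-s Hann segments of
concatenated within-window data), truncated to 2-48 Hz and normalised to
unit variance per source, concatenated; plus (b) beta1 and beta2
within-burst PLV matrices.  The pooled R2 between a state fingerprint and
a stimulation fingerprint averages, over the feature blocks used (spectra,
PLV, or both; N_f = 2 for the combined case), the squared error normalised
by the stimulation features' variance about their own mean, and subtracts
from one: 1 is a perfect match, negative values are worse than a flat line.
Stimulated fingerprints use only data within delivered stimulation epochs.
Mask presets cover the full circuit and an "empirical" variant that drops
the hidden nodes (GPi, Thal) from the spectra and restricts PLV to the
basal ganglia.  Phase-recovery curves can optionally be realigned so the
phase of maximum recovery maps to zero; recovery is otherwise computed
linearly after the realignment.

## Sequential ABC

Priors are log-normal (log-sd 0.5) around the shipped defaults for gains,
taus and weights — preserving the sign of inhibitory weights — and uniform
for delays.  Each generation simulates every particle with its own derived
seed, scores the mean squared error over the concatenated (PSD + NPD)
feature vector (the 1/f flattening is applied symmetrically to simulated
and target features), keeps the best 30%, and resamples survivors with a
Gaussian perturbation at half the survivors' spread (log-space for
positive-scale parameters).  Survivors carry their recorded scores into
the next generation's selection pool, so the acceptance threshold never
increases; iteration stops when its relative improvement drops below
`grad_tol` or at `max_gens`.  The point estimate is the per-parameter mode
of the marginal posterior (Gaussian KDE).  Model evidence is approximated
by the fraction of posterior draws whose simulated features land within a
common distance threshold.  The desk-scale defaults — 200 particles, at
most 10 generations, 30-s simulations — are sized for parameter-recovery
validation of the machinery, not for production-scale model inversion.

## Synthetic fixtures

`gen_bursty_oscillation` emulates transient band-limited bursts: a
band-centre carrier under a boxcar-smoothed envelope (baseline 0.1, burst
amplitude 1.1, default 300-ms bursts at 0.5 /s) over 1/f background noise
at a configurable SNR, returning the true intervals.  `gen_coupled_pair`
emulates two phase-coupled oscillations: a frequency-wandering in-band
phase process, repeated with a fixed lag plus von Mises jitter whose
concentration solves `I1(k)/I0(k) = plv_target`.  The jitter is temporally
correlated (Gaussian copula, ~2-Hz bandwidth) with an exact von Mises
marginal: white jitter would be smoothed away by any band-pass used in
measurement, inflating the observed PLV above its target.  Narrow-band
measurement (the beta1 Butterworth) still smooths slightly and biases PLV
upward by a few hundredths; estimator-validation tests therefore measure
with a band wide enough to pass the jitter sidebands.  What these fixtures
do not emulate: non-sinusoidal waveform shape, amplitude-phase coupling,
nonstationary burst statistics, or measurement noise correlated across
channels — passing tests show estimator correctness on known ground truth,
not robustness to those features of real recordings.

## Problem sizes and numerical choices

Simulations integrate at 0.5 ms and are analysed at 250 Hz.  The standard
analysis run is 128 s; state calibration averages three 60-s evaluations
per bisection step (5% stopping tolerance on the power ratio); the
closed-loop phase sweep uses 12 phases over 64-s runs sharing one noise
realization; ABC recovery uses 30-s simulations.  Percentiles use linear
interpolation throughout.  Phase differences are computed as the angle of
`exp(i a) exp(-i b)` (wrap-safe); circular SD is `sqrt(-2 ln Rbar)`;
Watson-Williams applies the standard kappa correction and warns when the
pooled resultant is below 0.45.  Cluster permutation forms clusters at the
two-sided alpha t-threshold, uses summed-t mass against a max-mass label
permutation null (500 permutations), drops clusters under 20 ms and
reports at most five.  The cluster test is exactly calibrated on smooth
(band-limited) traces; on white noise the 20-ms duration rule makes it
conservative — intended, since its inputs are envelope and phase traces.

## Known limitations

* The default circuit is a tuned surrogate; closed-loop effect sizes are
  an order of magnitude below those attainable with empirically fitted
  parameters, so stimulation analyses here are about phase structure,
  not clinical effect magnitude.
* The model cannot represent high-frequency (>60 Hz) stimulation
  biophysics: the lumped synaptic kernels low-pass filter such drive.
* Stimulation is a voltage added to one population's input; no spatial
  spread or field model is included.
* The zero-crossing tracker assumes a fixed 18-Hz rhythm; its accuracy
  degrades with frequency deviation beyond +-2 Hz and at low SNR.
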