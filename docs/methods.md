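# Methods

This note documents the models and procedures implemented in `whiskephys`,
the assumptions behind them, the defaults that matter, and what the
synthetic-data generators do and do not emulate.

## Whisker kinematics

The whisker angle θ(t) (degrees, 500 Hz) is decomposed into four variables.
The angle is band-pass filtered to the whisking band (4–25 Hz; zero-phase
Butterworth, effective 4th order via forward–backward filtering) and the
instantaneous **phase** ϕ(t) is the angle of its analytic signal, so ϕ = 0
falls on the most protracted position and ϕ = ±π on the end of retraction.
Increasing angle is protraction by default; a config flag
(`protraction_positive`) flips the convention for retraction-positive
tracking setups.

**Amplitude** and **midpoint** are evaluated on the *raw* angle at phase
events: at an adjacent protraction/retraction event pair,
θ_amp = (θ_{ϕ=0} − θ_{ϕ=±π})/2 and θ_mid = θ_{ϕ=±π} + (θ_{ϕ=0} − θ_{ϕ=±π})/2,
linearly interpolated between events and held constant outside the first and
last event. Raw angle is used because the decomposition must reconstruct raw
position: θ̂ = θ_mid + θ_amp·cos(ϕ). Phase events are detected as wrapped
zero-crossings (protraction) and ±π wraps (retraction) of the phase track,
which is more robust than raw-trace extrema and coincides with them on clean
oscillations. The **setpoint** is a zero-phase low-pass of the raw angle at
6 Hz; this filter is designed one step steeper (order 4 before the
forward–backward pass) than the band-pass so that whisking at frequencies
just above the cutoff leaves under 10% ripple on the setpoint.

Sweeps are tiled into **epochs** with 1, 2 or 3 s windows, greedily
preferring longer windows. A window is *whisking* when the band-passed
envelope (Hilbert magnitude) stays above 2.5° throughout, *quiet* when it
stays below 1°; ambiguous stretches stay unlabelled and are skipped in 0.5 s
steps. The envelope thresholds and the greedy tiling are this package's
choices — the source convention specifies only the window lengths and the
qualitative quiet/whisking distinction. The **onset** of a whisking epoch
that follows a quiet epoch is the first sample whose raw angle exceeds the
quiet baseline by 1°, with baseline defined here as the median raw angle of
the preceding quiet window.

## Spike analysis

Units are classified from the mean extracellular waveform (channel with the
largest trough): trough-to-peak < 0.4 ms is fast-spiking (FS), > 0.5 ms is
regular-spiking (RS), intermediate widths are excluded. Firing rates are
Z-scored against the mean and SD of 2 s bins pooled over all sweeps of a
session (Light-ON and Light-OFF pooled); a unit with zero SD is flagged
unanalyzable for Z-based statistics.

Whisking modulation compares per-epoch rates (count/duration) between quiet
and whisking epochs with a Wilcoxon rank-sum test (the nonparametric
convention; the source does not name the test), requiring at least 5 epochs
per label. p-values are Benjamini–Hochberg corrected across the units of a
session; a unit is W-Exc/W-Inh when q < 0.05 with higher/lower whisking
rate, otherwise NM. W-ΔAP is the whisking-minus-quiet difference of mean
rates in the unit's Z units. Peri-event time histograms use 200 ms bins
around whisking onset, converted to Z units, averaged over onsets with full
window coverage, Gaussian-smoothed (SD = 1 bin), and baseline-subtracted
over −1.0 to −0.2 s. The light-modulation index is
(rate_ON − rate_OFF)/(rate_ON + rate_OFF), undefined when both are zero.

## Tuning to whisking variables

Only whisking-epoch samples enter tuning (phase is meaningless when quiet).
Each variable (phase, amplitude, midpoint) is divided into 50
equal-probability bins at empirical quantiles; the tuning histogram is
spikes per bin divided by time in the bin. The smoother is an interface
whose default is a penalized cubic smoothing spline with GCV-selected
smoothness (`scipy.interpolate.make_smoothing_spline`), applied over three
tiled periods for phase so the curve is effectively periodic, and clipped at
zero. This stand-in has the same contract as a free-knot spline smoother
(BARS): a smooth nonnegative curve exposing max/min/argmax; a BARS backend
can be slotted in without touching downstream statistics.

Significance is a two-step gate. Step 1: one-way ANOVA across bins at
α = 0.05 on per-element responses, where an element is one whisking sample
of the variable track and its response is that sample's spike rate.
Fixed-duration elements matter: rates of variable-length bin visits carry
bin-dependent variances (phase velocity differs across bouts), which
breaks the exchangeability the permutation null assumes and inflates its
type-I error. Step 2, only for step-1 passers: the responses are permuted
across elements 1,000 times (the element-to-bin structure is fixed) and
the ANOVA F recomputed per permutation. The unit is tuned when the
observed F sits in the top α fraction of the permutation null *including
the observed statistic* — the finite-sample-exact permutation convention,
which bounds the expected type-I error by α, whereas a strict
"greater than the 95th percentile of the shuffles alone" rule exceeds α
slightly by discreteness. The reported shuffle p-value is the plain
fraction of permuted F values at or above the observed one, and each unit
uses its own shuffle distribution. The acceptance script measures the
procedure's empirical type-I error on 500 null units.

Curve statistics: modulation depth = (max − min)/baseline, with baseline
defined as the mean rate over quiet epochs (the source leaves "baseline
spike rate" undefined; units with zero baseline are flagged); modulation
index = (max − min)/(max + min); preferred value = argmax. Preferred-phase
shifts between conditions are wrapped to (−π, π], with −π mapped to +π.

## Membrane potential

Action potentials are detected on dV/dt (> 10 V/s, 2 ms refractory) and
excised by linear interpolation from 1 ms before to 4 ms after the AP peak;
all subthreshold statistics are computed on the cleaned trace (detection
can be skipped by supplying `cleaned_vm` directly). Per-epoch mean,
variance and AP rate are aggregated into whisking − quiet deltas per light
condition. Slow-wave amplitude is the 1–5 Hz integral of the one-sided FFT
magnitude (2|X|/N, trapezoid on the frequency grid) averaged over
non-overlapping 2 s segments, untapered. Note that magnitude-spectrum
integrals are resolution-specific; the 2 s segmentation is part of the
definition and comparisons are only meaningful at that resolution.

Phase-locked Vm is the average of the cleaned trace over 64 equal-width
phase bins of the whisking samples, with Vm interpolated onto the kinematic
sample clock (the native resolution of the phase estimate); depth is its
peak-to-trough. Significance comes from circular shuffling: each of 1,000
iterations rotates each whisking epoch's Vm by an independent uniform
offset (phase labels fixed) and recomputes the depth; p is the fraction of
shuffled depths ≥ the observed depth. The shuffle null is valid for
signals stationary within an epoch; it is calibrated empirically in the
acceptance suite. Liquid junction potential is not corrected.

## LFP and current source density

LFP is anti-alias resampled (1 kHz for spectra, 3 kHz for CSD) and
zero-phase low-passed at 100 Hz. State spectra are Welch-style averages of
Hann-tapered 2 s segment periodograms from epochs longer than 2 s, and all
spectra are normalized to the peak of the averaged Light-OFF spectrum, so
the OFF peak is exactly 1.

CSD is the discrete second spatial derivative of the touch-triggered
average along one probe column (odd or even channels of the two-column
shank; Δz from the column's depth map), with the sink-negative convention
CSD_i = −(V_{i−1} − 2V_i + V_{i+1})/Δz² in mV/mm², so the sink under a
negative touch response is negative at its channel. Boundary channels are
padded by duplication and never win the sink criterion. Which physical
column a channel index belongs to is hardware metadata carried by the
sidecar/recipe, not inferred from the data.

Layer-4 localization scores each column channel on three criteria of the
touch-triggered average: shortest peak latency (restricted to channels with
at least half the maximal response, since latency presupposes a response),
largest peak amplitude, and fastest CSD sink onset (first crossing of 20%
of the channel's peak sink; channels whose sink is below 25% of the
column's largest sink are excluded as source/noise channels). The criteria
vote; ties and three-way splits resolve toward the amplitude winner with a
disagreement flag. The winner is anchored at a subpial depth of 500 µm and
layer boundaries come from an editable config table.

## Condition comparisons

Paired OFF/ON comparisons test the paired differences for normality
(Shapiro–Wilk at 0.05; the source says normality was "routinely tested"
without naming the test) and use a paired t test when normal, Wilcoxon
signed-rank otherwise; identical pairs degenerate to p = 1. Light-OFF
sweeps always precede Light-ON sweeps; the order is metadata.

## Synthetic data

Generators produce data with exactly the structure the analysis assumes,
plus ground truth for oracles:

* **Whisker traces**: cosine bouts (frequency in 4–25 Hz, fixed amplitude
  and midpoint per bout, analytic phase stored) over a quiet baseline with
  Gaussian jitter. Default study conditions used in validation: 300 s
  sweeps with 7 s bouts covering roughly 60% of the sweep at 8–15 Hz and
  6–15° amplitude, which is a realistic bout-rich awake session.
* **Spike trains**: inhomogeneous Poisson via thinning against λ(t) =
  baseline · state-gain · exp(κ·cos(ϕ − ϕ_pref))/I₀(κ) · linear
  amplitude/midpoint terms (floored at zero, with a warning) ·
  (1 − suppression) on Light-ON sweeps. The Bessel normalization keeps the
  time-averaged phase factor at 1 so the baseline rate stays interpretable.
  Candidates are drawn homogeneously at max λ and accepted by the rate at
  the enclosing 500 Hz sample, equivalent to per-sample thinning with
  uniform jitter.
* **Vm**: rest potential + 1–5 Hz band-limited noise whose SD switches
  between quiet and whisking values + whisking depolarization + phase-locked
  cosine + membrane-filtered (80 Hz) measurement noise; stereotyped 2 ms
  spikes are inserted at threshold crossings of the subthreshold trace.
  State transitions are smoothed with a 50 ms raised cosine so gain
  switching cannot masquerade as spikes, and noise filtering is padded by
  5 s per side so filter transients never contaminate edge epochs.
* **Laminar LFP**: per touch, a negative alpha-function deflection
  (τ = 8 ms) whose amplitude falls off as a Gaussian (σ = 100 µm) of depth
  distance from the true L4 channel and whose latency grows by 1 ms per
  channel of distance, over pink background noise. The noiseless field's
  second spatial derivative sinks at the true channel by construction.

All generators are bit-reproducible given (params, seed). The light
suppression is a constant per-sweep factor; no suppression time course is
modelled because none is quantified per epoch in the source conventions.

What the generators do **not** emulate — and hence what passing tests do
not demonstrate about real data: tracking noise with heavy tails or dropped
frames, non-sinusoidal whisk cycles (real protraction is faster than
retraction), rate adaptation and refractoriness in spike trains, Vm
up/down-state bimodality, electrode drift, and volume-conduction geometry
beyond a separable space–time dipole.

## Validation problem sizes

The bundled validation suite runs at sizes chosen to make each statistical
check well-powered on a desktop machine: 500 null units for the tuning
type-I calibration, 100 seeded units for tuning recovery/power, 500-run
null cohorts for the circular-shuffle calibration (200 shuffles per run;
p-resolution 0.005 is ample to score p < 0.05), 100 seeded sessions for
CSD localization at SNR 5, and 80/200-unit cohorts for the whisking
classification calibration.

## Known limitations

* The spline smoother is a deterministic surrogate for BARS; it matches
  BARS in contract, not in posterior uncertainty.
* Phase is undefined during quiet epochs; any consumer of the phase track
  must mask by whisking epochs (the tuning and Vm modules do).
* Amplitude/midpoint tracks are frozen outside the first/last phase event
  of a sweep.
* The FFT band integral inherits the resolution dependence of magnitude
  integrals (see above).
* Equal-probability binning merges bins under heavy ties and flags the
  result; downstream tests treat merged-bin units as having fewer bins.
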