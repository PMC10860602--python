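"""Synthetic data with known ground truth for every pipeline stage.

The generators emulate the statistical structure the analysis assumes:

* **whisker traces** — rhythmic 4-25 Hz cosine bouts (known frequency,
  amplitude, midpoint, analytic phase) interleaved with quiet periods of
  Gaussian jitter around a baseline angle;
* **spike trains** — inhomogeneous Poisson units whose rate combines a
  baseline, a whisking-state gain, a von Mises phase factor (normalized by
  the Bessel ratio so the time-averaged factor is 1 and the baseline rate
  stays interpretable), linear amplitude/midpoint terms (floored at zero),
  and a multiplicative Light-ON suppression;
* **Vm traces** — rest potential plus 1-5 Hz band-limited noise whose SD
  drops during whisking, a whisking depolarization, a phase-locked cosine
  term, white noise, and stereotyped 2 ms spikes inserted at threshold
  crossings;
* **laminar LFP** — per touch, a spatiotemporal dipole whose deflection is
  largest and fastest at the true L4 channel (Gaussian spatial profile,
  latency increasing with channel distance) over pink background noise.

Everything is bit-reproducible given (params, seed), and each generator
returns its ground truth alongside the data so downstream statistics can be
checked against analytic or brute-force oracles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal, special

from .kinematics import EpochSet, KinematicDecomposition, WhiskerTrace
from .lfp import LaminarSession
from .spikes import SpikeUnit
from .vm import VmRecording

__all__ = [
    "WhiskGenParams",
    "TuningGroundTruth",
    "VmGroundTruth",
    "LaminarGroundTruth",
    "SyntheticWhisk",
    "generate_whisker_trace",
    "truth_decomposition",
    "truth_epochs",
    "rate_function",
    "generate_spike_train",
    "generate_vm_trace",
    "generate_laminar_lfp",
    "make_waveform",
]


# ---------------------------------------------------------------- whiskers

@dataclass
class WhiskGenParams:
    """One synthetic sweep: bout schedule over a quiet baseline.

    Each bout is (start_s, end_s, freq_hz, amplitude_deg, midpoint_deg);
    bouts must be non-overlapping, inside the sweep, with frequencies in
    the whisking band [4, 25] Hz and nonnegative amplitudes.
    """

    sweep_duration: float = 60.0
    sample_rate: float = 500.0
    bout_schedule: list[tuple[float, float, float, float, float]] = field(default_factory=list)
    baseline_deg: float = 5.0
    quiet_noise_sd: float = 0.1
    phase0: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        prev_end = -np.inf
        for s, e, f, a, m in sorted(self.bout_schedule):
            if s < prev_end:
                raise ValueError("overlapping bouts")
            if s < 0 or e > self.sweep_duration or e <= s:
                raise ValueError("bout outside sweep or empty")
            if not (4.0 <= f <= 25.0):
                raise ValueError("bout frequency outside [4, 25] Hz")
            if a < 0:
                raise ValueError("negative bout amplitude")
            prev_end = e


@dataclass
class SyntheticWhisk:
    """Generated trace plus analytic ground truth (NaN phase outside bouts)."""

    trace: WhiskerTrace
    true_phase: np.ndarray
    true_amplitude: np.ndarray
    true_midpoint: np.ndarray
    bouts: list[tuple[float, float, float, float, float]]
    params: WhiskGenParams


def generate_whisker_trace(params: WhiskGenParams) -> SyntheticWhisk:
    """Cosine bouts over a noisy quiet baseline, with analytic phase truth."""
    rng = np.random.default_rng(params.seed)
    n = int(round(params.sweep_duration * params.sample_rate))
    t = np.arange(n) / params.sample_rate
    angle = np.full(n, params.baseline_deg)
    if params.quiet_noise_sd > 0:
        angle = angle + rng.normal(0.0, params.quiet_noise_sd, n)
    phase = np.full(n, np.nan)
    amp = np.zeros(n)
    mid = np.full(n, params.baseline_deg)
    for s, e, f, a, m in params.bout_schedule:
        sel = (t >= s) & (t < e)
        arg = 2 * np.pi * f * (t[sel] - s) + params.phase0
        angle[sel] = m + a * np.cos(arg)
        phase[sel] = np.angle(np.exp(1j * arg))
        amp[sel] = a
        mid[sel] = m
    trace = WhiskerTrace(angle, params.sample_rate)
    return SyntheticWhisk(trace, phase, amp, mid, list(params.bout_schedule), params)


def truth_decomposition(synth: SyntheticWhisk) -> KinematicDecomposition:
    """Ground-truth decomposition built from the analytic bout parameters.

    Independent of the Hilbert pipeline, for oracle comparisons. Phase is 0
    outside bouts (where it is meaningless and masked by the epochs).
    """
    phase = np.nan_to_num(synth.true_phase, nan=0.0)
    prot = np.nonzero(np.isclose(np.abs(phase), 0.0) & (synth.true_amplitude > 0))[0]
    d = np.diff(synth.true_phase)
    retr = np.nonzero(d < -np.pi)[0]
    return KinematicDecomposition(
        phase=phase, amplitude=synth.true_amplitude.copy(),
        midpoint=synth.true_midpoint.copy(), setpoint=synth.true_midpoint.copy(),
        protraction_events=prot, retraction_events=retr,
        sample_rate=synth.params.sample_rate)


def truth_epochs(params: WhiskGenParams, guard_s: float = 0.0) -> EpochSet:
    """Epochs straight from the bout schedule: bouts whisking, rest quiet."""
    eps: list[tuple[str, float, float]] = []
    prev = 0.0
    for s, e, *_ in sorted(params.bout_schedule):
        if s - prev > 2 * guard_s + 1e-9:
            eps.append(("quiet", prev + guard_s, s - guard_s))
        eps.append(("whisking", s, e))
        prev = e
    if params.sweep_duration - prev > 2 * guard_s + 1e-9:
        eps.append(("quiet", prev + guard_s, params.sweep_duration - guard_s))
    return EpochSet(epochs=eps, onset_times=[s for s, *_ in sorted(params.bout_schedule)])


# ------------------------------------------------------------------ spikes

@dataclass
class TuningGroundTruth:
    """Rate model of one synthetic unit.

    whisking_gain > 1 makes a W-Exc-like unit, < 1 W-Inh-like, = 1
    non-modulated. The von Mises phase factor is divided by I0(κ) so its
    average over uniform phase is 1, decoupling tuning sharpness from the
    mean rate. light_suppression multiplies the rate by (1 − s) on
    Light-ON sweeps.
    """

    baseline_rate: float = 5.0
    whisking_gain: float = 1.0
    phase_kappa: float = 0.0
    preferred_phase: float = 0.0
    amp_slope: float = 0.0        # Hz-fraction per degree
    mid_slope: float = 0.0
    light_suppression: float = 0.0

    def __post_init__(self) -> None:
        if self.baseline_rate < 0 or self.whisking_gain < 0:
            raise ValueError("rates and gains must be nonnegative")
        if not (0.0 <= self.light_suppression <= 1.0):
            raise ValueError("light_suppression must lie in [0, 1]")


def rate_function(decomp: KinematicDecomposition, whisk_mask: np.ndarray,
                  truth: TuningGroundTruth, light_on: bool = False) -> np.ndarray:
    """λ(t) on the kinematic sample grid, Hz."""
    lam = np.full(decomp.phase.size, truth.baseline_rate)
    w = whisk_mask.astype(bool)
    lam[w] *= truth.whisking_gain
    if truth.phase_kappa > 0:
        vm = np.exp(truth.phase_kappa * np.cos(decomp.phase[w] - truth.preferred_phase))
        lam[w] *= vm / special.i0(truth.phase_kappa)
    lin = 1.0 + truth.amp_slope * decomp.amplitude + truth.mid_slope * decomp.midpoint
    if np.any(lin < 0):
        warnings.warn("linear amplitude/midpoint term went negative; floored at 0")
        lin = np.clip(lin, 0.0, None)
    lam *= lin
    if light_on:
        lam *= 1.0 - truth.light_suppression
    return lam


def generate_spike_train(decomp: KinematicDecomposition, epochs: EpochSet,
                         truth: TuningGroundTruth, light_on: bool = False,
                         seed: int = 0, unit_id: str = "u0", sweep_id: str = "sweep0",
                         trough_to_peak_ms: float = 0.6) -> SpikeUnit:
    """Inhomogeneous-Poisson spike train via thinning against λ(t).

    Candidate spikes are drawn homogeneously at max λ and accepted with
    probability λ(t)/λmax, with λ evaluated at the enclosing kinematic
    sample — equivalent to per-sample thinning with uniform jitter. The
    ground-truth λ(t) is attached as ``rate_true``.
    """
    rng = np.random.default_rng(seed)
    fs = decomp.sample_rate
    n = decomp.phase.size
    duration = n / fs
    mask = epochs.sample_mask("whisking", n, fs, decomp.t0)
    lam = rate_function(decomp, mask, truth, light_on)
    lam_max = float(lam.max())
    if lam_max > 0:
        n_cand = rng.poisson(lam_max * duration)
        cand = np.sort(rng.uniform(0.0, duration, n_cand))
        idx = np.minimum((cand * fs).astype(int), n - 1)
        keep = rng.uniform(0.0, 1.0, n_cand) < lam[idx] / lam_max
        times = cand[keep]
    else:
        times = np.array([])
    return SpikeUnit(unit_id=unit_id, spike_times={sweep_id: times},
                     sweep_durations={sweep_id: duration},
                     mean_waveform=make_waveform(trough_to_peak_ms),
                     rate_true=lam, light_on={sweep_id: light_on})


def make_waveform(trough_to_peak_ms: float, rate_hz: float = 30000.0,
                  duration_ms: float = 3.0) -> np.ndarray:
    """Stereotyped extracellular waveform with a given trough-to-peak time."""
    n = int(round(duration_ms * 1e-3 * rate_hz))
    t = np.arange(n) / rate_hz * 1000.0
    t_tr = duration_ms / 3.0
    t_pk = t_tr + trough_to_peak_ms
    w = -np.exp(-((t - t_tr) ** 2) / (2 * 0.08 ** 2))
    w += 0.45 * np.exp(-((t - t_pk) ** 2) / (2 * (0.1 + 0.25 * trough_to_peak_ms) ** 2))
    return w


# ---------------------------------------------------------------------- Vm

@dataclass
class VmGroundTruth:
    """Subthreshold Vm model: slow waves that shrink during whisking, a
    whisking depolarization, and phase-locked modulation."""

    rest_vm: float = -60.0
    slow_wave_band: tuple[float, float] = (1.0, 5.0)
    slow_wave_sd_quiet: float = 3.0
    slow_wave_sd_whisk: float = 1.0
    whisk_depol: float = 3.0
    phase_lock_amp: float = 0.0
    phase_lock_pref: float = 0.0
    noise_sd: float = 0.3
    spike_threshold: float = -40.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.slow_wave_sd_whisk > self.slow_wave_sd_quiet:
            raise ValueError("slow-wave SD must not grow during whisking")
        if self.spike_threshold <= self.rest_vm:
            raise ValueError("spike threshold must exceed the resting potential")


def generate_vm_trace(decomp: KinematicDecomposition, epochs: EpochSet,
                      truth: VmGroundTruth, sample_rate: float = 10000.0
                      ) -> tuple[VmRecording, dict]:
    """Whole-cell Vm with known subthreshold components.

    Returns ``(recording, ground_truth)`` where the ground truth carries the
    noiseless subthreshold trace, each additive component, and the inserted
    spike times.
    """
    rng = np.random.default_rng(truth.seed)
    fs = sample_rate
    duration = decomp.phase.size / decomp.sample_rate
    n = int(round(duration * fs))
    t = np.arange(n) / fs

    kin_t = decomp.times
    mask_kin = epochs.sample_mask("whisking", decomp.phase.size, decomp.sample_rate, decomp.t0)
    whisk = np.interp(t, kin_t, mask_kin.astype(float)) > 0.5
    cosph = np.interp(t, kin_t, np.cos(decomp.phase))
    sinph = np.interp(t, kin_t, np.sin(decomp.phase))
    phase = np.arctan2(sinph, cosph)
    # soft state transitions (50 ms raised cosine) so switching the state
    # gains never injects step artefacts that look like spikes
    ramp = int(round(0.05 * fs))
    if ramp > 1:
        kern = np.hanning(2 * ramp + 1)
        kern /= kern.sum()
        soft = np.convolve(whisk.astype(float), kern, mode="same")
    else:
        soft = whisk.astype(float)

    # slow-wave: unit-SD band-limited noise scaled per state; generated
    # with 5 s padding on both sides so filter startup transients (which
    # would inflate edge-epoch variance) never enter the sweep
    pad = int(round(5.0 * fs))
    white = rng.standard_normal(n + 2 * pad)
    sos = signal.butter(2, truth.slow_wave_band, btype="bandpass", fs=fs, output="sos")
    slow = signal.sosfiltfilt(sos, white)[pad:pad + n]
    sd = float(np.std(slow))
    slow = slow / sd if sd > 0 else slow
    sw_scale = truth.slow_wave_sd_quiet + (truth.slow_wave_sd_whisk
                                           - truth.slow_wave_sd_quiet) * soft
    slow_component = slow * sw_scale
    depol_component = truth.whisk_depol * soft
    lock_component = soft * truth.phase_lock_amp * np.cos(phase - truth.phase_lock_pref)

    sub = truth.rest_vm + slow_component + depol_component + lock_component
    if truth.noise_sd > 0:
        # membrane-filtered measurement noise (~2 ms time constant), so the
        # noise derivative stays far below spike-detection dV/dt thresholds
        fast = rng.standard_normal(n + 2 * pad)
        sos_lp = signal.butter(2, 80.0, btype="low", fs=fs, output="sos")
        fast = signal.sosfiltfilt(sos_lp, fast)[pad:pad + n]
        fast *= truth.noise_sd / np.std(fast)
        vm = sub + fast
    else:
        vm = sub.copy()

    # stereotyped 2 ms spikes at upward threshold crossings of the
    # subthreshold trace (rare unless the threshold is set low on purpose)
    above = sub >= truth.spike_threshold
    crossings = np.nonzero(above[1:] & ~above[:-1])[0] + 1
    spike_len = int(round(2e-3 * fs))
    half = spike_len // 2
    template = 45.0 * np.exp(-((np.arange(spike_len) - half) ** 2) / (2 * (spike_len / 7) ** 2))
    spike_times = []
    last = -np.inf
    for c in crossings:
        if c - last < 2 * spike_len or c + spike_len > n:
            continue
        vm[c:c + spike_len] += template
        spike_times.append(c / fs)
        last = c
    rec = VmRecording(vm=vm, sample_rate=fs)
    gt = {
        "subthreshold": sub, "slow_component": slow_component,
        "depol_component": depol_component, "lock_component": lock_component,
        "spike_times": np.asarray(spike_times), "whisk_mask": whisk, "truth": truth,
    }
    return rec, gt


# --------------------------------------------------------------------- LFP

@dataclass
class LaminarGroundTruth:
    """Touch-evoked laminar dipole with a sink at a known channel."""

    n_channels: int = 32
    channel_spacing_um: float = 25.0   # along the shank; odd/even columns are 2x
    true_l4_channel: int = 14
    touch_times: tuple[float, ...] = (1.0, 3.0, 5.0)
    sink_latency_gradient_ms: float = 1.0   # per channel of distance
    sink_amplitude_mv: float = 0.5
    duration_s: float = 8.0
    sample_rate: float = 3000.0
    spatial_sigma_um: float = 100.0
    kernel_tau_ms: float = 8.0
    noise_sd_mv: float = 0.02
    depth_top_um: float = 150.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.true_l4_channel < self.n_channels):
            raise ValueError("true_l4_channel outside the array")
        if any(t < 0 or t > self.duration_s for t in self.touch_times):
            raise ValueError("touch times outside the sweep")


def _alpha_kernel(t: np.ndarray, tau: float) -> np.ndarray:
    """Unit-peak alpha function, zero for t < 0; peak at t = tau."""
    out = np.zeros_like(t)
    pos = t > 0
    out[pos] = (t[pos] / tau) * np.exp(1.0 - t[pos] / tau)
    return out


def generate_laminar_lfp(truth: LaminarGroundTruth) -> tuple[LaminarSession, dict]:
    """Laminar touch-evoked LFP over pink background noise.

    Per touch and channel: a negative alpha-function deflection whose
    amplitude falls off as a Gaussian of depth distance from the true L4
    channel and whose latency grows with channel distance. Returns the
    session and the noiseless field for oracle checks.
    """
    rng = np.random.default_rng(truth.seed)
    fs = truth.sample_rate
    n = int(round(truth.duration_s * fs))
    t = np.arange(n) / fs
    ch = np.arange(truth.n_channels)
    depths = truth.depth_top_um + ch * truth.channel_spacing_um
    dist_um = np.abs(depths - depths[truth.true_l4_channel])
    amp = truth.sink_amplitude_mv * np.exp(-dist_um ** 2 / (2 * truth.spatial_sigma_um ** 2))
    latency = truth.sink_latency_gradient_ms * 1e-3 * np.abs(ch - truth.true_l4_channel)

    field_clean = np.zeros((truth.n_channels, n))
    tau = truth.kernel_tau_ms * 1e-3
    for t0 in truth.touch_times:
        for i in ch:
            field_clean[i] -= amp[i] * _alpha_kernel(t - t0 - latency[i], tau)

    lfp = field_clean.copy()
    if truth.noise_sd_mv > 0:
        spec = np.fft.rfft(rng.standard_normal((truth.n_channels, n)), axis=1)
        f = np.fft.rfftfreq(n, 1 / fs)
        shaping = 1.0 / np.sqrt(np.maximum(f, 1.0))  # pink-ish above 1 Hz
        pink = np.fft.irfft(spec * shaping, n, axis=1)
        pink *= truth.noise_sd_mv / np.std(pink)
        lfp += pink

    session = LaminarSession(lfp, depths, fs, np.asarray(truth.touch_times))
    return session, {"field_clean": field_clean, "depths": depths,
                     "amplitude_profile": amp, "latency_s": latency, "truth": truth}
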