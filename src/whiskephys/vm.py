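"""Subthreshold membrane-potential (Vm) analysis for whole-cell recordings.

Action potentials are detected by a dV/dt threshold and excised (linear
interpolation from 1 ms before to 4 ms after each AP peak) so that epoch
means and variances describe the subthreshold dynamics. Per-epoch statistics
(mean, variance, AP rate) are aggregated into whisking − quiet deltas per
light condition. Slow-wave power is the 1-5 Hz integral of the FFT magnitude
averaged over 2 s segments. Whisking-phase-locked Vm modulation is the
peak-to-trough depth of the phase-binned average Vm, with significance from
circular shuffling of each whisking epoch's trace (p = fraction of shuffled
depths ≥ observed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import AnalysisConfig
from .kinematics import EpochSet, KinematicDecomposition

__all__ = [
    "VmRecording",
    "VmEpochStats",
    "PhaseLockedVm",
    "detect_and_clean_spikes",
    "epoch_vm_stats",
    "vm_condition_deltas",
    "vm_band_fft",
    "phase_locked_vm",
    "test_phase_lock",
]


@dataclass
class VmRecording:
    """One whole-cell sweep: raw Vm plus detected/cleaned derivatives."""

    vm: np.ndarray                # mV
    sample_rate: float            # Hz, >= 10 kHz typically
    sweep_id: str = "sweep0"
    t0: float = 0.0
    light_on: bool = False
    ap_times: np.ndarray | None = None
    cleaned_vm: np.ndarray | None = None

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.vm.size) / self.sample_rate

    @property
    def duration(self) -> float:
        return self.vm.size / self.sample_rate


@dataclass
class VmEpochStats:
    label: str
    start_s: float
    end_s: float
    mean_vm: float                # mV
    vm_variance: float            # mV^2
    ap_rate: float                # Hz
    fft_band_integral: float      # mV over the slow-wave band (NaN if epoch < 2 s)
    light_on: bool = False


@dataclass
class PhaseLockedVm:
    phase_centers: np.ndarray
    mean_vm: np.ndarray           # mV per phase bin
    modulation_depth: float       # mV, peak-to-trough
    most_depolarized_phase: float
    n_cycles: int
    p_shuffle: float = np.nan
    enough_cycles: bool = True


def detect_and_clean_spikes(rec: VmRecording, config: AnalysisConfig | None = None) -> VmRecording:
    """Detect APs by dV/dt threshold and excise them from the trace.

    Crossings of ``vm_dvdt_threshold`` (V/s) within the refractory window
    are merged into one AP; the AP time is the Vm peak after the crossing.
    The cleaned trace linearly interpolates from ``vm_excise_pre_ms``
    before to ``vm_excise_post_ms`` after each peak.
    """
    config = config or AnalysisConfig()
    fs = rec.sample_rate
    vm = rec.vm
    dvdt = np.gradient(vm) * fs / 1000.0  # mV/sample -> V/s
    above = dvdt > config.vm_dvdt_threshold
    crossings = np.nonzero(above[1:] & ~above[:-1])[0] + 1

    refrac = int(round(config.vm_refractory_ms * 1e-3 * fs))
    peak_search = int(round(2e-3 * fs))
    peaks: list[int] = []
    last = -np.inf
    for c in crossings:
        if c - last < refrac:
            continue
        seg_end = min(c + peak_search, vm.size)
        peaks.append(c + int(np.argmax(vm[c:seg_end])))
        last = c
    peaks_arr = np.asarray(peaks, dtype=int)

    cleaned = vm.astype(float).copy()
    pre = int(round(config.vm_excise_pre_ms * 1e-3 * fs))
    post = int(round(config.vm_excise_post_ms * 1e-3 * fs))
    for p in peaks_arr:
        i0, i1 = max(p - pre, 0), min(p + post, vm.size - 1)
        cleaned[i0:i1 + 1] = np.linspace(cleaned[i0], cleaned[i1], i1 - i0 + 1)

    rec.ap_times = rec.t0 + peaks_arr / fs
    rec.cleaned_vm = cleaned
    return rec


def vm_band_fft(x: np.ndarray, fs: float, band: tuple[float, float] = (1.0, 5.0),
                segment_s: float = 2.0):
    """FFT magnitude spectrum averaged over non-overlapping segments.

    Magnitudes are one-sided amplitude spectra (2|X|/N, mV); the band
    integral is a trapezoid over the frequency grid restricted to ``band``.
    Returns ``(freqs, mean_spectrum, band_integral)``.
    """
    nseg = int(round(segment_s * fs))
    if x.size < nseg:
        raise ValueError(f"trace shorter than one {segment_s} s segment")
    nwin = x.size // nseg
    segs = x[:nwin * nseg].reshape(nwin, nseg)
    spec = np.abs(np.fft.rfft(segs, axis=1)) / nseg
    spec[:, 1:] *= 2.0
    mean_spec = spec.mean(axis=0)
    freqs = np.fft.rfftfreq(nseg, 1.0 / fs)
    sel = (freqs >= band[0]) & (freqs <= band[1])
    integral = float(np.trapezoid(mean_spec[sel], freqs[sel]))
    return freqs, mean_spec, integral


def epoch_vm_stats(rec: VmRecording, epochs: EpochSet,
                   config: AnalysisConfig | None = None) -> list[VmEpochStats]:
    """Mean, variance, AP rate and slow-wave band integral per epoch.

    Statistics are computed on the cleaned (AP-excised) trace; call
    :func:`detect_and_clean_spikes` first (done automatically here when
    needed).
    """
    config = config or AnalysisConfig()
    if rec.cleaned_vm is None:
        detect_and_clean_spikes(rec, config)
    fs, t0 = rec.sample_rate, rec.t0
    out = []
    for lab, s, e in epochs.epochs:
        i0 = max(0, int(round((s - t0) * fs)))
        i1 = min(rec.vm.size, int(round((e - t0) * fs)))
        seg = rec.cleaned_vm[i0:i1]
        n_ap = int(np.sum((rec.ap_times >= s) & (rec.ap_times < e)))
        dur = e - s
        if seg.size >= int(config.fft_segment_s * fs):
            _, _, integral = vm_band_fft(seg - np.mean(seg), fs, config.vm_band_hz,
                                         config.fft_segment_s)
        else:
            integral = np.nan
        out.append(VmEpochStats(lab, s, e, float(np.mean(seg)), float(np.var(seg)),
                                n_ap / dur, integral, rec.light_on))
    return out


def vm_condition_deltas(stats_list: list[VmEpochStats]) -> dict[str, float]:
    """Whisking − quiet differences of the per-epoch means.

    Returns ΔVm (mV), ΔAP (Hz), ΔVariance (mV²) plus the per-state band
    integrals, the convention used for whole-cell condition tables.
    """
    def _mean(label: str, attr: str) -> float:
        vals = [getattr(s, attr) for s in stats_list if s.label == label]
        vals = [v for v in vals if np.isfinite(v)]
        return float(np.mean(vals)) if vals else np.nan

    return {
        "delta_vm_mv": _mean("whisking", "mean_vm") - _mean("quiet", "mean_vm"),
        "delta_ap_hz": _mean("whisking", "ap_rate") - _mean("quiet", "ap_rate"),
        "delta_variance_mv2": _mean("whisking", "vm_variance") - _mean("quiet", "vm_variance"),
        "band_integral_quiet_mv": _mean("quiet", "fft_band_integral"),
        "band_integral_whisk_mv": _mean("whisking", "fft_band_integral"),
    }


def _whisk_segments(rec: VmRecording, decomp: KinematicDecomposition, epochs: EpochSet,
                    n_bins: int):
    """Per-whisking-epoch (vm_on_kinematic_clock, phase_bin) pairs.

    Vm is linearly interpolated onto the kinematic sample clock, the native
    resolution of the phase estimate.
    """
    vm = rec.cleaned_vm if rec.cleaned_vm is not None else rec.vm
    t_vm = rec.times
    kin_t = decomp.times
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    segments = []
    for s, e in epochs.by_label("whisking"):
        sel = (kin_t >= s) & (kin_t < e)
        if not np.any(sel):
            continue
        v = np.interp(kin_t[sel], t_vm, vm)
        b = np.clip(np.searchsorted(edges, decomp.phase[sel], side="right") - 1, 0, n_bins - 1)
        segments.append((v, b))
    return segments, edges


def _pooled_depth(segments, n_bins: int) -> tuple[np.ndarray, float]:
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins)
    for v, b in segments:
        sums += np.bincount(b, weights=v, minlength=n_bins)
        counts += np.bincount(b, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    ok = np.isfinite(means)
    depth = float(np.max(means[ok]) - np.min(means[ok])) if ok.any() else np.nan
    return means, depth


def phase_locked_vm(rec: VmRecording, decomp: KinematicDecomposition, epochs: EpochSet,
                    config: AnalysisConfig | None = None) -> PhaseLockedVm:
    """Average Vm as a function of whisking phase.

    Whisking-epoch Vm samples are binned into equal-width phase bins and
    averaged; depth is the peak-to-trough of the average, the most
    depolarized phase its argmax.
    """
    config = config or AnalysisConfig()
    segments, edges = _whisk_segments(rec, decomp, epochs, config.vm_phase_bins)
    centers = (edges[:-1] + edges[1:]) / 2
    means, depth = _pooled_depth(segments, config.vm_phase_bins)
    n_cycles = 0
    for s, e in epochs.by_label("whisking"):
        ev_t = decomp.t0 + decomp.protraction_events / decomp.sample_rate
        n_cycles += int(np.sum((ev_t >= s) & (ev_t < e)))
    pref = float(centers[int(np.nanargmax(means))]) if np.isfinite(means).any() else np.nan
    return PhaseLockedVm(centers, means, depth, pref, n_cycles,
                         enough_cycles=n_cycles >= config.vm_min_whisk_cycles)


def test_phase_lock(rec: VmRecording, decomp: KinematicDecomposition, epochs: EpochSet,
                    n_shuffles: int = 1000, config: AnalysisConfig | None = None,
                    rng: np.random.Generator | None = None) -> PhaseLockedVm:
    """Circular-shuffle significance of phase-locked Vm modulation.

    Each shuffle circularly rotates each whisking epoch's Vm samples by an
    independent uniform offset (phase labels fixed) and recomputes the
    peak-to-trough depth of the pooled average; p is the fraction of
    shuffled depths ≥ the observed depth.
    """
    import warnings

    config = config or AnalysisConfig()
    rng = rng or np.random.default_rng(config.seed)
    if n_shuffles < 100:
        warnings.warn("fewer than 100 shuffles gives coarse p-value resolution")
    result = phase_locked_vm(rec, decomp, epochs, config)
    segments, _ = _whisk_segments(rec, decomp, epochs, config.vm_phase_bins)
    if not segments or not np.isfinite(result.modulation_depth):
        result.p_shuffle = np.nan
        return result
    depths = np.empty(n_shuffles)
    for i in range(n_shuffles):
        rolled = [(np.roll(v, rng.integers(v.size)), b) for v, b in segments]
        _, depths[i] = _pooled_depth(rolled, config.vm_phase_bins)
    result.p_shuffle = float(np.mean(depths >= result.modulation_depth))
    return result
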