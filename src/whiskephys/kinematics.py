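"""Whisker kinematic decomposition and epoch segmentation.

A whisker angle trace θ(t) (degrees, typically filmed at 500 Hz) is broken
down into four slow variables:

* **phase** ϕ(t): instantaneous position within the whisk cycle, from the
  Hilbert transform of the 4-25 Hz band-passed angle. ϕ = 0 is the most
  protracted position, ϕ = ±π the end of retraction.
* **amplitude** θ_amp(t): half the protraction-retraction excursion,
  (θ_{ϕ=0} − θ_{ϕ=±π}) / 2, evaluated on the raw angle at phase events and
  linearly interpolated between them.
* **midpoint** θ_mid(t): the centre of the excursion,
  θ_{ϕ=±π} + (θ_{ϕ=0} − θ_{ϕ=±π}) / 2, interpolated the same way.
* **setpoint** θ_set(t): the slow envelope of the angle, a zero-phase 6 Hz
  low-pass of the raw trace.

Sweeps are tiled into *quiet* and *whisking* epochs using 3/2/1 s windows,
and each whisking epoch that follows a quiet window gets an onset time: the
first sample where the raw angle exceeds the quiet baseline by 1 degree.

The raw trace is reconstructible as θ̂ = θ_mid + θ_amp·cos(ϕ), which is the
consistency check :func:`reconstruct` reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .config import AnalysisConfig

__all__ = [
    "WhiskerTrace",
    "KinematicDecomposition",
    "EpochSet",
    "bandpass_whisker",
    "hilbert_phase",
    "decompose",
    "compute_setpoint",
    "segment_epochs",
    "detect_whisking_onset",
    "kinematic_summaries",
    "reconstruct",
]


@dataclass
class WhiskerTrace:
    """A single-sweep whisker angle time series (degrees)."""

    angle: np.ndarray
    sample_rate: float = 500.0
    sweep_id: str = "sweep0"
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.angle = np.asarray(self.angle, dtype=float)
        if self.angle.ndim != 1:
            raise ValueError("angle must be a 1-D array")
        if not np.all(np.isfinite(self.angle)):
            raise ValueError("angle trace contains non-finite samples")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.angle.size) / self.sample_rate

    @property
    def duration(self) -> float:
        return self.angle.size / self.sample_rate


@dataclass
class KinematicDecomposition:
    """Per-sample whisking variables derived from one trace."""

    phase: np.ndarray            # rad, in (-pi, pi]
    amplitude: np.ndarray        # deg, >= 0
    midpoint: np.ndarray         # deg
    setpoint: np.ndarray         # deg
    protraction_events: np.ndarray  # sample indices where phase crosses 0
    retraction_events: np.ndarray   # sample indices where phase crosses +/-pi
    sample_rate: float
    t0: float = 0.0
    degenerate: bool = False     # True when the trace carried no oscillation
    defined: bool = True         # False when < 2 phase events were found

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.phase.size) / self.sample_rate


@dataclass
class EpochSet:
    """Non-overlapping quiet/whisking epochs of one sweep."""

    epochs: list[tuple[str, float, float]] = field(default_factory=list)
    onset_times: list[float] = field(default_factory=list)

    def by_label(self, label: str) -> list[tuple[float, float]]:
        return [(s, e) for lab, s, e in self.epochs if lab == label]

    def sample_mask(self, label: str, n: int, fs: float, t0: float = 0.0) -> np.ndarray:
        """Boolean mask over n samples covering all epochs of one label."""
        mask = np.zeros(n, dtype=bool)
        for s, e in self.by_label(label):
            i0 = max(0, int(np.ceil((s - t0) * fs)))
            i1 = min(n, int(np.floor((e - t0) * fs)))
            mask[i0:i1] = True
        return mask

    @property
    def total_duration(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for lab, s, e in self.epochs:
            out[lab] = out.get(lab, 0.0) + (e - s)
        return out


def _zero_phase_sos(order: int, wn, fs: float, btype: str):
    # filtfilt doubles the effective order, so design at order // 2
    return signal.butter(max(1, order // 2), wn, btype=btype, fs=fs, output="sos")


def bandpass_whisker(trace: WhiskerTrace, config: AnalysisConfig | None = None) -> WhiskerTrace:
    """Zero-phase 4-25 Hz band-pass of the whisker angle.

    Zero phase matters: phase events derived from the filtered trace must
    stay aligned with the raw angle samples used for amplitude/midpoint.
    """
    config = config or AnalysisConfig()
    if trace.duration < 1.0:
        raise ValueError("trace shorter than 1 s cannot be band-pass filtered reliably")
    sos = _zero_phase_sos(config.filter_order, config.whisk_band_hz, trace.sample_rate, "bandpass")
    filt = signal.sosfiltfilt(sos, trace.angle - np.mean(trace.angle))
    return WhiskerTrace(filt, trace.sample_rate, trace.sweep_id, trace.t0)


def hilbert_phase(filtered: WhiskerTrace) -> tuple[np.ndarray, bool]:
    """Instantaneous whisking phase from the analytic signal.

    Returns ``(phase, degenerate)``. ϕ = 0 at protraction maxima of the
    filtered trace (angle increasing = protraction), ϕ = ±π at the end of
    retraction. A flat trace has no meaningful phase; it is flagged
    degenerate and the phase array is all zero.
    """
    x = filtered.angle
    if float(np.std(x)) < 1e-9:
        return np.zeros_like(x), True
    analytic = signal.hilbert(x)
    return np.angle(analytic), False


def _phase_events(phase: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sample indices of protraction (ϕ crosses 0) and retraction (ϕ wraps ±π)."""
    d = np.diff(phase)
    # upward zero crossing without wrap
    up = np.where((phase[:-1] < 0) & (phase[1:] >= 0) & (d > 0) & (d < np.pi))[0]
    # nearest of the two straddling samples, so ϕ≈0 at the reported index
    prot = np.where(np.abs(phase[up]) <= np.abs(phase[up + 1]), up, up + 1)
    wrap = np.where(d < -np.pi)[0]
    retr = np.where(np.abs(np.abs(phase[wrap]) - np.pi) <= np.abs(np.abs(phase[wrap + 1]) - np.pi),
                    wrap, wrap + 1)
    return prot.astype(int), retr.astype(int)


def compute_setpoint(trace: WhiskerTrace, config: AnalysisConfig | None = None) -> np.ndarray:
    """Whisking setpoint: zero-phase low-pass of the raw angle at 6 Hz.

    Designed at full order (steeper than the band-pass) so that whisking
    frequencies just above the cutoff leave < 10% ripple on the setpoint.
    """
    config = config or AnalysisConfig()
    sos = signal.butter(config.filter_order, config.setpoint_cutoff_hz,
                        btype="low", fs=trace.sample_rate, output="sos")
    return signal.sosfiltfilt(sos, trace.angle)


def decompose(trace: WhiskerTrace, config: AnalysisConfig | None = None) -> KinematicDecomposition:
    """Full kinematic decomposition of one whisker angle trace.

    Amplitude and midpoint are evaluated on the *raw* angle at phase events
    (the formulas reconstruct raw position) and linearly interpolated
    between consecutive events; outside the first/last event they are held
    constant. Amplitude is clipped at zero.
    """
    config = config or AnalysisConfig()
    raw = trace.angle if config.protraction_positive else -trace.angle
    work = WhiskerTrace(raw, trace.sample_rate, trace.sweep_id, trace.t0)
    filtered = bandpass_whisker(work, config)
    phase, degenerate = hilbert_phase(filtered)
    setpt = compute_setpoint(work, config)

    n = raw.size
    if degenerate:
        return KinematicDecomposition(
            phase=phase, amplitude=np.zeros(n), midpoint=raw.copy(), setpoint=setpt,
            protraction_events=np.array([], int), retraction_events=np.array([], int),
            sample_rate=trace.sample_rate, t0=trace.t0, degenerate=True, defined=False)

    prot, retr = _phase_events(phase)
    events = np.concatenate([prot, retr])
    kinds = np.concatenate([np.zeros(prot.size, int), np.ones(retr.size, int)])  # 0=prot, 1=retr
    order = np.argsort(events, kind="stable")
    events, kinds = events[order], kinds[order]

    if events.size < 2:
        return KinematicDecomposition(
            phase=phase, amplitude=np.zeros(n), midpoint=raw.copy(), setpoint=setpt,
            protraction_events=prot, retraction_events=retr,
            sample_rate=trace.sample_rate, t0=trace.t0, defined=False)

    # one amplitude/midpoint value per event, from the adjacent opposite-type event
    ev_amp = np.full(events.size, np.nan)
    ev_mid = np.full(events.size, np.nan)
    for k in range(events.size):
        j = k + 1 if k + 1 < events.size else k - 1
        if kinds[j] == kinds[k]:  # duplicate type (noise); look one further
            j2 = k + 2 if k + 2 < events.size else k - 2
            if 0 <= j2 < events.size and kinds[j2] != kinds[k]:
                j = j2
            else:
                continue
        i_prot = events[k] if kinds[k] == 0 else events[j]
        i_retr = events[j] if kinds[k] == 0 else events[k]
        th0, thpi = raw[i_prot], raw[i_retr]
        ev_amp[k] = (th0 - thpi) / 2.0
        ev_mid[k] = thpi + (th0 - thpi) / 2.0

    ok = np.isfinite(ev_amp)
    idx = np.arange(n)
    amplitude = np.interp(idx, events[ok], ev_amp[ok])
    midpoint = np.interp(idx, events[ok], ev_mid[ok])
    amplitude = np.clip(amplitude, 0.0, None)

    return KinematicDecomposition(
        phase=phase, amplitude=amplitude, midpoint=midpoint, setpoint=setpt,
        protraction_events=prot, retraction_events=retr,
        sample_rate=trace.sample_rate, t0=trace.t0)


def detect_whisking_onset(trace: WhiskerTrace, baseline_span: tuple[float, float],
                          search_span: tuple[float, float],
                          config: AnalysisConfig | None = None) -> float | None:
    """Whisking onset: first time the raw angle exceeds baseline + 1 deg.

    ``baseline_span`` is the preceding quiet interval (seconds, trace
    clock); the baseline is its median raw angle. Returns the onset time or
    None when the threshold is never crossed inside ``search_span``.
    """
    config = config or AnalysisConfig()
    fs, t0 = trace.sample_rate, trace.t0
    b0, b1 = (int(round((t - t0) * fs)) for t in baseline_span)
    s0, s1 = (int(round((t - t0) * fs)) for t in search_span)
    b0, s0 = max(b0, 0), max(s0, 0)
    b1, s1 = min(b1, trace.angle.size), min(s1, trace.angle.size)
    if b1 <= b0 or s1 <= s0:
        return None
    baseline = float(np.median(trace.angle[b0:b1]))
    above = np.nonzero(trace.angle[s0:s1] > baseline + config.onset_threshold_deg)[0]
    if above.size == 0:
        return None
    return t0 + (s0 + int(above[0])) / fs


def segment_epochs(trace: WhiskerTrace, config: AnalysisConfig | None = None) -> EpochSet:
    """Tile a sweep into quiet and whisking epochs with 3/2/1 s windows.

    A window is *whisking* when the band-passed envelope stays above
    ``whisk_envelope_deg`` throughout, *quiet* when it stays below
    ``quiet_envelope_deg`` throughout. Tiling is greedy and prefers longer
    windows; unlabellable stretches are skipped in 0.5 s steps. Each
    whisking epoch directly preceded by a quiet epoch is assigned an onset
    by the 1-degree rule, with the quiet epoch as baseline.
    """
    config = config or AnalysisConfig()
    fs, t0 = trace.sample_rate, trace.t0
    filtered = bandpass_whisker(trace, config)
    envelope = np.abs(signal.hilbert(filtered.angle))

    win_samples = [int(round(w * fs)) for w in config.epoch_windows_s]
    step = max(1, int(round(0.5 * fs)))
    n = trace.angle.size
    epochs: list[tuple[str, float, float]] = []
    pos = 0
    while pos < n:
        labelled = False
        for w in win_samples:
            if pos + w > n:
                continue
            seg = envelope[pos:pos + w]
            if np.all(seg > config.whisk_envelope_deg):
                lab = "whisking"
            elif np.all(seg < config.quiet_envelope_deg):
                lab = "quiet"
            else:
                continue
            epochs.append((lab, t0 + pos / fs, t0 + (pos + w) / fs))
            pos += w
            labelled = True
            break
        if not labelled:
            pos += step

    if not epochs:
        import warnings
        warnings.warn("no window qualified as quiet or whisking; empty epoch set")

    onsets: list[float] = []
    for i, (lab, s, e) in enumerate(epochs):
        if lab != "whisking" or i == 0:
            continue
        prev_lab, ps, pe = epochs[i - 1]
        if prev_lab != "quiet":
            continue
        onset = detect_whisking_onset(trace, (ps, pe), (pe, e), config)
        if onset is not None:
            onsets.append(onset)
    return EpochSet(epochs=epochs, onset_times=onsets)


def kinematic_summaries(trace: WhiskerTrace, decomp: KinematicDecomposition,
                        epochs: EpochSet) -> list[dict[str, float]]:
    """Per-whisking-epoch movement summaries.

    Mean amplitude; midpoint and setpoint excursion (max - min); mean peak
    protraction and retraction speed per half-cycle (deg/s); and mean whisk
    cycle duration (inter-protraction-event interval).
    """
    fs, t0 = decomp.sample_rate, decomp.t0
    velocity = np.gradient(trace.angle) * fs
    prot_t = t0 + decomp.protraction_events / fs
    retr_t = t0 + decomp.retraction_events / fs
    all_ev = np.sort(np.concatenate([decomp.protraction_events, decomp.retraction_events]))

    out = []
    for s, e in epochs.by_label("whisking"):
        i0, i1 = int((s - t0) * fs), int((e - t0) * fs)
        sl = slice(max(i0, 0), min(i1, trace.angle.size))
        p_in = prot_t[(prot_t >= s) & (prot_t < e)]
        cyc = float(np.mean(np.diff(p_in))) if p_in.size >= 2 else np.nan

        # peak speed per half-cycle: split on all events inside the epoch
        ev_t = t0 + all_ev / fs
        ev_in = all_ev[(ev_t >= s) & (ev_t < e)]
        prot_speeds, retr_speeds = [], []
        for a, b in zip(ev_in[:-1], ev_in[1:]):
            seg = velocity[a:b + 1]
            if seg.size == 0:
                continue
            if np.max(seg) > -np.min(seg):
                prot_speeds.append(float(np.max(seg)))
            else:
                retr_speeds.append(float(-np.min(seg)))
        out.append({
            "start_s": s, "end_s": e,
            "mean_amplitude_deg": float(np.mean(decomp.amplitude[sl])),
            "midpoint_excursion_deg": float(np.ptp(decomp.midpoint[sl])),
            "setpoint_excursion_deg": float(np.ptp(decomp.setpoint[sl])),
            "mean_protraction_speed_deg_s": float(np.mean(prot_speeds)) if prot_speeds else np.nan,
            "mean_retraction_speed_deg_s": float(np.mean(retr_speeds)) if retr_speeds else np.nan,
            "mean_cycle_duration_s": cyc,
            "n_retraction_events": int(((retr_t >= s) & (retr_t < e)).sum()),
        })
    return out


def reconstruct(trace: WhiskerTrace, decomp: KinematicDecomposition) -> tuple[np.ndarray, float]:
    """θ̂ = θ_mid + θ_amp·cos(ϕ) and its RMS error against the raw trace."""
    rec = decomp.midpoint + decomp.amplitude * np.cos(decomp.phase)
    err = float(np.sqrt(np.mean((rec - trace.angle) ** 2)))
    return rec, err
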