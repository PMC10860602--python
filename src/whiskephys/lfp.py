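"""Laminar LFP analysis: preprocessing, state spectra, CSD and L4 localization.

A laminar session is a channels-by-time LFP array from a multi-shank probe
with a channel-depth map and active-touch event times. The analysis chain:

* anti-aliased down-sampling (1 kHz for spectra, 3 kHz for CSD) followed by
  a zero-phase 100 Hz low-pass;
* state-resolved power spectra from 2 s segments of quiet/whisking epochs
  longer than 2 s, normalized to the peak of the averaged Light-OFF
  spectrum;
* current source density as the discrete second spatial derivative of the
  touch-triggered average LFP along depth, computed separately on the odd
  and even channel columns of the two-column probe. Sinks are negative:
  CSD_i = −(V_{i−1} − 2 V_i + V_{i+1}) / Δz², so the thalamorecipient sink
  under the touch response is a negative deflection at its channel;
* layer-4 localization by three criteria on the touch-triggered average —
  shortest LFP peak latency, largest LFP peak amplitude, fastest CSD sink
  onset — combined by majority vote with ties broken toward the amplitude
  criterion. The winning channel is anchored at a subpial depth of 500 µm
  and layer boundaries follow the configured depth table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy import signal

from .config import AnalysisConfig
from .kinematics import EpochSet

__all__ = [
    "LaminarSession",
    "CsdProfile",
    "L4Localization",
    "preprocess_lfp",
    "touch_triggered_average",
    "state_spectra",
    "normalize_spectra",
    "band_power",
    "compute_csd",
    "locate_layer4",
]


@dataclass
class LaminarSession:
    """Multichannel LFP with depth map and touch events (single sweep)."""

    lfp: np.ndarray               # (channels, samples), mV
    channel_depths: np.ndarray    # um below pia, per channel
    sample_rate: float
    touch_times: np.ndarray = field(default_factory=lambda: np.array([]))
    light_on: bool = False
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.lfp = np.atleast_2d(np.asarray(self.lfp, dtype=float))
        self.channel_depths = np.asarray(self.channel_depths, dtype=float)
        if self.channel_depths.size != self.lfp.shape[0]:
            raise ValueError("one depth per channel required")
        for sub in ("odd", "even"):
            d = self.channel_depths[self.column_indices(sub)]
            if d.size > 1 and not np.all(np.diff(d) > 0):
                raise ValueError(f"{sub}-column depths must be strictly increasing")
        tt = np.asarray(self.touch_times, dtype=float)
        dur = self.lfp.shape[1] / self.sample_rate
        if tt.size and (tt.min() < self.t0 or tt.max() > self.t0 + dur):
            raise ValueError("touch times outside the recording")
        self.touch_times = tt

    def column_indices(self, subset: str) -> np.ndarray:
        n = self.lfp.shape[0]
        if subset == "odd":
            return np.arange(1, n, 2)
        if subset == "even":
            return np.arange(0, n, 2)
        raise ValueError("subset must be 'odd' or 'even'")

    @property
    def duration(self) -> float:
        return self.lfp.shape[1] / self.sample_rate


@dataclass
class CsdProfile:
    csd: np.ndarray               # (column channels, window samples), mV/mm^2, sinks < 0
    times: np.ndarray             # s relative to touch
    channel_indices: np.ndarray   # original channel ids of the column
    subset: str
    dz_um: float


@dataclass
class L4Localization:
    success: bool
    l4_channel: int | None = None
    l4_depth_um: float = np.nan
    subset: str = ""
    criteria: dict[str, int] = field(default_factory=dict)   # criterion -> winning channel
    disagreement: bool = False
    depth_offset_um: float = np.nan     # add to probe depths to get subpial depths
    layer_boundaries_um: dict[str, tuple[float, float]] = field(default_factory=dict)
    reason: str = ""


def preprocess_lfp(session: LaminarSession, target_rate: float,
                   cutoff: float = 100.0, config: AnalysisConfig | None = None) -> LaminarSession:
    """Anti-aliased resampling to ``target_rate`` plus zero-phase low-pass."""
    config = config or AnalysisConfig()
    fs = session.sample_rate
    x = session.lfp
    if target_rate < fs:
        frac = Fraction(target_rate / fs).limit_denominator(1000)
        x = signal.resample_poly(x, frac.numerator, frac.denominator, axis=1)
    sos = signal.butter(2, cutoff, btype="low", fs=target_rate, output="sos")
    x = signal.sosfiltfilt(sos, x, axis=1)
    out = LaminarSession(x, session.channel_depths, target_rate,
                         session.touch_times, session.light_on, session.t0)
    return out


def touch_triggered_average(session: LaminarSession,
                            window_s: tuple[float, float] = (-0.02, 0.1)):
    """Mean LFP around touches, per channel. Returns ``(times, avg)``."""
    if session.touch_times.size == 0:
        raise ValueError("session has no touch events")
    fs = session.sample_rate
    i0, i1 = int(round(window_s[0] * fs)), int(round(window_s[1] * fs))
    n = session.lfp.shape[1]
    snippets = []
    for t in session.touch_times:
        c = int(round((t - session.t0) * fs))
        if c + i0 < 0 or c + i1 > n:
            continue
        snippets.append(session.lfp[:, c + i0:c + i1])
    if not snippets:
        raise ValueError("no touch with full window coverage")
    avg = np.mean(np.asarray(snippets), axis=0)
    times = np.arange(i0, i1) / fs
    return times, avg


def state_spectra(x: np.ndarray, fs: float, epochs: EpochSet,
                  config: AnalysisConfig | None = None):
    """Welch-style state-resolved power spectra from 2 s Hann segments.

    Only epochs longer than ``lfp_min_epoch_s`` contribute; segments are
    non-overlapping within each epoch. Returns ``(freqs, {state: spectrum})``.
    """
    config = config or AnalysisConfig()
    nseg = int(round(config.lfp_segment_s * fs))
    win = np.hanning(nseg)
    norm = (win ** 2).sum() * fs
    freqs = np.fft.rfftfreq(nseg, 1.0 / fs)
    out: dict[str, np.ndarray] = {}
    for state in ("quiet", "whisking"):
        psds = []
        for s, e in epochs.by_label(state):
            if e - s < config.lfp_min_epoch_s:
                continue
            i0, i1 = int(round(s * fs)), int(round(e * fs))
            seg = x[i0:i1]
            for k in range(seg.size // nseg):
                chunk = seg[k * nseg:(k + 1) * nseg]
                chunk = (chunk - chunk.mean()) * win
                psd = np.abs(np.fft.rfft(chunk)) ** 2 / norm
                psd[1:-1] *= 2
                psds.append(psd)
        if psds:
            out[state] = np.mean(psds, axis=0)
    return freqs, out


def normalize_spectra(spectra_off: dict[str, np.ndarray],
                      spectra_on: dict[str, np.ndarray] | None = None):
    """Normalize all spectra to the peak of the averaged Light-OFF spectrum."""
    if not spectra_off:
        raise ValueError("no Light-OFF spectra to normalize against")
    off_avg = np.mean(list(spectra_off.values()), axis=0)
    peak = float(np.max(off_avg))
    if peak <= 0:
        raise ValueError("Light-OFF spectrum has no positive peak")
    norm_off = {k: v / peak for k, v in spectra_off.items()}
    norm_on = {k: v / peak for k, v in (spectra_on or {}).items()}
    return norm_off, norm_on, peak


def band_power(freqs: np.ndarray, spectrum: np.ndarray,
               band: tuple[float, float] = (1.0, 5.0)) -> float:
    sel = (freqs >= band[0]) & (freqs <= band[1])
    return float(np.trapezoid(spectrum[sel], freqs[sel]))


def compute_csd(avg_lfp: np.ndarray, times: np.ndarray, session: LaminarSession,
                subset: str = "even") -> CsdProfile:
    """CSD of the touch-triggered average along one probe column.

    Discrete second spatial derivative with the sink-negative convention,
    CSD_i = −(V_{i−1} − 2 V_i + V_{i+1}) / Δz²; boundary channels are padded
    by duplication (their CSD is therefore ~0 and never a sink winner).
    Units mV/mm².
    """
    cols = session.column_indices(subset)
    if cols.size < 3:
        raise ValueError("need at least 3 channels in the column")
    depths = session.channel_depths[cols]
    dz = np.diff(depths)
    if not np.allclose(dz, dz[0]):
        raise ValueError("column channel spacing must be uniform")
    dz_mm = dz[0] / 1000.0
    v = avg_lfp[cols]
    padded = np.vstack([v[0], v, v[-1]])
    csd = -(padded[:-2] - 2 * padded[1:-1] + padded[2:]) / dz_mm ** 2
    return CsdProfile(csd, times, cols, subset, float(dz[0]))


def _sink_onset_times(profile: CsdProfile, onset_fraction: float,
                      min_sink_fraction: float = 0.25) -> np.ndarray:
    """Per-channel first crossing of ``fraction``·(peak sink) after t = 0.

    Channels whose peak sink is below ``min_sink_fraction`` of the largest
    sink in the column carry no meaningful sink (sources or noise) and are
    excluded (onset = inf), so the criterion cannot fire on noise.
    """
    post = profile.times >= 0
    t_post = profile.times[post]
    peaks = profile.csd[:, post].min(axis=1)
    floor = min_sink_fraction * (-peaks.min()) if peaks.min() < 0 else np.inf
    out = np.full(profile.csd.shape[0], np.inf)
    for i, row in enumerate(profile.csd[:, post]):
        peak = row.min()
        if peak >= 0 or -peak < floor:
            continue
        below = np.nonzero(row <= onset_fraction * peak)[0]
        if below.size:
            out[i] = t_post[below[0]]
    return out


def locate_layer4(session: LaminarSession, subset: str | None = None,
                  config: AnalysisConfig | None = None,
                  window_s: tuple[float, float] = (-0.02, 0.1),
                  preprocess: bool = True) -> L4Localization:
    """Three-criterion L4 localization on the touch-triggered average.

    The session is first taken through the CSD preprocessing chain
    (resampling to ``lfp_csd_rate_hz`` and a zero-phase 100 Hz low-pass)
    unless ``preprocess=False``. Criteria, per channel of the chosen
    column: (1) shortest latency of the peak (most negative) touch
    response, (2) largest peak response amplitude, (3) fastest CSD sink
    onset (first crossing of 20% of the channel's peak sink). Majority
    vote across criteria; ties and three-way splits resolve toward the
    amplitude winner with a disagreement flag.
    """
    config = config or AnalysisConfig()
    if session.touch_times.size < 1:
        return L4Localization(False, reason="no touch events")
    if preprocess:
        session = preprocess_lfp(session, min(config.lfp_csd_rate_hz, session.sample_rate),
                                 config.lfp_lowpass_hz, config)
    try:
        times, avg = touch_triggered_average(session, window_s)
    except ValueError as exc:
        return L4Localization(False, reason=str(exc))

    if subset is None:  # pick the column with the larger touch response
        peaks = {s: float(np.max(-avg[session.column_indices(s)]))
                 for s in ("odd", "even")}
        subset = max(peaks, key=peaks.get)
    cols = session.column_indices(subset)
    v = avg[cols]
    post = times >= 0
    t_post = times[post]

    peak_idx = np.argmin(v[:, post], axis=1)
    latency = t_post[peak_idx]
    amplitude = -np.min(v[:, post], axis=1)
    if np.all(amplitude <= 0):
        return L4Localization(False, subset=subset, reason="no negative touch response")
    # a peak latency is only meaningful where there is a touch response;
    # exclude channels with less than half the maximal response
    latency = np.where(amplitude >= 0.5 * amplitude.max(), latency, np.inf)

    profile = compute_csd(avg, times, session, subset)
    sink_onset = _sink_onset_times(profile, config.csd_sink_onset_fraction)
    # boundary channels are padding artefacts; exclude from the sink criterion
    sink_onset[0] = sink_onset[-1] = np.inf

    winners = {
        "lfp_peak_latency": int(cols[np.argmin(latency)]),
        "lfp_peak_amplitude": int(cols[np.argmax(amplitude)]),
        "csd_sink_onset": int(cols[np.argmin(sink_onset)]),
    }
    votes: dict[int, int] = {}
    for ch in winners.values():
        votes[ch] = votes.get(ch, 0) + 1
    best = max(votes.values())
    leaders = [ch for ch, c in votes.items() if c == best]
    disagreement = len(votes) > 1
    if len(leaders) == 1:
        l4 = leaders[0]
    else:
        l4 = winners["lfp_peak_amplitude"]

    offset = config.l4_depth_um - session.channel_depths[l4]
    return L4Localization(True, l4_channel=l4, l4_depth_um=config.l4_depth_um,
                          subset=subset, criteria=winners, disagreement=disagreement,
                          depth_offset_um=float(offset),
                          layer_boundaries_um=dict(config.layer_boundaries_um))
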