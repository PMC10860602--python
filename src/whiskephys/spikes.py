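"""Single-unit spike analysis.

Covers the standard extracellular workflow downstream of spike sorting:

* waveform-based cell classification (fast-spiking vs regular-spiking by
  trough-to-peak time, intermediate widths excluded),
* Z-scoring of firing rates over 2 s bins pooled across sweeps,
* whisking-modulation classification (W-Exc / W-Inh / NM) from per-epoch
  rates with a rank-sum test and Benjamini-Hochberg correction across the
  units of a session,
* Z-scored peri-event time histograms aligned to whisking onset, and
* the light-modulation index (ON − OFF) / (ON + OFF).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats
from statsmodels.stats.multitest import multipletests

from .config import AnalysisConfig
from .kinematics import EpochSet

__all__ = [
    "SpikeUnit",
    "WhiskModResult",
    "ZScoredPETH",
    "classify_cell_type",
    "trough_to_peak_ms",
    "zscore_rates",
    "epoch_rates",
    "classify_whisk_modulation",
    "classify_whisk_modulation_cohort",
    "build_peth",
    "light_modulation_index",
]


@dataclass
class SpikeUnit:
    """One sorted unit: spike times per sweep plus its mean waveform."""

    unit_id: str
    spike_times: dict[str, np.ndarray]        # sweep_id -> times (s), increasing
    sweep_durations: dict[str, float]
    mean_waveform: np.ndarray | None = None   # (channels, samples) or (samples,)
    waveform_rate_hz: float = 30000.0
    depth_um: float = np.nan
    rate_true: np.ndarray | None = None       # generator ground-truth lambda(t), Hz
    light_on: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sw, t in self.spike_times.items():
            t = np.asarray(t, dtype=float)
            if t.size and (np.any(np.diff(t) < 0)):
                raise ValueError(f"spike times not increasing in sweep {sw}")
            dur = self.sweep_durations.get(sw)
            if dur is not None and t.size and (t[0] < 0 or t[-1] > dur):
                raise ValueError(f"spike times outside sweep bounds in {sw}")
            self.spike_times[sw] = t

    @property
    def n_spikes(self) -> int:
        return int(sum(t.size for t in self.spike_times.values()))

    def all_spikes(self, sweeps: list[str] | None = None) -> np.ndarray:
        keys = sweeps if sweeps is not None else sorted(self.spike_times)
        arrs = [self.spike_times[k] for k in keys if k in self.spike_times]
        return np.concatenate(arrs) if arrs else np.array([])


@dataclass
class WhiskModResult:
    category: str                 # 'W-Exc' | 'W-Inh' | 'NM'
    w_delta_ap: float             # mean whisking Z - mean quiet Z
    p_raw: float
    q_bh: float = np.nan
    testable: bool = True


@dataclass
class ZScoredPETH:
    bin_centers: np.ndarray       # s, relative to onset
    z_values: np.ndarray
    bin_width: float
    baseline_window: tuple[float, float]
    smooth_sd_bins: float
    n_onsets: int


def trough_to_peak_ms(waveform: np.ndarray, rate_hz: float) -> float:
    """Trough-to-subsequent-peak time of a mean waveform, in ms.

    For multichannel waveforms the channel with the largest trough
    amplitude is used.
    """
    w = np.atleast_2d(np.asarray(waveform, dtype=float))
    ch = int(np.argmin(w.min(axis=1)))
    x = w[ch]
    trough = int(np.argmin(x))
    if trough == x.size - 1:
        return np.nan
    peak = trough + int(np.argmax(x[trough:]))
    return (peak - trough) / rate_hz * 1000.0


def classify_cell_type(unit: SpikeUnit, config: AnalysisConfig | None = None) -> str:
    """FS if trough-to-peak < 0.4 ms, RS if > 0.5 ms, else 'excluded'."""
    config = config or AnalysisConfig()
    if unit.mean_waveform is None:
        return "excluded"
    t2p = trough_to_peak_ms(unit.mean_waveform, unit.waveform_rate_hz)
    if not np.isfinite(t2p):
        return "excluded"
    if t2p < config.fs_trough_to_peak_ms:
        return "FS"
    if t2p > config.rs_trough_to_peak_ms:
        return "RS"
    return "excluded"


def zscore_rates(unit: SpikeUnit, config: AnalysisConfig | None = None):
    """Z-score a unit's firing rate over 2 s bins of all sweeps.

    Returns ``(bin_start_times, z, mean, sd)`` with the bin times keyed as
    (sweep_id, start_s). SD = 0 (perfectly constant counts) flags the unit
    unanalyzable for Z-based statistics by returning z = None.
    """
    config = config or AnalysisConfig()
    bw = config.zscore_bin_s
    keys, rates = [], []
    for sw in sorted(unit.spike_times):
        dur = unit.sweep_durations[sw]
        nb = int(dur // bw)
        if nb < 1:
            continue
        edges = np.arange(nb + 1) * bw
        counts, _ = np.histogram(unit.spike_times[sw], bins=edges)
        rates.extend(counts / bw)
        keys.extend((sw, float(e)) for e in edges[:-1])
    rates = np.asarray(rates, dtype=float)
    if rates.size < 2:
        return keys, None, np.nan, np.nan
    mu, sd = float(np.mean(rates)), float(np.std(rates))
    if sd == 0:
        return keys, None, mu, 0.0
    return keys, (rates - mu) / sd, mu, sd


def epoch_rates(unit: SpikeUnit, epochs_by_sweep: dict[str, EpochSet], label: str) -> np.ndarray:
    """Firing rate (count / duration) in every epoch of one label."""
    out = []
    for sw, eps in epochs_by_sweep.items():
        t = unit.spike_times.get(sw, np.array([]))
        for s, e in eps.by_label(label):
            out.append(float(np.sum((t >= s) & (t < e))) / (e - s))
    return np.asarray(out)


def _z_stats(unit: SpikeUnit, config: AnalysisConfig) -> tuple[float, float]:
    """(mean, sd) of 2 s-bin rates, for converting epoch rates to Z units."""
    _, _, mu, sd = zscore_rates(unit, config)
    return mu, sd


def classify_whisk_modulation(unit: SpikeUnit, epochs_by_sweep: dict[str, EpochSet],
                              config: AnalysisConfig | None = None) -> WhiskModResult:
    """Quiet-vs-whisking classification of one unit (no BH correction).

    Wilcoxon rank-sum on per-epoch firing rates; W-ΔAP is the difference of
    the mean whisking and quiet rates expressed in the unit's Z units
    (2 s-bin mean/SD normalization).
    """
    config = config or AnalysisConfig()
    rq = epoch_rates(unit, epochs_by_sweep, "quiet")
    rw = epoch_rates(unit, epochs_by_sweep, "whisking")
    if rq.size < config.min_epochs_per_label or rw.size < config.min_epochs_per_label:
        return WhiskModResult("NM", np.nan, np.nan, testable=False)
    mu, sd = _z_stats(unit, config)
    w_delta = (float(np.mean(rw)) - float(np.mean(rq))) / sd if sd and sd > 0 else np.nan
    if unit.n_spikes == 0:
        return WhiskModResult("NM", np.nan, 1.0, testable=False)
    stat, p = stats.ranksums(rw, rq)
    return WhiskModResult("NM", w_delta, float(p))


def classify_whisk_modulation_cohort(units: list[SpikeUnit],
                                     epochs_by_sweep: dict[str, EpochSet],
                                     config: AnalysisConfig | None = None) -> list[WhiskModResult]:
    """Classify all units of a session with BH correction across units.

    A unit is W-Exc (W-Inh) when its BH-adjusted q-value is below α and its
    whisking rate is above (below) its quiet rate; otherwise NM.
    """
    config = config or AnalysisConfig()
    results = [classify_whisk_modulation(u, epochs_by_sweep, config) for u in units]
    testable = [i for i, r in enumerate(results) if r.testable and np.isfinite(r.p_raw)]
    if testable:
        _, q, _, _ = multipletests([results[i].p_raw for i in testable], method="fdr_bh")
        for i, qi in zip(testable, q):
            results[i].q_bh = float(qi)
            if qi < config.alpha and np.isfinite(results[i].w_delta_ap):
                results[i].category = "W-Exc" if results[i].w_delta_ap > 0 else "W-Inh"
    return results


def build_peth(unit: SpikeUnit, onsets_by_sweep: dict[str, list[float]],
               config: AnalysisConfig | None = None) -> ZScoredPETH:
    """Z-scored PETH around whisking onsets.

    Spike rates in 200 ms bins are converted to the unit's Z units (2 s-bin
    mean/SD), averaged across onsets, Gaussian-smoothed, and the mean over
    the baseline window (-1.0 to -0.2 s before onset) is subtracted. Only
    onsets with full pre/post window coverage enter the average. A unit
    whose 2 s-bin SD is zero (e.g. fully silent) yields an all-zero PETH.
    """
    config = config or AnalysisConfig()
    bw = config.peth_bin_s
    w0, w1 = config.peth_window_s
    edges = np.arange(w0, w1 + bw / 2, bw)
    centers = (edges[:-1] + edges[1:]) / 2
    mu, sd = _z_stats(unit, config)

    rows = []
    for sw, onsets in onsets_by_sweep.items():
        t = unit.spike_times.get(sw, np.array([]))
        dur = unit.sweep_durations.get(sw, np.inf)
        for on in onsets:
            if on + w0 < 0 or on + w1 > dur:
                continue
            counts, _ = np.histogram(t - on, bins=edges)
            rows.append(counts / bw)
    if not rows:
        raise ValueError("no onset with full pre/post window coverage")
    rates = np.mean(np.asarray(rows), axis=0)
    z = (rates - mu) / sd if sd and sd > 0 else np.zeros_like(rates)
    z = ndimage.gaussian_filter1d(z, config.peth_smooth_sd_bins, mode="nearest")
    base = (centers >= config.peth_baseline_s[0]) & (centers <= config.peth_baseline_s[1])
    z = z - float(np.mean(z[base]))
    return ZScoredPETH(centers, z, bw, config.peth_baseline_s,
                       config.peth_smooth_sd_bins, len(rows))


def light_modulation_index(rate_on: float, rate_off: float) -> float:
    """(ON − OFF) / (ON + OFF); NaN when both rates are zero."""
    if rate_on < 0 or rate_off < 0:
        raise ValueError("rates must be nonnegative")
    tot = rate_on + rate_off
    if tot == 0:
        return np.nan
    return (rate_on - rate_off) / tot
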