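"""Analysis configuration.

All tunable constants of the pipeline live in :class:`AnalysisConfig`.
Defaults follow the published analysis conventions for awake-mouse whisking
electrophysiology: a 4-25 Hz whisking band, a 6 Hz setpoint low-pass, 1/2/3 s
epoch windows with a 1 deg onset rule, 0.4/0.5 ms waveform cuts for FS/RS
classification, 2 s Z-score bins, 200 ms PETH bins with a -1.0..-0.2 s
baseline, 50 equal-probability tuning bins with a 1,000-iteration shuffle
test, a 1-5 Hz slow-wave band on 2 s FFT segments, a 100 Hz LFP low-pass and
a 500 um L4 depth anchor.

The config round-trips losslessly through YAML (``to_yaml``/``from_yaml``).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml


@dataclass
class AnalysisConfig:
    # whisker kinematics
    whisk_band_hz: tuple[float, float] = (4.0, 25.0)
    setpoint_cutoff_hz: float = 6.0
    filter_order: int = 4  # effective zero-phase IIR order
    onset_threshold_deg: float = 1.0
    epoch_windows_s: tuple[float, ...] = (3.0, 2.0, 1.0)
    whisk_envelope_deg: float = 2.5   # envelope above this throughout -> whisking
    quiet_envelope_deg: float = 1.0   # envelope below this throughout -> quiet
    protraction_positive: bool = True

    # spike analysis
    fs_trough_to_peak_ms: float = 0.4
    rs_trough_to_peak_ms: float = 0.5
    zscore_bin_s: float = 2.0
    peth_bin_s: float = 0.2
    peth_baseline_s: tuple[float, float] = (-1.0, -0.2)
    peth_window_s: tuple[float, float] = (-2.0, 3.0)
    peth_smooth_sd_bins: float = 1.0
    min_epochs_per_label: int = 5
    alpha: float = 0.05

    # tuning analysis
    n_tuning_bins: int = 50
    n_shuffles: int = 1000
    shuffle_percentile: float = 95.0

    # Vm analysis
    vm_band_hz: tuple[float, float] = (1.0, 5.0)
    fft_segment_s: float = 2.0
    vm_dvdt_threshold: float = 10.0       # V/s spike-detection threshold
    vm_refractory_ms: float = 2.0
    vm_excise_pre_ms: float = 1.0
    vm_excise_post_ms: float = 4.0
    vm_phase_bins: int = 64
    vm_min_whisk_cycles: int = 20

    # LFP / CSD
    lfp_spectrum_rate_hz: float = 1000.0
    lfp_csd_rate_hz: float = 3000.0
    lfp_lowpass_hz: float = 100.0
    lfp_segment_s: float = 2.0
    lfp_min_epoch_s: float = 2.0
    csd_sink_onset_fraction: float = 0.2
    l4_depth_um: float = 500.0
    # layer boundary table (subpial depth intervals, um); editable per atlas
    layer_boundaries_um: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "L1": (0.0, 100.0),
            "L2/3": (100.0, 400.0),
            "L4": (400.0, 600.0),
            "L5": (600.0, 900.0),
            "L6": (900.0, 1200.0),
        }
    )

    seed: int = 0

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        # tuples -> lists for YAML friendliness (restored on load)
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "AnalysisConfig":
        kwargs: dict[str, Any] = {}
        for f in dataclasses.fields(cls):
            if f.name not in d:
                continue
            v = d[f.name]
            if isinstance(v, list):
                v = tuple(v)
            if f.name == "layer_boundaries_um":
                v = {k: tuple(iv) for k, iv in v.items()}
            kwargs[f.name] = v
        unknown = set(d) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
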