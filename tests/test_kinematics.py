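import numpy as np
import pytest
from scipy import signal

import whiskephys as wp
from whiskephys.kinematics import _phase_events

FS = 500.0


def _trace(x, fs=FS):
    return wp.WhiskerTrace(np.asarray(x, float), fs)


def _dft_mask_filter(x, fs, lo, hi):
    """Brute-force frequency-domain band mask, as an independent oracle."""
    spec = np.fft.rfft(x)
    f = np.fft.rfftfreq(x.size, 1 / fs)
    spec[(f < lo) | (f > hi)] = 0
    return np.fft.irfft(spec, x.size)


class TestBandpass:
    t = np.arange(int(10 * FS)) / FS

    def test_in_band_amplitude_preserved(self):
        x = 10 * np.sin(2 * np.pi * 10 * self.t)
        out = wp.bandpass_whisker(_trace(x)).angle
        mid = slice(int(FS), int(9 * FS))
        assert np.max(np.abs(out[mid])) == pytest.approx(10, rel=0.05)

    def test_out_of_band_attenuated(self):
        x = 10 * np.sin(2 * np.pi * 0.5 * self.t)
        out = wp.bandpass_whisker(_trace(x)).angle
        assert np.max(np.abs(out)) < 1.0  # > 90% attenuation

    def test_mixture_matches_dft_mask_oracle(self):
        x = 5 * np.sin(2 * np.pi * 10 * self.t) + 8 * np.sin(2 * np.pi * 0.5 * self.t)
        out = wp.bandpass_whisker(_trace(x)).angle
        target = 5 * np.sin(2 * np.pi * 10 * self.t)
        mid = slice(int(FS), int(9 * FS))
        r = np.corrcoef(out[mid], target[mid])[0, 1]
        assert r > 0.99
        oracle = _dft_mask_filter(x, FS, 4, 25)
        assert np.corrcoef(out[mid], oracle[mid])[0, 1] > 0.99

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            wp.bandpass_whisker(_trace(np.zeros(100)))


class TestHilbertPhase:
    def test_cosine_phase_is_linear_and_zero_at_peaks(self):
        t = np.arange(int(10 * FS)) / FS
        x = np.cos(2 * np.pi * 8 * t)
        phase, degenerate = wp.hilbert_phase(_trace(x))
        assert not degenerate
        expected = np.angle(np.exp(1j * 2 * np.pi * 8 * t))
        mid = slice(int(FS), int(9 * FS))
        err = np.angle(np.exp(1j * (phase[mid] - expected[mid])))
        assert np.max(np.abs(err)) < 0.05
        peaks = signal.argrelmax(x)[0]
        assert np.max(np.abs(phase[peaks])) < 0.06

    def test_constant_trace_flagged_degenerate(self):
        phase, degenerate = wp.hilbert_phase(_trace(np.full(5000, 3.0)))
        assert degenerate

    def test_chirp_phase_matches_analytic(self):
        t = np.arange(int(20 * FS)) / FS
        f0, f1, T = 6.0, 20.0, t[-1]
        inst = 2 * np.pi * (f0 * t + (f1 - f0) * t ** 2 / (2 * T))
        x = np.cos(inst)
        phase, _ = wp.hilbert_phase(_trace(x))
        mid = slice(int(2 * FS), int(18 * FS))
        err = np.angle(np.exp(1j * (phase[mid] - inst[mid])))
        assert np.max(np.abs(err)) < 0.05


class TestDecompose:
    def test_symmetric_oscillation_amplitude_and_midpoint(self, single_bout):
        # theta at phi=0 is 25 deg, at phi=+/-pi is 5 deg -> amp 10, mid 15
        dec = wp.decompose(single_bout.trace)
        mid_bout = slice(int(3 * FS), int(5 * FS))
        assert np.allclose(dec.amplitude[mid_bout], 10.0, atol=0.5)
        assert np.allclose(dec.midpoint[mid_bout], 15.0, atol=0.5)

    def test_direct_formula_on_event_pair(self):
        # oscillation between 20 (protraction) and 10 (retraction): amp 5, mid 15
        t = np.arange(int(10 * FS)) / FS
        x = 15 + 5 * np.cos(2 * np.pi * 10 * t)
        dec = wp.decompose(_trace(x))
        mid = slice(int(2 * FS), int(8 * FS))
        assert np.allclose(dec.amplitude[mid], 5.0, atol=0.3)
        assert np.allclose(dec.midpoint[mid], 15.0, atol=0.3)

    def test_ramping_amplitude_recovered(self):
        t = np.arange(int(10 * FS)) / FS
        amp = 5 + 0.5 * t  # 5 -> 10 deg over the sweep
        x = 15 + amp * np.cos(2 * np.pi * 10 * t)
        dec = wp.decompose(_trace(x))
        mid = slice(int(1 * FS), int(9 * FS))
        rms = np.sqrt(np.mean((dec.amplitude[mid] - amp[mid]) ** 2))
        assert rms < 0.1 * np.mean(amp)

    def test_flat_trace_flagged_undefined(self):
        dec = wp.decompose(_trace(np.full(int(5 * FS), 12.0)))
        assert not dec.defined

    def test_phase_zero_at_protraction_events(self, single_bout):
        dec = wp.decompose(single_bout.trace)
        in_bout = dec.protraction_events[
            (dec.protraction_events > 2.2 * FS) & (dec.protraction_events < 5.8 * FS)]
        assert in_bout.size >= 30
        # one phase sample step at 10 Hz is 2*pi*10/500 = 0.126 rad
        assert np.max(np.abs(dec.phase[in_bout])) < 0.13

    def test_offset_invariance(self, single_bout):
        dec0 = wp.decompose(single_bout.trace)
        shifted = _trace(single_bout.trace.angle + 7.5)
        dec1 = wp.decompose(shifted)
        mid = slice(int(3 * FS), int(5 * FS))
        assert np.allclose(dec1.amplitude[mid], dec0.amplitude[mid], atol=1e-6)
        assert np.allclose(dec1.midpoint[mid], dec0.midpoint[mid] + 7.5, atol=1e-6)
        assert np.allclose(dec1.setpoint[mid], dec0.setpoint[mid] + 7.5, atol=1e-6)


class TestSetpoint:
    def test_constant_trace(self):
        sp = wp.compute_setpoint(_trace(np.full(int(5 * FS), 12.0)))
        assert np.allclose(sp, 12.0, atol=1e-6)

    def test_oscillation_above_cutoff_removed(self):
        t = np.arange(int(10 * FS)) / FS
        x = 15 + 10 * np.sin(2 * np.pi * 10 * t)
        sp = wp.compute_setpoint(_trace(x))
        mid = slice(int(FS), int(9 * FS))
        assert np.max(np.abs(sp[mid] - 15)) < 1.0  # ripple < 10% of amplitude

    def test_tracks_slow_drift(self):
        t = np.arange(int(10 * FS)) / FS
        drift = 15 + 5 * np.sin(2 * np.pi * 1.0 * t)
        x = drift + 8 * np.sin(2 * np.pi * 12 * t)
        sp = wp.compute_setpoint(_trace(x))
        mid = slice(int(FS), int(9 * FS))
        rms = np.sqrt(np.mean((sp[mid] - drift[mid]) ** 2))
        assert rms < 0.1 * np.sqrt(np.mean((drift[mid] - 15) ** 2)) + 0.5


class TestSegmentEpochs:
    def test_quiet_then_bout(self, single_bout):
        eps = wp.segment_epochs(single_bout.trace)
        assert len(eps.by_label("quiet")) >= 1
        assert len(eps.by_label("whisking")) >= 1
        q0 = eps.by_label("quiet")[0]
        assert q0[0] < 1.0  # quiet epoch starts at the beginning
        # onset: first raw-angle sample exceeding baseline + 1 deg
        angle = single_bout.trace.angle
        baseline = np.median(angle[: int(2 * FS)])
        truth_onset = np.nonzero(angle > baseline + 1.0)[0][0] / FS
        assert len(eps.onset_times) == 1
        assert abs(eps.onset_times[0] - truth_onset) <= 2 / FS

    def test_fully_quiet_trace(self):
        rng = np.random.default_rng(0)
        x = 5 + rng.normal(0, 0.1, int(10 * FS))
        eps = wp.segment_epochs(_trace(x))
        assert eps.by_label("whisking") == []

    def test_epoch_durations_at_least_one_window(self, rich_session, config):
        eps = rich_session["epochs"]
        for _, s, e in eps.epochs:
            assert e - s >= min(config.epoch_windows_s) - 1e-9

    def test_epochs_non_overlapping(self, rich_session):
        eps = sorted(rich_session["epochs"].epochs, key=lambda r: r[1])
        for (_, _, e0), (_, s1, _) in zip(eps[:-1], eps[1:]):
            assert s1 >= e0 - 1e-9


class TestOnsetRule:
    def test_ramp_onset_at_threshold_crossing(self):
        fs = FS
        t = np.arange(int(2 * fs)) / fs
        x = np.where(t < 1.0, 0.0, (t - 1.0) * 5.0)  # 1 s baseline then 0->5 deg ramp
        onset = wp.detect_whisking_onset(_trace(x), (0.0, 1.0), (1.0, 2.0))
        truth = np.nonzero(x > 1.0)[0][0] / fs
        assert onset == pytest.approx(truth, abs=1 / fs)

    def test_no_crossing_returns_none(self):
        x = np.zeros(int(2 * FS))
        assert wp.detect_whisking_onset(_trace(x), (0.0, 1.0), (1.0, 2.0)) is None


class TestSummaries:
    def test_cycle_duration_and_speeds(self, single_bout):
        dec = wp.decompose(single_bout.trace)
        eps = wp.EpochSet(epochs=[("whisking", 2.2, 5.8)])
        (summ,) = wp.kinematic_summaries(single_bout.trace, dec, eps)
        assert summ["mean_cycle_duration_s"] == pytest.approx(0.1, abs=1 / FS)
        # peak speed of A*cos(2*pi*f*t) is 2*pi*f*A = 628 deg/s
        expected = 2 * np.pi * 10 * 10
        assert summ["mean_protraction_speed_deg_s"] == pytest.approx(expected, rel=0.05)
        assert summ["mean_retraction_speed_deg_s"] == pytest.approx(expected, rel=0.05)
        assert summ["midpoint_excursion_deg"] < 1.0  # constant-midpoint bout

    def test_time_reversal_swaps_speeds(self, single_bout):
        trace = single_bout.trace
        rev = wp.WhiskerTrace(trace.angle[::-1].copy(), trace.sample_rate)
        eps = wp.EpochSet(epochs=[("whisking", 2.2, 5.8)])
        rev_eps = wp.EpochSet(epochs=[("whisking", 10 - 5.8, 10 - 2.2)])
        (fwd,) = wp.kinematic_summaries(trace, wp.decompose(trace), eps)
        (bwd,) = wp.kinematic_summaries(rev, wp.decompose(rev), rev_eps)
        assert fwd["mean_protraction_speed_deg_s"] == pytest.approx(
            bwd["mean_retraction_speed_deg_s"], rel=0.05)


class TestReconstruct:
    def test_noiseless_bout_reconstruction(self, single_bout):
        dec = wp.decompose(single_bout.trace)
        rec, _ = wp.reconstruct(single_bout.trace, dec)
        mid = slice(int(2.5 * FS), int(5.5 * FS))
        rms = np.sqrt(np.mean((rec[mid] - single_bout.trace.angle[mid]) ** 2))
        assert rms < 0.1 * 10.0  # < 10% of bout amplitude

    def test_zero_amplitude_reduces_to_midpoint(self):
        n = 1000
        dec = wp.KinematicDecomposition(
            phase=np.linspace(-np.pi, np.pi, n), amplitude=np.zeros(n),
            midpoint=np.full(n, 14.0), setpoint=np.full(n, 14.0),
            protraction_events=np.array([], int), retraction_events=np.array([], int),
            sample_rate=FS)
        rec, _ = wp.reconstruct(_trace(np.full(n, 14.0)), dec)
        assert np.allclose(rec, 14.0)


def test_protraction_retraction_events_alternate(single_bout):
    dec = wp.decompose(single_bout.trace)
    prot, retr = _phase_events(dec.phase)
    inside = lambda ev: ev[(ev > 2.2 * FS) & (ev < 5.8 * FS)]
    merged = np.sort(np.concatenate([inside(prot), inside(retr)]))
    kinds = np.isin(merged, retr).astype(int)
    assert np.all(np.abs(np.diff(kinds)) == 1)  # strictly alternating
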