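import numpy as np
import pytest
from scipy import special

import whiskephys as wp

FS = 500.0


class TestWhiskerGenerator:
    def test_bout_peak_value_exact(self, single_bout):
        # mid 15 + amp 10 at a cosine peak = 25 deg exactly (noise off)
        i_peak = int(2.0 * FS)  # phase0 = 0 -> peak at bout start
        assert single_bout.trace.angle[i_peak] == pytest.approx(25.0, abs=1e-12)

    def test_empty_schedule_constant(self):
        p = wp.WhiskGenParams(sweep_duration=5.0, bout_schedule=[],
                              quiet_noise_sd=0.0, baseline_deg=7.0)
        syn = wp.generate_whisker_trace(p)
        assert np.allclose(syn.trace.angle, 7.0)

    def test_dominant_dft_component_at_bout_frequency(self, single_bout):
        # oracle: dense DFT of the bout segment
        seg = single_bout.trace.angle[int(2 * FS):int(6 * FS)]
        spec = np.abs(np.fft.rfft(seg - seg.mean()))
        freqs = np.fft.rfftfreq(seg.size, 1 / FS)
        assert freqs[np.argmax(spec)] == pytest.approx(10.0, abs=0.3)

    def test_overlapping_bouts_rejected(self):
        with pytest.raises(ValueError):
            wp.WhiskGenParams(sweep_duration=10.0,
                              bout_schedule=[(1, 4, 10, 10, 15), (3, 6, 8, 5, 15)])

    def test_out_of_band_frequency_rejected(self):
        with pytest.raises(ValueError):
            wp.WhiskGenParams(sweep_duration=10.0, bout_schedule=[(1, 4, 30, 10, 15)])

    def test_reproducible(self):
        p = wp.WhiskGenParams(sweep_duration=5.0, bout_schedule=[(1, 3, 10, 8, 12)],
                              quiet_noise_sd=0.5, seed=42)
        a = wp.generate_whisker_trace(p).trace.angle
        b = wp.generate_whisker_trace(p).trace.angle
        assert np.array_equal(a, b)


class TestSpikeGenerator:
    def test_homogeneous_rate(self, continuous_whisk300):
        truth = wp.TuningGroundTruth(baseline_rate=5.0, whisking_gain=1.0)
        u = wp.generate_spike_train(continuous_whisk300["decomp"],
                                    continuous_whisk300["epochs"], truth, seed=0)
        n = u.spike_times["sweep0"].size
        se = np.sqrt(5.0 * 300)
        assert abs(n - 5.0 * 300) < 3 * se

    def test_light_suppression_rate(self, rich_session):
        # oracle: the mean of lambda(t) itself
        truth = wp.TuningGroundTruth(baseline_rate=10.0, light_suppression=0.95)
        u = wp.generate_spike_train(rich_session["truth_decomp"],
                                    rich_session["truth_epochs"], truth,
                                    light_on=True, seed=1)
        lam_mean = u.rate_true.mean()
        assert lam_mean == pytest.approx(0.5, abs=1e-9)
        n = u.spike_times["sweep0"].size
        dur = u.sweep_durations["sweep0"]
        assert abs(n / dur - 0.5) < 4 * np.sqrt(0.5 * dur) / dur

    def test_phase_tuned_circular_mean(self, continuous_whisk300):
        truth = wp.TuningGroundTruth(baseline_rate=5.0, phase_kappa=2.0,
                                     preferred_phase=0.7)
        u = wp.generate_spike_train(continuous_whisk300["decomp"],
                                    continuous_whisk300["epochs"], truth, seed=2)
        st = u.spike_times["sweep0"]
        dec = continuous_whisk300["decomp"]
        ph = dec.phase[np.minimum((st * FS).astype(int), dec.phase.size - 1)]
        circ_mean = np.angle(np.mean(np.exp(1j * ph)))
        # oracle: lambda-weighted circular mean equals the preferred phase
        lam = u.rate_true
        oracle = np.angle(np.sum(lam * np.exp(1j * dec.phase)))
        assert abs(np.angle(np.exp(1j * (circ_mean - truth.preferred_phase)))) < 0.2
        assert abs(np.angle(np.exp(1j * (circ_mean - oracle)))) < 0.2

    def test_counts_match_rate_integral(self, rich_session):
        # Poisson property: total count within 4 SE of integral of lambda
        truth = wp.TuningGroundTruth(baseline_rate=6.0, whisking_gain=2.0,
                                     phase_kappa=1.0, preferred_phase=0.3)
        counts, integrals = [], []
        for seed in range(5):
            u = wp.generate_spike_train(rich_session["truth_decomp"],
                                        rich_session["truth_epochs"], truth, seed=seed)
            counts.append(u.spike_times["sweep0"].size)
            integrals.append(u.rate_true.sum() / FS)
        total, expected = np.sum(counts), np.sum(integrals)
        assert abs(total - expected) < 4 * np.sqrt(expected)

    def test_von_mises_normalizer_keeps_baseline(self, continuous_whisk300):
        # time-averaged phase factor is 1: mean lambda ~ baseline * gain
        truth = wp.TuningGroundTruth(baseline_rate=5.0, phase_kappa=2.0)
        u = wp.generate_spike_train(continuous_whisk300["decomp"],
                                    continuous_whisk300["epochs"], truth, seed=0)
        assert u.rate_true.mean() == pytest.approx(5.0, rel=0.02)

    def test_reproducible(self, rich_session):
        truth = wp.TuningGroundTruth(baseline_rate=5.0)
        a = wp.generate_spike_train(rich_session["truth_decomp"],
                                    rich_session["truth_epochs"], truth, seed=9)
        b = wp.generate_spike_train(rich_session["truth_decomp"],
                                    rich_session["truth_epochs"], truth, seed=9)
        assert np.array_equal(a.spike_times["sweep0"], b.spike_times["sweep0"])


class TestVmGenerator:
    def test_all_zero_modulation_constant(self, rich_session):
        truth = wp.VmGroundTruth(rest_vm=-60.0, slow_wave_sd_quiet=0.0,
                                 slow_wave_sd_whisk=0.0, whisk_depol=0.0,
                                 phase_lock_amp=0.0, noise_sd=0.0)
        rec, _ = wp.generate_vm_trace(rich_session["truth_decomp"],
                                      rich_session["truth_epochs"], truth)
        assert np.allclose(rec.vm, -60.0)

    def test_phase_lock_peak_to_trough(self, rich_session):
        # cosine of amplitude 2 mV -> phase-averaged peak-to-trough 4 mV
        truth = wp.VmGroundTruth(slow_wave_sd_quiet=0.0, slow_wave_sd_whisk=0.0,
                                 whisk_depol=0.0, phase_lock_amp=2.0, noise_sd=0.0)
        rec, _ = wp.generate_vm_trace(rich_session["truth_decomp"],
                                      rich_session["truth_epochs"], truth)
        pl = wp.phase_locked_vm(rec, rich_session["truth_decomp"],
                                rich_session["truth_epochs"])
        assert pl.modulation_depth == pytest.approx(4.0, rel=0.1)

    def test_slow_wave_state_ratio(self, rich_session):
        # sd 4 mV quiet vs 1 mV whisking -> band-integral ratio ~ 4
        truth = wp.VmGroundTruth(slow_wave_sd_quiet=4.0, slow_wave_sd_whisk=1.0,
                                 whisk_depol=0.0, phase_lock_amp=0.0, noise_sd=0.0,
                                 seed=4)
        rec, gt = wp.generate_vm_trace(rich_session["truth_decomp"],
                                       rich_session["truth_epochs"], truth)
        stats = wp.epoch_vm_stats(rec, rich_session["truth_epochs"])
        d = wp.vm_condition_deltas(stats)
        ratio = d["band_integral_quiet_mv"] / d["band_integral_whisk_mv"]
        assert ratio == pytest.approx(4.0, rel=0.35)
        # oracle: brute-force DFT band integral of the noiseless slow
        # component at the definition's own 2 s segmentation (amplitude
        # integrals are resolution-specific, so the oracle must match it)
        fs = rec.sample_rate
        sl = gt["slow_component"]
        q0, q1 = rich_session["truth_epochs"].by_label("quiet")[0]
        seg = sl[int(q0 * fs):int(q1 * fs)]
        nseg = int(2.0 * fs)
        vals = []
        for k in range(seg.size // nseg):
            chunk = seg[k * nseg:(k + 1) * nseg]
            amps = [2 / nseg * abs(np.sum(chunk * np.exp(-2j * np.pi * m
                                                         * np.arange(nseg) / nseg)))
                    for m in range(2, 11)]  # 1..5 Hz at 0.5 Hz spacing
            vals.append(amps)
        f_band = 1.0 + 0.5 * np.arange(9)
        oracle = np.trapezoid(np.mean(vals, axis=0), f_band)
        _, _, integral = wp.vm_band_fft(seg, fs)
        assert integral == pytest.approx(oracle, rel=0.02)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            wp.VmGroundTruth(slow_wave_sd_quiet=1.0, slow_wave_sd_whisk=2.0)
        with pytest.raises(ValueError):
            wp.VmGroundTruth(rest_vm=-50.0, spike_threshold=-55.0)

    def test_spikes_inserted_at_low_threshold(self, rich_session):
        truth = wp.VmGroundTruth(slow_wave_sd_quiet=3.0, slow_wave_sd_whisk=1.0,
                                 whisk_depol=3.0, noise_sd=0.0,
                                 spike_threshold=-57.0, seed=0)
        rec, gt = wp.generate_vm_trace(rich_session["truth_decomp"],
                                       rich_session["truth_epochs"], truth)
        assert gt["spike_times"].size > 0
        assert rec.vm.max() > truth.spike_threshold + 20  # spike waveforms present


class TestLaminarGenerator:
    def test_noiseless_min_channel_is_true_l4(self):
        truth = wp.LaminarGroundTruth(noise_sd_mv=0.0, touch_times=(1.0,),
                                      duration_s=2.0, seed=0)
        sess, gt = wp.generate_laminar_lfp(truth)
        ch_min = np.unravel_index(np.argmin(sess.lfp), sess.lfp.shape)[0]
        assert ch_min == truth.true_l4_channel

    def test_csd_oracle_on_analytic_field(self):
        # finite differences on the noiseless field: strongest sink at L4
        truth = wp.LaminarGroundTruth(noise_sd_mv=0.0, touch_times=(1.0,),
                                      duration_s=2.0, seed=0)
        sess, gt = wp.generate_laminar_lfp(truth)
        field = gt["field_clean"][::2]  # even column
        d2 = field[:-2] - 2 * field[1:-1] + field[2:]
        sink = -d2  # sink-negative convention
        i, _ = np.unravel_index(np.argmin(sink), sink.shape)
        assert (i + 1) * 2 == truth.true_l4_channel

    def test_zero_touches_localization_fails(self):
        truth = wp.LaminarGroundTruth(touch_times=(), duration_s=2.0, seed=0)
        sess, _ = wp.generate_laminar_lfp(truth)
        loc = wp.locate_layer4(sess)
        assert not loc.success
        assert "touch" in loc.reason

    def test_reproducible(self):
        truth = wp.LaminarGroundTruth(seed=11, duration_s=2.0, touch_times=(1.0,))
        a, _ = wp.generate_laminar_lfp(truth)
        b, _ = wp.generate_laminar_lfp(truth)
        assert np.array_equal(a.lfp, b.lfp)
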