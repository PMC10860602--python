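"""Session orchestration: synth → kinematics → spikes/tuning/vm/lfp → report.

A *session recipe* describes a synthetic session (sweep layout, unit ground
truths, optional Vm cell and laminar probe). :func:`run_session` generates
the data, runs every analysis stage on the pipeline's own outputs (never on
the generator's ground truth), and writes deterministic CSV/JSON tables
plus a provenance record. :func:`compare_conditions` implements the
two-sample convention for paired Light-OFF/ON comparisons: paired t test
when the paired differences pass a normality check, Wilcoxon signed-rank
otherwise.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import io as wio
from .config import AnalysisConfig
from .kinematics import decompose, segment_epochs
from .spikes import classify_cell_type, classify_whisk_modulation_cohort, light_modulation_index
from .synth import (LaminarGroundTruth, TuningGroundTruth, VmGroundTruth, WhiskGenParams,
                    generate_laminar_lfp, generate_spike_train, generate_vm_trace,
                    generate_whisker_trace, truth_decomposition, truth_epochs)
from .tuning import analyze_tuning
from .lfp import locate_layer4, normalize_spectra, preprocess_lfp, state_spectra
from .vm import detect_and_clean_spikes, epoch_vm_stats, test_phase_lock, vm_condition_deltas

__all__ = ["SessionRecipe", "ConditionComparison", "run_session", "compare_conditions",
           "pool_sweeps"]


@dataclass
class SessionRecipe:
    """Synthetic session layout: sweeps, units, optional Vm and probe."""

    whisk: WhiskGenParams = field(default_factory=lambda: WhiskGenParams(
        sweep_duration=40.0,
        bout_schedule=[(5.0, 10.0, 8.0, 12.0, 15.0), (15.0, 21.0, 12.0, 8.0, 12.0),
                       (26.0, 32.0, 10.0, 10.0, 14.0)]))
    n_sweeps_off: int = 3
    n_sweeps_on: int = 3
    units: list[TuningGroundTruth] = field(default_factory=lambda: [
        TuningGroundTruth(baseline_rate=5.0, whisking_gain=2.0, phase_kappa=1.5,
                          preferred_phase=0.5, light_suppression=0.8),
        TuningGroundTruth(baseline_rate=8.0, whisking_gain=0.5, light_suppression=0.8),
        TuningGroundTruth(baseline_rate=4.0),
    ])
    vm: VmGroundTruth | None = None
    laminar: LaminarGroundTruth | None = None
    # probe column used for CSD; hardware metadata (as in a real sidecar),
    # not inferred from the data
    csd_subset: str = "even"
    seed: int = 0


@dataclass
class ConditionComparison:
    variable: str
    n: int
    test_used: str                # 'paired-t' | 'signed-rank'
    normal: bool
    p: float
    median_off: float
    median_on: float
    q1_off: float = np.nan
    q3_off: float = np.nan
    q1_on: float = np.nan
    q3_on: float = np.nan


def compare_conditions(variable: str, values_off, values_on,
                       alpha_normality: float = 0.05) -> ConditionComparison:
    """Paired OFF-vs-ON comparison with normality-driven test selection.

    Shapiro-Wilk on the paired differences decides between a paired t test
    and a Wilcoxon signed-rank test. All-identical pairs degenerate to
    p = 1 under the signed-rank path.
    """
    off = np.asarray(values_off, float)
    on = np.asarray(values_on, float)
    if off.size != on.size or off.size < 2:
        raise ValueError("need equal-length paired samples (n >= 2)")
    diffs = on - off
    if np.allclose(diffs, 0):
        return ConditionComparison(variable, off.size, "signed-rank", False, 1.0,
                                   float(np.median(off)), float(np.median(on)))
    normal = False
    if off.size >= 3 and np.ptp(diffs) > 0:
        normal = stats.shapiro(diffs).pvalue > alpha_normality
    if normal:
        p = float(stats.ttest_rel(on, off).pvalue)
        test = "paired-t"
    else:
        p = float(stats.wilcoxon(on, off, zero_method="wilcox").pvalue)
        test = "signed-rank"
    q = lambda x, v: float(np.percentile(x, v))
    return ConditionComparison(variable, off.size, test, normal, p,
                               float(np.median(off)), float(np.median(on)),
                               q(off, 25), q(off, 75), q(on, 25), q(on, 75))


def pool_sweeps(tracks: list[np.ndarray], masks: list[np.ndarray],
                spike_times: list[np.ndarray], fs: float):
    """Concatenate per-sweep variable tracks, whisking masks and spikes
    onto one virtual clock (sweep k offset by k·duration)."""
    track = np.concatenate(tracks)
    mask = np.concatenate(masks)
    offs, acc = [], 0.0
    for tr in tracks:
        offs.append(acc)
        acc += tr.size / fs
    spikes = np.concatenate([t + o for t, o in zip(spike_times, offs)]) \
        if spike_times else np.array([])
    return track, mask, spikes


def run_session(out_dir, recipe: SessionRecipe | None = None,
                config: AnalysisConfig | None = None) -> dict:
    """Generate a synthetic session and run the full analysis chain.

    Writes whisker/decomposition/epoch CSVs per sweep, a per-unit results
    table, Vm statistics, laminar localization JSON and a provenance
    record. Returns the report dict. Deterministic given the recipe seed.
    """
    recipe = recipe or SessionRecipe()
    config = config or AnalysisConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng_seeds = np.random.SeedSequence(recipe.seed).generate_state(4096) % (2 ** 31)
    seed_i = iter(rng_seeds.tolist())

    sweeps = [("off", i) for i in range(recipe.n_sweeps_off)] + \
             [("on", i) for i in range(recipe.n_sweeps_on)]
    per_sweep = {}
    for cond, i in sweeps:
        sw_id = f"{cond}{i}"
        params = WhiskGenParams(**{**recipe.whisk.__dict__, "seed": next(seed_i),
                                   "bout_schedule": list(recipe.whisk.bout_schedule)})
        synth = generate_whisker_trace(params)
        dec = decompose(synth.trace, config)
        eps = segment_epochs(synth.trace, config)
        wio.write_whisker_csv(out / f"whisker_{sw_id}.csv", synth.trace)
        wio.write_decomposition_csv(out / f"decomp_{sw_id}.csv", dec)
        wio.write_epochs_csv(out / f"epochs_{sw_id}.csv", eps)
        per_sweep[sw_id] = dict(cond=cond, synth=synth, decomp=dec, epochs=eps,
                                truth_dec=truth_decomposition(synth),
                                truth_eps=truth_epochs(params))

    # ---- units: generate per sweep, then analyze on pipeline outputs
    units = []
    for ui, truth in enumerate(recipe.units):
        spike_times, durations, light = {}, {}, {}
        lam = None
        for sw_id, s in per_sweep.items():
            u1 = generate_spike_train(s["truth_dec"], s["truth_eps"], truth,
                                      light_on=s["cond"] == "on", seed=next(seed_i),
                                      unit_id=f"u{ui}", sweep_id=sw_id)
            spike_times[sw_id] = u1.spike_times[sw_id]
            durations[sw_id] = u1.sweep_durations[sw_id]
            light[sw_id] = s["cond"] == "on"
            lam = u1.rate_true
        unit = type(u1)(unit_id=f"u{ui}", spike_times=spike_times,
                        sweep_durations=durations, mean_waveform=u1.mean_waveform,
                        rate_true=lam, light_on=light)
        units.append(unit)
    wio.write_spikes_csv(out / "spikes.csv", units)

    off_sweeps = [sw for sw, s in per_sweep.items() if s["cond"] == "off"]
    epochs_off = {sw: per_sweep[sw]["epochs"] for sw in off_sweeps}
    mods = classify_whisk_modulation_cohort(units, epochs_off, config)

    fs = recipe.whisk.sample_rate
    rows = []
    for unit, mod, truth in zip(units, mods, recipe.units):
        tot_off = sum(unit.sweep_durations[sw] for sw in off_sweeps)
        on_sweeps = [sw for sw in per_sweep if per_sweep[sw]["cond"] == "on"]
        tot_on = sum(unit.sweep_durations[sw] for sw in on_sweeps)
        r_off = sum(unit.spike_times[sw].size for sw in off_sweeps) / tot_off
        r_on = (sum(unit.spike_times[sw].size for sw in on_sweeps) / tot_on
                if tot_on else np.nan)
        lmi = light_modulation_index(r_on, r_off) if np.isfinite(r_on) else np.nan

        track, mask, spikes = pool_sweeps(
            [per_sweep[sw]["decomp"].phase for sw in off_sweeps],
            [per_sweep[sw]["epochs"].sample_mask(
                "whisking", per_sweep[sw]["decomp"].phase.size, fs) for sw in off_sweeps],
            [unit.spike_times[sw] for sw in off_sweeps], fs)
        quiet_rates = []
        for sw in off_sweeps:
            for s0, e0 in per_sweep[sw]["epochs"].by_label("quiet"):
                t = unit.spike_times[sw]
                quiet_rates.append(np.sum((t >= s0) & (t < e0)) / (e0 - s0))
        baseline = float(np.mean(quiet_rates)) if quiet_rates else np.nan
        try:
            tun = analyze_tuning(spikes, track, mask, fs, "phase", baseline, config,
                                 np.random.default_rng(next(seed_i)))
            tuned, p_sh, depth, index, pref = (tun.tuned, tun.p_shuffle,
                                               tun.modulation_depth, tun.modulation_index,
                                               tun.preferred_value)
        except ValueError:
            tuned, p_sh, depth, index, pref = False, np.nan, np.nan, np.nan, np.nan
        rows.append({
            "unit_id": unit.unit_id, "cell_class": classify_cell_type(unit, config),
            "category": mod.category, "w_delta_ap": mod.w_delta_ap,
            "p_raw": mod.p_raw, "q_bh": mod.q_bh, "light_mod_index": lmi,
            "phase_tuned": tuned, "p_shuffle": p_sh, "modulation_depth": depth,
            "modulation_index": index, "preferred_phase": pref,
        })
    units_df = pd.DataFrame(rows)
    units_df.to_csv(out / "units.csv", index=False, float_format="%.6g")

    report: dict = {"n_sweeps": len(sweeps), "n_units": len(units),
                    "stages": {"kinematics": "ok", "spikes": "ok"}}

    # ---- Vm stage (optional)
    if recipe.vm is not None:
        sw = off_sweeps[0]
        dec, eps = per_sweep[sw]["decomp"], per_sweep[sw]["epochs"]
        vm_truth = VmGroundTruth(**{**recipe.vm.__dict__, "seed": next(seed_i)})
        rec, _ = generate_vm_trace(per_sweep[sw]["truth_dec"], per_sweep[sw]["truth_eps"],
                                   vm_truth)
        detect_and_clean_spikes(rec, config)
        st = epoch_vm_stats(rec, eps, config)
        deltas = vm_condition_deltas(st)
        pl = test_phase_lock(rec, dec, eps, config.n_shuffles, config,
                             np.random.default_rng(next(seed_i)))
        vm_row = {**deltas, "pl_depth_mv": pl.modulation_depth,
                  "pl_phase_rad": pl.most_depolarized_phase, "pl_p": pl.p_shuffle}
        pd.DataFrame([vm_row]).to_csv(out / "vm.csv", index=False, float_format="%.6g")
        report["stages"]["vm"] = "ok"
    else:
        report["stages"]["vm"] = "skipped (no Vm inputs)"

    # ---- laminar stage (optional)
    if recipe.laminar is not None:
        lam_truth = LaminarGroundTruth(**{**recipe.laminar.__dict__, "seed": next(seed_i)})
        session, _ = generate_laminar_lfp(lam_truth)
        loc = locate_layer4(session, subset=recipe.csd_subset, config=config)
        spec_sess = preprocess_lfp(session, config.lfp_spectrum_rate_hz,
                                   config.lfp_lowpass_hz, config)
        sw = off_sweeps[0]
        freqs, spectra = state_spectra(spec_sess.lfp[lam_truth.true_l4_channel],
                                       spec_sess.sample_rate, per_sweep[sw]["epochs"],
                                       config)
        loc_doc = {"success": loc.success, "l4_channel": loc.l4_channel,
                   "l4_depth_um": loc.l4_depth_um, "subset": loc.subset,
                   "criteria": loc.criteria, "disagreement": loc.disagreement}
        (out / "localization.json").write_text(json.dumps(loc_doc, indent=1, sort_keys=True))
        report["stages"]["lfp"] = "ok"
        report["l4_channel"] = loc.l4_channel
    else:
        report["stages"]["lfp"] = "skipped (no laminar inputs)"

    # ---- provenance
    cfg_yaml = json.dumps(config.to_dict(), sort_keys=True, default=str)
    prov = {"config_sha256": hashlib.sha256(cfg_yaml.encode()).hexdigest(),
            "recipe_seed": recipe.seed, "schema_version": wio.SIDE_SCHEMA_VERSION}
    (out / "provenance.json").write_text(json.dumps(prov, indent=1, sort_keys=True))
    report["out_dir"] = str(out)
    return report
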