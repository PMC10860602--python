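"""File formats: CSV tables and binary float matrices with JSON sidecars."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .kinematics import EpochSet, KinematicDecomposition, WhiskerTrace

SIDE_SCHEMA_VERSION = 1


def write_whisker_csv(path, trace: WhiskerTrace) -> None:
    pd.DataFrame({"time_s": trace.times, "angle_deg": trace.angle}).to_csv(path, index=False)


def read_whisker_csv(path, sweep_id: str = "sweep0") -> WhiskerTrace:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy()
    dt = np.diff(t)
    if t.size < 2 or not np.allclose(dt, dt[0]):
        raise ValueError("time_s must be uniformly sampled")
    return WhiskerTrace(df["angle_deg"].to_numpy(), 1.0 / dt[0], sweep_id, float(t[0]))


def write_decomposition_csv(path, decomp: KinematicDecomposition) -> None:
    pd.DataFrame({
        "time_s": decomp.times, "phase_rad": decomp.phase,
        "amp_deg": decomp.amplitude, "mid_deg": decomp.midpoint,
        "set_deg": decomp.setpoint,
    }).to_csv(path, index=False)


def read_decomposition_csv(path) -> KinematicDecomposition:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy()
    fs = 1.0 / (t[1] - t[0])
    phase = df["phase_rad"].to_numpy()
    d = np.diff(phase)
    up = np.where((phase[:-1] < 0) & (phase[1:] >= 0) & (d > 0) & (d < np.pi))[0] + 1
    wrap = np.where(d < -np.pi)[0] + 1
    return KinematicDecomposition(
        phase=phase, amplitude=df["amp_deg"].to_numpy(),
        midpoint=df["mid_deg"].to_numpy(), setpoint=df["set_deg"].to_numpy(),
        protraction_events=up, retraction_events=wrap,
        sample_rate=fs, t0=float(t[0]))


def write_epochs_csv(path, epochs: EpochSet) -> None:
    rows = [{"label": lab, "start_s": s, "end_s": e} for lab, s, e in epochs.epochs]
    df = pd.DataFrame(rows, columns=["label", "start_s", "end_s"])
    df["onset_s"] = np.nan
    onsets = list(epochs.onset_times)
    for on in onsets:
        hit = df[(df.label == "whisking") & (df.start_s <= on) & (on < df.end_s)]
        if len(hit):
            df.loc[hit.index[0], "onset_s"] = on
    df.to_csv(path, index=False)


def read_epochs_csv(path) -> EpochSet:
    df = pd.read_csv(path)
    eps = [(r.label, float(r.start_s), float(r.end_s)) for r in df.itertuples()]
    onsets = [float(v) for v in df.get("onset_s", pd.Series(dtype=float)) if np.isfinite(v)]
    return EpochSet(epochs=eps, onset_times=onsets)


def write_spikes_csv(path, units) -> None:
    rows = []
    for u in units:
        for sw, times in sorted(u.spike_times.items()):
            rows.extend({"unit_id": u.unit_id, "sweep_id": sw, "spike_time_s": t}
                        for t in times)
    pd.DataFrame(rows, columns=["unit_id", "sweep_id", "spike_time_s"]).to_csv(path, index=False)


def write_matrix(path, matrix: np.ndarray, sidecar: dict) -> None:
    """float32 binary matrix + JSON sidecar describing shape/rate/units."""
    path = Path(path)
    arr = np.asarray(matrix, dtype=np.float32)
    arr.tofile(path)
    meta = {"schema_version": SIDE_SCHEMA_VERSION, "dtype": "float32",
            "shape": list(arr.shape), **sidecar}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))


def read_matrix(path) -> tuple[np.ndarray, dict]:
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    arr = np.fromfile(path, dtype=meta["dtype"]).reshape(meta["shape"]).astype(float)
    return arr, meta


def write_ground_truth(path, payload: dict) -> None:
    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        return str(o)
    doc = {"schema_version": SIDE_SCHEMA_VERSION, **payload}
    Path(path).write_text(json.dumps(doc, indent=1, default=_default))
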