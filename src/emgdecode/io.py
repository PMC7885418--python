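"""Plain-text / HDF5 serialization of recordings, stimuli and logs."""

from __future__ import annotations

import csv
import json
from pathlib import Path

import h5py
import numpy as np

from .synth import RawEmgRecording, StimulusEncoding


def write_recording_csv(path, recording: RawEmgRecording) -> None:
    """One column per channel; header row carries the sampling rate."""
    path = Path(path)
    with path.open("w", newline="") as f:
        writer = csv.writer(f)
        writer.writerow(
            [f"ch{i}" for i in range(recording.n_channels)]
            + [f"fs={recording.sampling_rate}", f"bits={recording.quantization_bits}"]
        )
        for t in range(recording.n_samples):
            writer.writerow([repr(float(v)) for v in recording.voltages[:, t]])


def read_recording_csv(path) -> RawEmgRecording:
    path = Path(path)
    with path.open() as f:
        reader = csv.reader(f)
        header = next(reader)
        meta = {}
        n_channels = 0
        for cell in header:
            if "=" in cell:
                key, val = cell.split("=", 1)
                meta[key] = float(val)
            else:
                n_channels += 1
        rows = [[float(v) for v in row] for row in reader]
    volts = np.asarray(rows).T
    return RawEmgRecording(
        voltages=volts,
        sampling_rate=meta.get("fs", 200.0),
        quantization_bits=int(meta.get("bits", 8)),
    )


def write_stimulus_csv(path, stimulus: StimulusEncoding) -> None:
    with Path(path).open("w", newline="") as f:
        writer = csv.writer(f)
        writer.writerow([f"dof{j}" for j in range(stimulus.n_dofs)])
        for t in range(stimulus.n_samples):
            writer.writerow([int(v) for v in stimulus.values[:, t]])


def read_stimulus_csv(path) -> StimulusEncoding:
    with Path(path).open() as f:
        reader = csv.reader(f)
        next(reader)
        rows = [[int(v) for v in row] for row in reader]
    return StimulusEncoding(values=np.asarray(rows, int).T)


def write_session_hdf5(path, recording: RawEmgRecording,
                       stimulus: StimulusEncoding) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("emg", data=recording.voltages)
        f.create_dataset("stimulus", data=stimulus.values)
        f.attrs["fs"] = recording.sampling_rate
        f.attrs["bits"] = recording.quantization_bits


def read_session_hdf5(path) -> tuple[RawEmgRecording, StimulusEncoding]:
    with h5py.File(path, "r") as f:
        rec = RawEmgRecording(
            voltages=f["emg"][...],
            sampling_rate=float(f.attrs["fs"]),
            quantization_bits=int(f.attrs["bits"]),
        )
        stim = StimulusEncoding(values=f["stimulus"][...])
    return rec, stim


def write_trial_logs(out_dir, logs, seed: int) -> None:
    """Per-trial CSV trajectories plus a JSON session manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": seed, "trials": []}
    for k, log in enumerate(logs):
        traj_path = out_dir / f"trial_{k:02d}.csv"
        with traj_path.open("w", newline="") as f:
            writer = csv.writer(f)
            writer.writerow(["t", "x", "y"])
            for idx, (x, y) in enumerate(log.trajectory):
                writer.writerow([idx / 200.0, x, y])
        manifest["trials"].append(
            {
                "file": traj_path.name,
                "center": list(log.target.center),
                "radius": log.target.radius,
                "success": bool(log.success),
                "completion_time": log.completion_time,
                "overshoots": log.overshoots,
            }
        )
    (out_dir / "session.json").write_text(json.dumps(manifest, indent=1))


def write_feature_table_csv(path, rows) -> None:
    """Feature windows as CSV: window_start, label, then the 4*I features."""
    rows = list(rows)
    with Path(path).open("w", newline="") as f:
        writer = csv.writer(f)
        n_features = len(rows[0][1]) if rows else 0
        writer.writerow(["window_start", "label"] + [f"f{i}" for i in range(n_features)])
        for start, vec, label in rows:
            writer.writerow([start, -1 if label is None else label]
                            + [repr(float(v)) for v in vec])


def write_metrics_report(path_base, metric_sets: dict) -> None:
    """Session metrics as both JSON and CSV (one row per session)."""
    base = Path(path_base)
    payload = {name: ms.as_dict() for name, ms in metric_sets.items()}
    base.with_suffix(".json").write_text(json.dumps(payload, indent=1))
    with base.with_suffix(".csv").open("w", newline="") as f:
        writer = csv.writer(f)
        writer.writerow(["session", "CR", "CT", "PE", "O", "T"])
        for name, d in payload.items():
            writer.writerow([name, d["CR"], d["CT"], d["PE"], d["O"], d["T"]])


def write_training_log_csv(path, log) -> None:
    with Path(path).open("w", newline="") as f:
        writer = csv.writer(f)
        writer.writerow(["iteration", "total", "inference", "contractive", "validation"])
        for row in log.to_rows():
            writer.writerow(row)
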