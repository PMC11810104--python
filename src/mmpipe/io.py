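"""Session bundles on disk.

A bundle is a directory holding one recording:

* ``manifest.json`` — site_id, frame rate, loop type, seed, config echo;
* ``behavior.csv`` — time_s, run_speed_cmps, sound_db, visual_flow, pupil;
* ``events.csv`` — the event table;
* ``fluorescence.h5`` — datasets ``F`` (neurons x frames), ``neuron_site``,
  and optionally ``dff`` added by the preprocessing stage;
* ``ground_truth.csv`` — optional generator labels.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .events import EventTable
from .preprocess import DffMatrix
from .synthgen import GroundTruthNeuron, Session, SimConfig

__all__ = ["write_bundle", "read_bundle", "add_dff", "read_dff"]


def write_bundle(session: Session, path: str | Path) -> Path:
    """Write a session bundle; returns the bundle directory."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest = {
        "site_id": int(session.site_id),
        "frame_rate_hz": float(session.frame_rate_hz),
        "loop_type": session.loop_type,
        "n_neurons": int(session.n_neurons),
        "n_frames": int(session.n_frames),
        "config": dataclasses.asdict(session.config) if session.config else None,
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    behav = pd.DataFrame({
        "time_s": session.t,
        "run_speed_cmps": session.run_speed,
        "sound_db": session.sound_db,
        "visual_flow": session.visual_flow,
        "pupil": session.pupil if session.pupil is not None
                 else np.full(session.n_frames, np.nan),
    })
    behav.to_csv(path / "behavior.csv", index=False)
    session.events.to_csv(path / "events.csv", index=False)
    with h5py.File(path / "fluorescence.h5", "w") as h5:
        h5.create_dataset("F", data=session.F)
        h5.create_dataset("neuron_site", data=np.asarray(session.neuron_site))
    if session.ground_truth is not None:
        pd.DataFrame([dataclasses.asdict(gt) for gt in session.ground_truth]
                     ).to_csv(path / "ground_truth.csv", index=False)
    return path


def read_bundle(path: str | Path) -> Session:
    """Read a session bundle back into a :class:`Session`.

    Raises a validation error naming the offending fields if trace lengths
    disagree with the manifest.
    """
    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    behav = pd.read_csv(path / "behavior.csv")
    events = EventTable(pd.read_csv(path / "events.csv"))
    with h5py.File(path / "fluorescence.h5", "r") as h5:
        F = h5["F"][:]
        neuron_site = h5["neuron_site"][:]
    n = manifest["n_frames"]
    problems = []
    if len(behav) != n:
        problems.append(f"behavior.csv has {len(behav)} rows, manifest says {n}")
    if F.shape != (manifest["n_neurons"], n):
        problems.append(f"F has shape {F.shape}, manifest says "
                        f"({manifest['n_neurons']}, {n})")
    if problems:
        raise ValueError("bundle validation failed: " + "; ".join(problems))
    gt = None
    gt_path = path / "ground_truth.csv"
    if gt_path.exists():
        gt = [GroundTruthNeuron(**{**row, "site_id": int(row["site_id"])})
              for row in pd.read_csv(gt_path).to_dict("records")]
    cfg = None
    if manifest.get("config"):
        cfg = SimConfig(**manifest["config"])
    pupil = behav["pupil"].to_numpy()
    return Session(
        site_id=manifest["site_id"],
        frame_rate_hz=manifest["frame_rate_hz"],
        t=behav["time_s"].to_numpy(),
        run_speed=behav["run_speed_cmps"].to_numpy(),
        sound_db=behav["sound_db"].to_numpy(),
        visual_flow=behav["visual_flow"].to_numpy(),
        events=events,
        F=F,
        loop_type=manifest["loop_type"],
        pupil=None if np.all(np.isnan(pupil)) else pupil,
        ground_truth=gt,
        neuron_site=neuron_site,
        config=cfg,
    )


def add_dff(path: str | Path, dff: DffMatrix) -> None:
    """Store a ΔF/F matrix alongside the raw fluorescence and log the
    parameters used in the manifest."""
    path = Path(path)
    with h5py.File(path / "fluorescence.h5", "a") as h5:
        for name in ("dff", "dff_f0"):
            if name in h5:
                del h5[name]
        h5.create_dataset("dff", data=dff.dff)
        h5.create_dataset("dff_f0", data=dff.f0)
    mpath = path / "manifest.json"
    manifest = json.loads(mpath.read_text())
    manifest["dff_params"] = {
        "baseline_percentile": dff.baseline_percentile,
        "window_s": dff.window_s,
        "f0": "median of raw trace",
        "numerator": "raw F minus percentile baseline",
    }
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True))


def read_dff(path: str | Path) -> DffMatrix:
    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    with h5py.File(path / "fluorescence.h5", "r") as h5:
        if "dff" not in h5:
            raise ValueError("bundle has no dff dataset; run preprocessing first")
        dff = h5["dff"][:]
        f0 = h5["dff_f0"][:]
    p = manifest["dff_params"]
    return DffMatrix(dff=dff, fs=manifest["frame_rate_hz"], f0=f0,
                     baseline_percentile=p["baseline_percentile"],
                     window_s=p["window_s"])
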