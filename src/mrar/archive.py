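"""HDF5 archive format for acquisition runs.

One file per run.  Schema (version 1):

* root attrs: ``schema_version``, ``config`` (YAML of the acquisition config)
* ``/pulse_roles`` (byte strings), ``/fast_time_grid`` — shared by all
  measurements
* ``/channel_XX/alines`` — float32 [n_measurements, n_pulses, n_samples]
* ``/channel_XX/observation_times`` — float64 [n_measurements]

Ground truth travels in text sidecars: a CSV with the per-measurement truth
(channel, T, f_true, A_true) and a JSON block with the analytic coagulation
parameters.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .config import AcquisitionConfig
from .simulate import GroundTruth, MeasurementRecord, RunArchive

SCHEMA_VERSION = 1

__all__ = ["write_archive", "read_archive", "write_ground_truth", "SCHEMA_VERSION"]


def write_archive(archive: RunArchive, path: str | Path) -> Path:
    """Write a :class:`RunArchive` to an HDF5 container."""
    path = Path(path)
    cfg = archive.config
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["config"] = yaml.safe_dump(dataclasses.asdict(cfg), sort_keys=True)
        first = archive.records[archive.channel_ids[0]][0]
        f.create_dataset("pulse_roles", data=np.array(first.pulse_roles, dtype="S16"))
        f.create_dataset("fast_time_grid", data=first.fast_time_grid)
        for ch in archive.channel_ids:
            records = archive.records[ch]
            g = f.create_group(f"channel_{ch:02d}")
            g.create_dataset(
                "alines",
                data=np.stack([r.alines for r in records]).astype(np.float32),
                compression="gzip",
                compression_opts=1,
            )
            g.create_dataset(
                "observation_times", data=np.array([r.observation_time_T for r in records])
            )
    return path


def read_archive(path: str | Path) -> RunArchive:
    """Read an HDF5 archive back into memory."""
    path = Path(path)
    with h5py.File(path, "r") as f:
        version = int(f.attrs["schema_version"])
        if version != SCHEMA_VERSION:
            raise ValueError(f"unsupported archive schema version {version}")
        cfg = AcquisitionConfig(**yaml.safe_load(f.attrs["config"]))
        roles = np.array([r.decode() for r in f["pulse_roles"][()]])
        fast_time = f["fast_time_grid"][()]
        records: dict = {}
        for name in sorted(k for k in f.keys() if k.startswith("channel_")):
            ch = int(name.split("_")[1])
            alines = f[name]["alines"][()].astype(float)
            times = f[name]["observation_times"][()]
            records[ch] = [
                MeasurementRecord(ch, float(T), alines[m], roles, fast_time)
                for m, T in enumerate(times)
            ]
    return RunArchive(config=cfg, records=records)


def write_ground_truth(truth: GroundTruth, base_path: str | Path) -> tuple[Path, Path]:
    """Write ground-truth sidecars ``<base>_truth.csv`` and ``<base>_truth.json``."""
    base = Path(base_path)
    rows = []
    params = {}
    for ch in truth.channels:
        for T, fv, av in zip(ch.observation_times, ch.f_true, ch.amp_true):
            rows.append({"channel": ch.channel_id, "T_s": T, "f_true_Hz": fv, "A_true_m": av})
        params[str(ch.channel_id)] = ch.params.to_row() if ch.params is not None else None
    csv_path = base.with_name(base.stem + "_truth.csv")
    json_path = base.with_name(base.stem + "_truth.json")
    pd.DataFrame(rows).to_csv(csv_path, index=False)
    json_path.write_text(json.dumps(params, indent=2, sort_keys=True))
    return csv_path, json_path
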