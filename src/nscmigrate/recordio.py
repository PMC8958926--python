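"""Save and reload simulation records.

A record is written as two text files next to each other: a long-format
``trajectories.csv`` (step, agent_id, coordinates, on_wm,
arrived_site) and a ``record.json`` sidecar holding the config echo,
the per-step series and the per-agent arrays, so metrics can be
recomputed later exactly as during the run.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .engine import SimulationRecord

__all__ = ["save_record", "load_record"]

TRAJ_NAME = "trajectories.csv"
SIDECAR_NAME = "record.json"


def save_record(record: SimulationRecord, outdir) -> Path:
    """Write trajectories.csv + record.json into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    # %.17g guarantees the positions round-trip bit-exactly through text
    record.to_dataframe().to_csv(outdir / TRAJ_NAME, index=False,
                                 float_format="%.17g")
    side = {
        "config": record.config,
        "seed": int(record.seed),
        "pixel_size": float(record.pixel_size),
        "injection_center": record.injection_center.tolist(),
        "snapshot_steps": record.snapshot_steps.tolist(),
        "wm_count": record.wm_count.tolist(),
        "arrival_counts": record.arrival_counts.tolist(),
        "arrived_step": record.arrived_step.tolist(),
        "arrived_site": record.arrived_site.tolist(),
        "first_entry_step": record.first_entry_step.tolist(),
        "path_at_entry": np.where(np.isnan(record.path_at_entry), None,
                                  record.path_at_entry).tolist(),
        "path_length": record.path_length.tolist(),
        "speed_factor": record.speed_factor.tolist(),
        "sens_factor": record.sens_factor.tolist(),
    }
    with open(outdir / SIDECAR_NAME, "w") as fh:
        json.dump(side, fh)
    return outdir / TRAJ_NAME


def load_record(path) -> SimulationRecord:
    """Reload a record from ``trajectories.csv`` (sidecar alongside)."""
    path = Path(path)
    if path.is_dir():
        path = path / TRAJ_NAME
    sidecar = path.parent / SIDECAR_NAME
    if not sidecar.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar}")
    with open(sidecar) as fh:
        side = json.load(fh)
    traj = pd.read_csv(path, float_precision="round_trip")
    steps = np.asarray(side["snapshot_steps"], dtype=np.int64)
    n = int(traj["agent_id"].max()) + 1
    coords = [c for c in "xyz" if c in traj.columns]
    d = len(coords)
    snapshots = np.empty((len(steps), n, d))
    on_wm = np.zeros((len(steps), n), dtype=bool)
    by_step = {s: g for s, g in traj.groupby("step")}
    for k, s in enumerate(steps):
        g = by_step[s].sort_values("agent_id")
        snapshots[k] = g[coords].to_numpy()
        on_wm[k] = g["on_wm"].to_numpy().astype(bool)
    pae = np.asarray([[np.nan if v is None else v for v in row]
                      for row in side["path_at_entry"]], dtype=float)
    if pae.size == 0:
        pae = pae.reshape(n, 0)
    ac = np.asarray(side["arrival_counts"], dtype=np.int64)
    if ac.size == 0:
        ac = ac.reshape(len(side["wm_count"]), 0)
    fes = np.asarray(side["first_entry_step"], dtype=np.int64)
    if fes.size == 0:
        fes = fes.reshape(n, 0)
    return SimulationRecord(
        config=side["config"],
        seed=side["seed"],
        pixel_size=side["pixel_size"],
        injection_center=np.asarray(side["injection_center"], dtype=float),
        snapshot_steps=steps,
        snapshots=snapshots,
        on_wm_snapshots=on_wm,
        wm_count=np.asarray(side["wm_count"], dtype=np.int64),
        arrival_counts=ac,
        arrived_step=np.asarray(side["arrived_step"], dtype=np.int64),
        arrived_site=np.asarray(side["arrived_site"], dtype=np.int64),
        first_entry_step=fes,
        path_at_entry=pae,
        path_length=np.asarray(side["path_length"], dtype=float),
        speed_factor=np.asarray(side["speed_factor"], dtype=float),
        sens_factor=np.asarray(side["sens_factor"], dtype=float),
    )
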