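"""Readouts of a simulation record.

Three population readouts summarise a run: the distance travelled from
the injection site (straight-line displacement, micrometres), the
percentage of agents sitting on white-matter voxels, and the cumulative
percentage that have entered each tumor arrival region.  A separate
pair of helpers converts experimentally reported cluster / cell counts
at a tumor site into arrival percentages of the administered dose.

All functions are pure: they only read the record (plus the tissue or
chemo field they are asked to compare against), so recomputing metrics
from a saved record reproduces the originals exactly.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import field as _field

logger = logging.getLogger(__name__)

__all__ = [
    "distances_per_agent",
    "distance_from_injection",
    "percent_on_white_matter",
    "arrival_percentage",
    "shortest_path_agent",
    "arrival_percentage_from_clusters",
    "arrival_percentage_from_cells",
]


def distances_per_agent(record, injection_center=None) -> np.ndarray:
    """(S, N) straight-line distances from the injection site, in um."""
    center = np.asarray(
        record.injection_center if injection_center is None
        else injection_center, dtype=float)
    diff = record.snapshots - center
    return np.linalg.norm(diff, axis=-1) * record.pixel_size


def distance_from_injection(record, injection_center=None) -> pd.DataFrame:
    """Box-plot summary of per-agent displacement per snapshot.

    Columns: step, time_days, q1/median/q3, whisker_low/high (1.5 IQR
    rule), n_outliers, mean and max, all distances in micrometres.
    """
    if record.snapshots.shape[0] == 0:
        raise ValueError("record holds no snapshots")
    dist = distances_per_agent(record, injection_center)
    q1, med, q3 = np.percentile(dist, [25, 50, 75], axis=1)
    iqr = q3 - q1
    lo_f, hi_f = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    rows = {
        "step": record.snapshot_steps,
        "time_days": record.snapshot_steps * record.dt,
        "q1": q1,
        "median": med,
        "q3": q3,
        "whisker_low": np.maximum(dist.min(axis=1), lo_f),
        "whisker_high": np.minimum(dist.max(axis=1), hi_f),
        "n_outliers": ((dist < lo_f[:, None]) | (dist > hi_f[:, None])).sum(axis=1),
        "mean": dist.mean(axis=1),
        "max": dist.max(axis=1),
    }
    return pd.DataFrame(rows)


def percent_on_white_matter(record, tissue: _field.TissueField | None = None
                            ) -> pd.DataFrame:
    """Percentage of agents on white-matter voxels per snapshot.

    Arrived agents count with the rest of the population.  When a
    tissue field is given the classification is recomputed from the
    snapshot positions (nearest voxel); otherwise the flags stored in
    the record are used.
    """
    if tissue is not None:
        on_wm = np.stack([
            _field.lookup(tissue, record.snapshots[k])[0]
            for k in range(record.snapshots.shape[0])])
    else:
        on_wm = record.on_wm_snapshots
    pct = 100.0 * on_wm.sum(axis=1) / record.n_agents
    return pd.DataFrame({
        "step": record.snapshot_steps,
        "time_days": record.snapshot_steps * record.dt,
        "pct_on_wm": pct,
    })


def arrival_percentage(record, cf=None) -> pd.DataFrame:
    """Cumulative arrival percentage per tumor site, per step.

    An agent counts from its first entry into the site's arrival
    region, whether or not it was absorbed there.
    """
    n_sites = record.arrival_counts.shape[1]
    if n_sites == 0:
        logger.warning("record has no tumor sites; empty arrival table")
        return pd.DataFrame(columns=["step", "time_days", "site", "pct_arrived"])
    steps = np.arange(record.arrival_counts.shape[0])
    frames = []
    for s in range(n_sites):
        frames.append(pd.DataFrame({
            "step": steps,
            "time_days": steps * record.dt,
            "site": s,
            "pct_arrived": 100.0 * record.arrival_counts[:, s] / record.n_agents,
        }))
    return pd.concat(frames, ignore_index=True)


def shortest_path_agent(record, site: int = 0):
    """Arrived agent with the smallest cumulative path at first entry.

    Returns ``(agent_id, trajectory)`` with the (S, d) snapshot
    trajectory of that agent; ties break toward the lower agent id.
    ``(None, empty)`` with a warning if nothing arrived at the site.
    """
    entries = record.first_entry_step[:, site]
    arrived = entries >= 0
    if not np.any(arrived):
        logger.warning("no agent arrived at site %d", site)
        return None, np.empty((0, record.snapshots.shape[2]))
    paths = np.where(arrived, record.path_at_entry[:, site], np.inf)
    agent = int(np.argmin(paths))  # argmin takes the first minimum: lower id
    return agent, record.snapshots[:, agent, :]


def arrival_percentage_from_clusters(clusters: float, cells_per_cluster: float,
                                     dose: float,
                                     clusters_sd: float | None = None):
    """Convert an observed NSC cluster count into an arrival percentage.

    ``100 * clusters * cells_per_cluster / dose`` rounded to two
    decimals; an uncertainty on the cluster count propagates linearly
    and is returned alongside.
    """
    if dose <= 0:
        raise ValueError("dose must be positive")
    if clusters < 0 or cells_per_cluster <= 0:
        raise ValueError("counts must be positive")
    pct = round(100.0 * clusters * cells_per_cluster / dose, 2)
    if clusters_sd is None:
        return pct
    return pct, round(100.0 * clusters_sd * cells_per_cluster / dose, 2)


def arrival_percentage_from_cells(cells: float, dose: float,
                                  cells_sd: float | None = None):
    """Convert an observed NSC cell count into an arrival percentage."""
    if dose <= 0:
        raise ValueError("dose must be positive")
    if cells < 0:
        raise ValueError("cells must be non-negative")
    pct = round(100.0 * cells / dose, 2)
    if cells_sd is None:
        return pct
    return pct, round(100.0 * cells_sd / dose, 2)


def summary(record, cf=None) -> dict:
    """Compact JSON-ready end-of-run summary."""
    final_arrivals = (record.first_entry_step >= 0).sum(axis=0)
    dist = distances_per_agent(record)[-1]
    return {
        "n_agents": int(record.n_agents),
        "n_steps": int(record.n_steps),
        "final_pct_on_wm": float(100.0 * record.wm_count[-1] / record.n_agents),
        "final_pct_arrived_per_site": [
            float(100.0 * c / record.n_agents) for c in final_arrivals],
        "median_distance_um": float(np.median(dist)),
        "max_distance_um": float(dist.max()),
        "median_path_length_um": float(np.median(record.path_length)),
    }
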