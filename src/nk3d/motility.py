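"""Per-cell motility metrics and per-FOV / per-sample aggregation.

Three per-cell statistics, all evaluated in the x–y imaging plane:

* **motile** — a cell is motile if it moves away from its starting point by
  at least 13 µm at any time within a 5 min window (inclusive threshold).
* **speed** — the diagonal of the planar bounding box of the trajectory,
  divided by the 5 min measurement time (µm/min).
* **persistence** — the mean cosine of the turning angles between
  consecutive displacements; 0 is random motion, 1 is ballistic.
  Displacements shorter than ``min_step`` are dropped first, since the
  turning angle of a near-zero step is dominated by sub-pixel jitter.

Aggregation follows the study design: the motile fraction is computed per
field of view, and a sample is summarised as the mean ± standard error
over its fields of view.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tracking import Trajectory

__all__ = [
    "MOTILE_THRESHOLD_UM",
    "MOTILE_WINDOW_MIN",
    "classify_motile",
    "speed",
    "persistence",
    "compute_metrics",
    "summarize",
]

#: Displacement threshold of the motile rule (µm, inclusive).
MOTILE_THRESHOLD_UM = 13.0
#: Measurement window of the motile rule and of the speed metric (minutes).
MOTILE_WINDOW_MIN = 5.0


def _window_slice(traj: Trajectory, window_min: float) -> slice | None:
    """Frames within ``window_min`` minutes of the trajectory start.

    Returns None when the trajectory does not cover the window (half a
    frame of tolerance on the end point).
    """
    t = np.asarray(traj.t_s, dtype=float)
    if len(t) < 2:
        return None
    rel = t - t[0]
    dt = np.min(np.diff(t))
    if rel[-1] < window_min * 60.0 - dt / 2.0:
        return None
    n_in = int(np.searchsorted(rel, window_min * 60.0 + dt / 2.0, side="right"))
    return slice(0, n_in)


def classify_motile(
    traj: Trajectory,
    threshold: float = MOTILE_THRESHOLD_UM,
    window: float = MOTILE_WINDOW_MIN,
) -> bool | None:
    """True iff the cell displaces >= ``threshold`` µm (planar) from its
    start at any frame within ``window`` minutes.

    Returns None when the trajectory is shorter than the window; such cells
    are excluded from the motile-fraction denominator.
    """
    sl = _window_slice(traj, window)
    if sl is None:
        return None
    pos = traj.positions()[sl, :2]
    disp = np.linalg.norm(pos - pos[0], axis=1)
    return bool(disp.max() >= threshold)


def speed(traj: Trajectory, window: float = MOTILE_WINDOW_MIN) -> float | None:
    """Planar bounding-box diagonal divided by the measurement time (µm/min).

    Returns None for single-point trajectories.
    """
    pos = traj.positions()[:, :2]
    if pos.shape[0] < 2:
        return None
    span = pos.max(axis=0) - pos.min(axis=0)
    return float(math.hypot(span[0], span[1]) / window)


def persistence(traj: Trajectory, min_step: float = 0.2) -> float | None:
    """Mean cosine of turning angles between consecutive planar steps.

    Steps shorter than ``min_step`` µm are discarded before pairing; with
    fewer than two usable steps the metric is undefined (None).
    """
    pos = traj.positions()[:, :2]
    if pos.shape[0] < 3:
        return None
    steps = np.diff(pos, axis=0)
    norms = np.linalg.norm(steps, axis=1)
    steps = steps[norms >= min_step]
    if steps.shape[0] < 2:
        return None
    # cos of heading differences: exact (+1/-1) for straight/reversing steps
    headings = np.arctan2(steps[:, 1], steps[:, 0])
    return float(np.cos(np.diff(headings)).mean())


def compute_metrics(
    trajectories: list[Trajectory],
    threshold: float = MOTILE_THRESHOLD_UM,
    window: float = MOTILE_WINDOW_MIN,
    min_step: float = 0.2,
    fov: str | int = 0,
    sample: str = "sample",
) -> pd.DataFrame:
    """Per-cell metric table for the NK trajectories of one field of view."""
    rows = []
    for traj in trajectories:
        if traj.cell_class != "NK":
            continue
        rows.append({
            "sample": sample,
            "fov": fov,
            "cell_id": traj.cell_id,
            "motile": classify_motile(traj, threshold, window),
            "speed": speed(traj, window),
            "persistence": persistence(traj, min_step),
            "n_steps_used": max(len(traj) - 1, 0),
        })
    return pd.DataFrame(rows, columns=[
        "sample", "fov", "cell_id", "motile", "speed", "persistence",
        "n_steps_used",
    ])


def _mean_se(values: np.ndarray) -> tuple[float, float]:
    values = values[~np.isnan(values)]
    if values.size == 0:
        return float("nan"), float("nan")
    m = float(values.mean())
    se = float(values.std(ddof=1) / math.sqrt(values.size)) if values.size > 1 \
        else float("nan")
    return m, se


def summarize(metrics: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Aggregate per-cell metrics into per-FOV and per-sample summaries.

    The motile fraction of a FOV is motile / (motile + nonmotile), with
    cells of undetermined motility (trajectory shorter than the window)
    excluded from the denominator.  Sample-level means carry a standard
    error over FOVs (NaN for a single FOV).  Speed and persistence are
    averaged over motile cells per FOV, then over FOVs.
    """
    fov_rows = []
    for (sample, fov), grp in metrics.groupby(["sample", "fov"]):
        determined = grp[grp["motile"].notna()]
        if len(determined) == 0:
            warnings.warn(f"FOV {fov!r} has no classifiable cells; excluded",
                          stacklevel=2)
            continue
        motile = determined[determined["motile"].astype(bool)]
        fov_rows.append({
            "sample": sample,
            "fov": fov,
            "n_cells": len(determined),
            "n_motile": len(motile),
            "motile_fraction": len(motile) / len(determined),
            "speed_motile": motile["speed"].astype(float).mean()
                if len(motile) else float("nan"),
            "persistence_motile": motile["persistence"].astype(float).mean()
                if len(motile) else float("nan"),
        })
    per_fov = pd.DataFrame(fov_rows)
    sample_rows = []
    for sample, grp in per_fov.groupby("sample"):
        frac_m, frac_se = _mean_se(grp["motile_fraction"].to_numpy(float))
        sp_m, sp_se = _mean_se(grp["speed_motile"].to_numpy(float))
        pe_m, pe_se = _mean_se(grp["persistence_motile"].to_numpy(float))
        sample_rows.append({
            "sample": sample,
            "n_fov": len(grp),
            "motile_fraction_mean": frac_m,
            "motile_fraction_se": frac_se,
            "speed_mean": sp_m,
            "speed_se": sp_se,
            "persistence_mean": pe_m,
            "persistence_se": pe_se,
        })
    return {"per_fov": per_fov, "per_sample": pd.DataFrame(sample_rows)}
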