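"""Frame-to-frame linking of detections into trajectories.

Detections in consecutive frames are linked by an exact minimum-total-cost
bipartite assignment (Hungarian algorithm) within each cell class, with
cost d_xy^2 + z_weight * d_z^2.  The z term is what disambiguates two cells
whose paths appear to cross in the projection but sit at different depths.
Links whose planar displacement exceeds ``max_link_distance`` are
forbidden; unmatched detections open new trajectories and trajectories end
as soon as they go unmatched (no gap closing).

To make the result independent of detection order, detections are brought
into a canonical (x, y, z) order per frame before matching.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .detection import Detection

__all__ = ["Trajectory", "link"]

_FORBIDDEN = 1e30


@dataclass
class Trajectory:
    """Time-ordered positions of one tracked cell (µm; strictly increasing frames)."""

    cell_id: int
    cell_class: str
    frames: list[int] = field(default_factory=list)
    t_s: list[float] = field(default_factory=list)
    x: list[float] = field(default_factory=list)
    y: list[float] = field(default_factory=list)
    z: list[float] = field(default_factory=list)
    detections: list[Detection] = field(default_factory=list)
    viability: list[str] = field(default_factory=list)

    def append(self, det: Detection, t_s: float) -> None:
        self.frames.append(det.frame)
        self.t_s.append(t_s)
        self.x.append(det.centroid_x)
        self.y.append(det.centroid_y)
        self.z.append(det.z_est)
        self.detections.append(det)
        self.viability.append(det.viability)

    def __len__(self) -> int:
        return len(self.frames)

    def positions(self) -> np.ndarray:
        """(n, 3) array of x, y, z in µm."""
        return np.column_stack([self.x, self.y, self.z])


def _canonical(dets: list[Detection]) -> list[Detection]:
    return sorted(dets, key=lambda d: (d.centroid_x, d.centroid_y, d.z_est))


def link(
    frames: list[list[Detection]],
    max_link_distance: float = 15.0,
    z_weight: float = 1.0,
    frame_interval: float = 30.0,
) -> list[Trajectory]:
    """Link per-frame detection lists into trajectories.

    ``frames[t]`` holds the detections of frame t (frame indices are taken
    as consecutive).  Linking is restricted to detections of the same cell
    class; 'ambiguous' detections are never linked.  Returns trajectories
    sorted by cell_id (creation order).
    """
    trajectories: list[Trajectory] = []
    active: list[Trajectory] = []
    next_id = 0
    if not frames:
        return []

    for t, dets in enumerate(frames):
        dets = _canonical([d for d in dets if d.cell_class != "ambiguous"])
        t_sec = t * frame_interval
        matched_new: dict[int, Trajectory] = {}
        if active and dets:
            classes = sorted({d.cell_class for d in dets}
                             & {tr.cell_class for tr in active})
            for cls in classes:
                tr_idx = [i for i, tr in enumerate(active) if tr.cell_class == cls]
                de_idx = [j for j, d in enumerate(dets) if d.cell_class == cls]
                last = np.array([[active[i].x[-1], active[i].y[-1], active[i].z[-1]]
                                 for i in tr_idx])
                cur = np.array([[dets[j].centroid_x, dets[j].centroid_y,
                                 dets[j].z_est] for j in de_idx])
                dxy2 = ((last[:, None, :2] - cur[None, :, :2]) ** 2).sum(-1)
                dz2 = (last[:, None, 2] - cur[None, :, 2]) ** 2
                cost = dxy2 + z_weight * dz2
                cost[dxy2 > max_link_distance ** 2] = _FORBIDDEN
                rows, cols = linear_sum_assignment(cost)
                for r, cidx in zip(rows, cols):
                    if cost[r, cidx] >= _FORBIDDEN:
                        continue
                    matched_new[de_idx[cidx]] = active[tr_idx[r]]
        still_active: list[Trajectory] = []
        for j, det in enumerate(dets):
            tr = matched_new.get(j)
            if tr is None:
                tr = Trajectory(cell_id=next_id, cell_class=det.cell_class)
                next_id += 1
                trajectories.append(tr)
            tr.append(det, t_sec)
            still_active.append(tr)
        active = still_active

    return trajectories
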