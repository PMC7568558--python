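"""Reading and writing the pipeline's file formats.

Tables travel as CSV (one row per cell per frame for trajectories and
ground truth; one row per detection for detections); image stacks as
multi-page TIFF with a YAML sidecar holding the calibration
(pixel_size_um, z_step_um, frame_interval_s).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .detection import Detection
from .errors import MissingMetadataError
from .projection import ImageStack, ProjectionFrame
from .tracking import Trajectory

__all__ = [
    "write_stack", "read_stack",
    "write_trajectories", "read_trajectories",
    "write_detections", "read_detections",
    "write_projection", "read_projection",
]

_SIDECAR_SUFFIX = ".yaml"


def write_stack(path: str | Path, stack: ImageStack) -> None:
    """Write a (t, z, y, x) stack as multi-page TIFF plus a YAML sidecar."""
    path = Path(path)
    tifffile.imwrite(path, stack.data, metadata={"axes": "TZYX"})
    sidecar = {
        "pixel_size_um": float(stack.pixel_size),
        "z_step_um": float(stack.z_step),
        "frame_interval_s": float(stack.frame_interval),
        "shape_tzyx": [int(s) for s in stack.data.shape],
    }
    path.with_suffix(path.suffix + _SIDECAR_SUFFIX).write_text(
        yaml.safe_dump(sidecar))


def read_stack(path: str | Path) -> ImageStack:
    path = Path(path)
    sidecar_path = path.with_suffix(path.suffix + _SIDECAR_SUFFIX)
    if not sidecar_path.exists():
        raise MissingMetadataError(f"missing calibration sidecar {sidecar_path}")
    meta = yaml.safe_load(sidecar_path.read_text())
    data = tifffile.imread(path)
    data = np.asarray(data).reshape(meta["shape_tzyx"])
    return ImageStack(
        data=data,
        pixel_size=meta["pixel_size_um"],
        z_step=meta["z_step_um"],
        frame_interval=meta["frame_interval_s"],
    )


def write_projection(path_prefix: str | Path, frame: ProjectionFrame) -> None:
    """Write min/max projections as TIFF and the z-map as 16-bit TIFF."""
    prefix = Path(path_prefix)
    tifffile.imwrite(prefix.with_name(prefix.name + "_min.tif"),
                     frame.min_projection)
    tifffile.imwrite(prefix.with_name(prefix.name + "_max.tif"),
                     frame.max_projection)
    tifffile.imwrite(prefix.with_name(prefix.name + "_zmap.tif"),
                     np.asarray(frame.z_map, dtype=np.uint16))


def read_projection(path_prefix: str | Path, t_index: int = 0,
                    pixel_size: float | None = None,
                    z_step: float | None = None) -> ProjectionFrame:
    prefix = Path(path_prefix)
    return ProjectionFrame(
        min_projection=tifffile.imread(prefix.with_name(prefix.name + "_min.tif")),
        max_projection=tifffile.imread(prefix.with_name(prefix.name + "_max.tif")),
        z_map=tifffile.imread(prefix.with_name(prefix.name + "_zmap.tif")),
        t_index=t_index, pixel_size=pixel_size, z_step=z_step,
    )


def write_trajectories(path: str | Path, trajectories: list[Trajectory]) -> None:
    rows = []
    for tr in trajectories:
        for i in range(len(tr)):
            rows.append({
                "cell_id": tr.cell_id,
                "class": tr.cell_class,
                "frame": tr.frames[i],
                "t_s": tr.t_s[i],
                "x_um": tr.x[i],
                "y_um": tr.y[i],
                "z_um": tr.z[i],
                "alive": tr.viability[i] != "dead",
            })
    pd.DataFrame(rows, columns=["cell_id", "class", "frame", "t_s",
                                "x_um", "y_um", "z_um", "alive"]).to_csv(
        path, index=False)


def read_trajectories(path: str | Path) -> list[Trajectory]:
    df = pd.read_csv(path)
    trajectories = []
    for cell_id, grp in df.groupby("cell_id", sort=True):
        grp = grp.sort_values("frame")
        tr = Trajectory(cell_id=int(cell_id), cell_class=str(grp["class"].iloc[0]))
        tr.frames = [int(v) for v in grp["frame"]]
        tr.t_s = [float(v) for v in grp["t_s"]]
        tr.x = [float(v) for v in grp["x_um"]]
        tr.y = [float(v) for v in grp["y_um"]]
        tr.z = [float(v) for v in grp["z_um"]]
        tr.viability = ["live" if bool(a) else "dead" for a in grp["alive"]]
        trajectories.append(tr)
    return trajectories


def write_detections(path: str | Path, detections: list[Detection],
                     frame_interval: float = 30.0) -> None:
    rows = [{
        "frame": d.frame,
        "t_s": d.frame * frame_interval,
        "x_um": d.centroid_x,
        "y_um": d.centroid_y,
        "z_um": d.z_est,
        "diameter_um": d.equiv_diameter,
        "class": d.cell_class,
        "viability": d.viability,
        "contrast": d.mean_contrast,
        "eccentricity": d.eccentricity,
    } for d in detections]
    pd.DataFrame(rows, columns=["frame", "t_s", "x_um", "y_um", "z_um",
                                "diameter_um", "class", "viability",
                                "contrast", "eccentricity"]).to_csv(
        path, index=False)


def read_detections(path: str | Path) -> list[list[Detection]]:
    """Read detections grouped per frame (list index = frame index)."""
    df = pd.read_csv(path)
    if len(df) == 0:
        return []
    n_frames = int(df["frame"].max()) + 1
    frames: list[list[Detection]] = [[] for _ in range(n_frames)]
    for _, row in df.iterrows():
        frames[int(row["frame"])].append(Detection(
            frame=int(row["frame"]),
            centroid_x=float(row["x_um"]),
            centroid_y=float(row["y_um"]),
            z_est=float(row["z_um"]),
            equiv_diameter=float(row["diameter_um"]),
            cell_class=str(row["class"]),
            viability=str(row["viability"]),
            mean_contrast=float(row["contrast"]),
            eccentricity=float(row.get("eccentricity", 0.0)),
        ))
    return frames
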