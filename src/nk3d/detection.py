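"""Cell detection in projection frames and K562 viability classification.

Cells appear as connected dark regions in the minimum intensity
projection.  Detection thresholds the projection at ``c`` robust standard
deviations below the background, labels connected components, and applies
the study's size rules: objects with an equivalent diameter below 4 µm are
discarded as cell fragments, objects larger than 14 µm (strictly) are K562
targets, and everything in between is an NK cell.  The axial position is
read off the z-map under the object mask.

K562 viability is classified from appearance dynamics along a track: a
live target is round and wiggles with a 1–2 µm amplitude; death is called
at the first frame where the wiggle ceases *and* the bright-field contrast
or shape changes persistently.  Transient shape changes with recovery do
not count — death is irreversible, so the transition is forced to happen at
most once.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from skimage import measure

from .errors import MissingMetadataError
from .projection import ProjectionFrame

__all__ = [
    "Detection",
    "ViabilityCall",
    "estimate_background",
    "detect_cells",
    "classify_by_size",
    "classify_viability",
    "MIN_NK_DIAMETER_UM",
    "MIN_K562_DIAMETER_UM",
]

#: Objects below this equivalent diameter are discarded as cell fragments.
MIN_NK_DIAMETER_UM = 4.0
#: Objects strictly larger than this are classed as K562 targets.
MIN_K562_DIAMETER_UM = 14.0


@dataclass
class Detection:
    """One detected cell in one projection frame (coordinates in µm)."""

    frame: int
    centroid_x: float
    centroid_y: float
    z_est: float
    equiv_diameter: float
    cell_class: str               # 'NK' | 'K562' | 'ambiguous'
    viability: str = "not_applicable"   # 'live' | 'dead' | 'not_applicable'
    mean_contrast: float = 0.0
    eccentricity: float = 0.0


@dataclass
class ViabilityCall:
    """Outcome of viability classification along one K562 track."""

    series: list[str]             # 'live'/'dead' per frame of the track
    death_frame: int | None       # track-local index of the first dead frame
    indeterminate: bool = False   # track too short to classify


def estimate_background(min_projection: np.ndarray) -> tuple[float, float]:
    """Robust (median, MAD-based sd) background statistics of a projection.

    Cells cover a small area fraction, so the median and the scaled median
    absolute deviation of the projection estimate the cell-free background.
    """
    med = float(np.median(min_projection))
    mad = float(np.median(np.abs(min_projection - med)))
    return med, 1.4826 * mad


def classify_by_size(equiv_diameter_um: float,
                     ambiguous_above_um: float | None = None) -> str | None:
    """Apply the size rules: None (fragment), 'NK', 'K562' or 'ambiguous'.

    The 4 µm bound is inclusive (a 4.0 µm object is an NK cell); the 14 µm
    bound is strict (a 14.0 µm object is still an NK cell, only *larger*
    objects are K562).
    """
    d = equiv_diameter_um
    if d < MIN_NK_DIAMETER_UM:
        return None
    if ambiguous_above_um is not None and d > ambiguous_above_um:
        return "ambiguous"
    if d > MIN_K562_DIAMETER_UM:
        return "K562"
    return "NK"


def detect_cells(
    frame: ProjectionFrame,
    pixel_size: float | None = None,
    z_step: float | None = None,
    background_stats: tuple[float, float] | None = None,
    c: float = 4.0,
    ambiguous_above_um: float = 30.0,
) -> list[Detection]:
    """Detect cells in one projection frame.

    ``background_stats`` is (mean, sd) of the cell-free background of the
    minimum projection; when omitted it is estimated robustly from the
    frame itself.  Objects are connected regions darker than
    ``mean - c * sd``.  Very large blobs (above ``ambiguous_above_um``,
    typically merged cells) are flagged ``'ambiguous'`` so they can be
    excluded from counts.
    """
    pixel_size = pixel_size if pixel_size is not None else frame.pixel_size
    z_step = z_step if z_step is not None else frame.z_step
    if pixel_size is None or z_step is None:
        raise MissingMetadataError(
            "pixel_size and z_step are required to calibrate detections"
        )
    minp = np.asarray(frame.min_projection)
    if background_stats is None:
        background_stats = estimate_background(minp)
    bg_mean, bg_sd = background_stats
    mask = minp < bg_mean - c * bg_sd
    labels = measure.label(mask, connectivity=2)
    detections: list[Detection] = []
    for region in measure.regionprops(labels, intensity_image=minp):
        d_um = 2.0 * math.sqrt(region.area / math.pi) * pixel_size
        cls = classify_by_size(d_um, ambiguous_above_um)
        if cls is None:
            continue
        cy, cx = region.centroid
        rr, cc = region.coords[:, 0], region.coords[:, 1]
        z_idx = float(np.median(np.asarray(frame.z_map)[rr, cc]))
        contrast = (bg_mean - float(region.intensity_mean)) / bg_mean
        detections.append(Detection(
            frame=frame.t_index,
            centroid_x=cx * pixel_size,
            centroid_y=cy * pixel_size,
            z_est=z_idx * z_step,
            equiv_diameter=d_um,
            cell_class=cls,
            viability="live" if cls == "K562" else "not_applicable",
            mean_contrast=contrast,
            eccentricity=float(region.eccentricity),
        ))
    return detections


def _trailing_wiggle(track: Sequence[Detection], i: int, window: int) -> float:
    """RMS frame-to-frame planar displacement over the trailing window."""
    pts = np.array([(d.centroid_x, d.centroid_y)
                    for d in track[i - window + 1: i + 1]])
    steps = np.diff(pts, axis=0)
    return float(np.sqrt(np.mean(np.sum(steps ** 2, axis=1))))


def classify_viability(
    track: Sequence[Detection],
    window: int = 10,
    wiggle_min: float = 0.5,
    c_contrast: float = 0.15,
    c_shape: float = 0.2,
) -> ViabilityCall:
    """Classify a K562 track as live or dead and locate the death frame.

    Baseline contrast and eccentricity are averaged over the first
    ``window`` frames.  The cell is called dead at the first frame whose
    trailing ``window`` frames show an RMS wiggle below ``wiggle_min`` µm
    *and* either a relative contrast change above ``c_contrast`` or an
    eccentricity increase above ``c_shape`` versus baseline.  Once dead,
    dead forever.  Tracks shorter than the window are reported live with
    ``indeterminate=True``.
    """
    n = len(track)
    if n < window:
        return ViabilityCall(series=["live"] * n, death_frame=None,
                             indeterminate=True)
    base_contrast = float(np.mean([d.mean_contrast for d in track[:window]]))
    base_ecc = float(np.mean([d.eccentricity for d in track[:window]]))
    series = ["live"] * n
    death_frame: int | None = None
    for i in range(window - 1, n):
        win = track[i - window + 1: i + 1]
        wiggle = _trailing_wiggle(track, i, window)
        contrast = float(np.mean([d.mean_contrast for d in win]))
        ecc = float(np.mean([d.eccentricity for d in win]))
        rel_contrast = abs(contrast - base_contrast) / abs(base_contrast) \
            if base_contrast != 0 else 0.0
        if wiggle < wiggle_min and (rel_contrast > c_contrast
                                    or ecc - base_ecc > c_shape):
            death_frame = i
            break
    if death_frame is not None:
        for j in range(death_frame, n):
            series[j] = "dead"
    return ViabilityCall(series=series, death_frame=death_frame)
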