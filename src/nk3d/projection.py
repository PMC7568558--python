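"""Minimum/maximum intensity projection of bright-field z-stacks.

Cells embedded in a thick gel and imaged in bright field appear as dark
blobs in the minimum intensity projection along z.  Alongside the two
projections we keep a *z-map*: for every (y, x) pixel, the z-plane index at
which the minimum was attained.  The z-map provides an estimate of each
cell's axial position and is what lets the tracker tell two cells apart
when their paths appear to cross in the projection.

The projector is streaming: it consumes one z-plane at a time and never
needs the full stack in memory, mirroring acquisition software that
projects on the fly instead of storing every plane.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np

from .errors import InvalidConfigError

__all__ = ["ImageStack", "ProjectionFrame", "MinMaxProjector", "project"]


@dataclass
class ImageStack:
    """Calibrated 4-D intensity grid for one field of view.

    Parameters
    ----------
    data
        Array of shape (t, z, y, x); intensities must be nonnegative.
    pixel_size
        Lateral calibration in µm/pixel.
    z_step
        Axial plane spacing in µm.
    frame_interval
        Time between frames in seconds.
    """

    data: np.ndarray
    pixel_size: float
    z_step: float
    frame_interval: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise InvalidConfigError(
                f"stack must be 4-D (t, z, y, x), got shape {self.data.shape}"
            )
        if min(self.data.shape) < 1:
            raise InvalidConfigError("all stack dimensions must be >= 1")
        for name in ("pixel_size", "z_step", "frame_interval"):
            if getattr(self, name) is None or getattr(self, name) <= 0:
                raise InvalidConfigError(f"{name} must be > 0")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_planes(self) -> int:
        return self.data.shape[1]

    def iter_planes(self, t: int) -> Iterator[np.ndarray]:
        """Yield the z-planes of frame ``t`` one at a time."""
        for z in range(self.n_planes):
            yield self.data[t, z]


@dataclass
class ProjectionFrame:
    """Per-timepoint min/max projections plus the z-index map of the minimum."""

    min_projection: np.ndarray
    max_projection: np.ndarray
    z_map: np.ndarray
    t_index: int
    pixel_size: float | None = None
    z_step: float | None = None


class MinMaxProjector:
    """Streaming min/max projector over z-planes.

    Feed planes in z order with :meth:`add_plane`; at any point the running
    projections are available.  Ties in the minimum are broken toward the
    lowest z index (the first plane attaining the value wins), which makes
    the z-map deterministic and independent of revisiting planes.
    """

    def __init__(self) -> None:
        self._min: np.ndarray | None = None
        self._max: np.ndarray | None = None
        self._zmap: np.ndarray | None = None
        self._z = 0

    def add_plane(self, plane: np.ndarray) -> None:
        plane = np.asarray(plane)
        if self._min is None:
            self._min = plane.copy()
            self._max = plane.copy()
            self._zmap = np.zeros(plane.shape, dtype=np.uint16)
        else:
            better = plane < self._min  # strict: first minimum keeps its z
            self._min[better] = plane[better]
            self._zmap[better] = self._z
            np.maximum(self._max, plane, out=self._max)
        self._z += 1

    @property
    def n_planes_seen(self) -> int:
        return self._z

    def result(self, t_index: int = 0, pixel_size: float | None = None,
               z_step: float | None = None) -> ProjectionFrame:
        if self._min is None:
            raise InvalidConfigError("no planes were added")
        return ProjectionFrame(
            min_projection=self._min,
            max_projection=self._max,
            z_map=self._zmap,
            t_index=t_index,
            pixel_size=pixel_size,
            z_step=z_step,
        )


def project(stack: ImageStack, t: int) -> ProjectionFrame:
    """Project frame ``t`` of a stack along z.

    Raises ``IndexError`` if ``t`` is out of range.  Internally streams
    plane by plane through :class:`MinMaxProjector`.
    """
    if not 0 <= t < stack.n_frames:
        raise IndexError(f"frame index {t} out of range [0, {stack.n_frames})")
    return project_planes(
        stack.iter_planes(t), t_index=t,
        pixel_size=stack.pixel_size, z_step=stack.z_step,
    )


def project_planes(planes: Iterable[np.ndarray], t_index: int = 0,
                   pixel_size: float | None = None,
                   z_step: float | None = None) -> ProjectionFrame:
    """Project an iterable of z-planes without materialising a stack."""
    proj = MinMaxProjector()
    for plane in planes:
        proj.add_plane(plane)
    return proj.result(t_index=t_index, pixel_size=pixel_size, z_step=z_step)
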