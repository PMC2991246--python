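"""Shared data containers for the transport-quantification pipeline.

Conventions used throughout the package:

* image arrays are indexed ``(time, row, column)`` for movies and
  ``(z, y, x)`` for confocal stacks, all intensities nonnegative;
* positions along a traced path are in micrometres with position 0 at the
  soma end, so anterograde movement has positive velocity;
* times are in seconds, frequencies in events per minute;
* pixel coordinates are 0-based; rectangular regions are half-open.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Movie",
    "RegionOfInterest",
    "DendritePath",
    "ZStack",
]


@dataclass
class Movie:
    """A calibrated grayscale time-lapse movie.

    Parameters
    ----------
    frames
        3-D array ``(time, row, column)`` of nonnegative intensities.
    pixel_size_um
        Lateral calibration in micrometres per pixel.
    frame_interval_s
        Time between consecutive frames in seconds (0.5 s in the
        acquisitions this pipeline models).
    """

    frames: np.ndarray
    pixel_size_um: float
    frame_interval_s: float = 0.5

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError("movie frames must be a (time, row, col) array with >=1 frame")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    @property
    def duration_s(self) -> float:
        return self.n_frames * self.frame_interval_s


@dataclass(frozen=True)
class RegionOfInterest:
    """Rectangular pixel region ``[row0, row1) x [col0, col1)``, 0-based."""

    row0: int
    col0: int
    row1: int
    col1: int

    def __post_init__(self) -> None:
        if self.row1 <= self.row0 or self.col1 <= self.col0:
            raise ValueError("ROI must be nonempty (row1 > row0 and col1 > col0)")
        if self.row0 < 0 or self.col0 < 0:
            raise ValueError("ROI indices must be nonnegative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.row1 - self.row0, self.col1 - self.col0

    def contained_in(self, frame_shape: tuple[int, int], margin: int = 0) -> bool:
        """True if the ROI stays inside ``frame_shape`` under every
        displacement of at most ``margin`` pixels."""
        rows, cols = frame_shape
        return (
            self.row0 - margin >= 0
            and self.col0 - margin >= 0
            and self.row1 + margin <= rows
            and self.col1 + margin <= cols
        )


@dataclass
class DendritePath:
    """A user-traced dendrite/cilium path as an ordered polyline.

    ``vertices`` are fractional ``(row, col)`` pixel coordinates; vertex 0
    is the soma end and the last vertex the ciliary-tip end.
    ``junction_arclength_um`` optionally marks the boundary between the
    middle and distal ciliary segments for two-segment IFT analysis.
    """

    vertices: np.ndarray
    junction_arclength_um: float | None = None

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2 or len(self.vertices) < 2:
            raise ValueError("path needs >=2 (row, col) vertices")
        seg = np.diff(self.vertices, axis=0)
        if np.any(np.hypot(seg[:, 0], seg[:, 1]) <= 0):
            raise ValueError("cumulative arclength must be strictly increasing")

    def arclengths_px(self) -> np.ndarray:
        """Cumulative arclength of each vertex, in pixels."""
        seg = np.diff(self.vertices, axis=0)
        return np.concatenate([[0.0], np.cumsum(np.hypot(seg[:, 0], seg[:, 1]))])

    def length_px(self) -> float:
        return float(self.arclengths_px()[-1])

    def length_um(self, pixel_size_um: float) -> float:
        return self.length_px() * pixel_size_um

    def reversed(self) -> "DendritePath":
        j = self.junction_arclength_um
        return DendritePath(self.vertices[::-1].copy(), junction_arclength_um=j)


@dataclass
class ZStack:
    """A confocal z-stack with voxel calibration.

    ``z_step_um`` defaults to 0.7 um, the optical sectioning interval of
    the ciliary-fluorescence acquisitions this module reproduces.
    """

    voxels: np.ndarray
    z_step_um: float = 0.7
    xy_pixel_size_um: float = 0.1

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3 or self.voxels.shape[0] < 1:
            raise ValueError("z-stack must be a (z, y, x) array with >=1 slice")
        if self.z_step_um <= 0 or self.xy_pixel_size_um <= 0:
            raise ValueError("voxel spacings must be positive")

    @property
    def voxel_volume_um3(self) -> float:
        return self.z_step_um * self.xy_pixel_size_um**2
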