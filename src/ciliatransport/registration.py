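"""Translation registration of time-lapse movies by MSD minimization.

Stage/animal drift is removed by estimating, for every pair of
consecutive frames, the integer displacement that minimizes the mean
square difference (MSD) of pixel intensities over a user-chosen ROI, and
chaining the pairwise estimates into cumulative per-frame offsets.  The
estimator is an exhaustive scan of the ``(2*search_radius + 1)^2``
displacement grid — the scan *is* the definition, so the implementation
doubles as its own oracle on small inputs.

Conventions: an offset ``(drow, dcol)`` is the displacement of a frame's
content relative to frame 0; ``translate(frame, offset)`` moves content
*by* ``-offset`` (i.e. samples ``frame[p + offset]``), so registering
frame ``t`` applies ``translate(frame_t, offsets[t])``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Movie, RegionOfInterest

__all__ = [
    "DriftTrack",
    "translate",
    "estimate_pairwise_offset",
    "register_movie",
]


@dataclass
class DriftTrack:
    """Estimated drift of each frame relative to frame 0.

    ``offsets`` is an ``(n_frames, 2)`` integer array of ``(drow, dcol)``
    content displacements (``offsets[0] == (0, 0)``); ``msd_values`` holds
    the minimized pairwise MSD for each frame (0 for frame 0).
    """

    offsets: np.ndarray
    msd_values: np.ndarray

    def __post_init__(self) -> None:
        self.offsets = np.asarray(self.offsets, dtype=int)
        self.msd_values = np.asarray(self.msd_values, dtype=float)
        if self.offsets.ndim != 2 or self.offsets.shape[1] != 2:
            raise ValueError("offsets must be (n_frames, 2)")
        if tuple(self.offsets[0]) != (0, 0):
            raise ValueError("offsets[0] must be (0, 0)")
        if len(self.msd_values) != len(self.offsets):
            raise ValueError("msd_values length must match offsets")


def translate(frame: np.ndarray, offset: tuple[int, int], fill: float = 0.0) -> np.ndarray:
    """Integer translation: ``out[p] = frame[p + offset]`` with ``fill``
    for out-of-bounds samples."""
    dr, dc = int(offset[0]), int(offset[1])
    rows, cols = frame.shape
    out = np.full_like(frame, fill)
    r0_src, r1_src = max(0, dr), min(rows, rows + dr)
    c0_src, c1_src = max(0, dc), min(cols, cols + dc)
    if r0_src >= r1_src or c0_src >= c1_src:
        return out
    out[r0_src - dr : r1_src - dr, c0_src - dc : c1_src - dc] = frame[r0_src:r1_src, c0_src:c1_src]
    return out


def bright_object_mask(frame: np.ndarray, factor: float = 6.0, dilate_px: int = 5) -> np.ndarray:
    """Mask of bright punctate objects (moving cargo) in a frame.

    Pixels brighter than ``median + factor * 1.4826*MAD`` are flagged and
    dilated by ``dilate_px`` pixels to cover the PSF support.  Used to
    keep moving fluorescent particles from hijacking drift estimation —
    the automated counterpart of choosing a registration ROI over
    stationary structure only.
    """
    from scipy.ndimage import maximum_filter

    med = np.median(frame)
    spread = 1.4826 * np.median(np.abs(frame - med))
    mask = frame > med + factor * spread
    if mask.any() and dilate_px > 0:
        mask = maximum_filter(mask, size=2 * dilate_px + 1)
    return mask


def estimate_pairwise_offset(
    frame_a: np.ndarray,
    frame_b: np.ndarray,
    roi: RegionOfInterest,
    search_radius: int = 10,
    exclude_mask: np.ndarray | None = None,
) -> tuple[tuple[int, int], float]:
    """Displacement of ``frame_b``'s content relative to ``frame_a``.

    Scans every integer displacement ``d`` with ``|drow|, |dcol| <=
    search_radius`` and returns the one minimizing
    ``MSD(d) = mean_{p in ROI} (frame_b[p + d] - frame_a[p])^2``,
    together with that minimum.  Ties are broken by smallest ``||d||``,
    then lexicographically on ``(drow, dcol)``.  ``exclude_mask`` (full
    frame shape, True = excluded) drops pixels — e.g. moving particles —
    from the ROI mean, identically for every candidate displacement.
    """
    frame_a = np.asarray(frame_a, dtype=np.float64)
    frame_b = np.asarray(frame_b, dtype=np.float64)
    if frame_a.shape != frame_b.shape or frame_a.ndim != 2:
        raise ValueError("frames must be 2-D arrays of equal shape")
    if search_radius < 0:
        raise ValueError("search_radius must be nonnegative")
    if not roi.contained_in(frame_a.shape, margin=search_radius):
        raise ValueError(
            f"ROI {roi} leaves the frame under displacements up to {search_radius} px"
        )
    a = frame_a[roi.row0 : roi.row1, roi.col0 : roi.col1]
    valid = None
    if exclude_mask is not None:
        valid = ~np.asarray(exclude_mask, dtype=bool)[roi.row0 : roi.row1, roi.col0 : roi.col1]
        if valid.sum() < 16:  # nearly everything masked: fall back to all pixels
            valid = None
    size = 2 * search_radius + 1
    msd = np.empty((size, size))
    for i, dr in enumerate(range(-search_radius, search_radius + 1)):
        for j, dc in enumerate(range(-search_radius, search_radius + 1)):
            b = frame_b[roi.row0 + dr : roi.row1 + dr, roi.col0 + dc : roi.col1 + dc]
            diff = b - a
            sq = diff * diff
            msd[i, j] = np.mean(sq[valid]) if valid is not None else np.mean(sq)
    best = msd.min()
    ties = np.argwhere(msd == best)
    disp = ties - search_radius
    order = np.lexsort((disp[:, 1], disp[:, 0], np.einsum("ij,ij->i", disp, disp)))
    dr, dc = disp[order[0]]
    return (int(dr), int(dc)), float(best)


def register_movie(
    movie: Movie,
    roi: RegionOfInterest,
    search_radius: int = 10,
    fill: float | None = None,
    mask_moving: bool = True,
) -> tuple[Movie, DriftTrack]:
    """Register a movie by chained consecutive-pair MSD estimates.

    Cumulative offsets are composed from the pairwise estimates (so slow
    error accumulation is possible over very long movies) and each frame
    is translated back by its cumulative offset, padding exposed edges
    with ``fill`` (default: the median of frame 0, a robust background
    estimate).  With ``mask_moving`` (default) bright punctate objects
    are masked out of each pairwise MSD so that moving cargo cannot bias
    the drift estimate.  A drift-free movie is returned unchanged.
    """
    if movie.n_frames < 2:
        raise ValueError("need >= 2 frames to register a movie")
    if fill is None:
        fill = float(np.median(movie.frames[0]))
    n = movie.n_frames
    offsets = np.zeros((n, 2), dtype=int)
    msds = np.zeros(n)
    for t in range(1, n):
        mask = bright_object_mask(movie.frames[t - 1]) if mask_moving else None
        (dr, dc), msd = estimate_pairwise_offset(
            movie.frames[t - 1], movie.frames[t], roi, search_radius, exclude_mask=mask
        )
        offsets[t] = offsets[t - 1] + (dr, dc)
        msds[t] = msd
    registered = np.empty_like(movie.frames)
    for t in range(n):
        if offsets[t, 0] or offsets[t, 1]:
            registered[t] = translate(movie.frames[t], tuple(offsets[t]), fill=fill)
        else:
            registered[t] = movie.frames[t]
    out = Movie(registered, pixel_size_um=movie.pixel_size_um,
                frame_interval_s=movie.frame_interval_s)
    return out, DriftTrack(offsets=offsets, msd_values=msds)
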