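"""Per-direction transport statistics and genotype comparisons.

Computes, from scored transport events: per-direction velocity mean,
s.e.m. (sample SD with the n-1 denominator over sqrt(n)) and histogram;
per-direction event frequency (events per minute of observation, pooling
multiple movies by summed counts and times); two-segment (middle/distal)
IFT velocities restricted by a junction arclength; and Welch two-sample
t tests between genotypes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .events import LinearSegment, ParticleTrace, TransportEvent

__all__ = [
    "DirectionStats",
    "TransportStats",
    "GroupComparison",
    "SegmentRegionStats",
    "velocity_stats",
    "event_frequencies",
    "segment_restricted_velocities",
    "compare_groups",
]

DIRECTIONS = ("anterograde", "retrograde")


@dataclass
class DirectionStats:
    """Velocity and frequency summary for one direction."""

    direction: str
    n: int
    mean_velocity_um_s: float  # nan when n == 0
    sem_velocity_um_s: float  # nan when n < 2 (reported as missing)
    frequency_per_min: float
    histogram_counts: np.ndarray
    histogram_edges_um_s: np.ndarray

    def as_dict(self) -> dict:
        return {
            "direction": self.direction,
            "n": self.n,
            "mean_velocity_um_s": self.mean_velocity_um_s,
            "sem_velocity_um_s": self.sem_velocity_um_s,
            "frequency_per_min": self.frequency_per_min,
        }


@dataclass
class TransportStats:
    """Per-direction statistics over one pooled set of movies."""

    total_time_min: float
    anterograde: DirectionStats
    retrograde: DirectionStats

    def __getitem__(self, direction: str) -> DirectionStats:
        if direction not in DIRECTIONS:
            raise KeyError(direction)
        return getattr(self, direction)


@dataclass
class GroupComparison:
    """Welch two-sample t test between two groups of event velocities."""

    t_statistic: float
    degrees_of_freedom: float
    p_value: float
    ratio_of_means: float
    test: str = "Welch two-sample t"


@dataclass
class SegmentRegionStats:
    """Anterograde segment-velocity summary for one ciliary region."""

    region: str  # "middle" | "distal"
    n: int
    mean_velocity_um_s: float
    sem_velocity_um_s: float
    velocities_um_s: np.ndarray


def _direction_stats(
    velocities: np.ndarray, direction: str, total_time_min: float, bin_width: float
) -> DirectionStats:
    n = len(velocities)
    mean = float(np.mean(velocities)) if n else math.nan
    sem = float(np.std(velocities, ddof=1) / math.sqrt(n)) if n >= 2 else math.nan
    vmax = float(velocities.max()) if n else 0.0
    edges = np.arange(0.0, vmax + 2 * bin_width, bin_width)
    counts, edges = np.histogram(velocities, bins=edges)
    return DirectionStats(
        direction=direction,
        n=n,
        mean_velocity_um_s=mean,
        sem_velocity_um_s=sem,
        frequency_per_min=n / total_time_min,
        histogram_counts=counts,
        histogram_edges_um_s=edges,
    )


def velocity_stats(
    events: list[TransportEvent],
    total_time_min: float,
    bin_width_um_s: float = 0.2,
) -> TransportStats:
    """Per-direction velocity mean/s.e.m./histogram and event frequency.

    Histograms use fixed-width bins anchored at 0.  Events from several
    movies may simply be concatenated, with ``total_time_min`` the summed
    observation time.
    """
    if total_time_min <= 0:
        raise ValueError("total_time_min must be positive")
    if bin_width_um_s <= 0:
        raise ValueError("bin width must be positive")
    per_dir = {}
    for direction in DIRECTIONS:
        v = np.array([e.velocity_um_s for e in events if e.direction == direction])
        per_dir[direction] = _direction_stats(v, direction, total_time_min, bin_width_um_s)
    return TransportStats(
        total_time_min=total_time_min,
        anterograde=per_dir["anterograde"],
        retrograde=per_dir["retrograde"],
    )


def event_frequencies(events: list[TransportEvent], total_time_min: float) -> dict[str, float]:
    """Events per minute by direction (pooled counts over pooled time)."""
    if total_time_min <= 0:
        raise ValueError("total observation time must be positive")
    return {
        d: sum(1 for e in events if e.direction == d) / total_time_min for d in DIRECTIONS
    }


def _split_segment(
    trace: ParticleTrace,
    segment: LinearSegment,
    junction_um: float,
    min_points: int,
    frame_interval_s: float,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Split a straddling segment's points at the junction crossing; keep
    each part with >= min_points.  The split is by observed position (the
    frames measured below the junction versus at or above it), which
    locates the crossing better than the segment's blended overall fit."""
    start, stop = segment.point_slice
    frames = trace.frames[start:stop]
    pos = trace.positions_um[start:stop]
    below = pos < junction_um
    parts = []
    for mask in (below, ~below):
        if mask.sum() >= min_points:
            parts.append((frames[mask], pos[mask]))
    return parts if parts else [(frames, pos)]


def segment_restricted_velocities(
    traces_with_segments: list[tuple[ParticleTrace, list[LinearSegment]]],
    junction_arclength_um: float,
    path_length_um: float | None = None,
    min_points: int = 4,
    frame_interval_s: float = 0.5,
    min_run_um: float = 1.0,
) -> tuple[SegmentRegionStats, SegmentRegionStats]:
    """Anterograde steady-segment velocities by ciliary region.

    Each steady segment is assigned to the middle region when its mean
    position is below the junction arclength, else to the distal region;
    segments straddling the junction are split at the crossing frame and
    each part is refit and kept if it still has ``min_points`` points.
    Pieces whose fitted displacement is below ``min_run_um`` are ignored:
    a velocity needs a discernible run, and near-stationary residual
    clutter would otherwise bias the region means.  Returns
    ``(middle, distal)`` anterograde summaries (mean +- s.e.m.).
    """
    if junction_arclength_um <= 0 or (
        path_length_um is not None and junction_arclength_um >= path_length_um
    ):
        raise ValueError("junction arclength must lie strictly inside the path")
    region_v: dict[str, list[float]] = {"middle": [], "distal": []}
    for trace, segments in traces_with_segments:
        for seg in segments:
            pos = trace.positions_um[seg.point_slice[0] : seg.point_slice[1]]
            straddles = pos.min() < junction_arclength_um < pos.max()
            pieces = (
                _split_segment(trace, seg, junction_arclength_um, min_points, frame_interval_s)
                if straddles
                else [(trace.frames[seg.point_slice[0] : seg.point_slice[1]], pos)]
            )
            for frames, positions in pieces:
                slope, intercept = np.polyfit(frames * frame_interval_s, positions, 1)
                if slope <= 0:  # anterograde only
                    continue
                if abs(slope) * (frames[-1] - frames[0]) * frame_interval_s < min_run_um:
                    continue
                region = "middle" if positions.mean() < junction_arclength_um else "distal"
                region_v[region].append(float(slope))
    out = []
    for region in ("middle", "distal"):
        v = np.array(region_v[region])
        n = len(v)
        out.append(
            SegmentRegionStats(
                region=region,
                n=n,
                mean_velocity_um_s=float(v.mean()) if n else math.nan,
                sem_velocity_um_s=float(v.std(ddof=1) / math.sqrt(n)) if n >= 2 else math.nan,
                velocities_um_s=v,
            )
        )
    return out[0], out[1]


def compare_groups(
    events_a: list[TransportEvent],
    events_b: list[TransportEvent],
    direction: str,
) -> GroupComparison:
    """Welch unequal-variance two-sample t test on event velocities.

    The t statistic is signed as mean(a) - mean(b); the p value is
    two-sided; ``ratio_of_means`` is mean(b)/mean(a).
    """
    va = np.array([e.velocity_um_s for e in events_a if e.direction == direction])
    vb = np.array([e.velocity_um_s for e in events_b if e.direction == direction])
    if len(va) < 2 or len(vb) < 2:
        raise ValueError("need >= 2 events per group in the chosen direction")
    if np.std(va) == 0 and np.std(vb) == 0:
        if np.mean(va) == np.mean(vb):
            return GroupComparison(0.0, float(len(va) + len(vb) - 2), 1.0,
                                   float(np.mean(vb) / np.mean(va)))
        raise ValueError("zero variance in both groups with unequal means")
    res = sps.ttest_ind(va, vb, equal_var=False)
    return GroupComparison(
        t_statistic=float(res.statistic),
        degrees_of_freedom=float(res.df),
        p_value=float(res.pvalue),
        ratio_of_means=float(np.mean(vb) / np.mean(va)),
    )
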