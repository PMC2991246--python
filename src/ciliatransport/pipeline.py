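"""End-to-end workflows: simulate/load -> register -> kymograph -> events -> stats.

Two entry layers live here:

* :func:`run_pipeline` executes one configured run on a single movie and
  writes its outputs (drift CSV, kymograph TIFF, events CSV, stats JSON,
  run log), for the CLI;
* the session helpers (:func:`run_transport_session`,
  :func:`run_ift_session`, :func:`run_stack_pair`) simulate a whole
  observation campaign as a series of short movies — mirroring how the
  time-lapse acquisitions were collected in ~1-minute bouts — analyse
  each through the full pipeline and pool events over summed observation
  time.  The analysis drivers and the acceptance script are thin wrappers
  over these.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as ctio
from .core import DendritePath, Movie, RegionOfInterest
from .events import L_MIN_UM, LinearSegment, ParticleTrace, TransportEvent, extract_events
from .kymograph import Kymograph, build_kymograph
from .presets import StackPreset, TransportPreset, load_preset
from .quantify import FluorescenceMeasure, fluorescence_ratio, quantify_stack, threshold_stack
from .registration import DriftTrack, register_movie
from .simulate import (
    GroundTruthEvent,
    preset_path,
    simulate_cilium_stack,
    simulate_transport_movie,
)
from .stats import SegmentRegionStats, TransportStats, segment_restricted_velocities, velocity_stats

__all__ = [
    "DetectionParams",
    "PipelineConfig",
    "SessionResult",
    "default_registration_roi",
    "analyze_movie",
    "run_pipeline",
    "run_transport_session",
    "run_ift_session",
    "run_stack_pair",
]

logger = logging.getLogger("ciliatransport")


@dataclass
class DetectionParams:
    """Trace-detection and scoring parameters (see :mod:`.events`)."""

    min_prominence: float | None = None  # None -> 3x robust spread
    min_separation_um: float = 0.4
    max_jump_um: float = 1.25
    max_gap_frames: int = 2
    rho_um: float = 0.3
    min_points: int = 4
    l_min_um: float = L_MIN_UM


@dataclass
class PipelineConfig:
    """Configuration of one single-movie pipeline run.

    Either ``movie_path`` (a multi-page TIFF, with ``path_file`` tracing
    the dendrite) or ``preset`` (simulate the movie and use the preset's
    straight path) must be given.  All calibration comes from here, never
    from TIFF metadata.
    """

    movie_path: str | None = None
    preset: str | None = None
    path_file: str | None = None
    pixel_size_um: float = 0.1
    frame_interval_s: float = 0.5
    register: bool = True
    roi: tuple[int, int, int, int] | None = None  # row0, col0, row1, col1
    search_radius: int = 6
    half_width_px: int = 2
    reducer: str = "max"
    detection: DetectionParams = field(default_factory=DetectionParams)
    output_dir: str = "results/run"
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        if (self.movie_path is None) == (self.preset is None):
            raise ValueError("exactly one of movie_path or preset must be set")
        if self.movie_path is not None and self.path_file is None:
            raise ValueError("a path_file is required when analysing a movie file")
        if self.movie_path is not None and not Path(self.movie_path).exists():
            raise ValueError(f"movie file not found: {self.movie_path}")
        if self.path_file is not None and not Path(self.path_file).exists():
            raise ValueError(f"path file not found: {self.path_file}")
        if self.search_radius < 0:
            raise ValueError("search_radius must be nonnegative")


def default_registration_roi(
    frame_shape: tuple[int, int],
    path: DendritePath | None = None,
    search_radius: int = 6,
) -> RegionOfInterest:
    """The default registration ROI: the whole frame minus a margin.

    The MSD estimator needs static structure to lock onto; using (almost)
    the full field of view makes the minimum sharp and keeps the sparse
    moving particles a negligible fraction of the ROI pixels, so they
    cannot hijack the estimate even when drift carries the path across
    the frame.  The margin keeps the ROI in bounds under every candidate
    displacement up to ``search_radius``.
    """
    rows, cols = frame_shape
    margin = search_radius + 2
    if rows - 2 * margin < 6 or cols - 2 * margin < 6:
        raise ValueError("frame too small for a registration ROI at this search radius")
    return RegionOfInterest(margin, margin, rows - margin, cols - margin)


@dataclass
class MovieAnalysis:
    """Everything the pipeline derives from one movie."""

    movie: Movie
    drift: DriftTrack | None
    kymograph: Kymograph
    events: list[TransportEvent]
    traces_with_segments: list[tuple[ParticleTrace, list[LinearSegment]]]


def analyze_movie(
    movie: Movie,
    path: DendritePath,
    register: bool = True,
    roi: RegionOfInterest | None = None,
    search_radius: int = 6,
    half_width_px: int = 2,
    reducer: str = "max",
    detection: DetectionParams | None = None,
) -> MovieAnalysis:
    """Register a movie, build its kymograph and score transport events."""
    detection = detection or DetectionParams()
    drift = None
    if register:
        if roi is None:
            roi = default_registration_roi(movie.frame_shape, path, search_radius)
        movie, drift = register_movie(movie, roi, search_radius)
    kymo = build_kymograph(movie, path, half_width_px=half_width_px, reducer=reducer)
    events, traces = extract_events(
        kymo,
        min_prominence=detection.min_prominence,
        min_separation_um=detection.min_separation_um,
        max_jump_um=detection.max_jump_um,
        max_gap_frames=detection.max_gap_frames,
        rho_um=detection.rho_um,
        min_points=detection.min_points,
        l_min_um=detection.l_min_um,
    )
    return MovieAnalysis(movie, drift, kymo, events, traces)


@dataclass
class SessionResult:
    """Pooled result of a multi-movie observation session."""

    preset: TransportPreset
    total_time_min: float
    events: list[TransportEvent]
    traces_with_segments: list[tuple[ParticleTrace, list[LinearSegment]]]
    ground_truth: list[GroundTruthEvent]
    stats: TransportStats
    n_movies: int

    def count(self, direction: str) -> int:
        return sum(1 for e in self.events if e.direction == direction)


def run_transport_session(
    preset: TransportPreset,
    seed: int,
    movie_minutes: float | None = None,
    n_movies: int | None = None,
    register: bool = True,
    search_radius: int = 6,
    detection: DetectionParams | None = None,
) -> SessionResult:
    """Simulate and analyse a whole observation session.

    The preset's total observation time is split into ``n_movies``
    acquisitions of ``movie_minutes`` each; by default the session covers
    ``preset.duration_min`` in acquisitions of ~4 minutes (long enough
    that runs truncated at movie boundaries are a small fraction of all
    runs).  Every movie is simulated with an independent child seed of
    ``seed`` and pushed through the full pipeline.  Events, traces and
    ground truth are pooled; frequencies divide by the summed time.
    """
    if n_movies is None:
        n_movies = max(1, int(round(preset.duration_min / (movie_minutes or 4.0))))
    if movie_minutes is None:
        movie_minutes = preset.duration_min / n_movies
    rng = np.random.default_rng(seed)
    child_seeds = rng.integers(0, 2**31 - 1, size=n_movies)
    path = preset_path(preset)
    events: list[TransportEvent] = []
    traces: list[tuple[ParticleTrace, list[LinearSegment]]] = []
    ground_truth: list[GroundTruthEvent] = []
    trace_offset = 0
    particle_offset = 0
    for m, child in enumerate(child_seeds):
        p = preset.replace(duration_min=movie_minutes, seed=int(child))
        movie, gt, _drift = simulate_transport_movie(p)
        result = analyze_movie(
            movie, path, register=register, search_radius=search_radius, detection=detection
        )
        for e in result.events:
            e.trace_id += trace_offset
            events.append(e)
        for trace, segs in result.traces_with_segments:
            trace.trace_id += trace_offset
            traces.append((trace, segs))
        for g in gt:
            g.particle_id += particle_offset
            ground_truth.append(g)
        trace_offset += max((t.trace_id for t, _ in result.traces_with_segments), default=0) + 1
        particle_offset += len(gt)
        logger.debug("movie %d/%d: %d events", m + 1, n_movies, len(result.events))
    total_time = n_movies * movie_minutes
    return SessionResult(
        preset=preset,
        total_time_min=total_time,
        events=events,
        traces_with_segments=traces,
        ground_truth=ground_truth,
        stats=velocity_stats(events, total_time),
        n_movies=n_movies,
    )


def run_ift_session(
    preset: TransportPreset | None = None,
    seed: int = 0,
    movie_minutes: float = 1.0,
    n_movies: int | None = None,
    detection: DetectionParams | None = None,
) -> tuple[SessionResult, SegmentRegionStats, SegmentRegionStats]:
    """Two-segment IFT analysis on the packaged (or a custom) IFT preset.

    Returns the session plus middle- and distal-segment anterograde
    velocity summaries, assigned by the preset's junction arclength.
    """
    if preset is None:
        preset = load_preset("IFT")  # type: ignore[assignment]
    junction = preset.junction_arclength_um
    if junction is None:
        raise ValueError("IFT analysis needs a preset with a velocity profile (junction)")
    session = run_transport_session(
        preset, seed, movie_minutes=movie_minutes, n_movies=n_movies, detection=detection
    )
    middle, distal = segment_restricted_velocities(
        session.traces_with_segments,
        junction_arclength_um=junction,
        path_length_um=preset.path_length_um,
        frame_interval_s=preset.frame_interval_s,
    )
    return session, middle, distal


def run_stack_pair(
    seed: int,
    preset_ref: StackPreset | None = None,
    preset_test: StackPreset | None = None,
    threshold: float | str | None = None,
) -> dict:
    """Simulate the paired z-stack fixture and measure the test/reference
    total-fluorescence ratio in percent.

    By default the packaged ``stack_wt`` / ``stack_chb3`` pair is used
    with a common absolute threshold halfway between the background and
    the dimmer stack's signal plateau — a common absolute threshold
    avoids threshold-induced bias between the paired stacks.
    """
    if preset_ref is None:
        preset_ref = load_preset("stack_wt")  # type: ignore[assignment]
    if preset_test is None:
        preset_test = load_preset("stack_chb3")  # type: ignore[assignment]
    rng = np.random.default_rng(seed)
    sa, sb = rng.integers(0, 2**31 - 1, size=2)
    preset_ref = preset_ref.replace(seed=int(sa))
    preset_test = preset_test.replace(seed=int(sb))
    stack_ref, stack_test, truth = simulate_cilium_stack(preset_ref, preset_test)
    if threshold is None:
        dim = min(
            preset_ref.amplitude * preset_ref.intensity_scale,
            preset_test.amplitude * preset_test.intensity_scale,
        )
        background = max(preset_ref.background, preset_test.background)
        threshold = background + 0.5 * dim
    mask_ref, thr = threshold_stack(stack_ref, threshold)
    mask_test, _ = threshold_stack(stack_test, threshold)
    m_ref = quantify_stack(stack_ref, mask_ref, thr)
    m_test = quantify_stack(stack_test, mask_test, thr)
    return {
        "reference": m_ref,
        "test": m_test,
        "measured_ratio_percent": fluorescence_ratio(m_test, m_ref),
        "truth_ratio_percent": 100.0 * truth["ratio"],
        "threshold": thr,
    }


def _resolve_movie_and_path(config: PipelineConfig) -> tuple[Movie, DendritePath, list | None]:
    if config.preset is not None:
        preset = load_preset(config.preset)
        if not isinstance(preset, TransportPreset):
            raise ValueError(f"preset {config.preset!r} is not a transport preset")
        preset = preset.replace(seed=config.seed)
        movie, ground_truth, _ = simulate_transport_movie(preset)
        return movie, preset_path(preset), ground_truth
    movie = ctio.read_movie(config.movie_path, config.pixel_size_um, config.frame_interval_s)
    return movie, ctio.read_path(config.path_file), None


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute one configured run and write its outputs.

    Writes, under ``config.output_dir``: ``drift.csv``,
    ``kymograph.tif``, ``events.csv``, ``stats.json``, and ``run_log.json``
    (all resolved parameters plus the seed, sufficient to re-execute the
    run).  Returns the report dictionary.
    """
    config.validate()
    logging.basicConfig(level=config.log_level)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    movie, path, ground_truth = _resolve_movie_and_path(config)
    roi = RegionOfInterest(*config.roi) if config.roi is not None else None
    stage = "registration"
    try:
        analysis = analyze_movie(
            movie,
            path,
            register=config.register,
            roi=roi,
            search_radius=config.search_radius,
            half_width_px=config.half_width_px,
            reducer=config.reducer,
            detection=config.detection,
        )
        stage = "statistics"
        total_time_min = movie.duration_s / 60.0
        stats = velocity_stats(analysis.events, total_time_min)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage}: {exc}") from exc

    import tifffile

    if analysis.drift is not None:
        ctio.drift_to_frame(analysis.drift).to_csv(out / "drift.csv", index=False)
    tifffile.imwrite(out / "kymograph.tif", analysis.kymograph.values.astype(np.float32))
    ctio.write_events_csv(analysis.events, out / "events.csv")
    if ground_truth is not None:
        ctio.ground_truth_to_frame(ground_truth).to_csv(out / "ground_truth.csv", index=False)
    report = {
        "total_time_min": total_time_min,
        "n_events": len(analysis.events),
        "anterograde": stats.anterograde.as_dict(),
        "retrograde": stats.retrograde.as_dict(),
    }
    (out / "stats.json").write_text(json.dumps(report, indent=1))
    log = dataclasses.asdict(config)
    log["position_step_um"] = analysis.kymograph.position_step_um
    (out / "run_log.json").write_text(json.dumps(log, indent=1, default=str))
    return report
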