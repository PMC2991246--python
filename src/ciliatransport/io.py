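"""File I/O: multi-page TIFF movies/stacks, path files, and CSV tables.

Calibration (um/px, s/frame, um/z-step) always comes from explicit
arguments or config — TIFF resolution tags are deliberately ignored to
avoid dialect ambiguity.  Integer and float32 data round-trip
bit-identically.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .core import DendritePath, Movie, ZStack
from .events import TransportEvent
from .registration import DriftTrack
from .simulate import GroundTruthEvent

__all__ = [
    "read_movie",
    "write_movie",
    "read_stack",
    "write_stack",
    "read_path",
    "write_path",
    "events_to_frame",
    "write_events_csv",
    "read_events_csv",
    "ground_truth_to_frame",
    "drift_to_frame",
]


def _read_gray_pages(path: str | Path) -> np.ndarray:
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tif:
            pages = []
            for i, page in enumerate(tif.pages):
                try:
                    arr = page.asarray()
                except Exception as exc:  # corrupt page
                    raise ValueError(f"cannot read TIFF page {i} of {path}: {exc}") from exc
                if arr.ndim != 2:
                    raise ValueError(
                        f"grayscale required: page {i} of {path} has shape {arr.shape}"
                    )
                if pages and arr.shape != pages[0].shape:
                    raise ValueError(f"inconsistent page shapes in {path} at page {i}")
                pages.append(arr)
    except tifffile.TiffFileError as exc:
        raise ValueError(f"unreadable TIFF {path}: {exc}") from exc
    if not pages:
        raise ValueError(f"no image pages in {path}")
    return np.stack(pages)


def read_movie(path: str | Path, pixel_size_um: float, frame_interval_s: float = 0.5) -> Movie:
    """Read a multi-page grayscale TIFF time-lapse movie."""
    return Movie(_read_gray_pages(path), pixel_size_um, frame_interval_s)


def write_movie(movie: Movie, path: str | Path) -> None:
    """Write a movie as a multi-page TIFF (one page per frame)."""
    tifffile.imwrite(Path(path), movie.frames)


def read_stack(path: str | Path, z_step_um: float = 0.7, xy_pixel_size_um: float = 0.1) -> ZStack:
    """Read a multi-page grayscale TIFF z-stack."""
    return ZStack(_read_gray_pages(path), z_step_um, xy_pixel_size_um)


def write_stack(stack: ZStack, path: str | Path) -> None:
    tifffile.imwrite(Path(path), stack.voxels)


def read_path(path_file: str | Path) -> DendritePath:
    """Read a traced path from CSV (row,col columns) or JSON.

    JSON form: ``{"vertices": [[row, col], ...],
    "junction_arclength_um": s_j | null}``; the junction is optional in
    both formats (CSV may carry it as a ``# junction_arclength_um=..``
    first comment line).
    """
    path_file = Path(path_file)
    if path_file.suffix == ".json":
        data = json.loads(path_file.read_text())
        return DendritePath(
            np.asarray(data["vertices"], dtype=float),
            junction_arclength_um=data.get("junction_arclength_um"),
        )
    junction = None
    text = path_file.read_text().splitlines()
    if text and text[0].startswith("#") and "junction_arclength_um=" in text[0]:
        junction = float(text[0].split("=", 1)[1])
    df = pd.read_csv(path_file, comment="#")
    return DendritePath(df[["row", "col"]].to_numpy(float), junction_arclength_um=junction)


def write_path(path: DendritePath, path_file: str | Path) -> None:
    path_file = Path(path_file)
    if path_file.suffix == ".json":
        data = {
            "vertices": path.vertices.tolist(),
            "junction_arclength_um": path.junction_arclength_um,
        }
        path_file.write_text(json.dumps(data, indent=1))
        return
    lines = []
    if path.junction_arclength_um is not None:
        lines.append(f"# junction_arclength_um={path.junction_arclength_um}")
    lines.append("row,col")
    lines.extend(f"{r},{c}" for r, c in path.vertices)
    path_file.write_text("\n".join(lines) + "\n")


def events_to_frame(events: list[TransportEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "trace_id": e.trace_id,
                "direction": e.direction,
                "velocity_um_s": e.velocity_um_s,
                "run_length_um": e.run_length_um,
                "first_frame": e.first_frame,
                "last_frame": e.last_frame,
            }
            for e in events
        ],
        columns=["trace_id", "direction", "velocity_um_s", "run_length_um",
                 "first_frame", "last_frame"],
    )


def write_events_csv(events: list[TransportEvent], path: str | Path) -> None:
    events_to_frame(events).to_csv(path, index=False)


def read_events_csv(path: str | Path) -> list[TransportEvent]:
    df = pd.read_csv(path)
    return [
        TransportEvent(
            trace_id=int(r.trace_id),
            direction=str(r.direction),
            velocity_um_s=float(r.velocity_um_s),
            run_length_um=float(r.run_length_um),
            first_frame=int(r.first_frame),
            last_frame=int(r.last_frame),
        )
        for r in df.itertuples()
    ]


def ground_truth_to_frame(ground_truth: list[GroundTruthEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "particle_id": g.particle_id,
                "direction": g.direction,
                "entry_frame": g.entry_frame,
                "exit_frame": g.exit_frame,
                "true_velocity_um_s": g.true_velocity_um_s,
                "entry_position_um": g.entry_position_um,
                "run_length_um": g.run_length_um,
            }
            for g in ground_truth
        ],
        columns=["particle_id", "direction", "entry_frame", "exit_frame",
                 "true_velocity_um_s", "entry_position_um", "run_length_um"],
    )


def drift_to_frame(drift: DriftTrack) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "frame": np.arange(len(drift.offsets)),
            "drow": drift.offsets[:, 0],
            "dcol": drift.offsets[:, 1],
            "msd": drift.msd_values,
        }
    )
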