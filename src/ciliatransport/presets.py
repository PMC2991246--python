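"""Generative presets for the synthetic transport movies and z-stacks.

A :class:`TransportPreset` bundles everything needed to simulate one
genotype/condition of the dendritic- or intraflagellar-transport
experiments: Poisson arrival rates per direction, per-direction velocity
distributions, optics (PSF width, pixel size, frame interval), noise and
drift, and the seed.  A :class:`StackPreset` does the same for the paired
confocal z-stacks used to quantify total ciliary fluorescence.

Packaged presets
----------------
``WT``
    Wild-type dendritic transport of a ciliary membrane protein in a
    phasmid neuron: anterograde events at 134/34 per minute with mean
    velocity 1.11 um/s, retrograde at 88/34 per minute with mean
    0.80 um/s.  Velocity spreads are the sample SDs implied by the
    published s.e.m. values (0.044*sqrt(134) and 0.036*sqrt(88) um/s).
``chb3``
    Transport-impaired mutant: anterograde events at 147/64 per minute,
    retrograde at 67/64 per minute.  Only the mutant *rates* are published;
    the mutant velocity means used here (0.85 / 0.60 um/s) are invented
    fixture values chosen so that the wild type is faster — analyses assert
    only the direction and significance of the difference, never these
    numbers.
``IFT``
    Two-segment intraflagellar transport along a cilium: anterograde
    particles move at ~0.4 um/s along the middle segment and accelerate to
    ~1 um/s along the distal segment, encoded as a piecewise-constant
    speed-multiplier profile with the junction at 4 um.
``stack_wt`` / ``stack_chb3``
    A paired z-stack fixture whose ground-truth total-fluorescence ratio
    is exactly 26% (``intensity_scale`` 1.0 vs 0.26 on identical
    geometry).
"""

from __future__ import annotations

import dataclasses
import json
import math
import re
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = [
    "TransportPreset",
    "StackPreset",
    "load_preset",
    "PACKAGED_PRESETS",
    "parse_noise_model",
]

_NOISE_RE = re.compile(r"^gaussian\((\d+(?:\.\d+)?)\)$")


def parse_noise_model(spec: str) -> tuple[str, float]:
    """Parse a noise-model string into ``(kind, sigma)``.

    Accepted: ``"poisson"`` (shot noise on background + signal),
    ``"gaussian(SIGMA)"`` (additive read noise of that SD), ``"none"``.
    """
    if spec == "poisson":
        return "poisson", 0.0
    if spec == "none":
        return "none", 0.0
    m = _NOISE_RE.match(spec)
    if m:
        return "gaussian", float(m.group(1))
    raise ValueError(f"unknown noise model {spec!r}; use 'poisson', 'none' or 'gaussian(sigma)'")


@dataclass
class TransportPreset:
    """Parameters of one simulated transport condition.

    Rates are per minute, velocities in um/s, lengths in um.
    ``velocity_profile`` is an optional list of ``(start_um, end_um,
    multiplier)`` intervals covering ``[0, path_length_um]``: a particle's
    instantaneous speed is its drawn base speed times the multiplier of
    the interval containing its current arclength (used for the
    middle/distal IFT segments).  ``drift_step_px`` is the SD of the
    integer random-walk stage-drift step per frame and axis.
    """

    name: str = "custom"
    duration_min: float = 1.0
    rate_antero: float = 0.0
    rate_retro: float = 0.0
    v_antero_mean: float = 1.0
    v_antero_sd: float = 0.1
    v_retro_mean: float = 1.0
    v_retro_sd: float = 0.1
    velocity_profile: list[tuple[float, float, float]] | None = None
    path_length_um: float = 15.0
    pixel_size_um: float = 0.1
    frame_interval_s: float = 0.5
    psf_sigma_um: float = 0.15
    background_level: float = 20.0
    particle_amplitude: float = 80.0
    texture_amplitude: float = 15.0
    noise_model: str = "poisson"
    drift_step_px: float = 0.0
    frame_shape: tuple[int, int] = (64, 256)
    seed: int = 0

    def __post_init__(self) -> None:
        nonneg = {
            "duration_min": self.duration_min,
            "rate_antero": self.rate_antero,
            "rate_retro": self.rate_retro,
            "v_antero_mean": self.v_antero_mean,
            "v_antero_sd": self.v_antero_sd,
            "v_retro_mean": self.v_retro_mean,
            "v_retro_sd": self.v_retro_sd,
            "psf_sigma_um": self.psf_sigma_um,
            "background_level": self.background_level,
            "particle_amplitude": self.particle_amplitude,
            "texture_amplitude": self.texture_amplitude,
            "drift_step_px": self.drift_step_px,
        }
        for key, value in nonneg.items():
            if value < 0:
                raise ValueError(f"{key} must be nonnegative, got {value}")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.path_length_um <= 0:
            raise ValueError("path_length_um must be positive")
        parse_noise_model(self.noise_model)
        self.frame_shape = tuple(int(v) for v in self.frame_shape)  # type: ignore[assignment]
        if len(self.frame_shape) != 2 or min(self.frame_shape) < 1:
            raise ValueError("frame_shape must be two positive integers")
        if self.velocity_profile is not None:
            prof = [(float(a), float(b), float(m)) for a, b, m in self.velocity_profile]
            prof.sort()
            if not math.isclose(prof[0][0], 0.0, abs_tol=1e-9):
                raise ValueError("velocity_profile must start at arclength 0")
            for (a0, b0, _), (a1, _, _) in zip(prof, prof[1:]):
                if not math.isclose(b0, a1, abs_tol=1e-9):
                    raise ValueError("velocity_profile intervals must tile without gaps")
            if prof[-1][1] < self.path_length_um - 1e-9:
                raise ValueError("velocity_profile must cover the whole path")
            if any(m <= 0 for _, _, m in prof):
                raise ValueError("velocity multipliers must be positive")
            self.velocity_profile = prof

    @property
    def junction_arclength_um(self) -> float | None:
        """Arclength of the first profile boundary, if a profile is set.

        For the packaged two-segment IFT preset this is the middle/distal
        segment boundary.
        """
        if self.velocity_profile is None or len(self.velocity_profile) < 2:
            return None
        return self.velocity_profile[0][1]

    def replace(self, **kwargs) -> "TransportPreset":
        return dataclasses.replace(self, **kwargs)


@dataclass
class StackPreset:
    """Parameters of one simulated ciliary z-stack.

    The fluorescent region is an axis-aligned ellipsoid of
    ``region_shape`` semi-axes (z, y, x in um) at the stack centre, with
    uniform signal ``amplitude * intensity_scale`` on top of
    ``background``.  ``intensity_scale`` realises a prescribed
    between-stack ratio: two presets with identical geometry and scales
    ``1.0`` and ``r`` have ground-truth total-fluorescence ratio exactly
    ``r``.
    """

    name: str = "custom"
    region_shape: tuple[float, float, float] = (1.2, 0.9, 2.2)
    amplitude: float = 200.0
    background: float = 2.0
    z_step_um: float = 0.7
    xy_pixel_size_um: float = 0.1
    noise_model: str = "poisson"
    intensity_scale: float = 1.0
    stack_shape: tuple[int, int, int] = (9, 56, 72)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.z_step_um <= 0 or self.xy_pixel_size_um <= 0:
            raise ValueError("voxel spacings must be positive")
        if self.amplitude < 0 or self.background < 0 or self.intensity_scale < 0:
            raise ValueError("amplitude, background and intensity_scale must be nonnegative")
        if len(self.region_shape) != 3 or min(self.region_shape) <= 0:
            raise ValueError("region_shape must be three positive semi-axes (z, y, x) in um")
        parse_noise_model(self.noise_model)
        self.stack_shape = tuple(int(v) for v in self.stack_shape)  # type: ignore[assignment]
        if len(self.stack_shape) != 3 or min(self.stack_shape) < 1:
            raise ValueError("stack_shape must be three positive integers")

    def replace(self, **kwargs) -> "StackPreset":
        return dataclasses.replace(self, **kwargs)


# Published observation spans and event counts: 34 min / 134 antero / 88
# retro (wild type) and 64 min / 147 antero / 67 retro (mutant); the
# velocity SDs are sem*sqrt(n) from the printed s.e.m. values.
_WT_SD_A = 0.044 * math.sqrt(134.0)
_WT_SD_R = 0.036 * math.sqrt(88.0)

PACKAGED_PRESETS: dict[str, dict] = {
    "WT": dict(
        name="WT",
        duration_min=34.0,
        rate_antero=134.0 / 34.0,
        rate_retro=88.0 / 34.0,
        v_antero_mean=1.11,
        v_antero_sd=_WT_SD_A,
        v_retro_mean=0.80,
        v_retro_sd=_WT_SD_R,
        path_length_um=15.0,
        drift_step_px=0.35,
    ),
    "chb3": dict(
        name="chb3",
        duration_min=64.0,
        rate_antero=147.0 / 64.0,
        rate_retro=67.0 / 64.0,
        # Mutant velocity means are not published; fixture values, slower
        # than wild type in both directions (see module docstring).
        v_antero_mean=0.85,
        v_antero_sd=0.45,
        v_retro_mean=0.60,
        v_retro_sd=0.30,
        path_length_um=15.0,
        drift_step_px=0.35,
    ),
    "IFT": dict(
        name="IFT",
        duration_min=6.0,
        rate_antero=8.0,
        rate_retro=0.0,
        # Base anterograde speed ~1 um/s; the profile slows the middle
        # segment to ~0.4 um/s with the junction at 4 um arclength.
        v_antero_mean=1.0,
        v_antero_sd=0.08,
        velocity_profile=[(0.0, 4.0, 0.4), (4.0, 7.5, 1.0)],
        path_length_um=7.5,
        frame_shape=(64, 192),
        drift_step_px=0.0,
    ),
    "stack_wt": dict(name="stack_wt", intensity_scale=1.0),
    "stack_chb3": dict(name="stack_chb3", intensity_scale=0.26),
}

_STACK_PRESET_NAMES = {"stack_wt", "stack_chb3"}


def _from_mapping(data: dict, source: str) -> TransportPreset | StackPreset:
    kind = data.pop("kind", None)
    if kind is None:
        kind = "stack" if "intensity_scale" in data or "region_shape" in data else "transport"
    cls = {"transport": TransportPreset, "stack": StackPreset}.get(kind)
    if cls is None:
        raise ValueError(f"unknown preset kind {kind!r} in {source}")
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown preset field(s) {sorted(unknown)} in {source}")
    if "velocity_profile" in data and data["velocity_profile"] is not None:
        data["velocity_profile"] = [tuple(iv) for iv in data["velocity_profile"]]
    for key in ("frame_shape", "stack_shape", "region_shape"):
        if key in data and data[key] is not None:
            data[key] = tuple(data[key])
    return cls(**data)


def load_preset(name: str) -> TransportPreset | StackPreset:
    """Return a packaged preset by name, or load one from a config file.

    ``name`` is either a packaged preset name (``WT``, ``chb3``, ``IFT``,
    ``stack_wt``, ``stack_chb3``) or a path to a YAML/JSON mapping with
    the preset field names; a ``kind: transport|stack`` key disambiguates
    when needed.  Unknown fields are rejected.
    """
    if name in PACKAGED_PRESETS:
        data = dict(PACKAGED_PRESETS[name])
        if name in _STACK_PRESET_NAMES:
            return StackPreset(**data)
        return TransportPreset(**data)
    path = Path(name)
    if not path.exists():
        raise ValueError(
            f"unknown preset {name!r}: not a packaged preset "
            f"({', '.join(sorted(PACKAGED_PRESETS))}) and no such file"
        )
    text = path.read_text()
    try:
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    except (json.JSONDecodeError, yaml.YAMLError) as exc:
        raise ValueError(f"malformed preset config {path}: {exc}") from exc
    if not isinstance(data, dict):
        raise ValueError(f"preset config {path} must be a mapping of field names")
    return _from_mapping(data, str(path))
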