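"""Synthetic endocytic-patch data with the statistical structure the analysis assumes.

The motion model is the minimal three-phase model reproducing the signatures
the stage detectors rely on:

1. *stationary* — the patch assembles at a fixed cortical site; observed
   positions scatter around it with isotropic localization noise;
2. *directed* — the membrane invaginates and the centroid drifts at constant
   speed in a random fixed direction for a few seconds;
3. *post-scission* — the freed vesicle diffuses (2D Brownian motion with
   per-axis step variance 2·D·dt).

Intensity rises piecewise-linearly from 0 to its peak, reaching the peak at
the stationary→directed boundary (coat proteins reach their maximum exactly
when invagination starts), then decays linearly, with multiplicative Gaussian
noise. A logistic rise is available as an alternative profile.

Every generator is a pure function of its parameters and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd

from .core import Track
from .errors import InvalidTrackError
from .storm import LocalizationCloud

__all__ = [
    "EventParams",
    "TrackTruth",
    "generate_endocytic_track",
    "generate_track_set",
    "generate_nanocage_intensities",
    "generate_storm_cloud",
]

#: Invagination (coat-protein centroid) speeds measured in the two yeasts, nm/s.
BUDDING_SPEED = 23.8
FISSION_SPEED = 51.8


@dataclass
class EventParams:
    """Parameters of one simulated endocytic event.

    Defaults emulate a fission-yeast coat-protein event imaged at 9 Hz: the
    patch is stationary for 30–120 s (drawn uniformly per event when
    ``stationary_duration`` is None), then moves inward at 51.8 nm/s for
    4.5 s, after which the vesicle diffuses. ``localization_sd`` is the
    centroid localization noise per coordinate in nm.
    """

    stationary_duration: float | None = None  # s; None -> draw U(30, 120)
    directed_duration: float = 4.5  # s
    speed: float = FISSION_SPEED  # nm/s
    diffusion_coefficient: float = 4000.0  # nm^2/s, post-scission vesicle
    localization_sd: float = 15.0  # nm per coordinate
    intensity_peak: float = 1000.0  # a.u.
    rise_time: float | None = None  # s; None -> whole stationary phase
    decay_time: float = 10.0  # s, peak -> 0
    intensity_noise_cv: float = 0.1
    frame_interval: float = 1.0 / 9.0  # s
    post_scission_duration: float = 3.0  # s
    intensity_profile: Literal["linear", "logistic"] = "linear"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.stationary_duration is not None and self.stationary_duration <= 0:
            raise ValueError("stationary_duration must be positive")
        for name in ("directed_duration", "post_scission_duration", "frame_interval",
                     "decay_time"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.speed < 0:
            raise ValueError("speed must be non-negative")
        if self.localization_sd < 0:
            raise ValueError("localization_sd must be non-negative")
        if self.diffusion_coefficient < 0:
            raise ValueError("diffusion_coefficient must be non-negative")

    @classmethod
    def fission_like(cls, **overrides) -> "EventParams":
        """Preset: fission-yeast coat event (51.8 nm/s, 9 Hz)."""
        return cls(**{"speed": FISSION_SPEED, **overrides})

    @classmethod
    def budding_like(cls, **overrides) -> "EventParams":
        """Preset: budding-yeast coat event (23.8 nm/s, 9 Hz)."""
        return cls(**{"speed": BUDDING_SPEED, **overrides})


@dataclass
class TrackTruth:
    """Ground truth returned alongside a simulated track."""

    track_id: str
    t_inflection: float  # s, stationary -> directed boundary
    t_scission: float  # s, directed -> diffusive boundary
    speed: float  # nm/s during the directed phase
    stationary_duration: float
    direction: float  # radians
    start_x: float
    start_y: float


def generate_endocytic_track(
    params: EventParams,
    track_id: str = "event_0",
    protein: str = "coat",
    fluorophore: str = "mEGFP",
    start: tuple[float, float] = (0.0, 0.0),
) -> tuple[Track, TrackTruth]:
    """Simulate one endocytic event; returns the track and its ground truth.

    The stationary duration is snapped to the frame grid so the true
    inflection time coincides with a frame.
    """
    rng = np.random.default_rng(params.seed)
    dt = params.frame_interval

    stationary = params.stationary_duration
    if stationary is None:
        stationary = rng.uniform(30.0, 120.0)
    stationary = max(1, round(stationary / dt)) * dt  # truth on the frame grid

    t_scission = stationary + params.directed_duration
    total = t_scission + params.post_scission_duration
    n = int(round(total / dt)) + 1
    times = np.arange(n) * dt

    theta = rng.uniform(0.0, 2.0 * math.pi)
    u = np.array([math.cos(theta), math.sin(theta)])

    # deterministic backbone: stationary, then linear drift capped at scission
    drift = np.clip(times - stationary, 0.0, params.directed_duration)
    base = np.outer(drift * params.speed, u)

    # Brownian increments after scission; partial first step handled exactly
    if params.diffusion_coefficient > 0:
        prev = np.maximum(times[:-1], t_scission)
        step_var = 2.0 * params.diffusion_coefficient * np.maximum(times[1:] - prev, 0.0)
        steps = rng.standard_normal((n - 1, 2)) * np.sqrt(step_var)[:, None]
        base[1:] += np.cumsum(steps, axis=0)

    pos = base + np.asarray(start, dtype=float)
    if params.localization_sd > 0:
        pos = pos + rng.normal(0.0, params.localization_sd, size=(n, 2))

    # intensity: linear (or logistic) rise to the peak at the inflection, then decay
    rise = params.rise_time if params.rise_time is not None else stationary
    rise = min(rise, stationary)
    rising = times <= stationary
    if params.intensity_profile == "logistic":
        # midpoint at stationary - rise/2, ~98% of peak reached at the boundary
        k = 8.0 / rise
        clean_rise = params.intensity_peak / (1.0 + np.exp(-k * (times - (stationary - rise / 2.0))))
    else:
        clean_rise = params.intensity_peak * np.clip((times - (stationary - rise)) / rise, 0.0, 1.0)
    clean_decay = params.intensity_peak * np.clip(1.0 - (times - stationary) / params.decay_time, 0.0, 1.0)
    clean = np.where(rising, clean_rise, clean_decay)

    if params.intensity_noise_cv > 0:
        intensity = clean * (1.0 + params.intensity_noise_cv * rng.standard_normal(n))
        floor = -3.0 * params.intensity_noise_cv * params.intensity_peak
        intensity = np.maximum(intensity, floor)
    else:
        intensity = clean

    track = Track(
        track_id=track_id,
        times=times,
        x=pos[:, 0],
        y=pos[:, 1],
        intensity=intensity,
        frame_interval=dt,
        protein=protein,
        fluorophore=fluorophore,
    )
    truth = TrackTruth(
        track_id=track_id,
        t_inflection=stationary,
        t_scission=t_scission,
        speed=params.speed,
        stationary_duration=stationary,
        direction=theta,
        start_x=start[0],
        start_y=start[1],
    )
    return track, truth


def generate_track_set(
    n: int,
    params: EventParams | None = None,
    between_event_cv: float = 0.05,
    seed: int | None = None,
    roi_size: float = 5000.0,
    protein: str = "coat",
    fluorophore: str = "mEGFP",
) -> tuple[list[Track], pd.DataFrame]:
    """Simulate ``n`` events with event-to-event parameter variability.

    Speed, directed duration and intensity peak are jittered multiplicatively
    by Gaussian factors with the stated CV; stationary durations are drawn per
    event (or jittered when fixed). Start positions scatter uniformly over a
    ``roi_size`` × ``roi_size`` field. Per-event seeds derive deterministically
    from the master seed, so a fixed seed reproduces the full ground-truth
    table bit for bit.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if between_event_cv < 0:
        raise ValueError("between_event_cv must be non-negative")
    base = params if params is not None else EventParams()
    master = base.seed if seed is None else seed
    rng = np.random.default_rng(master)

    tracks: list[Track] = []
    rows: list[dict] = []
    for i in range(n):
        child_seed = int(rng.integers(0, 2**31 - 1))
        jit = lambda: max(1e-6, 1.0 + between_event_cv * rng.standard_normal())  # noqa: E731
        ev = replace(
            base,
            speed=base.speed * jit(),
            directed_duration=base.directed_duration * jit(),
            intensity_peak=base.intensity_peak * jit(),
            stationary_duration=(
                None if base.stationary_duration is None else base.stationary_duration * jit()
            ),
            seed=child_seed,
        )
        start = tuple(rng.uniform(0.0, roi_size, size=2))
        track, truth = generate_endocytic_track(
            ev, track_id=f"event_{i:03d}", protein=protein,
            fluorophore=fluorophore, start=start,
        )
        tracks.append(track)
        rows.append(
            {
                "track_id": truth.track_id,
                "t_inflection": truth.t_inflection,
                "t_scission": truth.t_scission,
                "speed": truth.speed,
                "stationary_duration": truth.stationary_duration,
                "direction": truth.direction,
                "start_x": truth.start_x,
                "start_y": truth.start_y,
            }
        )
    return tracks, pd.DataFrame(rows)


def generate_nanocage_intensities(
    n: int, mean: float = 1000.0, sd: float = 150.0, seed: int = 0
) -> np.ndarray:
    """Gaussian intensities of a fluorescent calibration particle, truncated at 0."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if mean <= 0:
        raise ValueError("mean must be positive")
    if sd < 0:
        raise ValueError("sd must be non-negative")
    rng = np.random.default_rng(seed)
    values = rng.normal(mean, sd, size=n) if sd > 0 else np.full(n, float(mean))
    return np.maximum(values, 0.0)


def generate_storm_cloud(
    length: float,
    width: float = 40.0,
    n_points: int = 150,
    angle: float = 0.0,
    localization_sd: float = 10.0,
    pixel_size: float = 160.0,
    seed: int = 0,
    label: str = "rod",
    include_endpoints: bool = True,
) -> LocalizationCloud:
    """A rod-like localization cloud: points uniform along a length × width
    rectangle rotated by ``angle`` degrees, plus isotropic localization noise.

    Lengths/widths/noise are in nm; the returned coordinates are in pixels
    (``pixel_size`` nm per pixel), matching reconstructed-image conventions.
    With ``include_endpoints`` the first two points sit exactly on the rod
    tips, so a noise-free axis-aligned cloud has extent exactly ``length``.
    """
    if length <= 0:
        raise ValueError("length must be positive")
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    rng = np.random.default_rng(seed)
    xs = rng.uniform(-length / 2.0, length / 2.0, size=n_points)
    ys = rng.uniform(-width / 2.0, width / 2.0, size=n_points) if width > 0 else np.zeros(n_points)
    if include_endpoints:
        xs[0], ys[0] = -length / 2.0, 0.0
        xs[1], ys[1] = length / 2.0, 0.0
    pts = np.column_stack([xs, ys])
    a = math.radians(angle)
    rot = np.array([[math.cos(a), -math.sin(a)], [math.sin(a), math.cos(a)]])
    pts = pts @ rot.T
    if localization_sd > 0:
        pts = pts + rng.normal(0.0, localization_sd, size=pts.shape)
    return LocalizationCloud(points=pts / pixel_size, pixel_size=pixel_size, label=label)
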