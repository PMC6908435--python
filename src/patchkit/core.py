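"""Domain types and elementary per-track series computations.

A :class:`Track` is the time series produced by centroid particle tracking of
one endocytic patch: centroid position (nm), background-subtracted fluorescence
intensity (a.u.) and time (s) sampled at a nominally fixed frame interval.
Positions are stored in nanometres; conversion from camera pixels happens once,
at load time (see :mod:`patchkit.trackio`), so no downstream code mixes units.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .errors import InvalidTrackError

__all__ = [
    "Track",
    "DisplacementSeries",
    "AlignmentReference",
    "AlignedEnsemble",
    "frame_displacements",
    "displacement_from_origin",
]


def _as_float_array(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise InvalidTrackError(f"{name} must be one-dimensional, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise InvalidTrackError(f"{name} contains non-finite values")
    return arr


@dataclass(eq=False)
class Track:
    """One patch's centroid trajectory and intensity time course.

    Parameters
    ----------
    track_id : str
        Identifier, unique within a movie.
    times : array of float
        Acquisition times in seconds, strictly increasing and uniform to
        within half a frame interval.
    x, y : array of float
        Centroid position in nanometres (image convention: y increases
        downward; only relative displacements matter downstream).
    intensity : array of float
        Background-subtracted fluorescence (a.u.); may dip below zero from
        noise but the peak must be positive.
    frame_interval : float
        Nominal time between frames in seconds.
    protein, fluorophore : str
        Labels used for alignment-mode selection and brightness correction.
    """

    track_id: str
    times: np.ndarray
    x: np.ndarray
    y: np.ndarray
    intensity: np.ndarray
    frame_interval: float
    protein: str = ""
    fluorophore: str = "GFP"

    def __post_init__(self) -> None:
        self.times = _as_float_array(self.times, "times")
        self.x = _as_float_array(self.x, "x")
        self.y = _as_float_array(self.y, "y")
        self.intensity = _as_float_array(self.intensity, "intensity")
        n = len(self.times)
        if n < 3:
            raise InvalidTrackError(f"track {self.track_id!r}: fewer than 3 time points")
        for name in ("x", "y", "intensity"):
            if len(getattr(self, name)) != n:
                raise InvalidTrackError(
                    f"track {self.track_id!r}: {name} length differs from times"
                )
        if self.frame_interval <= 0:
            raise InvalidTrackError(f"track {self.track_id!r}: non-positive frame interval")
        dt = np.diff(self.times)
        if np.any(dt <= 0):
            raise InvalidTrackError(f"track {self.track_id!r}: times not strictly increasing")
        if np.any(np.abs(dt - self.frame_interval) >= 0.5 * self.frame_interval):
            raise InvalidTrackError(
                f"track {self.track_id!r}: non-uniform sampling beyond half a frame interval"
            )
        if self.intensity.max() <= 0:
            raise InvalidTrackError(f"track {self.track_id!r}: non-positive peak intensity")

    def __len__(self) -> int:
        return len(self.times)

    def __eq__(self, other) -> bool:
        if not isinstance(other, Track):
            return NotImplemented
        return (
            self.track_id == other.track_id
            and self.protein == other.protein
            and self.fluorophore == other.fluorophore
            and np.isclose(self.frame_interval, other.frame_interval)
            and all(
                np.array_equal(getattr(self, f), getattr(other, f))
                for f in ("times", "x", "y", "intensity")
            )
        )

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    def positions(self) -> np.ndarray:
        """(n, 2) array of centroid positions in nm."""
        return np.column_stack([self.x, self.y])


DisplacementKind = Literal["frame_by_frame", "from_origin"]


@dataclass
class DisplacementSeries:
    """A non-negative displacement series derived from a track.

    ``kind="frame_by_frame"`` holds the Euclidean step between consecutive
    centroid positions (one value per frame pair); ``kind="from_origin"``
    holds the distance of each position from the track's first position.
    """

    times: np.ndarray
    values: np.ndarray
    kind: DisplacementKind

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise InvalidTrackError("displacement times/values length mismatch")
        if np.any(self.values < 0):
            raise InvalidTrackError("displacements must be non-negative")
        if self.kind == "from_origin" and self.values[0] != 0.0:
            raise InvalidTrackError("from-origin displacement must start at zero")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class AlignmentReference:
    """The per-track time origin used for ensemble alignment.

    ``mode="inflection"`` marks the stationary-to-directed motion transition
    (onset of membrane invagination for coat proteins); ``mode="half_max"``
    marks the rising 50%-of-peak intensity crossing (used for actin markers).
    ``t_ref`` is on the track's own clock. ``flagged`` is set when the
    reference is a fallback (e.g. intensity already above half-max at the
    first frame).
    """

    track_id: str
    mode: Literal["inflection", "half_max"]
    t_ref: float
    flagged: bool = False


@dataclass
class AlignedEnsemble:
    """Per-relative-time mean/SD of rescaled intensity and displacement.

    Bins not covered by at least ``n_min`` tracks hold NaN; ``n_per_bin``
    records coverage. Intensity is rescaled per track to its own maximum, so
    the ensemble mean never exceeds 1 (up to interpolation tolerance).
    Displacement is measured from each track's position at its alignment
    reference, so the ensemble displacement is ~0 at relative time 0.
    """

    rel_times: np.ndarray
    mean_intensity: np.ndarray
    sd_intensity: np.ndarray
    mean_displacement: np.ndarray
    sd_displacement: np.ndarray
    n_per_bin: np.ndarray
    mode: str = ""

    def __post_init__(self) -> None:
        self.rel_times = np.asarray(self.rel_times, dtype=float)
        for name in ("mean_intensity", "sd_intensity", "mean_displacement", "sd_displacement"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != self.rel_times.shape:
                raise InvalidTrackError(f"ensemble field {name} length mismatch")
            setattr(self, name, arr)
        self.n_per_bin = np.asarray(self.n_per_bin, dtype=int)
        if self.n_per_bin.shape != self.rel_times.shape:
            raise InvalidTrackError("ensemble n_per_bin length mismatch")
        defined = np.isfinite(self.mean_intensity) | np.isfinite(self.mean_displacement)
        if np.any(self.n_per_bin[defined] < 1):
            raise InvalidTrackError("ensemble has defined bins with zero coverage")
        for name in ("sd_intensity", "sd_displacement"):
            arr = getattr(self, name)
            if np.any(arr[np.isfinite(arr)] < 0):
                raise InvalidTrackError(f"{name} must be non-negative")

    def __len__(self) -> int:
        return len(self.rel_times)


def frame_displacements(track: Track) -> DisplacementSeries:
    """Euclidean distance between consecutive centroid positions, in nm.

    The i-th value is the step from frame i to frame i+1 and is stamped with
    the later frame's time, so the series has ``len(track) - 1`` entries.
    """
    if len(track) < 2:
        raise InvalidTrackError("frame displacements need at least 2 points")
    values = np.hypot(np.diff(track.x), np.diff(track.y))
    return DisplacementSeries(times=track.times[1:], values=values, kind="frame_by_frame")


def displacement_from_origin(track: Track) -> DisplacementSeries:
    """Distance of each centroid position from the track's first position, nm."""
    values = np.hypot(track.x - track.x[0], track.y - track.y[0])
    values[0] = 0.0  # exact by construction
    return DisplacementSeries(times=track.times.copy(), values=values, kind="from_origin")
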