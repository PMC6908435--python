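"""Read/write trajectory, ensemble and localization data.

Two trajectory input dialects are supported:

* the text report of the ImageJ Particle Tracker plugin — per-trajectory
  blocks headed by ``%% Trajectory N`` with whitespace-separated rows of
  ``frame x y intensity [...]`` (extra moment columns are ignored);
* a headered CSV with columns ``track_id, frame, x_px, y_px, intensity``.

File coordinates are pixels with the image origin at the top left and y
increasing downward (the plugin's convention); they are converted once, at
load, to nanometres via a :class:`PixelScale`, and frames to seconds via the
frame interval. The package's own track CSV (written by :func:`write_tracks`)
stores nanometres and seconds and round-trips losslessly.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import AlignedEnsemble, Track
from .errors import InvalidTrackError, TrackFormatError
from .storm import LocalizationCloud

__all__ = [
    "PixelScale",
    "LoadReport",
    "read_particle_tracker",
    "read_tracks",
    "write_tracks",
    "write_ensemble",
    "read_ensemble",
    "read_localizations",
    "write_localizations",
]

logger = logging.getLogger(__name__)

#: Effective camera pixel size of the live-imaging setup, nm.
LIVE_PIXEL_NM = 65.0
#: Pixel size of reconstructed STORM images, nm.
STORM_PIXEL_NM = 160.0


@dataclass(frozen=True)
class PixelScale:
    """Conversion between camera pixels and nanometres."""

    nm_per_pixel: float = LIVE_PIXEL_NM

    def __post_init__(self) -> None:
        if self.nm_per_pixel <= 0:
            raise ValueError("nm_per_pixel must be positive")

    def to_nm(self, pixels) -> np.ndarray:
        return np.asarray(pixels, dtype=float) * self.nm_per_pixel


@dataclass
class LoadReport:
    """What a trajectory load kept and dropped, with reasons."""

    n_read: int = 0
    dropped: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n_kept(self) -> int:
        return self.n_read - len(self.dropped)


_TRAJ_HEADER = re.compile(r"^%+\s*Trajectory\s+(\d+)", re.IGNORECASE)


def _build_track(
    track_id: str,
    rows: list[tuple[float, float, float, float]],
    scale: PixelScale,
    frame_interval: float,
) -> Track:
    rows = sorted(rows, key=lambda r: r[0])
    frames = np.array([r[0] for r in rows])
    return Track(
        track_id=track_id,
        times=frames * frame_interval,
        x=scale.to_nm([r[1] for r in rows]),
        y=scale.to_nm([r[2] for r in rows]),
        intensity=np.array([r[3] for r in rows]),
        frame_interval=frame_interval,
    )


def _collect(
    blocks: dict[str, list[tuple[float, float, float, float]]],
    scale: PixelScale,
    frame_interval: float,
) -> tuple[list[Track], LoadReport]:
    report = LoadReport(n_read=len(blocks))
    tracks: list[Track] = []
    for track_id, rows in blocks.items():
        try:
            tracks.append(_build_track(track_id, rows, scale, frame_interval))
        except InvalidTrackError as exc:
            reason = str(exc)
            report.dropped.append((track_id, reason))
            logger.info("dropped track %s at load: %s", track_id, reason)
    return tracks, report


def _parse_particle_tracker_text(
    lines: list[str],
) -> dict[str, list[tuple[float, float, float, float]]]:
    blocks: dict[str, list[tuple[float, float, float, float]]] = {}
    current: str | None = None
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        header = _TRAJ_HEADER.match(line)
        if header:
            current = header.group(1)
            blocks.setdefault(current, [])
            continue
        if line.startswith(("%", "#")):
            continue  # other report commentary
        if current is None:
            raise TrackFormatError(f"line {lineno}: data before any trajectory header")
        fields = line.split()
        if len(fields) < 4:
            raise TrackFormatError(f"line {lineno}: expected at least 4 columns, got {len(fields)}")
        try:
            frame, x, y, intensity = (float(v) for v in fields[:4])
        except ValueError as exc:
            raise TrackFormatError(f"line {lineno}: non-numeric value ({exc})") from None
        if frame < 0:
            raise TrackFormatError(f"line {lineno}: negative frame number {frame:g}")
        blocks[current].append((frame, x, y, intensity))
    return blocks


def read_particle_tracker(
    path: str | Path,
    scale: PixelScale,
    frame_interval: float,
) -> tuple[list[Track], LoadReport]:
    """Load tracks from a Particle Tracker report or the pixel-CSV dialect.

    Positions are converted to nm and frames to seconds. Trajectories
    violating the track invariants (too short, non-positive peak intensity,
    missing frames) are dropped; each drop is logged and listed in the
    returned :class:`LoadReport`.
    """
    path = Path(path)
    text = path.read_text()
    first = next((ln for ln in text.splitlines() if ln.strip()), "")
    if "track_id" in first and "," in first:
        df = pd.read_csv(path)
        required = {"track_id", "frame", "x_px", "y_px", "intensity"}
        missing = required - set(df.columns)
        if missing:
            raise TrackFormatError(f"CSV missing columns: {sorted(missing)}")
        if (df["frame"] < 0).any():
            raise TrackFormatError("negative frame numbers in CSV")
        blocks = {
            str(tid): list(
                zip(sub["frame"].astype(float), sub["x_px"], sub["y_px"], sub["intensity"])
            )
            for tid, sub in df.groupby("track_id", sort=False)
        }
    else:
        blocks = _parse_particle_tracker_text(text.splitlines())
    return _collect(blocks, scale, frame_interval)


_TRACK_COLUMNS = [
    "track_id", "protein", "fluorophore", "frame",
    "time_s", "x_nm", "y_nm", "intensity", "frame_interval_s",
]


def write_tracks(tracks: list[Track], path: str | Path) -> None:
    """Write tracks as CSV, one row per (track, frame), losslessly (nm, s)."""
    rows = []
    for tr in tracks:
        for i in range(len(tr)):
            rows.append(
                (
                    tr.track_id, tr.protein, tr.fluorophore, i,
                    tr.times[i], tr.x[i], tr.y[i], tr.intensity[i], tr.frame_interval,
                )
            )
    df = pd.DataFrame(rows, columns=_TRACK_COLUMNS)
    df.to_csv(path, index=False, float_format="%.17g")


def read_tracks(path: str | Path) -> list[Track]:
    """Read the CSV written by :func:`write_tracks` (already in nm and s)."""
    df = pd.read_csv(path, dtype={"track_id": str}, float_precision="round_trip")
    missing = set(_TRACK_COLUMNS) - set(df.columns)
    if missing:
        raise TrackFormatError(f"track CSV missing columns: {sorted(missing)}")
    tracks = []
    for tid, sub in df.groupby("track_id", sort=False):
        sub = sub.sort_values("frame")
        tracks.append(
            Track(
                track_id=str(tid),
                times=sub["time_s"].to_numpy(),
                x=sub["x_nm"].to_numpy(),
                y=sub["y_nm"].to_numpy(),
                intensity=sub["intensity"].to_numpy(),
                frame_interval=float(sub["frame_interval_s"].iloc[0]),
                protein=str(sub["protein"].iloc[0]) if pd.notna(sub["protein"].iloc[0]) else "",
                fluorophore=(
                    str(sub["fluorophore"].iloc[0]) if pd.notna(sub["fluorophore"].iloc[0]) else ""
                ),
            )
        )
    return tracks


def write_ensemble(ensemble: AlignedEnsemble, path: str | Path) -> None:
    """Write an aligned ensemble as CSV, one row per relative-time bin."""
    pd.DataFrame(
        {
            "rel_time_s": ensemble.rel_times,
            "mean_intensity": ensemble.mean_intensity,
            "sd_intensity": ensemble.sd_intensity,
            "mean_displacement_nm": ensemble.mean_displacement,
            "sd_displacement_nm": ensemble.sd_displacement,
            "n": ensemble.n_per_bin,
        }
    ).to_csv(path, index=False, float_format="%.17g")


def read_ensemble(path: str | Path, mode: str = "") -> AlignedEnsemble:
    df = pd.read_csv(path, float_precision="round_trip")
    return AlignedEnsemble(
        rel_times=df["rel_time_s"].to_numpy(),
        mean_intensity=df["mean_intensity"].to_numpy(),
        sd_intensity=df["sd_intensity"].to_numpy(),
        mean_displacement=df["mean_displacement_nm"].to_numpy(),
        sd_displacement=df["sd_displacement_nm"].to_numpy(),
        n_per_bin=df["n"].to_numpy(),
        mode=mode,
    )


def write_localizations(cloud: LocalizationCloud, path: str | Path) -> None:
    """Write a localization list as CSV (x_px, y_px[, z_px])."""
    cols = ["x_px", "y_px", "z_px"][: cloud.points.shape[1]]
    pd.DataFrame(cloud.points, columns=cols).to_csv(path, index=False, float_format="%.17g")


def read_localizations(
    path: str | Path, pixel_size: float = STORM_PIXEL_NM, label: str = ""
) -> LocalizationCloud:
    """Read a localization CSV into a cloud with the given pixel scale."""
    df = pd.read_csv(path, float_precision="round_trip")
    cols = [c for c in ("x_px", "y_px", "z_px") if c in df.columns]
    if len(cols) < 2:
        raise TrackFormatError("localization CSV needs x_px and y_px columns")
    return LocalizationCloud(
        points=df[cols].to_numpy(dtype=float), pixel_size=pixel_size,
        label=label or Path(path).stem,
    )
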