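"""Length measurement of endocytic structures from STORM localization clouds.

A :class:`LocalizationCloud` is the single-molecule position list of one
pre-cropped endocytic structure from a reconstructed STORM image, in pixel
units (160 nm per pixel by default). Two length rules are provided:

* :func:`structure_length` — the invagination-length rule: the structure is
  first rotated so its long axis is horizontal, then the longest Euclidean
  distance is taken over point pairs whose y-coordinates differ by at most a
  small threshold (0.01 px by default). If no pair satisfies the threshold it
  is doubled (and logged) until one does.
* :func:`longest_axis` — the vesicle rule: the longest pairwise distance with
  no y constraint.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .errors import DegenerateInputError

__all__ = [
    "LocalizationCloud",
    "rotate_cloud",
    "structure_length",
    "longest_axis",
    "measure_structures",
]

logger = logging.getLogger(__name__)


@dataclass
class LocalizationCloud:
    """A STORM point set for one endocytic structure.

    ``points`` is (n, 2) or (n, 3) in pixels; ``pixel_size`` converts to nm.
    z coordinates are carried but ignored by the 2D length rules unless
    explicitly requested.
    """

    points: np.ndarray
    pixel_size: float = 160.0
    label: str = ""

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.shape[1] not in (2, 3):
            raise ValueError("points must have 2 or 3 columns (x, y[, z])")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def xy(self) -> np.ndarray:
        return self.points[:, :2]


def rotate_cloud(cloud: LocalizationCloud, angle: float | str = "auto") -> LocalizationCloud:
    """Rotate the cloud in the xy plane about its centroid.

    ``angle="auto"`` aligns the principal axis of the xy covariance with the
    x-axis (the orientation step applied before the invagination-length rule).
    An explicit angle is in degrees, counter-clockwise.
    """
    if len(cloud) < 2:
        raise DegenerateInputError("rotation needs at least 2 points")
    xy = cloud.xy
    centroid = xy.mean(axis=0)
    centred = xy - centroid
    if isinstance(angle, str):
        if angle != "auto":
            raise ValueError(f"unknown angle mode {angle!r}")
        cov = np.cov(centred.T)
        if not np.any(np.abs(centred) > 1e-12):
            raise DegenerateInputError("all points identical: principal axis undefined")
        evals, evecs = np.linalg.eigh(cov)
        major = evecs[:, int(np.argmax(evals))]
        theta = -math.atan2(major[1], major[0])
    else:
        theta = math.radians(float(angle))
    rot = np.array([[math.cos(theta), -math.sin(theta)], [math.sin(theta), math.cos(theta)]])
    new_xy = centred @ rot.T + centroid
    pts = cloud.points.copy()
    pts[:, :2] = new_xy
    return LocalizationCloud(points=pts, pixel_size=cloud.pixel_size, label=cloud.label)


def structure_length(
    cloud: LocalizationCloud,
    y_threshold: float = 0.01,
    use_z: bool = False,
    _return_threshold: bool = False,
):
    """Invagination length in nm of a horizontally oriented cloud.

    Maximum Euclidean distance over all point pairs whose |Δy| is at most
    ``y_threshold`` (pixels). The threshold doubles automatically (logged)
    whenever no pair qualifies, so a result is always produced.
    """
    if len(cloud) < 2:
        raise DegenerateInputError("length measurement needs at least 2 points")
    if y_threshold <= 0:
        raise ValueError("y_threshold must be positive")
    pts = cloud.points if use_z and cloud.points.shape[1] == 3 else cloud.xy
    dy = np.abs(cloud.xy[:, 1][:, None] - cloud.xy[:, 1][None, :])
    dist = squareform(pdist(pts))
    thr = float(y_threshold)
    while True:
        mask = dy <= thr
        np.fill_diagonal(mask, False)
        if mask.any():
            break
        thr *= 2.0
        logger.info(
            "cloud %s: no pair within |dy| <= %g px, doubling threshold to %g",
            cloud.label, thr / 2.0, thr,
        )
    length = float(dist[mask].max()) * cloud.pixel_size
    if _return_threshold:
        return length, thr
    return length


def longest_axis(cloud: LocalizationCloud, use_z: bool = False) -> float:
    """Longest pairwise Euclidean distance in nm (the vesicle-axis rule)."""
    if len(cloud) < 2:
        raise DegenerateInputError("length measurement needs at least 2 points")
    pts = cloud.points if use_z and cloud.points.shape[1] == 3 else cloud.xy
    return float(pdist(pts).max()) * cloud.pixel_size


def measure_structures(
    clouds: list[LocalizationCloud],
    y_threshold: float = 0.01,
    auto_rotate: bool = True,
) -> pd.DataFrame:
    """Rotate and measure a batch of structures.

    Returns one row per cloud: label, length_nm, longest_axis_nm, n_points
    and the |Δy| threshold actually used (after any doubling).
    """
    rows = []
    for cloud in clouds:
        oriented = rotate_cloud(cloud, "auto") if auto_rotate else cloud
        length, thr = structure_length(oriented, y_threshold, _return_threshold=True)
        rows.append(
            {
                "label": cloud.label,
                "length_nm": length,
                "longest_axis_nm": longest_axis(cloud),
                "n_points": len(cloud),
                "threshold_used_px": thr,
            }
        )
    return pd.DataFrame(rows)
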