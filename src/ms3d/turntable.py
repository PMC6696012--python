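"""Turntable rotation-axis self-calibration from colored calibration stickers.

Two small stickers (yellow and red) sit off-center on the table surface.
Observing their 3D centroids at table rotations 0 and 180 degrees gives two
chords of circles centered on the rotation axis: for a half-turn, each
chord's midpoint lies exactly on the axis.  The axis center M is the mean of
the two midpoints; the axis direction P is the normal of the table plane
through the four sticker centers, oriented toward the camera's +Y.
"""

from __future__ import annotations

from dataclasses import dataclass
import json

import numpy as np
from skimage.color import rgb2hsv

from ms3d.pointcloud import SpectralPointCloud

__all__ = [
    "ColorSpec",
    "RotaryCalibration",
    "YELLOW",
    "RED",
    "detect_sticker_center",
    "estimate_axis",
    "estimate_axis_views",
    "calibrate_from_views",
]


class StickerDetectionError(RuntimeError):
    """Too few points matched the sticker color threshold."""


class DegenerateGeometryError(ValueError):
    """Sticker geometry cannot constrain the axis (collinear or on-axis)."""


@dataclass(frozen=True)
class ColorSpec:
    """HSV threshold defining one sticker color.

    Hue is in [0, 1); ``h_range`` may wrap around 1 (e.g. red: (0.95, 0.05)).
    """

    h_range: tuple[float, float]
    s_min: float = 0.35
    v_min: float = 0.25

    def mask(self, rgb: np.ndarray) -> np.ndarray:
        """Boolean mask over an (N, 3) uint8 RGB array."""
        hsv = rgb2hsv(rgb.reshape(-1, 1, 3).astype(float) / 255.0).reshape(-1, 3)
        h, s, v = hsv.T
        lo, hi = self.h_range
        if lo <= hi:
            hue_ok = (h >= lo) & (h <= hi)
        else:  # wrap-around
            hue_ok = (h >= lo) | (h <= hi)
        return hue_ok & (s >= self.s_min) & (v >= self.v_min)


#: Default sticker colors (disjoint hue bands).
YELLOW = ColorSpec(h_range=(0.10, 0.22))
RED = ColorSpec(h_range=(0.95, 0.04))


@dataclass(frozen=True)
class RotaryCalibration:
    """Turntable axis: center M (meters, camera frame), unit normal P, and the
    RMS plane residual of the sticker centers (meters)."""

    center: np.ndarray
    normal: np.ndarray
    residual: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "center", np.asarray(self.center, float).reshape(3))
        object.__setattr__(self, "normal", np.asarray(self.normal, float).reshape(3))
        if abs(np.linalg.norm(self.normal) - 1.0) > 1e-9:
            raise ValueError("normal must be unit length")
        if self.residual < 0:
            raise ValueError("residual must be >= 0")

    def to_json(self, **meta) -> str:
        return json.dumps(
            {
                "center_m": self.center.tolist(),
                "normal": self.normal.tolist(),
                "residual_m": self.residual,
                **meta,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "RotaryCalibration":
        d = json.loads(text)
        return cls(
            center=np.array(d["center_m"]),
            normal=np.array(d["normal"]),
            residual=d["residual_m"],
        )


def detect_sticker_center(
    cloud: SpectralPointCloud, spec: ColorSpec, min_points: int = 20
) -> tuple[np.ndarray, int]:
    """Centroid of the cloud points passing the sticker color threshold.

    Returns ``(center_xyz, inlier_count)``; raises
    :class:`StickerDetectionError` when fewer than ``min_points`` match.
    """
    mask = spec.mask(cloud.rgb)
    n = int(mask.sum())
    if n < min_points:
        raise StickerDetectionError(
            f"only {n} points matched the color threshold (need >= {min_points})"
        )
    return cloud.xyz[mask].mean(axis=0), n


def _plane_normal_cross(y1, r1, y2, r2, center) -> np.ndarray:
    n1 = np.cross(r1 - center, y1 - center)
    n2 = np.cross(r2 - center, y2 - center)
    n1 /= np.linalg.norm(n1)
    n2 /= np.linalg.norm(n2)
    if np.dot(n1, n2) < 0:
        n2 = -n2
    n = n1 + n2
    return n / np.linalg.norm(n)


def estimate_axis(
    y1: np.ndarray, r1: np.ndarray, y2: np.ndarray, r2: np.ndarray
) -> RotaryCalibration:
    """Axis from sticker centers at table rotations 0 (y1, r1) and 180
    degrees (y2, r2).

    M is the mean of midpoint(y1, y2) and midpoint(r1, r2); each midpoint
    lies on the axis because a half-turn maps a sticker to its antipode on
    its circle.  The normal is the average of the cross products
    (r1-M)x(y1-M) and (r2-M)x(y2-M), re-oriented so its angle with the
    camera +Y axis is acute; the residual is the RMS distance of the four
    sticker centers from the plane through their centroid.
    """
    y1, r1, y2, r2 = (np.asarray(p, float).reshape(3) for p in (y1, r1, y2, r2))
    if np.linalg.norm(y1 - y2) < 5e-3 or np.linalg.norm(r1 - r2) < 5e-3:
        raise DegenerateGeometryError(
            "sticker lies on (or too near) the rotation axis"
        )
    pts = np.stack([y1, r1, y2, r2])
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    # collinearity: RMS perpendicular distance from the best-fit line
    _, sv, _ = np.linalg.svd(centered, full_matrices=False)
    if np.sqrt((sv[1] ** 2 + sv[2] ** 2) / 4.0) < 1e-3:
        raise DegenerateGeometryError("sticker centers are nearly collinear")

    center = 0.5 * ((y1 + y2) / 2.0 + (r1 + r2) / 2.0)
    normal = _plane_normal_cross(y1, r1, y2, r2, center)
    if normal[1] < 0:
        normal = -normal
    residual = float(np.sqrt(np.mean((centered @ normal) ** 2)))
    return RotaryCalibration(center=center, normal=normal, residual=residual)


def estimate_axis_views(
    pairs: list[tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]],
) -> RotaryCalibration:
    """Least-squares axis over several 180-degree-separated sticker pairs.

    ``pairs`` is a list of (y_at_g, r_at_g, y_at_g+180, r_at_g+180) tuples.
    All midpoints are averaged into M; the normal is the smallest-variance
    direction (SVD) of all sticker centers, +Y oriented.
    """
    if not pairs:
        raise ValueError("need at least one 180-degree pair")
    if len(pairs) == 1:
        return estimate_axis(*pairs[0])
    mids = []
    allpts = []
    for y1, r1, y2, r2 in pairs:
        y1, r1, y2, r2 = (np.asarray(p, float).reshape(3) for p in (y1, r1, y2, r2))
        mids.append((y1 + y2) / 2.0)
        mids.append((r1 + r2) / 2.0)
        allpts.extend([y1, r1, y2, r2])
    center = np.mean(mids, axis=0)
    pts = np.stack(allpts)
    centered = pts - pts.mean(axis=0)
    _, sv, vt = np.linalg.svd(centered, full_matrices=False)
    if np.sqrt((sv[1] ** 2 + sv[2] ** 2) / len(pts)) < 1e-3:
        raise DegenerateGeometryError("sticker centers are nearly collinear")
    normal = vt[2]
    if normal[1] < 0:
        normal = -normal
    residual = float(np.sqrt(np.mean((centered @ normal) ** 2)))
    return RotaryCalibration(center=center, normal=normal, residual=residual)


def calibrate_from_views(
    cloud_0: SpectralPointCloud,
    cloud_180: SpectralPointCloud,
    yellow: ColorSpec = YELLOW,
    red: ColorSpec = RED,
    min_points: int = 20,
) -> tuple[RotaryCalibration, dict]:
    """Full self-calibration from two RGB-D views of the bare table.

    Detects both sticker centroids in each view and estimates the axis.
    Returns the calibration and a diagnostics dict (inlier counts).
    """
    y1, ny1 = detect_sticker_center(cloud_0, yellow, min_points)
    r1, nr1 = detect_sticker_center(cloud_0, red, min_points)
    y2, ny2 = detect_sticker_center(cloud_180, yellow, min_points)
    r2, nr2 = detect_sticker_center(cloud_180, red, min_points)
    calib = estimate_axis(y1, r1, y2, r2)
    info = {
        "inliers": {"yellow_0": ny1, "red_0": nr1, "yellow_180": ny2, "red_180": nr2}
    }
    return calib, info
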