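"""Point-cloud geometry: unprojection, turntable rough registration, ICP, fusion.

The reconstruction chain mirrors the physical rig.  Each depth image is
unprojected through the pinhole intrinsics to a camera-frame cloud; the
turntable calibration (axis center M and unit normal P) then moves every view
into a common "table" frame — translate by -M, rotate the axis normal onto
+Y with one rotation about X and one about Z, and finally undo the table spin
with a rotation about Y (the rough registration).  Sequential pairwise ICP
refines the alignment before the views are concatenated and voxel-downsampled
into the fused multispectral model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "BAND_NAMES",
    "CameraIntrinsics",
    "SpectralPointCloud",
    "ViewPose",
    "RoiBox",
    "unproject",
    "project",
    "common_frame_matrix",
    "to_common_frame",
    "crop_roi",
    "remove_outliers",
    "icp",
    "voxel_downsample",
    "fuse_views",
    "extract_canopy",
    "apply_rigid",
]

#: Reflectance band order used throughout (columns of ``reflectance``).
BAND_NAMES = ("blue", "green", "red", "rededge", "nir")

#: Band centers in nm for the default five-band configuration.
BAND_CENTERS_NM = {
    "blue": 466.93,
    "green": 564.91,
    "red": 696.32,
    "rededge": 722.94,
    "nir": 841.4,
}

#: Depth-sensor trusted range in meters; readings outside are invalid.
DEPTH_RANGE_M = (0.50, 4.50)


class DegenerateAxisError(ValueError):
    """Turntable axis (nearly) parallel to the camera X axis."""


class NoOverlapError(RuntimeError):
    """ICP found zero gated correspondences at the initial pose."""


@dataclass(frozen=True)
class CameraIntrinsics:
    """Pinhole intrinsics: principal point (c_x, c_y) and focal lengths."""

    cx: float
    cy: float
    fx: float
    fy: float

    def __post_init__(self) -> None:
        if self.fx <= 0 or self.fy <= 0:
            raise ValueError("focal lengths must be positive")


@dataclass(frozen=True)
class ViewPose:
    """Turntable pose of one view: index and inverse spin angle gamma.

    gamma = view_index * 360 / n_views * spin_sign (degrees).
    """

    view_index: int
    gamma_deg: float

    @classmethod
    def from_index(
        cls, view_index: int, n_views: int, spin_sign: int = 1
    ) -> "ViewPose":
        return cls(view_index, view_index * 360.0 / n_views * spin_sign)


@dataclass(frozen=True)
class RoiBox:
    """Axis-aligned crop box in meters, (min, max) per axis."""

    x: tuple[float, float]
    y: tuple[float, float]
    z: tuple[float, float]

    def __post_init__(self) -> None:
        for lo, hi in (self.x, self.y, self.z):
            if not lo < hi:
                raise ValueError("RoiBox min must be < max on every axis")


@dataclass
class SpectralPointCloud:
    """Columnar point cloud: geometry plus color, reflectance and provenance.

    Attributes
    ----------
    xyz : (N, 3) float64, meters.
    rgb : (N, 3) uint8.
    reflectance : (N, 5) float64 in [0, 1] or NaN, columns ordered as
        :data:`BAND_NAMES`.
    pixel : (N, 2) int32, source (i=column, j=row) in the originating depth
        image, or -1 after fusion destroys provenance.
    view_id : (N,) int32.
    extra : str -> (N,) float64; per-point derived attributes (vegetation
        indices, predicted SPAD, ...).
    """

    xyz: np.ndarray
    rgb: np.ndarray | None = None
    reflectance: np.ndarray | None = None
    pixel: np.ndarray | None = None
    view_id: np.ndarray | None = None
    extra: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float).reshape(-1, 3)
        n = len(self.xyz)
        if not np.isfinite(self.xyz).all():
            raise ValueError("xyz must be finite")
        if self.rgb is None:
            self.rgb = np.zeros((n, 3), dtype=np.uint8)
        self.rgb = np.asarray(self.rgb, dtype=np.uint8).reshape(-1, 3)
        if self.reflectance is None:
            self.reflectance = np.full((n, len(BAND_NAMES)), np.nan)
        self.reflectance = np.asarray(self.reflectance, dtype=float).reshape(
            -1, len(BAND_NAMES)
        )
        if self.pixel is None:
            self.pixel = np.full((n, 2), -1, dtype=np.int32)
        self.pixel = np.asarray(self.pixel, dtype=np.int32).reshape(-1, 2)
        if self.view_id is None:
            self.view_id = np.zeros(n, dtype=np.int32)
        self.view_id = np.asarray(self.view_id, dtype=np.int32).reshape(-1)
        for arr in (self.rgb, self.reflectance, self.pixel, self.view_id):
            if len(arr) != n:
                raise ValueError("attribute arrays must match xyz length")
        for k in self.extra:
            self.extra[k] = np.asarray(self.extra[k], dtype=float).reshape(-1)
            if len(self.extra[k]) != n:
                raise ValueError(f"extra[{k!r}] length mismatch")

    def __len__(self) -> int:
        return len(self.xyz)

    def band(self, name: str) -> np.ndarray:
        return self.reflectance[:, BAND_NAMES.index(name)]

    def select(self, mask: np.ndarray) -> "SpectralPointCloud":
        return SpectralPointCloud(
            xyz=self.xyz[mask],
            rgb=self.rgb[mask],
            reflectance=self.reflectance[mask],
            pixel=self.pixel[mask],
            view_id=self.view_id[mask],
            extra={k: v[mask] for k, v in self.extra.items()},
        )

    def transformed(self, matrix: np.ndarray) -> "SpectralPointCloud":
        """Return a copy with xyz mapped through a 4x4 homogeneous matrix."""
        return SpectralPointCloud(
            xyz=apply_rigid(matrix, self.xyz),
            rgb=self.rgb.copy(),
            reflectance=self.reflectance.copy(),
            pixel=self.pixel.copy(),
            view_id=self.view_id.copy(),
            extra={k: v.copy() for k, v in self.extra.items()},
        )

    @classmethod
    def concatenate(
        cls, clouds: list["SpectralPointCloud"]
    ) -> "SpectralPointCloud":
        keys = set().union(*(c.extra.keys() for c in clouds)) if clouds else set()
        extra = {}
        for k in keys:
            extra[k] = np.concatenate(
                [c.extra.get(k, np.full(len(c), np.nan)) for c in clouds]
            )
        return cls(
            xyz=np.concatenate([c.xyz for c in clouds]),
            rgb=np.concatenate([c.rgb for c in clouds]),
            reflectance=np.concatenate([c.reflectance for c in clouds]),
            pixel=np.concatenate([c.pixel for c in clouds]),
            view_id=np.concatenate([c.view_id for c in clouds]),
            extra=extra,
        )


def apply_rigid(matrix: np.ndarray, xyz: np.ndarray) -> np.ndarray:
    """Apply a 4x4 homogeneous transform to an (N, 3) array."""
    m = np.asarray(matrix, dtype=float)
    return xyz @ m[:3, :3].T + m[:3, 3]


def unproject(
    depth_mm: np.ndarray,
    k: CameraIntrinsics,
    rgb: np.ndarray | None = None,
    view_id: int = 0,
    depth_range_m: tuple[float, float] = DEPTH_RANGE_M,
) -> SpectralPointCloud:
    """Convert a depth image (uint16/float, millimeters) to a 3D cloud.

    For a pixel at column i, row j with depth z meters:
    ``x = (i - c_x) z / f_x``, ``y = -(j - c_y) z / f_y``, ``z = Depth/1000``.
    The sign flip on y makes +y point up in camera space (image rows grow
    downward).  Pixels with depth 0, NaN, or outside the sensor's trusted
    range produce no point.  Pixel provenance (i, j) is retained so that
    registered reflectance can later be attached per point.
    """
    d = np.asarray(depth_mm, dtype=float)
    if d.ndim != 2:
        raise ValueError("depth image must be 2D")
    z = d / 1000.0
    valid = np.isfinite(z) & (z >= depth_range_m[0]) & (z <= depth_range_m[1])
    jj, ii = np.nonzero(valid)
    zv = z[jj, ii]
    x = (ii - k.cx) * zv / k.fx
    y = -(jj - k.cy) * zv / k.fy
    xyz = np.column_stack([x, y, zv])
    colors = None
    if rgb is not None:
        rgb = np.asarray(rgb)
        if rgb.shape[:2] != d.shape:
            raise ValueError("rgb image shape must match depth image shape")
        colors = rgb[jj, ii]
    return SpectralPointCloud(
        xyz=xyz,
        rgb=colors,
        pixel=np.column_stack([ii, jj]).astype(np.int32),
        view_id=np.full(len(xyz), view_id, dtype=np.int32),
    )


def project(cloud: SpectralPointCloud, k: CameraIntrinsics) -> np.ndarray:
    """Inverse of :func:`unproject`: per point (i, j, depth_mm), unrounded."""
    x, y, z = cloud.xyz.T
    i = x * k.fx / z + k.cx
    j = -y * k.fy / z + k.cy
    return np.column_stack([i, j, z * 1000.0])


def common_frame_matrix(
    center: np.ndarray, normal: np.ndarray, gamma_deg: float = 0.0
) -> np.ndarray:
    """4x4 camera-to-table transform from the turntable calibration.

    Composition, in order: translate by -M so the axis passes through the
    origin; rotate about X by alpha (cos = b/sqrt(b^2+c^2)) until the axis
    normal has no z component; rotate about Z by beta (cos = sqrt(b^2+c^2))
    until it has no x component, leaving it exactly on +Y; finally rotate
    about Y by the inverse spin angle gamma.
    """
    m0 = np.asarray(center, dtype=float).reshape(3)
    a, b, c = np.asarray(normal, dtype=float).reshape(3) / np.linalg.norm(normal)
    s = np.hypot(b, c)
    if s < 1e-12:
        raise DegenerateAxisError("axis normal parallel to camera X axis")
    t = np.eye(4)
    t[:3, 3] = -m0
    rx = np.eye(4)
    rx[1:3, 1:3] = np.array([[b / s, c / s], [-c / s, b / s]])
    rz = np.eye(4)
    rz[:2, :2] = np.array([[s, -a], [a, s]])
    g = np.deg2rad(gamma_deg)
    ry = np.eye(4)
    ry[0, 0] = ry[2, 2] = np.cos(g)
    ry[0, 2] = -np.sin(g)
    ry[2, 0] = np.sin(g)
    return ry @ rz @ rx @ t


def to_common_frame(cloud: SpectralPointCloud, calib, pose: ViewPose) -> SpectralPointCloud:
    """Express a camera-frame cloud in the common turntable frame."""
    m = common_frame_matrix(calib.center, calib.normal, pose.gamma_deg)
    return cloud.transformed(m)


def crop_roi(cloud: SpectralPointCloud, box: RoiBox) -> SpectralPointCloud:
    lo = np.array([box.x[0], box.y[0], box.z[0]])
    hi = np.array([box.x[1], box.y[1], box.z[1]])
    mask = np.all((cloud.xyz >= lo) & (cloud.xyz <= hi), axis=1)
    return cloud.select(mask)


def remove_outliers(
    cloud: SpectralPointCloud, k_neighbors: int = 20, std_ratio: float = 2.0
) -> SpectralPointCloud:
    """Statistical outlier removal.

    A point is discarded when its mean distance to its k nearest neighbors
    exceeds the global mean of that statistic by more than ``std_ratio``
    standard deviations.
    """
    n = len(cloud)
    if n <= k_neighbors:
        raise ValueError(f"cloud size {n} must exceed k_neighbors={k_neighbors}")
    tree = cKDTree(cloud.xyz)
    dist, _ = tree.query(cloud.xyz, k=k_neighbors + 1)
    mean_d = dist[:, 1:].mean(axis=1)  # drop self-match
    thresh = mean_d.mean() + std_ratio * mean_d.std()
    return cloud.select(mean_d <= thresh)


def _rigid_fit(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    """Closed-form least-squares rigid transform mapping src onto dst
    (SVD of the cross-covariance; reflection guarded)."""
    cs = src.mean(axis=0)
    cd = dst.mean(axis=0)
    h = (src - cs).T @ (dst - cd)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    m = np.eye(4)
    m[:3, :3] = r
    m[:3, 3] = cd - r @ cs
    return m


def icp(
    source: SpectralPointCloud | np.ndarray,
    target: SpectralPointCloud | np.ndarray,
    max_corr_dist: float = 0.01,
    max_iter: int = 50,
    tol: float = 1e-6,
) -> tuple[np.ndarray, float, int]:
    """Point-to-point ICP; returns (4x4 transform source->target, rms, n_corr).

    Each iteration gates nearest-neighbor correspondences at
    ``max_corr_dist`` (meters) and solves the closed-form rigid fit; stops
    when the correspondence RMS changes by less than ``tol`` or after
    ``max_iter`` iterations.
    """
    src = source.xyz if isinstance(source, SpectralPointCloud) else np.asarray(source, float)
    dst = target.xyz if isinstance(target, SpectralPointCloud) else np.asarray(target, float)
    if len(src) == 0 or len(dst) == 0:
        raise ValueError("ICP requires non-empty clouds")
    tree = cKDTree(dst)
    total = np.eye(4)
    cur = src
    prev_rms = np.inf
    rms = np.inf
    n_corr = 0
    for it in range(max_iter):
        dist, idx = tree.query(cur, k=1, distance_upper_bound=max_corr_dist)
        mask = np.isfinite(dist)
        n_corr = int(mask.sum())
        if n_corr == 0:
            if it == 0:
                raise NoOverlapError("no correspondences within gate at initial pose")
            break
        rms = float(np.sqrt(np.mean(dist[mask] ** 2)))
        step = _rigid_fit(cur[mask], dst[idx[mask]])
        cur = apply_rigid(step, cur)
        total = step @ total
        if abs(prev_rms - rms) < tol:
            break
        prev_rms = rms
    return total, rms, n_corr


def voxel_downsample(cloud: SpectralPointCloud, voxel: float) -> SpectralPointCloud:
    """Average points within cubic voxels of edge ``voxel`` meters.

    XYZ, RGB, reflectance and extra attributes are averaged (NaN-aware for
    the float attributes); the view id is decided by majority vote; pixel
    provenance is no longer meaningful and is reset to -1.
    """
    if voxel <= 0:
        raise ValueError("voxel size must be positive")
    if len(cloud) == 0:
        return cloud
    keys = np.floor(cloud.xyz / voxel).astype(np.int64)
    df = pd.DataFrame(
        {
            "vx": keys[:, 0],
            "vy": keys[:, 1],
            "vz": keys[:, 2],
            "x": cloud.xyz[:, 0],
            "y": cloud.xyz[:, 1],
            "z": cloud.xyz[:, 2],
            "r": cloud.rgb[:, 0].astype(float),
            "g": cloud.rgb[:, 1].astype(float),
            "b": cloud.rgb[:, 2].astype(float),
            "view_id": cloud.view_id,
        }
    )
    for bi, name in enumerate(BAND_NAMES):
        df[f"rho_{name}"] = cloud.reflectance[:, bi]
    for k, v in cloud.extra.items():
        df[f"extra_{k}"] = v
    grp = df.groupby(["vx", "vy", "vz"], sort=True)
    mean = grp.mean()
    view = grp["view_id"].agg(lambda s: int(s.mode().iloc[0]))
    xyz = mean[["x", "y", "z"]].to_numpy()
    rgb = np.clip(np.rint(mean[["r", "g", "b"]].to_numpy()), 0, 255).astype(np.uint8)
    refl = mean[[f"rho_{n}" for n in BAND_NAMES]].to_numpy()
    extra = {k: mean[f"extra_{k}"].to_numpy() for k in cloud.extra}
    return SpectralPointCloud(
        xyz=xyz,
        rgb=rgb,
        reflectance=refl,
        view_id=view.to_numpy().astype(np.int32),
        extra=extra,
    )


def fuse_views(
    clouds: list[SpectralPointCloud],
    max_corr_dist: float = 0.01,
    max_iter: int = 50,
    tol: float = 1e-6,
    voxel: float = 0.002,
    report: list | None = None,
) -> SpectralPointCloud:
    """Sequential accumulate-and-register fusion of roughly aligned views.

    Views are merged pairwise in order: the accumulated model and the next
    view are ICP-registered, the newly registered pair becomes the model,
    and the procedure repeats until every view is merged; each ICP step only
    refines the rough alignment already provided by the turntable
    calibration.  The incoming view is the one moved: keeping the
    accumulated model fixed anchors the result in the rough common frame, so
    per-view sensor biases cannot drag the whole model as views are added
    (the relative pairwise alignment is identical either way).  The
    concatenation is voxel-downsampled into the fused model.  If ``report``
    is a list, a dict of per-pair ICP diagnostics is appended to it.
    """
    if len(clouds) < 2:
        raise ValueError("fusion requires at least two views")
    model = clouds[0]
    for nxt in clouds[1:]:
        t, rms, n_corr = icp(nxt, model, max_corr_dist, max_iter, tol)
        if report is not None:
            report.append(
                {
                    "target_view": int(nxt.view_id[0]) if len(nxt) else -1,
                    "icp_rms_m": rms,
                    "n_corr": n_corr,
                }
            )
        model = SpectralPointCloud.concatenate([model, nxt.transformed(t)])
    return voxel_downsample(model, voxel)


def extract_canopy(
    cloud: SpectralPointCloud, pot_top_height: float
) -> SpectralPointCloud:
    """Keep the canopy: points above the pot rim (Y > pot_top_height) in the
    common frame, where the axis center is the origin and +Y points up."""
    return cloud.select(cloud.xyz[:, 1] > pot_top_height)
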