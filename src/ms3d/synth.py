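"""Synthetic turntable plant scenes with full ground truth.

Emulates the physical rig: a leafy potted plant on a 20 cm rotary table with
two 5 cm calibration stickers (yellow and red), imaged by a pinhole RGB-D
camera about a meter away, plus a co-mounted narrow-band reflectance imager
whose pixel grid differs from the depth grid by an unknown 2D similarity
transform.  Every latent quantity — the rotation axis, per-view rigid
poses, the sensor-to-sensor similarity transform, per-point class labels,
true SPAD and band reflectance — is exposed for oracle comparisons, so each
pipeline stage can be tested without any recorded data.

World frame: origin at the table center on its surface, +Y up, table in the
XZ plane.  The camera sits on the -Z side looking at the plant; camera
coordinates follow the unprojection convention (x right, y up, z forward).

Reflectance is tied to chlorophyll through one invertible published
calibration curve (default: the CIG exponential model): each plant point
draws a true SPAD value, the curve is inverted to the implied
near-infrared/green band ratio, and plausible band values with additive
noise realize that ratio.  Recovering the curve from rendered data is
therefore a well-posed end-to-end check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ms3d.imreg import RegistrationTransform2D, apply_similarity
from ms3d.pointcloud import (
    BAND_NAMES,
    CameraIntrinsics,
    apply_rigid,
    common_frame_matrix,
)
from ms3d.spectral_map import SpectralCube
from ms3d import spad as spad_mod

__all__ = ["SceneParams", "SyntheticScene", "ViewRender", "GroundTruth",
           "make_scene", "render_view", "render_calibration_pair", "ground_truth"]

#: Per-point class labels.
LABELS = ("table", "sticker_yellow", "sticker_red", "pot", "stem", "leaf")

_CLASS_RGB = {
    "table": (30, 60, 160),
    "sticker_yellow": (235, 205, 40),
    "sticker_red": (220, 35, 35),
    "pot": (120, 100, 85),  # desaturated brown, outside both sticker hue bands
    "stem": (55, 110, 45),
    "leaf": (60, 145, 60),
}


@dataclass(frozen=True)
class SceneParams:
    """Scene geometry, sensors and noise; defaults emulate the study rig
    (20 cm table, 5 cm stickers, camera ~1 m away) at reduced resolution."""

    # plant
    n_leaves: int = 8
    leaf_length: float = 0.13  # m
    leaf_width: float = 0.055  # m
    stem_height: float = 0.30  # m above the pot rim
    pot_radius: float = 0.05
    pot_height: float = 0.12
    # table
    table_radius: float = 0.10
    sticker_radius: float = 0.025
    sticker_offset: float = 0.065  # radial distance of sticker centers
    # sampling
    point_spacing: float = 0.0015  # m between surface samples
    # chlorophyll / reflectance
    spad_range: tuple[float, float] = (31.46, 60.90)
    spad_model_index: str = "CIG"
    reflectance_noise: float = 0.01
    # sensors
    width: int = 320
    height: int = 240
    fx: float = 300.0
    fy: float = 300.0
    cx: float = 159.5
    cy: float = 119.5
    camera_distance: float = 1.0
    camera_height: float = 0.35
    look_at_height: float = 0.18
    depth_noise_mm: float = 1.5
    spectral_dx: float = 8.0
    spectral_dy: float = -5.0
    spectral_theta: float = 4.0
    spectral_sigma: float = 0.85

    @property
    def intrinsics(self) -> CameraIntrinsics:
        return CameraIntrinsics(cx=self.cx, cy=self.cy, fx=self.fx, fy=self.fy)

    @property
    def spectral_transform(self) -> RegistrationTransform2D:
        return RegistrationTransform2D(
            dx=self.spectral_dx,
            dy=self.spectral_dy,
            theta0=self.spectral_theta,
            sigma=self.spectral_sigma,
        )


@dataclass
class SyntheticScene:
    """World-frame point samples (at table rotation 0) with ground truth."""

    params: SceneParams
    seed: int
    points: np.ndarray  # (N, 3) world frame
    labels: np.ndarray  # (N,) str
    rgb: np.ndarray  # (N, 3) uint8
    reflectance: np.ndarray  # (N, 5)
    spad: np.ndarray  # (N,), NaN off the plant
    cam_from_world: np.ndarray  # 4x4

    @property
    def axis_center_cam(self) -> np.ndarray:
        return apply_rigid(self.cam_from_world, np.zeros((1, 3)))[0]

    @property
    def axis_normal_cam(self) -> np.ndarray:
        return self.cam_from_world[:3, :3] @ np.array([0.0, 1.0, 0.0])


@dataclass
class ViewRender:
    """One rendered view: sensor images plus per-pixel ground truth."""

    rgb: np.ndarray  # (H, W, 3) uint8
    depth_mm: np.ndarray  # (H, W) uint16, 0 = no return
    cube: SpectralCube  # on the spectral imager's grid
    aligned_reflectance: dict[str, np.ndarray]  # truth on the depth grid, NaN bg
    point_index: np.ndarray  # (H, W) int winning scene-point per pixel, -1 bg
    gamma_table_deg: float


@dataclass(frozen=True)
class GroundTruth:
    axis_center_cam: np.ndarray
    axis_normal_cam: np.ndarray
    spectral_transform: RegistrationTransform2D
    cam_from_world: np.ndarray
    labels: np.ndarray
    spad: np.ndarray
    reflectance: np.ndarray

    def view_matrix(self, gamma_table_deg: float) -> np.ndarray:
        """World -> camera transform for the table rotated by gamma."""
        return self.cam_from_world @ _roty(gamma_table_deg)


def _roty(deg: float) -> np.ndarray:
    g = np.deg2rad(deg)
    m = np.eye(4)
    m[0, 0] = m[2, 2] = np.cos(g)
    m[0, 2] = np.sin(g)
    m[2, 0] = -np.sin(g)
    return m


def _look_at(camera_pos: np.ndarray, target: np.ndarray) -> np.ndarray:
    """4x4 world->camera transform; camera axes x right, y up, z forward."""
    zc = target - camera_pos
    zc = zc / np.linalg.norm(zc)
    up = np.array([0.0, 1.0, 0.0])
    xc = np.cross(up, zc)
    xc = xc / np.linalg.norm(xc)
    yc = np.cross(zc, xc)
    r = np.stack([xc, yc, zc])  # rows: camera axes in world coords
    m = np.eye(4)
    m[:3, :3] = r
    m[:3, 3] = -r @ camera_pos
    return m


def _disc(radius: float, spacing: float, y: float, center=(0.0, 0.0)) -> np.ndarray:
    r = np.arange(-radius, radius + spacing, spacing)
    xx, zz = np.meshgrid(r, r)
    m = xx**2 + zz**2 <= radius**2
    x = xx[m] + center[0]
    z = zz[m] + center[1]
    return np.column_stack([x, np.full(x.shape, y), z])


def _cylinder(
    radius: float, y0: float, y1: float, spacing: float, center=(0.0, 0.0)
) -> np.ndarray:
    n_th = max(8, int(round(2 * math.pi * radius / spacing)))
    th = np.linspace(0, 2 * math.pi, n_th, endpoint=False)
    ys = np.arange(y0, y1 + spacing, spacing)
    tt, yy = np.meshgrid(th, ys)
    x = radius * np.cos(tt).ravel() + center[0]
    z = radius * np.sin(tt).ravel() + center[1]
    return np.column_stack([x, yy.ravel(), z])


def _leaf_surface(
    attach_y: float,
    azimuth: float,
    length: float,
    width: float,
    droop: float,
    spacing: float,
) -> np.ndarray:
    """Parametric leaf: elliptic blade along an arching midrib."""
    n_s = max(6, int(round(length / spacing)))
    n_t = max(4, int(round(width / spacing)))
    s = np.linspace(0.02, 1.0, n_s)  # along midrib
    t = np.linspace(-1.0, 1.0, n_t)  # across blade
    ss, tt = np.meshgrid(s, t)
    half_w = 0.5 * width * np.sin(np.pi * np.clip(ss, 0, 1)) ** 0.8
    radial = ss * length
    y = attach_y + 0.35 * length * np.sin(np.pi * ss) - droop * ss**2
    dx = np.cos(azimuth)
    dz = np.sin(azimuth)
    px = -dz  # horizontal perpendicular
    pz = dx
    x = radial * dx + tt * half_w * px
    z = radial * dz + tt * half_w * pz
    y = y + 0.15 * width * (1 - tt**2)  # slight across-blade cupping
    return np.column_stack([x.ravel(), y.ravel(), z.ravel()])


def make_scene(params: SceneParams | None = None, seed: int = 0) -> SyntheticScene:
    """Build the world-frame scene; deterministic given (params, seed)."""
    p = params or SceneParams()
    if not (0 < p.sticker_offset <= p.table_radius - p.sticker_radius + 1e-9):
        raise ValueError("sticker must lie fully on the table, off center")
    if p.spad_range[0] >= p.spad_range[1] or p.spad_range[0] <= 0:
        raise ValueError("invalid SPAD range")
    rng = np.random.default_rng(seed)
    sp = p.point_spacing

    chunks: list[np.ndarray] = []
    labels: list[str] = []

    table = _disc(p.table_radius, sp * 1.4, 0.0)
    # punch sticker holes so stickers sit cleanly on top
    def _hole(pts, cx, cz):
        d2 = (pts[:, 0] - cx) ** 2 + (pts[:, 2] - cz) ** 2
        return pts[d2 > p.sticker_radius**2]

    table = _hole(table, p.sticker_offset, 0.0)
    table = _hole(table, 0.0, p.sticker_offset)
    chunks.append(table)
    labels += ["table"] * len(table)

    sy = _disc(p.sticker_radius, sp, 0.0008, center=(p.sticker_offset, 0.0))
    chunks.append(sy)
    labels += ["sticker_yellow"] * len(sy)
    sr = _disc(p.sticker_radius, sp, 0.0008, center=(0.0, p.sticker_offset))
    chunks.append(sr)
    labels += ["sticker_red"] * len(sr)

    pot = _cylinder(p.pot_radius, 0.0, p.pot_height, sp * 1.4)
    pot_top = _disc(p.pot_radius, sp * 1.4, p.pot_height)
    pot = np.vstack([pot, pot_top])
    chunks.append(pot)
    labels += ["pot"] * len(pot)

    stem_top = p.pot_height + p.stem_height
    stem = _cylinder(0.004, p.pot_height, stem_top, sp)
    chunks.append(stem)
    labels += ["stem"] * len(stem)

    n_leaf_pts = 0
    leaf_of_point: list[int] = []
    for li in range(p.n_leaves):
        azim = 2 * math.pi * li / max(p.n_leaves, 1) + rng.uniform(-0.25, 0.25)
        frac = 0.35 + 0.6 * li / max(p.n_leaves - 1, 1)
        attach = p.pot_height + frac * p.stem_height
        length = p.leaf_length * rng.uniform(0.8, 1.1)
        droop = rng.uniform(0.02, 0.06)
        leaf = _leaf_surface(attach, azim, length, p.leaf_width, droop, sp)
        chunks.append(leaf)
        labels += ["leaf"] * len(leaf)
        leaf_of_point += [li] * len(leaf)
        n_leaf_pts += len(leaf)

    points = np.vstack(chunks)
    labels_arr = np.array(labels)
    n = len(points)

    # true SPAD: one base value per leaf plus a within-leaf gradient; the
    # stem shares the plant's mean chlorophyll level
    spad = np.full(n, np.nan)
    lo, hi = p.spad_range
    leaf_base = rng.uniform(lo, hi, size=max(p.n_leaves, 1))
    leaf_mask = labels_arr == "leaf"
    if n_leaf_pts:
        ids = np.array(leaf_of_point)
        jitter = rng.normal(0.0, 1.0, size=n_leaf_pts)
        spad[leaf_mask] = np.clip(leaf_base[ids] + jitter, lo, hi)
    stem_mask = labels_arr == "stem"
    spad[stem_mask] = float(np.mean(leaf_base))

    refl = _reflectance_from_spad(p, rng, labels_arr, spad)

    rgb = np.empty((n, 3), dtype=np.uint8)
    for lab, color in _CLASS_RGB.items():
        m = labels_arr == lab
        base = np.array(color, dtype=float)
        rgb[m] = np.clip(
            base + rng.normal(0, 6, size=(int(m.sum()), 3)), 0, 255
        ).astype(np.uint8)

    cam_pos = np.array([0.0, p.camera_height, -p.camera_distance])
    target = np.array([0.0, p.look_at_height, 0.0])
    cam_from_world = _look_at(cam_pos, target)

    return SyntheticScene(
        params=p,
        seed=seed,
        points=points,
        labels=labels_arr,
        rgb=rgb,
        reflectance=refl,
        spad=spad,
        cam_from_world=cam_from_world,
    )


def _reflectance_from_spad(
    p: SceneParams, rng: np.random.Generator, labels: np.ndarray, spad: np.ndarray
) -> np.ndarray:
    """Band reflectances realizing the SPAD link plus plausible backgrounds.

    For plant points the published curve for ``spad_model_index`` is
    inverted to the implied NIR/green ratio; NIR is drawn near a typical
    canopy value and green follows from the ratio.  Red and blue are low
    (strong pigment absorption), red-edge intermediate.
    """
    n = len(labels)
    refl = np.full((n, len(BAND_NAMES)), np.nan)
    model = spad_mod.paper_model(p.spad_model_index)
    if model.prototype != "M3":
        raise ValueError(
            "scene reflectance link requires an invertible exponential model"
        )
    c, k = model.coefficients
    plant = np.isfinite(spad)
    npl = int(plant.sum())
    # invert SPAD = c*10^(k*CIG); GRVI = CIG + 1 = nir/green
    cig = np.log10(spad[plant] / c) / k
    grvi = np.clip(cig + 1.0, 1.05, None)
    nir = np.clip(0.72 + rng.normal(0, p.reflectance_noise, npl), 0.4, 0.95)
    green = np.clip(nir / grvi + rng.normal(0, p.reflectance_noise * 0.3, npl), 0.01, 1.0)
    red = np.clip(0.07 + rng.normal(0, p.reflectance_noise, npl), 0.01, 0.3)
    rededge = np.clip(
        0.5 * (nir + green) + rng.normal(0, p.reflectance_noise, npl), 0.01, 1.0
    )
    blue = np.clip(0.05 + rng.normal(0, p.reflectance_noise, npl), 0.01, 0.3)
    refl[plant] = np.column_stack([blue, green, red, rededge, nir])

    flat = {
        "table": (0.08, 0.10, 0.09, 0.10, 0.12),
        "sticker_yellow": (0.10, 0.55, 0.60, 0.55, 0.50),
        "sticker_red": (0.08, 0.10, 0.55, 0.50, 0.45),
        "pot": (0.10, 0.15, 0.25, 0.28, 0.30),
    }
    for lab, vals in flat.items():
        m = labels == lab
        nm = int(m.sum())
        refl[m] = np.clip(
            np.array(vals) + rng.normal(0, p.reflectance_noise, (nm, 5)), 0, 1
        )
    return refl


def render_view(
    scene: SyntheticScene,
    gamma_table_deg: float,
    noise_seed: int = 0,
    depth_noise_mm: float | None = None,
    table_only: bool = False,
) -> ViewRender:
    """Render one view with the table rotated by ``gamma_table_deg``.

    Occlusion-correct z-buffer point splatting: every scene point projects
    to its pixel and the nearest depth wins.  Gaussian depth noise (default
    from the scene parameters) is added in millimeters.  The reflectance
    cube is rendered on the spectral imager's grid, i.e. the depth-grid
    reflectance planes pushed through the scene's true similarity transform.

    ``table_only`` renders the bare table with its stickers (the plant and
    pot removed), emulating the axis self-calibration session that precedes
    placing the plant.
    """
    p = scene.params
    rng = np.random.default_rng(noise_seed)
    sigma_mm = p.depth_noise_mm if depth_noise_mm is None else depth_noise_mm

    if table_only:
        keep = np.isin(scene.labels, ("table", "sticker_yellow", "sticker_red"))
        sub_idx = np.nonzero(keep)[0]
        pts_world = scene.points[keep]
    else:
        sub_idx = np.arange(len(scene.points))
        pts_world = scene.points
    m = scene.cam_from_world @ _roty(gamma_table_deg)
    pts_cam = apply_rigid(m, pts_world)
    k = p.intrinsics
    x, y, z = pts_cam.T
    in_front = z > 0.05
    i = np.full(len(z), -1, dtype=int)
    j = np.full(len(z), -1, dtype=int)
    i[in_front] = np.rint(x[in_front] * k.fx / z[in_front] + k.cx).astype(int)
    j[in_front] = np.rint(-y[in_front] * k.fy / z[in_front] + k.cy).astype(int)
    ok = in_front & (i >= 0) & (i < p.width) & (j >= 0) & (j < p.height)

    depth = np.full((p.height, p.width), np.inf)
    winner = np.full((p.height, p.width), -1, dtype=np.int64)
    idx = np.nonzero(ok)[0]
    # z-buffer: process points sorted far-to-near so the last write wins
    order = idx[np.argsort(-z[idx])]
    depth[j[order], i[order]] = z[order]
    winner[j[order], i[order]] = sub_idx[order]  # original scene-point index

    # Real depth sensors integrate over the pixel footprint rather than
    # keeping the nearest sample; averaging all front-surface samples
    # (within 5 mm of the per-pixel minimum) avoids the toward-camera bias
    # that a pure min-depth splat shows on obliquely viewed surfaces.
    front = z[idx] <= depth[j[idx], i[idx]] + 0.005
    fi = idx[front]
    zsum = np.zeros((p.height, p.width))
    zcnt = np.zeros((p.height, p.width))
    np.add.at(zsum, (j[fi], i[fi]), z[fi])
    np.add.at(zcnt, (j[fi], i[fi]), 1.0)
    surf = np.divide(zsum, zcnt, out=np.full_like(zsum, np.inf), where=zcnt > 0)

    bg = winner < 0
    depth_mm = np.where(bg, 0.0, surf * 1000.0)
    if sigma_mm > 0:
        depth_mm = depth_mm + np.where(
            bg, 0.0, rng.normal(0.0, sigma_mm, size=depth_mm.shape)
        )
    depth_mm = np.clip(np.rint(depth_mm), 0, 65535).astype(np.uint16)

    rgb = np.full((p.height, p.width, 3), 40, dtype=np.uint8)
    rgb[~bg] = scene.rgb[winner[~bg]]

    aligned = {}
    for bi, name in enumerate(BAND_NAMES):
        plane = np.full((p.height, p.width), np.nan)
        plane[~bg] = scene.reflectance[winner[~bg], bi]
        aligned[name] = plane

    t = p.spectral_transform
    planes = []
    for name in BAND_NAMES:
        src = np.nan_to_num(aligned[name], nan=0.0)
        moved = apply_similarity(src, t, fill=0.0)
        moved = np.clip(
            moved + rng.normal(0, 0.002, size=moved.shape), 0.0, 1.0
        )
        planes.append(moved)
    cube = SpectralCube(planes=np.stack(planes))

    return ViewRender(
        rgb=rgb,
        depth_mm=depth_mm,
        cube=cube,
        aligned_reflectance=aligned,
        point_index=winner,
        gamma_table_deg=gamma_table_deg,
    )


def render_calibration_pair(
    scene: SyntheticScene, noise_seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Grayscale calibration-target pair for estimating the sensor transform.

    A checkerboard-plus-blobs pattern stands in for the calibration board
    seen by the depth camera; the spectral imager's view is the same pattern
    pushed through the scene's true similarity transform, with mild noise.
    Registration of the pair should recover ``params.spectral_transform``.
    """
    p = scene.params
    rng = np.random.default_rng(noise_seed + 7919)
    h, w = p.height, p.width
    yy, xx = np.mgrid[0:h, 0:w]
    checker = ((xx // 24 + yy // 24) % 2).astype(float)
    blobs = np.zeros((h, w))
    br = np.random.default_rng(12345)  # fixed board pattern, not a noise source
    for _ in range(12):
        cx0, cy0 = br.uniform(0.15, 0.85) * w, br.uniform(0.15, 0.85) * h
        r0 = br.uniform(6, 18)
        blobs += np.exp(-((xx - cx0) ** 2 + (yy - cy0) ** 2) / (2 * r0**2))
    board = 0.5 * checker + blobs
    moving = apply_similarity(board, p.spectral_transform, fill=0.0)
    moving = moving + rng.normal(0, 0.01, size=moving.shape)
    return board, moving


def ground_truth(scene: SyntheticScene) -> GroundTruth:
    """Expose every latent quantity for oracle comparisons."""
    return GroundTruth(
        axis_center_cam=scene.axis_center_cam,
        axis_normal_cam=scene.axis_normal_cam,
        spectral_transform=scene.params.spectral_transform,
        cam_from_world=scene.cam_from_world,
        labels=scene.labels,
        spad=scene.spad,
        reflectance=scene.reflectance,
    )


def true_surface_in_common_frame(scene: SyntheticScene) -> np.ndarray:
    """Scene surface expressed in the frame the reconstruction targets:
    camera coordinates mapped through the *true* axis calibration."""
    g = common_frame_matrix(scene.axis_center_cam, scene.axis_normal_cam, 0.0)
    pts_cam = apply_rigid(scene.cam_from_world, scene.points)
    return apply_rigid(g, pts_cam)
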