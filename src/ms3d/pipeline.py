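"""End-to-end orchestration: calibrate -> register -> reconstruct -> analyze.

Mirrors the acquisition flow of the physical system: initialize parameters,
self-calibrate the turntable axis, calibrate the sensor-to-sensor image
transform, convert each view's RGB-D + reflectance data into a common-frame
spectral cloud, fuse the views with sequential ICP, then compute canopy
vegetation indices, summary statistics and (optionally) per-point SPAD
predictions from a calibration model.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ms3d import indices as indices_mod
from ms3d import spad as spad_mod
from ms3d.imreg import RegistrationTransform2D
from ms3d.pointcloud import (
    BAND_NAMES,
    CameraIntrinsics,
    RoiBox,
    SpectralPointCloud,
    ViewPose,
    crop_roi,
    extract_canopy,
    fuse_views,
    remove_outliers,
    to_common_frame,
    unproject,
)
from ms3d.spectral_map import SpectralCube, attach_reflectance, register_cube
from ms3d.turntable import RotaryCalibration

__all__ = ["PipelineConfig", "ViewInput", "PipelineResult", "run_pipeline"]

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass(frozen=True)
class PipelineConfig:
    """All tunable pipeline parameters with rig-scale defaults."""

    intrinsics: CameraIntrinsics
    n_views: int = 4
    spin_sign: int = 1
    roi: RoiBox = field(
        default_factory=lambda: RoiBox(x=(-0.25, 0.25), y=(0.004, 0.8), z=(-0.25, 0.25))
    )
    pot_top_height: float = 0.13
    voxel: float = 0.002
    icp_max_corr_dist: float = 0.01
    icp_max_iter: int = 50
    icp_tol: float = 1e-6
    outlier_k: int = 20
    outlier_std_ratio: float = 2.0
    spad_index: str | None = "CIG"
    index_names: tuple[str, ...] = indices_mod.INDEX_NAMES

    def __post_init__(self) -> None:
        if self.n_views < 2:
            raise ValueError("n_views must be >= 2")
        if 360 % self.n_views != 0:
            log.warning("360 not divisible by n_views=%d", self.n_views)
        if self.spin_sign not in (1, -1):
            raise ValueError("spin_sign must be +1 or -1")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        kw = dict(d)
        kw["intrinsics"] = CameraIntrinsics(**kw["intrinsics"])
        if "roi" in kw:
            kw["roi"] = RoiBox(
                x=tuple(kw["roi"]["x"]), y=tuple(kw["roi"]["y"]), z=tuple(kw["roi"]["z"])
            )
        if "index_names" in kw:
            kw["index_names"] = tuple(kw["index_names"])
        return cls(**kw)

    def to_dict(self) -> dict:
        return {
            "intrinsics": {
                "cx": self.intrinsics.cx,
                "cy": self.intrinsics.cy,
                "fx": self.intrinsics.fx,
                "fy": self.intrinsics.fy,
            },
            "n_views": self.n_views,
            "spin_sign": self.spin_sign,
            "roi": {"x": list(self.roi.x), "y": list(self.roi.y), "z": list(self.roi.z)},
            "pot_top_height": self.pot_top_height,
            "voxel": self.voxel,
            "icp_max_corr_dist": self.icp_max_corr_dist,
            "icp_max_iter": self.icp_max_iter,
            "icp_tol": self.icp_tol,
            "outlier_k": self.outlier_k,
            "outlier_std_ratio": self.outlier_std_ratio,
            "spad_index": self.spad_index,
            "index_names": list(self.index_names),
        }


@dataclass
class ViewInput:
    """Raw per-view sensor data."""

    rgb: np.ndarray
    depth_mm: np.ndarray
    cube: SpectralCube


@dataclass
class PipelineResult:
    fused: SpectralPointCloud
    canopy: SpectralPointCloud
    stats: pd.DataFrame
    report: dict
    view_clouds: list[SpectralPointCloud]


def _stage(name: str):
    def deco(fn):
        def wrapped(*a, **kw):
            try:
                return fn(*a, **kw)
            except Exception as e:  # noqa: BLE001 - re-raise labeled
                raise StageError(f"stage {name!r} failed: {e}") from e

        return wrapped

    return deco


def build_view_cloud(
    cfg: PipelineConfig,
    view: ViewInput,
    view_index: int,
    calib: RotaryCalibration,
    transform: RegistrationTransform2D,
) -> SpectralPointCloud:
    """Single-view chain: register cube, unproject, attach, crop, de-noise."""
    stack = register_cube(view.cube, transform, view.depth_mm.shape)
    cloud = unproject(view.depth_mm, cfg.intrinsics, rgb=view.rgb, view_id=view_index)
    cloud = attach_reflectance(cloud, stack)
    pose = ViewPose.from_index(view_index, cfg.n_views, cfg.spin_sign)
    cloud = to_common_frame(cloud, calib, pose)
    cloud = crop_roi(cloud, cfg.roi)
    if len(cloud) > cfg.outlier_k:
        cloud = remove_outliers(cloud, cfg.outlier_k, cfg.outlier_std_ratio)
    return cloud


def summarize_canopy(
    canopy: SpectralPointCloud, index_names: tuple[str, ...]
) -> pd.DataFrame:
    """Mean / STD / CV% / point count per band and per index attribute."""
    rows = []
    for name in BAND_NAMES:
        try:
            s = indices_mod.canopy_stats(canopy.band(name))
            rows.append((f"rho_{name}", s.mean, s.std, s.cv_percent, s.n_points))
        except indices_mod.EmptyStatsError:
            rows.append((f"rho_{name}", np.nan, np.nan, np.nan, 0))
    for name in index_names:
        if name not in canopy.extra:
            continue
        try:
            s = indices_mod.canopy_stats(canopy.extra[name])
            rows.append((name, s.mean, s.std, s.cv_percent, s.n_points))
        except indices_mod.EmptyStatsError:
            rows.append((name, np.nan, np.nan, np.nan, 0))
    return pd.DataFrame(
        rows, columns=["variable", "mean", "std", "cv_percent", "n_points"]
    )


def run_pipeline(
    cfg: PipelineConfig,
    views: list[ViewInput],
    calib: RotaryCalibration,
    transform: RegistrationTransform2D,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Run the full reconstruction and analysis chain.

    Deterministic given identical inputs and config.  When ``out_dir`` is
    set, writes model.ply, canopy.ply, stats.csv and report.json there
    (partial outputs are preserved if a late stage fails).
    """
    if len(views) != cfg.n_views:
        raise StageError(
            f"stage 'input' failed: expected {cfg.n_views} views, got {len(views)}"
        )
    report: dict = {"config": cfg.to_dict(), "stages": {}}

    view_clouds = []
    counts = []
    for vi, view in enumerate(views):
        cloud = _stage(f"view{vi}")(build_view_cloud)(cfg, view, vi, calib, transform)
        view_clouds.append(cloud)
        counts.append(len(cloud))
    report["stages"]["views"] = {"point_counts": counts}

    icp_report: list = []
    fused = _stage("fusion")(fuse_views)(
        view_clouds,
        max_corr_dist=cfg.icp_max_corr_dist,
        max_iter=cfg.icp_max_iter,
        tol=cfg.icp_tol,
        voxel=cfg.voxel,
        report=icp_report,
    )
    report["stages"]["fusion"] = {
        "fused_points": len(fused),
        "icp": icp_report,
        "single_view_share": [c / len(fused) for c in counts] if len(fused) else [],
    }

    canopy = _stage("canopy")(extract_canopy)(fused, cfg.pot_top_height)
    canopy = _stage("indices")(indices_mod.annotate_cloud)(canopy, cfg.index_names)
    if cfg.spad_index:
        model = spad_mod.paper_model(cfg.spad_index)
        x = canopy.extra[cfg.spad_index]
        pred = np.full(len(canopy), np.nan)
        okm = np.isfinite(x)
        if model.prototype == "M4":
            okm &= x > 0
        pred[okm] = spad_mod.predict(model, x[okm])
        canopy.extra["spad_pred"] = pred
        report["stages"]["spad"] = {
            "model": cfg.spad_index,
            "prototype": model.prototype,
            "mean_spad_pred": float(np.nanmean(pred)) if okm.any() else None,
        }
    report["stages"]["canopy"] = {"canopy_points": len(canopy)}

    stats = summarize_canopy(canopy, cfg.index_names)

    if out_dir is not None:
        from ms3d import io as ms3d_io

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        ms3d_io.write_ply(out / "model.ply", fused)
        ms3d_io.write_ply(out / "canopy.ply", canopy)
        stats.to_csv(out / "stats.csv", index=False)
        (out / "report.json").write_text(json.dumps(report, indent=2))
    return PipelineResult(
        fused=fused, canopy=canopy, stats=stats, report=report, view_clouds=view_clouds
    )
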