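"""Map multiband reflectance onto the depth camera's pixel grid and points.

One similarity transform, calibrated once per rig with :mod:`ms3d.imreg`, is
applied to every band of the reflectance cube so that band images land on
the depth image grid.  Reflectance is then attached to cloud points through
their pixel provenance; pixels the spectral imager did not cover carry NaN.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ms3d.imreg import RegistrationTransform2D, warp_similarity
from ms3d.pointcloud import BAND_NAMES, BAND_CENTERS_NM, SpectralPointCloud

__all__ = [
    "SpectralCube",
    "register_cube",
    "attach_reflectance",
]

log = logging.getLogger(__name__)


class MissingProvenanceError(ValueError):
    """Cloud lacks per-point source-pixel provenance."""


@dataclass
class SpectralCube:
    """Ordered stack of narrow-band reflectance planes on the imager's grid.

    ``planes`` has shape (n_bands, H, W) with values in [0, 1] or NaN;
    ``bands`` is the matching list of (name, center wavelength nm).
    """

    planes: np.ndarray
    bands: tuple[tuple[str, float], ...] = tuple(
        (n, BAND_CENTERS_NM[n]) for n in BAND_NAMES
    )

    def __post_init__(self) -> None:
        self.planes = np.asarray(self.planes, dtype=float)
        if self.planes.ndim != 3:
            raise ValueError("planes must be (n_bands, H, W)")
        if len(self.bands) != self.planes.shape[0]:
            raise ValueError("band list length must match plane count")
        names = [n for n, _ in self.bands]
        if len(set(names)) != len(names):
            raise ValueError("band names must be unique")
        finite = self.planes[np.isfinite(self.planes)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            log.warning(
                "reflectance outside [0, 1] (min %.3g, max %.3g); clipping",
                finite.min(),
                finite.max(),
            )
            self.planes = np.clip(self.planes, 0.0, 1.0)

    @property
    def band_names(self) -> list[str]:
        return [n for n, _ in self.bands]

    def plane(self, name: str) -> np.ndarray:
        return self.planes[self.band_names.index(name)]


def register_cube(
    cube: SpectralCube,
    t: RegistrationTransform2D,
    depth_shape: tuple[int, int],
) -> dict[str, np.ndarray]:
    """Warp every band with the one calibrated transform onto the depth grid.

    Returns a dict band name -> plane of ``depth_shape``; pixels with no
    source coverage are NaN.  Identical transform for all bands keeps the
    cross-band registration consistent.
    """
    out: dict[str, np.ndarray] = {}
    for name in cube.band_names:
        src = cube.plane(name)
        # NaN-poisoning guard: warp a filled copy and a coverage mask, then
        # re-impose NaN where interpolation touched any missing source pixel.
        filled = np.where(np.isfinite(src), src, 0.0)
        warped = warp_similarity(filled, t, out_shape=depth_shape, fill=np.nan)
        cov = warp_similarity(
            np.isfinite(src).astype(float), t, out_shape=depth_shape, fill=0.0
        )
        warped[cov < 0.999] = np.nan
        out[name] = warped
    return out


def attach_reflectance(
    cloud: SpectralPointCloud,
    stack: dict[str, np.ndarray],
    clip: bool = True,
) -> SpectralPointCloud:
    """Sample the registered stack at each point's source pixel.

    Nearest-neighbor by construction: each point originated from exactly one
    depth pixel, and takes that pixel's registered reflectance (no
    interpolation across depth discontinuities).  Geometry, color and point
    count are untouched; bands absent from the stack stay NaN.
    """
    if cloud.pixel is None or (len(cloud) and (cloud.pixel < 0).all()):
        raise MissingProvenanceError(
            "cloud has no per-point pixel provenance; attach before fusion"
        )
    refl = np.full((len(cloud), len(BAND_NAMES)), np.nan)
    ii = cloud.pixel[:, 0]
    jj = cloud.pixel[:, 1]
    for bi, name in enumerate(BAND_NAMES):
        if name not in stack:
            continue
        plane = np.asarray(stack[name], dtype=float)
        ok = (jj >= 0) & (jj < plane.shape[0]) & (ii >= 0) & (ii < plane.shape[1])
        vals = np.full(len(cloud), np.nan)
        vals[ok] = plane[jj[ok], ii[ok]]
        refl[:, bi] = vals
    if clip:
        refl = np.where(np.isfinite(refl), np.clip(refl, 0.0, 1.0), np.nan)
    return SpectralPointCloud(
        xyz=cloud.xyz.copy(),
        rgb=cloud.rgb.copy(),
        reflectance=refl,
        pixel=cloud.pixel.copy(),
        view_id=cloud.view_id.copy(),
        extra={k: v.copy() for k, v in cloud.extra.items()},
    )
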