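"""Vegetation indices and canopy summary statistics.

Nine band-ratio indices built from five narrow-band reflectances
(rho_Blue 466.93, rho_Green 564.91, rho_Red 696.32, rho_Red-edge 722.94,
rho_Nir 841.4 nm):

    NDVI  = (nir - red) / (nir + red)
    GNDVI = (nir - green) / (nir + green)
    NDVIR = (nir - rededge) / (nir + rededge)
    CIG   = nir / green - 1
    RCIG  = nir / rededge - 1
    NG    = green / (nir + green + red)
    NR    = red / (nir + green + red)
    RVI   = nir / red
    GRVI  = nir / green

Indices are computed per point and averaged afterwards when a single scalar
per plant is needed (average-of-index, not index-of-average-reflectance).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ms3d.pointcloud import SpectralPointCloud

__all__ = ["INDEX_NAMES", "BandReflectance", "CanopyStats", "compute_index",
           "annotate_cloud", "canopy_stats"]

log = logging.getLogger(__name__)

_DENOM_EPS = 1e-9


class EmptyStatsError(ValueError):
    """No non-NaN values to summarize."""


@dataclass(frozen=True)
class BandReflectance:
    """Reflectance in the five bands; scalars or equally-shaped arrays."""

    blue: float | np.ndarray = np.nan
    green: float | np.ndarray = np.nan
    red: float | np.ndarray = np.nan
    rededge: float | np.ndarray = np.nan
    nir: float | np.ndarray = np.nan


def _safe_div(num, den):
    scalar = np.ndim(num) == 0 and np.ndim(den) == 0
    num_a, den_a = np.broadcast_arrays(
        np.atleast_1d(np.asarray(num, dtype=float)),
        np.atleast_1d(np.asarray(den, dtype=float)),
    )
    out = np.full(num_a.shape, np.nan)
    ok = np.isfinite(num_a) & np.isfinite(den_a) & (np.abs(den_a) >= _DENOM_EPS)
    out[ok] = num_a[ok] / den_a[ok]
    return float(out[0]) if scalar else out


_FORMULAS = {
    "NDVI": lambda r: _safe_div(r.nir - r.red, r.nir + r.red),
    "GNDVI": lambda r: _safe_div(r.nir - r.green, r.nir + r.green),
    "NDVIR": lambda r: _safe_div(r.nir - r.rededge, r.nir + r.rededge),
    "CIG": lambda r: _safe_div(r.nir, r.green) - 1.0,
    "RCIG": lambda r: _safe_div(r.nir, r.rededge) - 1.0,
    "NG": lambda r: _safe_div(r.green, r.nir + r.green + r.red),
    "NR": lambda r: _safe_div(r.red, r.nir + r.green + r.red),
    "RVI": lambda r: _safe_div(r.nir, r.red),
    "GRVI": lambda r: _safe_div(r.nir, r.green),
}

INDEX_NAMES = tuple(_FORMULAS)


@dataclass(frozen=True)
class CanopyStats:
    """Mean, sample standard deviation, CV (%) and count of non-NaN values."""

    mean: float
    std: float
    cv_percent: float
    n_points: int


def compute_index(r: BandReflectance, name: str):
    """Evaluate one vegetation index; NaN where a needed band is NaN or the
    denominator magnitude is below 1e-9."""
    if name not in _FORMULAS:
        raise KeyError(
            f"unknown index {name!r}; choose from {sorted(_FORMULAS)}"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        return _FORMULAS[name](r)


def annotate_cloud(
    cloud: SpectralPointCloud, names: tuple[str, ...] = INDEX_NAMES
) -> SpectralPointCloud:
    """Add one per-point extra attribute for each requested index."""
    r = BandReflectance(
        blue=cloud.band("blue"),
        green=cloud.band("green"),
        red=cloud.band("red"),
        rededge=cloud.band("rededge"),
        nir=cloud.band("nir"),
    )
    out = cloud.select(np.ones(len(cloud), dtype=bool))
    for name in names:
        out.extra[name] = np.asarray(compute_index(r, name), dtype=float)
    return out


def canopy_stats(values: np.ndarray) -> CanopyStats:
    """NaN-ignoring mean, sample (n-1) STD, CV = STD/mean x 100%, and count."""
    v = np.asarray(values, dtype=float).ravel()
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise EmptyStatsError("all values are NaN")
    mean = float(v.mean())
    std = float(v.std(ddof=1)) if v.size > 1 else 0.0
    if mean == 0.0:
        log.warning("mean is zero; CV undefined, reporting NaN")
        cv = float("nan")
    else:
        cv = std / mean * 100.0
    return CanopyStats(mean=mean, std=std, cv_percent=cv, n_points=int(v.size))
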