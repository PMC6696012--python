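"""File formats: PLY point clouds, PNG images, multiband TIFF cubes, configs.

The PLY writer emits binary little-endian by default (ASCII on request)
with the per-vertex properties x, y, z, red, green, blue, rho_blue,
rho_green, rho_red, rho_rededge, rho_nir, view_id, plus one float property
per extra attribute (vegetation indices, predicted SPAD).  Depth images are
16-bit PNGs in millimeters; reflectance cubes are multiband TIFFs with a
JSON sidecar listing band names and center wavelengths.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile
import yaml

from ms3d.pointcloud import BAND_NAMES, SpectralPointCloud
from ms3d.spectral_map import SpectralCube

__all__ = [
    "write_ply",
    "read_ply",
    "write_depth_png",
    "read_depth_png",
    "write_rgb_png",
    "read_rgb_png",
    "write_cube",
    "read_cube",
    "load_yaml",
    "dump_yaml",
]

_PLY_DTYPES = {
    "float": "<f4",
    "double": "<f8",
    "uchar": "u1",
    "uint8": "u1",
    "int": "<i4",
    "int32": "<i4",
    "uint": "<u4",
    "short": "<i2",
    "ushort": "<u2",
}
_INV_PLY = {"<f4": "float", "u1": "uchar", "<i4": "int"}


def _vertex_dtype(extra_names: list[str]) -> np.dtype:
    fields = [
        ("x", "<f4"),
        ("y", "<f4"),
        ("z", "<f4"),
        ("red", "u1"),
        ("green", "u1"),
        ("blue", "u1"),
    ]
    fields += [(f"rho_{n}", "<f4") for n in BAND_NAMES]
    fields += [("view_id", "<i4")]
    fields += [(n, "<f4") for n in extra_names]
    return np.dtype(fields)


def write_ply(
    path: str | Path, cloud: SpectralPointCloud, binary: bool = True
) -> None:
    """Write the cloud with all attributes as a PLY file."""
    extra_names = sorted(cloud.extra)
    dt = _vertex_dtype(extra_names)
    rec = np.empty(len(cloud), dtype=dt)
    rec["x"], rec["y"], rec["z"] = cloud.xyz.T.astype(np.float32)
    rec["red"], rec["green"], rec["blue"] = cloud.rgb.T
    for bi, n in enumerate(BAND_NAMES):
        rec[f"rho_{n}"] = cloud.reflectance[:, bi].astype(np.float32)
    rec["view_id"] = cloud.view_id
    for n in extra_names:
        rec[n] = cloud.extra[n].astype(np.float32)

    fmt = "binary_little_endian" if binary else "ascii"
    header = ["ply", f"format {fmt} 1.0", f"element vertex {len(cloud)}"]
    for name in dt.names:
        header.append(f"property {_INV_PLY[dt[name].str.lstrip('|')]} {name}")
    header.append("end_header")
    with open(path, "wb") as f:
        f.write(("\n".join(header) + "\n").encode("ascii"))
        if binary:
            f.write(rec.tobytes())
        else:
            for row in rec:
                vals = [
                    repr(float(row[n])) if np.issubdtype(dt[n], np.floating)
                    else str(int(row[n]))
                    for n in dt.names
                ]
                f.write((" ".join(vals) + "\n").encode("ascii"))


def read_ply(path: str | Path) -> SpectralPointCloud:
    """Read a PLY written by :func:`write_ply` (binary or ascii)."""
    with open(path, "rb") as f:
        lines = []
        while True:
            line = f.readline().decode("ascii").strip()
            lines.append(line)
            if line == "end_header":
                break
        fmt = next(ln.split()[1] for ln in lines if ln.startswith("format"))
        n = int(next(ln.split()[2] for ln in lines if ln.startswith("element vertex")))
        props = [
            (ln.split()[2], _PLY_DTYPES[ln.split()[1]])
            for ln in lines
            if ln.startswith("property")
        ]
        dt = np.dtype(props)
        if fmt == "binary_little_endian":
            rec = np.frombuffer(f.read(n * dt.itemsize), dtype=dt, count=n)
        elif fmt == "ascii":
            body = f.read().decode("ascii").split()
            arr = np.array(body, dtype=float).reshape(n, len(props))
            rec = np.empty(n, dtype=dt)
            for ci, (name, _) in enumerate(props):
                rec[name] = arr[:, ci]
        else:
            raise ValueError(f"unsupported PLY format {fmt!r}")

    names = set(rec.dtype.names)
    xyz = np.column_stack([rec["x"], rec["y"], rec["z"]]).astype(float)
    rgb = None
    if {"red", "green", "blue"} <= names:
        rgb = np.column_stack([rec["red"], rec["green"], rec["blue"]]).astype(np.uint8)
    refl = None
    if all(f"rho_{b}" in names for b in BAND_NAMES):
        refl = np.column_stack([rec[f"rho_{b}"] for b in BAND_NAMES]).astype(float)
    view = rec["view_id"].astype(np.int32) if "view_id" in names else None
    core = {"x", "y", "z", "red", "green", "blue", "view_id"} | {
        f"rho_{b}" for b in BAND_NAMES
    }
    extra = {nm: rec[nm].astype(float) for nm in rec.dtype.names if nm not in core}
    return SpectralPointCloud(
        xyz=xyz, rgb=rgb, reflectance=refl, view_id=view, extra=extra
    )


def write_depth_png(path: str | Path, depth_mm: np.ndarray) -> None:
    """16-bit grayscale PNG, value = millimeters (0 = invalid)."""
    d = np.asarray(depth_mm)
    if d.dtype != np.uint16:
        d = np.clip(np.rint(np.nan_to_num(d, nan=0.0)), 0, 65535).astype(np.uint16)
    iio.imwrite(Path(path), d)


def read_depth_png(path: str | Path) -> np.ndarray:
    return np.asarray(iio.imread(Path(path))).astype(np.uint16)


def write_rgb_png(path: str | Path, rgb: np.ndarray) -> None:
    iio.imwrite(Path(path), np.asarray(rgb, dtype=np.uint8))


def read_rgb_png(path: str | Path) -> np.ndarray:
    return np.asarray(iio.imread(Path(path)))


def write_cube(path: str | Path, cube: SpectralCube) -> None:
    """Multiband TIFF (band-major) plus a JSON band-list sidecar."""
    path = Path(path)
    tifffile.imwrite(path, cube.planes.astype(np.float32), compression="zlib")
    sidecar = path.with_suffix(".bands.json")
    sidecar.write_text(
        json.dumps(
            {"bands": [{"name": n, "center_nm": wl} for n, wl in cube.bands]},
            indent=2,
        )
    )


def read_cube(path: str | Path) -> SpectralCube:
    path = Path(path)
    planes = tifffile.imread(path).astype(float)
    if planes.ndim == 2:
        planes = planes[None]
    sidecar = path.with_suffix(".bands.json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        bands = tuple((b["name"], float(b["center_nm"])) for b in meta["bands"])
    else:
        bands = tuple((f"band{i}", float("nan")) for i in range(planes.shape[0]))
    return SpectralCube(planes=planes, bands=bands)


def load_yaml(path: str | Path) -> dict:
    with open(path) as f:
        return yaml.safe_load(f)


def dump_yaml(path: str | Path, data: dict) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(data, f, sort_keys=False)
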