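"""Minimal ENVI raster I/O for spectral cubes and label maps.

ENVI stores a raw binary array next to a small text header (``.hdr``) that
declares ``samples``/``lines``/``bands``, data type, byte order, interleave
(BIL/BSQ/BIP) and, for cubes, the wavelength list.  Cubes are written as
32-bit little-endian float BIL by default; label maps as single-band 16-bit
integer rasters with a category legend CSV alongside.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd

from .categories import CategoryScheme, build_category_scheme
from .scene import LabelMap, SpectralCube

__all__ = ["write_envi", "read_envi", "write_label_map", "read_label_map"]

_DTYPES = {2: np.int16, 3: np.int32, 4: np.float32, 5: np.float64, 1: np.uint8}
_CODES = {np.dtype(v): k for k, v in _DTYPES.items()}


def _write_header(path: Path, shape: tuple[int, int, int], dtype: np.dtype,
                  interleave: str, extra: dict[str, str]) -> None:
    lines, samples, bands = shape
    fields = {
        "samples": str(samples),
        "lines": str(lines),
        "bands": str(bands),
        "header offset": "0",
        "file type": "ENVI Standard",
        "data type": str(_CODES[np.dtype(dtype)]),
        "interleave": interleave,
        "byte order": "0",
        **extra,
    }
    body = "ENVI\n" + "\n".join(f"{k} = {v}" for k, v in fields.items()) + "\n"
    path.write_text(body)


def _parse_header(path: Path) -> dict[str, str]:
    text = path.read_text()
    if not text.lstrip().startswith("ENVI"):
        raise ValueError(f"{path} is not an ENVI header")
    # join wrapped { ... } blocks onto one line
    text = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), text)
    fields: dict[str, str] = {}
    for line in text.splitlines()[1:]:
        if "=" in line:
            k, v = line.split("=", 1)
            fields[k.strip().lower()] = v.strip()
    for req in ("samples", "lines", "bands", "data type", "interleave"):
        if req not in fields:
            raise ValueError(f"ENVI header missing required key {req!r}")
    return fields


def _interleave_axes(interleave: str) -> tuple[int, int, int]:
    # destination axis order of (lines, samples, bands) on disk
    return {"bil": (0, 2, 1), "bsq": (2, 0, 1), "bip": (0, 1, 2)}[interleave]


def write_envi(cube: SpectralCube, path: str | Path, interleave: str = "bil") -> None:
    """Write a cube as little-endian float32 ENVI (``path`` + ``path.hdr``).

    The plate mask is stored as a sidecar byte raster ``<path>.plate`` (+hdr)
    so a written cube round-trips losslessly.
    """
    interleave = interleave.lower()
    if interleave not in ("bil", "bsq", "bip"):
        raise ValueError(f"unknown interleave {interleave!r}")
    path = Path(path)
    data = cube.data.astype("<f4")
    arr = np.transpose(data, _interleave_axes(interleave))
    arr.tofile(path)
    wl = ", ".join(f"{w:.4f}" for w in cube.wavelength_nm)
    _write_header(path.with_suffix(path.suffix + ".hdr"),
                  (cube.lines, cube.samples, cube.n_bands), np.dtype("float32"),
                  interleave, {"wavelength units": "Nanometers",
                               "reefscan units": cube.units,
                               "wavelength": "{ " + wl + " }"})
    mask = cube.plate_mask.astype("<u1")[:, :, None]
    mpath = path.with_suffix(path.suffix + ".plate")
    mask.tofile(mpath)
    _write_header(mpath.with_suffix(mpath.suffix + ".hdr"),
                  (cube.lines, cube.samples, 1), np.dtype("uint8"), "bsq", {})


def _read_raw(path: Path, fields: dict[str, str]) -> np.ndarray:
    lines = int(fields["lines"])
    samples = int(fields["samples"])
    bands = int(fields["bands"])
    dtype = np.dtype(_DTYPES[int(fields["data type"])])
    if int(fields.get("byte order", "0")) == 1:
        dtype = dtype.newbyteorder(">")
    interleave = fields["interleave"].lower()
    raw = np.fromfile(path, dtype=dtype)
    expected = lines * samples * bands
    if raw.size != expected:
        raise ValueError(
            f"{path}: file holds {raw.size} values, header implies {expected}")
    disk_shape = {
        "bil": (lines, bands, samples),
        "bsq": (bands, lines, samples),
        "bip": (lines, samples, bands),
    }[interleave]
    arr = raw.reshape(disk_shape)
    inv = np.argsort(_interleave_axes(interleave))
    return np.transpose(arr, inv)


def read_envi(path: str | Path) -> SpectralCube:
    """Read an ENVI cube written by :func:`write_envi` (any interleave)."""
    path = Path(path)
    fields = _parse_header(path.with_suffix(path.suffix + ".hdr"))
    data = _read_raw(path, fields).astype(np.float32)
    bands = int(fields["bands"])
    m = re.search(r"\{([^}]*)\}", fields.get("wavelength", ""))
    if not m:
        raise ValueError("header lacks a wavelength block")
    wl = np.asarray([float(t) for t in m.group(1).split(",") if t.strip()])
    if len(wl) != bands:
        raise ValueError(f"header bands={bands} but {len(wl)} wavelengths")
    mpath = path.with_suffix(path.suffix + ".plate")
    if mpath.exists():
        mf = _parse_header(mpath.with_suffix(mpath.suffix + ".hdr"))
        plate = _read_raw(mpath, mf)[:, :, 0].astype(bool)
    else:
        plate = np.zeros(data.shape[:2], dtype=bool)
    return SpectralCube(data, wl, plate,
                        units=fields.get("reefscan units", "radiance"))


def write_label_map(lm: LabelMap, path: str | Path) -> None:
    """Single-band int16 ENVI raster plus ``<path>.legend.csv``."""
    path = Path(path)
    arr = lm.grid.astype("<i2")[:, :, None]
    arr.tofile(path)
    _write_header(path.with_suffix(path.suffix + ".hdr"),
                  (lm.shape[0], lm.shape[1], 1), np.dtype("int16"), "bsq",
                  {"reefscan level": lm.level,
                   "reefscan resolution_m": f"{lm.resolution_m:.6f}"})
    names = (lm.scheme.fine_names if lm.level == "fine" else lm.scheme.group_names)
    legend = pd.DataFrame({
        "index": range(len(names)),
        "name": names,
        "group": [lm.scheme.group_of(n) if lm.level == "fine" else n
                  for n in names],
    })
    legend.to_csv(path.with_suffix(path.suffix + ".legend.csv"), index=False)


def read_label_map(path: str | Path, scheme: CategoryScheme | None = None) -> LabelMap:
    path = Path(path)
    fields = _parse_header(path.with_suffix(path.suffix + ".hdr"))
    grid = _read_raw(path, fields)[:, :, 0]
    level = fields.get("reefscan level", "fine")
    res = float(fields.get("reefscan resolution_m", "1.0"))
    if scheme is None:
        legend = pd.read_csv(path.with_suffix(path.suffix + ".legend.csv"))
        if level == "fine":
            scheme = build_category_scheme(
                list(zip(legend["name"], legend["group"])),
                n_groups=legend["group"].nunique())
        else:
            raise ValueError("group-level maps need an explicit scheme")
    return LabelMap(grid, res, scheme, level=level)
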