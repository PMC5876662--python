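"""Minimal ENVI-style cube I/O: band-sequential (BSQ) float32 binary plus a
plain-text ``.hdr`` carrying ``samples``, ``lines``, ``bands`` and the
wavelength list. Covers exactly what the synthetic generator emits."""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np

from .core import HyperspectralCube

_HDR_TEMPLATE = """ENVI
description = {{seedhsi synthetic cube}}
samples = {cols}
lines = {rows}
bands = {bands}
header offset = 0
file type = ENVI Standard
data type = 4
interleave = bsq
byte order = 0
wavelength units = Nanometers
wavelength = {{
{wavelengths}
}}
"""


def write_envi(path: str | Path, data: np.ndarray, wavelengths: np.ndarray) -> None:
    """Write ``data`` (rows x cols x bands) as BSQ float32 + text header."""
    path = Path(path)
    data = np.asarray(data, dtype=np.float32)
    if data.ndim != 3:
        raise ValueError("cube must be rows x cols x bands")
    rows, cols, bands = data.shape
    if bands != len(wavelengths):
        raise ValueError("band count must match wavelength count")
    wl = ",\n".join(f"  {w:.6f}" for w in wavelengths)
    hdr = _HDR_TEMPLATE.format(cols=cols, rows=rows, bands=bands, wavelengths=wl)
    path.with_suffix(".hdr").write_text(hdr)
    # BSQ: band-major on disk
    np.ascontiguousarray(np.moveaxis(data, 2, 0)).tofile(path.with_suffix(".bsq"))


def read_envi(path: str | Path, **cube_kwargs) -> HyperspectralCube:
    """Read a BSQ float32 cube written by :func:`write_envi`."""
    path = Path(path)
    hdr_text = path.with_suffix(".hdr").read_text()

    def field(name: str) -> str:
        m = re.search(rf"^{name}\s*=\s*(.+)$", hdr_text, flags=re.M)
        if m is None:
            raise ValueError(f"header field {name!r} missing in {path.with_suffix('.hdr')}")
        return m.group(1).strip()

    rows, cols, bands = (int(field(k)) for k in ("lines", "samples", "bands"))
    if field("interleave").lower() != "bsq" or int(field("data type")) != 4:
        raise ValueError("only float32 BSQ cubes are supported")
    m = re.search(r"wavelength\s*=\s*\{([^}]*)\}", hdr_text, flags=re.S)
    if m is None:
        raise ValueError("wavelength list missing from header")
    wavelengths = np.array([float(tok) for tok in re.split(r"[,\s]+", m.group(1)) if tok])
    if wavelengths.size != bands:
        raise ValueError("wavelength count disagrees with bands")
    raw = np.fromfile(path.with_suffix(".bsq"), dtype=np.float32)
    if raw.size != rows * cols * bands:
        raise ValueError("binary payload size disagrees with header dimensions")
    data = np.moveaxis(raw.reshape(bands, rows, cols), 0, 2).astype(float)
    return HyperspectralCube(data=data, wavelengths=wavelengths, **cube_kwargs)
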