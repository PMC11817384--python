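"""Hyperspectral cube container, ENVI-dialect I/O and reflectance calibration.

The cube model is the usual pushbroom-scanner layout: ``lines x samples x
bands`` with a strictly increasing wavelength axis in nanometres.  Files are
written as an ASCII ``.hdr`` plus a raw little-endian binary payload in BIL
or BSQ interleave — the subset of the ENVI dialect that SWIR line-scan
tooling emits.  Reflectance calibration follows the white-plate convention
``R = (raw - dark) / (white - dark)`` with the dark current optional.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SpectralCube",
    "ROISpec",
    "CubeFormatError",
    "CalibrationError",
    "ROIError",
    "read_cube",
    "write_cube",
    "calibrate",
    "crop_roi",
]

_DTYPE_CODES = {np.dtype("float32"): 4, np.dtype("float64"): 5}
_CODE_DTYPES = {v: k for k, v in _DTYPE_CODES.items()}


class CubeFormatError(ValueError):
    """Header/payload inconsistency or unsupported encoding."""


class CalibrationError(ValueError):
    """White reference not strictly above dark current somewhere."""


class ROIError(ValueError):
    """Requested region of interest falls outside the cube."""


@dataclass
class SpectralCube:
    """Reflectance cube: ``data[line, sample, band]`` plus wavelength axis (nm)."""

    data: np.ndarray
    wavelengths: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.data.ndim != 3:
            raise CubeFormatError(f"cube must be 3-D, got shape {self.data.shape}")
        if self.data.shape[2] != self.wavelengths.size:
            raise CubeFormatError(
                f"bands ({self.data.shape[2]}) != wavelengths ({self.wavelengths.size})"
            )
        if self.wavelengths.size >= 2 and not np.all(np.diff(self.wavelengths) > 0):
            raise CubeFormatError("wavelength axis must be strictly increasing")
        if not np.all(np.isfinite(self.data)):
            raise CubeFormatError("cube contains non-finite values")

    @property
    def lines(self) -> int:
        return self.data.shape[0]

    @property
    def samples(self) -> int:
        return self.data.shape[1]

    @property
    def bands(self) -> int:
        return self.data.shape[2]


@dataclass
class ROISpec:
    """Centred crop window, 0-based (line, sample), height x width pixels.

    The default 50 x 300 window mirrors the central region analysed per
    dried-laver sheet.
    """

    center: tuple[int, int]
    height: int = 50
    width: int = 300

    def bounds(self) -> tuple[int, int, int, int]:
        """(line0, line1, sample0, sample1) half-open intervals."""
        l0 = self.center[0] - self.height // 2
        s0 = self.center[1] - self.width // 2
        return l0, l0 + self.height, s0, s0 + self.width


def write_cube(cube: SpectralCube, path: str, interleave: str = "bil") -> None:
    """Write ``path``.hdr + raw payload. ``path`` may or may not carry .hdr."""
    interleave = interleave.lower()
    if interleave not in ("bil", "bsq"):
        raise CubeFormatError(f"unsupported interleave {interleave!r} (BIL or BSQ only)")
    base = path[:-4] if path.endswith(".hdr") else path
    data = np.ascontiguousarray(cube.data)
    if data.dtype not in _DTYPE_CODES:
        data = data.astype(np.float32)
    if interleave == "bil":
        payload = np.transpose(data, (0, 2, 1))  # line, band, sample
    else:  # bsq: band, line, sample
        payload = np.transpose(data, (2, 0, 1))
    wl = ", ".join(f"{w:.4f}" for w in cube.wavelengths)
    lines = [
        "ENVI",
        f"samples = {cube.samples}",
        f"lines = {cube.lines}",
        f"bands = {cube.bands}",
        "header offset = 0",
        "file type = ENVI Standard",
        f"data type = {_DTYPE_CODES[data.dtype]}",
        f"interleave = {interleave}",
        "byte order = 0",
    ]
    for key, val in cube.metadata.items():
        lines.append(f"{key} = {val}")
    lines.append("wavelength = {" + wl + "}")
    with open(base + ".hdr", "w") as fh:
        fh.write("\n".join(lines) + "\n")
    payload.astype(payload.dtype.newbyteorder("<")).tofile(base + ".dat")


def _parse_header(text: str) -> dict:
    fields: dict[str, str] = {}
    key = None
    buf: list[str] = []
    in_block = False
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.upper() == "ENVI":
            continue
        if in_block:
            buf.append(line)
            if "}" in line:
                fields[key] = " ".join(buf)
                in_block = False
            continue
        if "=" not in line:
            continue
        key, _, val = line.partition("=")
        key, val = key.strip().lower(), val.strip()
        if val.startswith("{") and "}" not in val:
            buf = [val]
            in_block = True
        else:
            fields[key] = val
    return fields


def read_cube(path: str) -> SpectralCube:
    """Read an ENVI-dialect .hdr + payload pair written by :func:`write_cube`."""
    base = path[:-4] if path.endswith(".hdr") else path
    with open(base + ".hdr") as fh:
        fields = _parse_header(fh.read())
    try:
        n_samples = int(fields["samples"])
        n_lines = int(fields["lines"])
        n_bands = int(fields["bands"])
        interleave = fields["interleave"].lower()
        dtype_code = int(fields["data type"])
    except KeyError as exc:
        raise CubeFormatError(f"header missing required field: {exc}") from exc
    if "wavelength" not in fields:
        raise CubeFormatError("header missing wavelength block")
    wl_text = fields["wavelength"].strip().strip("{}").strip()
    wavelengths = np.array([float(tok) for tok in wl_text.replace(",", " ").split()])
    if wavelengths.size != n_bands:
        raise CubeFormatError(
            f"header bands={n_bands} but {wavelengths.size} wavelengths listed"
        )
    if interleave not in ("bil", "bsq"):
        raise CubeFormatError(f"unsupported interleave {interleave!r}")
    if dtype_code not in _CODE_DTYPES:
        raise CubeFormatError(f"unsupported data type code {dtype_code}")
    dtype = _CODE_DTYPES[dtype_code].newbyteorder("<")
    expected = n_lines * n_samples * n_bands
    payload = np.fromfile(base + ".dat", dtype=dtype)
    if payload.size != expected:
        raise CubeFormatError(
            f"payload has {payload.size} values, header implies {expected}"
        )
    if interleave == "bil":
        data = payload.reshape(n_lines, n_bands, n_samples).transpose(0, 2, 1)
    else:
        data = payload.reshape(n_bands, n_lines, n_samples).transpose(1, 2, 0)
    metadata = {
        k: v
        for k, v in fields.items()
        if k
        not in (
            "samples", "lines", "bands", "interleave", "data type",
            "byte order", "header offset", "file type", "wavelength",
        )
    }
    return SpectralCube(np.ascontiguousarray(data), wavelengths, metadata)


def calibrate(
    raw: SpectralCube,
    white: SpectralCube,
    dark: SpectralCube | None = None,
    clip: tuple[float, float] = (0.0, 1.5),
) -> SpectralCube:
    """White-plate reflectance calibration ``(raw - dark) / (white - dark)``.

    The dark-current cube defaults to zero.  Output is clipped to ``clip``
    to guard against specular outliers; a white reference not strictly above
    the dark current anywhere is a hard error listing the offending pixels.
    """
    if raw.data.shape != white.data.shape:
        raise CalibrationError(
            f"raw {raw.data.shape} and white {white.data.shape} dims differ"
        )
    if not np.allclose(raw.wavelengths, white.wavelengths):
        raise CalibrationError("raw and white wavelength axes differ")
    dark_data = np.zeros_like(white.data) if dark is None else dark.data
    if dark is not None and dark.data.shape != raw.data.shape:
        raise CalibrationError("dark cube dims differ from raw")
    denom = white.data - dark_data
    bad = denom <= 0
    if np.any(bad):
        idx = np.argwhere(bad)
        head = [tuple(int(i) for i in row) for row in idx[:10]]
        raise CalibrationError(
            f"white <= dark at {idx.shape[0]} voxels, e.g. {head}"
        )
    refl = (raw.data - dark_data) / denom
    refl = np.clip(refl, clip[0], clip[1])
    meta = dict(raw.metadata)
    meta["calibration"] = "white-reference"
    return SpectralCube(refl, raw.wavelengths.copy(), meta)


def crop_roi(cube: SpectralCube, roi: ROISpec) -> SpectralCube:
    """Extract the ROI window; wavelengths and metadata carry over."""
    l0, l1, s0, s1 = roi.bounds()
    if l0 < 0 or s0 < 0 or l1 > cube.lines or s1 > cube.samples:
        cl = (
            min(max(roi.center[0], roi.height // 2), cube.lines - (roi.height + 1) // 2),
            min(max(roi.center[1], roi.width // 2), cube.samples - (roi.width + 1) // 2),
        )
        raise ROIError(
            f"ROI [{l0}:{l1}, {s0}:{s1}] outside cube "
            f"{cube.lines}x{cube.samples}; nearest valid center {cl}"
        )
    return SpectralCube(
        cube.data[l0:l1, s0:s1].copy(), cube.wavelengths.copy(), dict(cube.metadata)
    )
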