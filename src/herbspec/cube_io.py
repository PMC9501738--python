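"""ENVI-style hyperspectral cube I/O and white/dark reflectance calibration.

A cube is stored as the de-facto instrument convention: an ASCII ``.hdr``
companion file carrying ``samples``/``lines``/``bands``/``interleave``/
``data type``/``wavelength`` keys next to a flat little-endian binary file.
Raw sensor counts are converted to relative reflectance against a white
reference (a tile of ~100% reflectance) and a dark reference (shutter
closed)::

    R = (raw - dark) / (white - dark)

clipped to [0, 1.5] because specular pixels routinely exceed the white tile.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

__all__ = [
    "SpectralCube",
    "ReferencePair",
    "CalibrationError",
    "EnviFormatError",
    "read_envi",
    "write_envi",
    "calibrate",
]

#: reflectance values are clipped to this interval after calibration
REFLECTANCE_CLIP = (0.0, 1.5)

# ENVI numeric codes for the supported sample types (little-endian)
_DTYPE_CODES = {12: np.dtype("<u2"), 4: np.dtype("<f4")}
_CODE_FOR_DTYPE = {v: k for k, v in _DTYPE_CODES.items()}


class EnviFormatError(ValueError):
    """Header/binary pair is malformed or uses an unsupported variant."""


class CalibrationError(ValueError):
    """White/dark references cannot calibrate the cube."""


@dataclass
class SpectralCube:
    """A (rows x cols x bands) grid with a wavelength axis in nm.

    ``kind`` distinguishes raw sensor counts from calibrated reflectance.
    """

    values: np.ndarray
    wavelengths: np.ndarray
    kind: Literal["raw_counts", "reflectance"] = "raw_counts"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("cube values must be 3-D (rows x cols x bands)")
        if self.wavelengths.ndim != 1 or len(self.wavelengths) != self.values.shape[2]:
            raise ValueError("wavelength axis length must equal the number of bands")
        if not np.all(np.isfinite(self.wavelengths)):
            raise ValueError("wavelengths must be finite")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if self.kind not in ("raw_counts", "reflectance"):
            raise ValueError(f"unknown cube kind {self.kind!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def n_bands(self) -> int:
        return self.values.shape[2]


@dataclass
class ReferencePair:
    """White and dark reference frames, broadcastable to a cube.

    Line-scan systems record references per scan line, so a reference may be
    1-D (per band), 2-D (cols x bands) or full 3-D; it is broadcast across
    the missing leading axes.
    """

    white: np.ndarray
    dark: np.ndarray

    def __post_init__(self) -> None:
        self.white = np.asarray(self.white, dtype=float)
        self.dark = np.asarray(self.dark, dtype=float)


def _broadcast_ref(ref: np.ndarray, shape: tuple[int, int, int]) -> np.ndarray:
    try:
        return np.broadcast_to(ref, shape)
    except ValueError as exc:
        raise CalibrationError(
            f"reference of shape {ref.shape} does not broadcast to cube {shape}"
        ) from exc


def calibrate(raw: SpectralCube, refs: ReferencePair) -> SpectralCube:
    """Convert raw counts to reflectance: ``(raw - dark)/(white - dark)``.

    The denominator must be strictly positive everywhere; offending bands
    are named in the error. Output is clipped to ``REFLECTANCE_CLIP``.
    """
    if raw.kind != "raw_counts":
        raise ValueError("calibrate expects a raw_counts cube")
    white = _broadcast_ref(refs.white, raw.shape)
    dark = _broadcast_ref(refs.dark, raw.shape)
    denom = white - dark
    bad = denom <= 0
    if np.any(bad):
        bad_bands = sorted(set(np.nonzero(bad)[2].tolist()))
        raise CalibrationError(
            f"white - dark is non-positive in band(s) {bad_bands}"
        )
    refl = (raw.values.astype(float) - dark) / denom
    np.clip(refl, *REFLECTANCE_CLIP, out=refl)
    return SpectralCube(refl, raw.wavelengths.copy(), kind="reflectance")


# ---------------------------------------------------------------------------
# ENVI-style header + flat binary

def _interleave_axes(interleave: str) -> tuple[int, int, int]:
    # axis order in the file, expressed as a transpose of (lines, samples, bands)
    return {
        "bsq": (2, 0, 1),  # band, line, sample
        "bil": (0, 2, 1),  # line, band, sample
        "bip": (0, 1, 2),  # line, sample, band
    }[interleave]


def write_envi(cube: SpectralCube, header_path: str | os.PathLike,
               interleave: str = "bil") -> str:
    """Write ``cube`` as a ``.hdr`` + flat binary pair; returns the data path."""
    interleave = interleave.lower()
    if interleave not in ("bil", "bip", "bsq"):
        raise EnviFormatError(f"unsupported interleave {interleave!r}")
    header_path = os.fspath(header_path)
    data_path = os.path.splitext(header_path)[0] + ".dat"

    values = cube.values
    if values.dtype not in _CODE_FOR_DTYPE:
        # store as float32 unless counts fit the unsigned 16-bit range exactly
        if (cube.kind == "raw_counts"
                and np.issubdtype(values.dtype, np.integer)
                and values.min() >= 0 and values.max() <= np.iinfo("u2").max):
            values = values.astype("<u2")
        else:
            values = values.astype("<f4")
    code = _CODE_FOR_DTYPE[np.dtype(values.dtype)]

    rows, cols, bands = values.shape
    wl = ", ".join(f"{w:.17g}" for w in cube.wavelengths)
    header = (
        "ENVI\n"
        f"samples = {cols}\n"
        f"lines = {rows}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {code}\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        "wavelength units = Nanometers\n"
        f"wavelength = {{ {wl} }}\n"
        f"cube kind = {cube.kind}\n"
    )
    with open(header_path, "w") as fh:
        fh.write(header)
    values.transpose(_interleave_axes(interleave)).tofile(data_path)
    return data_path


def _parse_header(text: str) -> dict[str, str]:
    fields: dict[str, str] = {}
    lines = iter(text.splitlines())
    for line in lines:
        if "=" not in line:
            continue
        key, _, val = line.partition("=")
        key = key.strip().lower()
        val = val.strip()
        if val.startswith("{") and "}" not in val:
            parts = [val]
            for cont in lines:
                parts.append(cont)
                if "}" in cont:
                    break
            val = " ".join(parts)
        fields[key] = val
    return fields


def read_envi(header_path: str | os.PathLike) -> SpectralCube:
    """Read an ENVI-style ``.hdr`` + binary pair into a :class:`SpectralCube`."""
    header_path = os.fspath(header_path)
    with open(header_path) as fh:
        fields = _parse_header(fh.read())

    try:
        cols = int(fields["samples"])
        rows = int(fields["lines"])
        bands = int(fields["bands"])
        code = int(fields["data type"])
        interleave = fields["interleave"].lower()
    except KeyError as exc:
        raise EnviFormatError(f"header missing required key {exc}") from exc
    if code not in _DTYPE_CODES:
        raise EnviFormatError(f"unsupported data type code {code}")
    if interleave not in ("bil", "bip", "bsq"):
        raise EnviFormatError(f"unsupported interleave {interleave!r}")
    if fields.get("byte order", "0").strip() != "0":
        raise EnviFormatError("only little-endian (byte order = 0) is supported")
    if "wavelength" not in fields:
        raise EnviFormatError("header carries no wavelength block")

    wl_text = fields["wavelength"].strip().strip("{}").strip()
    wavelengths = np.array([float(tok) for tok in wl_text.split(",") if tok.strip()])
    if len(wavelengths) != bands:
        raise EnviFormatError(
            f"header declares {bands} bands but lists {len(wavelengths)} wavelengths"
        )

    data_path = os.path.splitext(header_path)[0] + ".dat"
    if not os.path.exists(data_path):
        raise EnviFormatError(f"binary file {data_path} not found")
    dtype = _DTYPE_CODES[code]
    raw = np.fromfile(data_path, dtype=dtype)
    if raw.size != rows * cols * bands:
        raise EnviFormatError(
            f"binary size {raw.size} does not match header "
            f"{rows}x{cols}x{bands} = {rows * cols * bands}"
        )
    axes = _interleave_axes(interleave)
    file_shape = tuple((rows, cols, bands)[a] for a in axes)
    values = raw.reshape(file_shape).transpose(np.argsort(axes))
    kind = fields.get("cube kind", "raw_counts")
    if kind not in ("raw_counts", "reflectance"):
        kind = "raw_counts"
    return SpectralCube(values, wavelengths, kind=kind)
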