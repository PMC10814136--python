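"""Hyperspectral cube containers, ENVI I/O, reflectance calibration, band cropping.

A push-broom NIR camera stores raw digital counts; converting them to
reflectance uses a white reference cube W (imaged reflectance standard)
and a dark reference cube D (closed shutter): R = (I - D) / (W - D),
applied per pixel and band.  Cubes travel in the plain ENVI container
(ASCII ``.hdr`` plus raw binary, interleave BIL/BIP/BSQ) which is the
lingua franca of line-scan instruments.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass

import numpy as np

from .exceptions import FormatError, ParameterError

__all__ = [
    "RawCube",
    "ReflectanceCube",
    "read_envi",
    "write_envi",
    "calibrate_reflectance",
    "crop_bands",
    "DEFAULT_DROP_FRONT",
]

logger = logging.getLogger(__name__)

#: Dropping the first 15 of 224 bands leaves the 209 retained bands the
#: downstream sequence models consume (the noisy short-wavelength edge).
DEFAULT_DROP_FRONT = 15

_ENVI_DTYPES = {
    1: np.uint8, 2: np.int16, 3: np.int32, 4: np.float32, 5: np.float64,
    12: np.uint16, 13: np.uint32, 14: np.int64, 15: np.uint64,
}
_ENVI_CODES = {np.dtype(v): k for k, v in _ENVI_DTYPES.items()}


def _check_axis(wavelengths: np.ndarray):
    if wavelengths.ndim != 1 or wavelengths.size < 1:
        raise ParameterError("wavelengths must be a non-empty 1-D vector")
    if np.any(np.diff(wavelengths) <= 0):
        raise ParameterError("wavelengths must be strictly increasing")


@dataclass
class RawCube:
    """H x W x B stack of non-negative sensor counts with its wavelength axis."""

    data: np.ndarray
    wavelengths: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.data.ndim != 3:
            raise ParameterError("cube data must be H x W x B")
        _check_axis(self.wavelengths)
        if self.data.shape[2] != self.wavelengths.size:
            raise ParameterError("band axis length must match wavelengths")

    @property
    def shape(self):
        return self.data.shape


@dataclass
class ReflectanceCube:
    """H x W x B unitless reflectance with its wavelength axis."""

    data: np.ndarray
    wavelengths: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.data.ndim != 3:
            raise ParameterError("cube data must be H x W x B")
        if not np.all(np.isfinite(self.data)):
            raise ParameterError("reflectance must be finite everywhere")
        _check_axis(self.wavelengths)
        if self.data.shape[2] != self.wavelengths.size:
            raise ParameterError("band axis length must match wavelengths")

    @property
    def shape(self):
        return self.data.shape


# ---------------------------------------------------------------------------
# ENVI container
# ---------------------------------------------------------------------------

def _parse_header(text: str) -> dict:
    if not text.lstrip().lower().startswith("envi"):
        raise FormatError("not an ENVI header (missing 'ENVI' magic)")
    fields: dict[str, str] = {}
    lines = iter(text.splitlines())
    next(lines)  # magic
    for line in lines:
        if "=" not in line:
            continue
        key, _, value = line.partition("=")
        key = key.strip().lower()
        value = value.strip()
        if value.startswith("{") and "}" not in value:
            parts = [value]
            for cont in lines:
                parts.append(cont)
                if "}" in cont:
                    break
            value = " ".join(parts)
        fields[key] = value
    return fields


def _parse_list(value: str) -> list[float]:
    return [float(v) for v in value.strip().lstrip("{").rstrip("}").split(",") if v.strip()]


def read_envi(header_path: str | os.PathLike) -> RawCube:
    """Read an ENVI cube (any of BIL/BIP/BSQ) into H x W x B order.

    The binary file is taken from the header's ``data file`` field when
    present, otherwise by swapping the extension.
    """
    header_path = os.fspath(header_path)
    with open(header_path) as fh:
        fields = _parse_header(fh.read())
    try:
        height = int(fields["lines"])
        width = int(fields["samples"])
        bands = int(fields["bands"])
        interleave = fields["interleave"].strip().lower()
        dtype_code = int(fields["data type"])
    except KeyError as exc:
        raise FormatError(f"ENVI header missing required field: {exc}") from exc
    if "wavelength" not in fields:
        raise FormatError("ENVI header has no 'wavelength' field")
    wavelengths = np.array(_parse_list(fields["wavelength"]))
    if wavelengths.size != bands:
        raise FormatError("wavelength list length does not match bands")
    if interleave not in ("bil", "bip", "bsq"):
        raise FormatError(f"unsupported interleave {interleave!r}")
    if dtype_code not in _ENVI_DTYPES:
        raise FormatError(f"unsupported ENVI data type {dtype_code}")
    dtype = np.dtype(_ENVI_DTYPES[dtype_code])
    if int(fields.get("byte order", "0")) == 1:
        dtype = dtype.newbyteorder(">")

    data_path = fields.get("data file")
    if data_path is None:
        stem = os.path.splitext(header_path)[0]
        for ext in ("", ".raw", ".dat", ".img", ".bin"):
            if os.path.exists(stem + ext) and stem + ext != header_path:
                data_path = stem + ext
                break
        if data_path is None:
            raise FormatError(f"no binary file found next to {header_path}")
    elif not os.path.isabs(data_path):
        data_path = os.path.join(os.path.dirname(header_path), data_path)

    flat = np.fromfile(data_path, dtype=dtype)
    expected = height * width * bands
    if flat.size != expected:
        raise FormatError(
            f"binary size {flat.size} does not match header dims {height}x{width}x{bands}")
    if interleave == "bsq":
        cube = flat.reshape(bands, height, width).transpose(1, 2, 0)
    elif interleave == "bil":
        cube = flat.reshape(height, bands, width).transpose(0, 2, 1)
    else:  # bip
        cube = flat.reshape(height, width, bands)
    return RawCube(data=np.ascontiguousarray(cube), wavelengths=wavelengths)


def write_envi(header_path: str | os.PathLike, cube: RawCube | ReflectanceCube,
               interleave: str = "bil") -> str:
    """Write ``cube`` as an ENVI header + raw binary pair; returns the binary path."""
    header_path = os.fspath(header_path)
    interleave = interleave.lower()
    if interleave not in ("bil", "bip", "bsq"):
        raise ParameterError(f"unsupported interleave {interleave!r}")
    data = np.asarray(cube.data)
    if data.dtype not in _ENVI_CODES:
        data = data.astype(np.float64 if data.dtype == np.float64 else np.float32)
    height, width, bands = data.shape
    if interleave == "bsq":
        ordered = data.transpose(2, 0, 1)
    elif interleave == "bil":
        ordered = data.transpose(0, 2, 1)
    else:
        ordered = data
    stem = os.path.splitext(header_path)[0]
    data_path = stem + ".raw"
    np.ascontiguousarray(ordered).tofile(data_path)
    wl = ", ".join(f"{v:.6f}" for v in cube.wavelengths)
    header = (
        "ENVI\n"
        f"samples = {width}\n"
        f"lines = {height}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {_ENVI_CODES[data.dtype]}\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        f"data file = {os.path.basename(data_path)}\n"
        f"wavelength = {{ {wl} }}\n"
    )
    with open(header_path, "w") as fh:
        fh.write(header)
    return data_path


# ---------------------------------------------------------------------------
# Calibration and cropping
# ---------------------------------------------------------------------------

def calibrate_reflectance(image: RawCube, white: RawCube, dark: RawCube,
                          clip_max: float = 1.5) -> ReflectanceCube:
    """White/dark reflectance calibration: R = (I - D) / (W - D).

    Pixels/bands where the white and dark references coincide (dead
    pixels) are set to 0 and counted in a log warning so they cannot
    poison downstream ROI means.  Values above ``clip_max`` (specular
    highlights) are clipped.
    """
    for other in (white, dark):
        if other.data.shape != image.data.shape:
            raise ParameterError("image, white and dark cubes must share shape")
        if not np.array_equal(other.wavelengths, image.wavelengths):
            raise ParameterError("image, white and dark cubes must share wavelengths")
    i = image.data.astype(float)
    w = white.data.astype(float)
    d = dark.data.astype(float)
    denom = w - d
    dead = denom == 0
    n_dead = int(dead.sum())
    if n_dead:
        logger.warning("calibrate_reflectance: %d dead pixel-band entries (W == D) set to 0", n_dead)
        denom = np.where(dead, 1.0, denom)
    r = (i - d) / denom
    r[dead] = 0.0
    np.minimum(r, clip_max, out=r)
    return ReflectanceCube(data=r, wavelengths=image.wavelengths.copy())


def crop_bands(x, n_drop_front: int = DEFAULT_DROP_FRONT, n_drop_back: int = 0):
    """Trim noisy spectral edges from a cube or spectra matrix.

    Defaults drop the first 15 bands so a 224-band cube yields the
    209-band range the sequence models are sized for.  Works on
    :class:`ReflectanceCube` and on
    :class:`spectrareg.pipeline.SpectraMatrix`; the wavelength axis is
    cropped consistently.
    """
    if n_drop_front < 0 or n_drop_back < 0:
        raise ParameterError("crop counts must be non-negative")
    n_bands = x.wavelengths.size
    if n_drop_front + n_drop_back >= n_bands:
        raise ParameterError("cropping would leave zero bands")
    stop = n_bands - n_drop_back
    wavelengths = x.wavelengths[n_drop_front:stop].copy()
    if isinstance(x, (RawCube, ReflectanceCube)):
        return type(x)(data=x.data[:, :, n_drop_front:stop].copy(), wavelengths=wavelengths)
    # SpectraMatrix-like: N x B values
    return type(x)(values=x.values[:, n_drop_front:stop].copy(), wavelengths=wavelengths,
                   sample_ids=list(x.sample_ids))
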