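"""Hyperspectral cube data model, ENVI I/O, band lookup and color rendering.

A transect cube is a 3-axis radiance array ordered ``[line, sample, band]``:
``line`` is the along-track (push-broom frame) axis, ``sample`` the
across-track spatial axis, ``band`` the wavelength axis. ENVI header/binary
pairs are the on-disk container; interleaves bil/bsq/bip and data types
uint16/float32/float64 are supported (written as bil + float32 by default,
the push-broom native layout).
"""

from __future__ import annotations

import os
import re
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "SpectralCube",
    "read_envi",
    "write_envi",
    "band_index",
    "to_rgb",
    "rectify_aspect",
    "save_png",
]

# ENVI numeric data-type codes for the types we support.
_DTYPE_BY_CODE = {4: np.float32, 5: np.float64, 12: np.uint16}
_CODE_BY_DTYPE = {np.dtype(np.float32): 4, np.dtype(np.float64): 5, np.dtype(np.uint16): 12}


@dataclass
class SpectralCube:
    """Radiance cube: ``values[line, sample, band]`` with a wavelength axis in nm.

    Parameters
    ----------
    values : ndarray, shape (L, S, B)
        Linear radiance counts; the gain model of the imager is not assumed.
    wavelengths : ndarray, shape (B,)
        Band-center wavelengths in nm, strictly increasing.
    line_period : float, optional
        Seconds per scan line, when known.
    meta : dict
        Free-form acquisition record (altitude, swim speed, gain, timestamps).
    """

    values: np.ndarray
    wavelengths: np.ndarray
    line_period: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.values.ndim != 3:
            raise ValueError(f"cube values must be 3-D [line, sample, band], got {self.values.ndim}-D")
        L, S, B = self.values.shape
        if L < 1 or S < 1 or B < 2:
            raise ValueError(f"cube needs L>=1, S>=1, B>=2; got shape {(L, S, B)}")
        if self.wavelengths.ndim != 1 or self.wavelengths.size != B:
            raise ValueError(
                f"wavelength axis length {self.wavelengths.size} does not match band axis length {B}"
            )
        if not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("cube values must all be finite")
        if not np.all(np.isfinite(self.wavelengths)):
            raise ValueError("wavelengths must all be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def n_lines(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def n_bands(self) -> int:
        return self.values.shape[2]


def _format_envi_value(value) -> str:
    if isinstance(value, (list, tuple, np.ndarray)):
        return "{ " + " , ".join(repr(float(v)) if isinstance(v, (float, np.floating)) else str(v) for v in value) + " }"
    return str(value)


def _parse_envi_header(text: str) -> dict:
    """Parse an ENVI header into a {lowercased key: string} mapping.

    Brace-delimited blocks (which may span lines) are kept as their inner text.
    """
    if not text.lstrip().upper().startswith("ENVI"):
        raise ValueError("not an ENVI header: missing 'ENVI' magic on first line")
    body = text.lstrip()[4:]
    fields: dict[str, str] = {}
    pos = 0
    pattern = re.compile(r"^\s*([^={}\n][^=\n]*?)\s*=\s*", re.M)
    while True:
        m = pattern.search(body, pos)
        if m is None:
            break
        key = m.group(1).strip().lower()
        rest = body[m.end():]
        if rest.lstrip().startswith("{"):
            open_idx = rest.index("{")
            close_idx = rest.index("}", open_idx)
            fields[key] = rest[open_idx + 1 : close_idx].strip()
            pos = m.end() + close_idx + 1
        else:
            line_end = rest.find("\n")
            if line_end < 0:
                line_end = len(rest)
            fields[key] = rest[:line_end].strip()
            pos = m.end() + line_end
    return fields


def read_envi(header_path: str | os.PathLike) -> SpectralCube:
    """Read an ENVI header/binary pair into a :class:`SpectralCube`.

    The returned cube is always ordered ``[line, sample, band]`` regardless of
    the on-disk interleave. The header must carry a ``wavelength`` block in nm.
    """
    header_path = os.fspath(header_path)
    with open(header_path, "r") as fh:
        fields = _parse_envi_header(fh.read())

    for required in ("samples", "lines", "bands", "interleave", "data type"):
        if required not in fields:
            raise ValueError(f"ENVI header missing required field '{required}'")
    samples = int(fields["samples"])
    lines = int(fields["lines"])
    bands = int(fields["bands"])
    interleave = fields["interleave"].lower()
    code = int(fields["data type"])
    if code not in _DTYPE_BY_CODE:
        raise ValueError(
            f"unsupported ENVI data type code {code}; supported: "
            + ", ".join(f"{c} ({np.dtype(t).name})" for c, t in sorted(_DTYPE_BY_CODE.items()))
        )
    dtype = np.dtype(_DTYPE_BY_CODE[code])
    byte_order = int(fields.get("byte order", 0))
    dtype = dtype.newbyteorder("<" if byte_order == 0 else ">")

    if "wavelength" not in fields:
        raise ValueError("ENVI header has no 'wavelength' block; cannot build spectral axis")
    wavelengths = np.array([float(tok) for tok in fields["wavelength"].replace(",", " ").split()])
    if wavelengths.size != bands:
        raise ValueError(
            f"header declares bands={bands} but lists {wavelengths.size} wavelengths"
        )

    data_path = _sibling_data_path(header_path)
    raw = np.fromfile(data_path, dtype=dtype, count=lines * samples * bands)
    if raw.size != lines * samples * bands:
        raise ValueError(
            f"binary file {data_path} holds {raw.size} samples, header implies {lines * samples * bands}"
        )
    if interleave == "bil":  # line-major: [line, band, sample]
        values = raw.reshape(lines, bands, samples).transpose(0, 2, 1)
    elif interleave == "bsq":  # band-major: [band, line, sample]
        values = raw.reshape(bands, lines, samples).transpose(1, 2, 0)
    elif interleave == "bip":  # pixel-major: [line, sample, band]
        values = raw.reshape(lines, samples, bands)
    else:
        raise ValueError(f"unsupported interleave '{interleave}' (expected bil, bsq or bip)")

    meta = {
        k: v
        for k, v in fields.items()
        if k not in {"samples", "lines", "bands", "interleave", "data type", "byte order",
                     "wavelength", "header offset", "file type", "line period"}
    }
    line_period = float(fields["line period"]) if "line period" in fields else None
    return SpectralCube(np.ascontiguousarray(values), wavelengths, line_period=line_period, meta=meta)


def _sibling_data_path(header_path: str) -> str:
    stem = header_path[:-4] if header_path.lower().endswith(".hdr") else header_path
    for candidate in (stem, stem + ".dat", stem + ".bil", stem + ".bsq", stem + ".bip", stem + ".img"):
        if os.path.exists(candidate) and not candidate.lower().endswith(".hdr"):
            return candidate
    raise FileNotFoundError(f"no binary data file found next to header {header_path}")


def write_envi(
    cube: SpectralCube,
    header_path: str | os.PathLike,
    interleave: str = "bil",
    dtype: np.dtype | str | None = np.float32,
) -> None:
    """Write ``cube`` as an ENVI header/binary pair (``<stem>.hdr`` + ``<stem>.dat``).

    Wavelengths are serialized at full precision. Existing files are replaced.
    """
    header_path = os.fspath(header_path)
    interleave = interleave.lower()
    if interleave not in ("bil", "bsq", "bip"):
        raise ValueError(f"unsupported interleave '{interleave}'")
    out_dtype = np.dtype(dtype) if dtype is not None else cube.values.dtype
    if out_dtype not in _CODE_BY_DTYPE:
        raise ValueError(f"unsupported output dtype {out_dtype}; use uint16, float32 or float64")

    L, S, B = cube.shape
    values = np.asarray(cube.values, dtype=out_dtype)
    if interleave == "bil":
        raw = values.transpose(0, 2, 1)
    elif interleave == "bsq":
        raw = values.transpose(2, 0, 1)
    else:
        raw = values

    stem = header_path[:-4] if header_path.lower().endswith(".hdr") else header_path
    data_path = stem + ".dat"
    lines_out = [
        "ENVI",
        "file type = ENVI Standard",
        f"samples = {S}",
        f"lines = {L}",
        f"bands = {B}",
        "header offset = 0",
        f"data type = {_CODE_BY_DTYPE[out_dtype]}",
        f"interleave = {interleave}",
        "byte order = 0",
        "wavelength units = Nanometers",
        "wavelength = { " + " , ".join(repr(float(w)) for w in cube.wavelengths) + " }",
    ]
    if cube.line_period is not None:
        lines_out.append(f"line period = {cube.line_period!r}")
    for key, value in cube.meta.items():
        key_s = str(key).strip().lower()
        if key_s and "=" not in key_s and "{" not in str(value) and "}" not in str(value):
            lines_out.append(f"{key_s} = {_format_envi_value(value)}")
    with open(stem + ".hdr", "w") as fh:
        fh.write("\n".join(lines_out) + "\n")
    np.ascontiguousarray(raw).astype(out_dtype.newbyteorder("<")).tofile(data_path)


def band_index(cube: SpectralCube, wavelength: float) -> int:
    """Position of the band nearest ``wavelength`` (nm); ties go to the lower band.

    The query must lie within the wavelength axis extended by half the mean
    band spacing on either side.
    """
    wl = cube.wavelengths
    half_step = float(np.mean(np.diff(wl))) / 2.0
    lo, hi = wl[0] - half_step, wl[-1] + half_step
    if not (lo <= wavelength <= hi):
        raise ValueError(
            f"wavelength {wavelength} nm outside valid range [{lo:.3f}, {hi:.3f}] nm"
        )
    # argmin returns the first (lower-wavelength) index on exact ties
    return int(np.argmin(np.abs(wl - wavelength)))


def _stretch_channel(plane: np.ndarray, stretch: tuple[float, float]) -> np.ndarray:
    lo, hi = np.percentile(plane, stretch)
    if hi <= lo:
        warnings.warn("degenerate (constant) channel plane; mapped to 0", stacklevel=3)
        return np.zeros_like(plane, dtype=float)
    return np.clip((plane.astype(float) - lo) / (hi - lo), 0.0, 1.0)


def to_rgb(
    cube,
    rgb_wavelengths: Sequence[float] = (640.0, 540.0, 460.0),
    stretch: tuple[float, float] = (2.0, 98.0),
) -> np.ndarray:
    """Render a 3-channel color image from the nearest bands to R/G/B wavelengths.

    Each channel is percentile-stretched independently to [0, 1]; the source
    planes are never modified. Accepts a radiance or reflectance cube.
    """
    if len(rgb_wavelengths) != 3:
        raise ValueError("rgb_wavelengths must be a (red, green, blue) triple")
    channels = [
        _stretch_channel(cube.values[:, :, band_index(cube, w)], stretch) for w in rgb_wavelengths
    ]
    return np.stack(channels, axis=-1)


def rectify_aspect(
    image: np.ndarray,
    pixel_size: tuple[float, float],
    is_labels: bool = False,
) -> np.ndarray:
    """Resample so displayed pixels are square, preserving content extent.

    ``pixel_size`` is (transverse cm per line, lateral cm per sample) — e.g.
    the 0.2 x 2 cm pixels of a 1 m altitude / 20 m-min^-1 scan upsample the
    line axis 10x. Labels use nearest-neighbor (no new label values); color
    uses linear interpolation.
    """
    transverse, lateral = pixel_size
    if transverse <= 0 or lateral <= 0:
        raise ValueError("pixel dimensions must be > 0")
    target = min(transverse, lateral)
    zoom_line = transverse / target
    zoom_sample = lateral / target
    if zoom_line == 1.0 and zoom_sample == 1.0:
        return image.copy()

    from scipy import ndimage

    arr = np.asarray(image)
    factors = (zoom_line, zoom_sample) + (1.0,) * (arr.ndim - 2)
    order = 0 if is_labels else 1
    out = ndimage.zoom(arr, factors, order=order, mode="nearest", grid_mode=True)
    if is_labels:
        out = out.astype(arr.dtype)
    return out


def save_png(image: np.ndarray, path: str | os.PathLike) -> None:
    """Write a [0,1] color image (or a 2-D array, colormapped) as PNG."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    arr = np.asarray(image)
    if arr.ndim == 2:
        plt.imsave(os.fspath(path), arr)
    else:
        plt.imsave(os.fspath(path), np.clip(arr, 0.0, 1.0))
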