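"""In-scene gray-board reference correction: radiance -> relative reflectance.

A spectrally flat gray board (25 x 25 cm in the field protocol) is placed in
the scene; its mean radiance spectrum carries the downwelling illumination
times the water-column attenuation over the board's path. Dividing every
pixel spectrum by the board spectrum (times the board albedo) cancels the
shared light field and yields reflectance relative to the board. The single
transect-wide correction rests on the assumption that the average light
field does not change significantly over the 1-2 minutes of a transect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cube_io import SpectralCube, to_rgb

__all__ = ["ReflectanceCube", "board_spectrum", "to_reflectance", "true_color"]


@dataclass
class ReflectanceCube(SpectralCube):
    """Relative-reflectance cube; the board region maps to ``board_albedo``."""

    board_albedo: float = 1.0


def _region_mask(shape: tuple[int, int], region) -> np.ndarray:
    """Boolean pixel mask for a polygon region (vertices in (line, sample))."""
    from .classify import _rasterize_polygon

    return _rasterize_polygon(np.asarray(region, dtype=float), shape)


def board_spectrum(cube: SpectralCube, board_region) -> tuple[np.ndarray, np.ndarray]:
    """Per-band mean spectrum over the gray-board pixels, plus a QC CV.

    ``board_region`` is a polygon (vertex list in (line, sample) coordinates)
    or a boolean mask. Returns ``(mean, cv)`` where ``cv`` is the per-band
    coefficient of variation over the board pixels — a quality check on board
    uniformity/shadowing. The region must cover at least 25 pixels and every
    band mean must be positive to be a usable reference.
    """
    region = np.asarray(board_region)
    if region.dtype == bool:
        mask = region
    else:
        mask = _region_mask(cube.shape[:2], region)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("board region rasterizes to zero pixels")
    if n < 25:
        raise ValueError(f"board region covers only {n} pixels; need >= 25")
    pixels = cube.values[mask].astype(float)  # (n, B)
    mean = pixels.mean(axis=0)
    if np.any(mean <= 0):
        bad = int(np.sum(mean <= 0))
        raise ValueError(f"{bad} band(s) have non-positive board mean; unusable reference")
    cv = pixels.std(axis=0, ddof=0) / mean
    return mean, cv


def to_reflectance(
    cube: SpectralCube,
    board: np.ndarray,
    board_albedo: float = 1.0,
    smooth_board: int | None = None,
) -> tuple[ReflectanceCube, np.ndarray]:
    """Divide every pixel spectrum by the board spectrum (white balance).

    R(l, s, lambda) = board_albedo * I(l, s, lambda) / I_board(lambda).

    Values are deliberately not clipped — noise and shadow produce reflectance
    outside [0, 1] and clipping would bias derivative indices downstream;
    instead a boolean QC mask of out-of-gamut pixels (any band < 0 or > 1) is
    returned alongside the cube. ``smooth_board`` optionally boxcar-smooths a
    noisy board spectrum (odd width in bands) before use.
    """
    board = np.asarray(board, dtype=float)
    if board.ndim != 1 or board.size != cube.n_bands:
        raise ValueError(
            f"board spectrum length {board.size} does not match band count {cube.n_bands}"
        )
    if np.any(board <= 0):
        raise ValueError("board spectrum has non-positive entries; unusable reference")
    if smooth_board is not None:
        if smooth_board % 2 != 1 or smooth_board < 1:
            raise ValueError("smooth_board must be a positive odd width")
        kernel = np.ones(smooth_board) / smooth_board
        board = np.convolve(np.pad(board, smooth_board // 2, mode="edge"), kernel, mode="valid")

    values = board_albedo * (cube.values.astype(np.float64) / board[None, None, :])
    out_of_gamut = np.any((values < 0.0) | (values > 1.0), axis=2)
    rcube = ReflectanceCube(
        values,
        cube.wavelengths.copy(),
        line_period=cube.line_period,
        meta=dict(cube.meta),
        board_albedo=board_albedo,
    )
    return rcube, out_of_gamut


def true_color(
    rcube: ReflectanceCube,
    rgb_wavelengths=(640.0, 540.0, 460.0),
    stretch: tuple[float, float] = (2.0, 98.0),
) -> np.ndarray:
    """Color rendering of a reflectance cube; the gray board renders neutral.

    Unlike :func:`~benthoscan.cube_io.to_rgb` (display stretch per channel),
    the three reflectance planes share one percentile stretch — independent
    scaling would re-tint the scene the correction just removed.
    """
    from .cube_io import band_index

    planes = [rcube.values[:, :, band_index(rcube, w)].astype(float) for w in rgb_wavelengths]
    pooled = np.concatenate([p.ravel() for p in planes])
    lo, hi = np.percentile(pooled, stretch)
    if hi <= lo:
        import warnings

        warnings.warn("degenerate reflectance planes; true-color image is black")
        return np.zeros(planes[0].shape + (3,), dtype=float)
    return np.stack([np.clip((p - lo) / (hi - lo), 0.0, 1.0) for p in planes], axis=-1)
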