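"""Smoothed spectral derivatives and named photopigment/substrate index maps.

Derivative spectroscopy localizes narrow absorption features that broad-band
color cannot: a reflectance absorption dip is convex at its minimum, so the
second derivative evaluated at the feature wavelength is positive where the
absorber is present, and (for a Gaussian-shaped dip of depth d and width
sigma) scales linearly with d as d/sigma^2. Derivatives are computed with
local-polynomial (Savitzky-Golay) fits, which are the standard way to
stabilize band-to-band noise while preserving narrow features.

The built-in index registry:

====================  =====  ========  ====================================
name                  order  nm        interpretation
====================  =====  ========  ====================================
chl_670               2nd    670       chlorophyllic-pigment absorption
coral_rededge_700     1st    700       coral red-edge slope (positives kept)
chromo_580            2nd    580       coral host chromoprotein absorption
phyco_605             2nd    605       phycoerythrin (sediment microalgae)
====================  =====  ========  ====================================
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .cube_io import SpectralCube, band_index

__all__ = ["IndexSpec", "IndexMap", "INDEX_REGISTRY", "smooth_derivative", "index_map"]


@dataclass(frozen=True)
class IndexSpec:
    """A derivative index: which derivative, at which wavelength, which sign.

    ``sign`` states which sign of the derivative indicates presence of the
    target; ``rectify`` zeroes values of the opposite sign for display (used
    for the 700 nm red-edge index, defined on positive first derivatives).
    """

    name: str
    derivative_order: int
    wavelength: float
    sign: int = +1
    rectify: bool = False

    def __post_init__(self) -> None:
        if self.derivative_order not in (1, 2):
            raise ValueError("derivative_order must be 1 or 2")
        if self.sign not in (-1, +1):
            raise ValueError("sign must be +1 or -1")


@dataclass
class IndexMap:
    """Per-pixel scalar index values; units are reflectance * nm^(-order)."""

    values: np.ndarray
    spec: IndexSpec

    @property
    def units(self) -> str:
        return f"reflectance nm^-{self.spec.derivative_order}"


INDEX_REGISTRY: dict[str, IndexSpec] = {
    "chl_670": IndexSpec("chl_670", 2, 670.0, +1, False),
    "coral_rededge_700": IndexSpec("coral_rededge_700", 1, 700.0, +1, True),
    "chromo_580": IndexSpec("chromo_580", 2, 580.0, +1, False),
    "phyco_605": IndexSpec("phyco_605", 2, 605.0, +1, False),
}


def _check_even_grid(wavelengths: np.ndarray, tol: float = 0.01) -> float:
    steps = np.diff(wavelengths)
    mean_step = float(np.mean(steps))
    if mean_step <= 0:
        raise ValueError("wavelengths must be strictly increasing")
    if np.max(np.abs(steps - mean_step)) > tol * mean_step:
        raise ValueError(
            "wavelength grid is uneven beyond 1% tolerance; resample to an even "
            "grid (e.g. linear interpolation at the median spacing) before "
            "differentiation"
        )
    return mean_step


def smooth_derivative(
    spectrum: np.ndarray,
    wavelengths: np.ndarray,
    order: int,
    window: int = 7,
    polyorder: int | None = None,
) -> np.ndarray:
    """Savitzky-Golay derivative of one or many spectra, in physical units.

    Parameters
    ----------
    spectrum : array, (..., B)
        Reflectance (or radiance) spectra along the last axis.
    wavelengths : array, (B,)
        Band centers in nm; must be evenly spaced within 1%.
    order : {1, 2}
        Derivative order; output units are per nm or per nm^2.
    window : odd int
        Fit window in bands (default 7, ~10 nm at 1.5 nm sampling).
    polyorder : int, optional
        Local polynomial degree; defaults to 2 for first and 4 for second
        derivatives (a cubic's center second derivative equals a quadratic's
        and carries an O(h^2) bias proportional to the 4th derivative of the
        spectrum; the quartic cancels it, which matters for narrow pigment
        features). Edge bands come from one-sided polynomial fits.
    """
    spectrum = np.asarray(spectrum, dtype=float)
    wavelengths = np.asarray(wavelengths, dtype=float)
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    if polyorder is None:
        polyorder = 2 if order == 1 else 4
    if window % 2 != 1:
        raise ValueError("window must be odd")
    if not (window > polyorder >= order):
        raise ValueError("need window > polyorder >= order")
    if spectrum.shape[-1] < window:
        raise ValueError(f"need at least {window} bands, got {spectrum.shape[-1]}")
    step = _check_even_grid(wavelengths)
    return savgol_filter(
        spectrum, window_length=window, polyorder=polyorder, deriv=order,
        delta=step, axis=-1, mode="interp",
    )


def index_map(
    rcube: SpectralCube,
    spec: IndexSpec | str,
    window: int = 7,
    polyorder: int | None = None,
) -> IndexMap:
    """Evaluate a derivative index at its wavelength for every pixel.

    Uneven wavelength grids are linearly resampled to the median band spacing
    before differentiation. With ``spec.rectify`` true, values of the sign
    opposite ``spec.sign`` are set to 0 (the red-edge index is defined on
    positive first derivatives only).
    """
    if isinstance(spec, str):
        try:
            spec = INDEX_REGISTRY[spec]
        except KeyError:
            raise KeyError(
                f"unknown index '{spec}'; registered: {sorted(INDEX_REGISTRY)}"
            ) from None

    wl = rcube.wavelengths
    values = rcube.values
    steps = np.diff(wl)
    mean_step = float(np.mean(steps))
    if np.max(np.abs(steps - mean_step)) > 0.01 * mean_step:
        step = float(np.median(steps))
        wl_even = np.arange(wl[0], wl[-1] + step / 2, step)
        flat = values.reshape(-1, wl.size)
        values = np.stack([np.interp(wl_even, wl, row) for row in flat]).reshape(
            values.shape[:2] + (wl_even.size,)
        )
        wl = wl_even

    if not (wl[0] <= spec.wavelength <= wl[-1]):
        raise ValueError(
            f"index wavelength {spec.wavelength} nm outside cube range [{wl[0]}, {wl[-1]}] nm"
        )
    deriv = smooth_derivative(values, wl, spec.derivative_order, window, polyorder)
    band = int(np.argmin(np.abs(wl - spec.wavelength)))
    plane = deriv[:, :, band]
    if spec.rectify:
        plane = np.where(np.sign(plane) == spec.sign, plane, 0.0)
    return IndexMap(plane, spec)
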