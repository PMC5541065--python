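"""Synthetic underwater hyperspectral transect scenes with ground truth.

The simulator builds everything a field transect delivers — a radiance cube,
the true class layout, a gray reference board, a 1-Hz sensor track — from a
fully parameterized forward model, so every analysis stage can be verified
against known inputs:

    I(pixel, lambda) = E(lambda) * exp(-2 * Kd(lambda) * h_line)
                       * R_class(lambda) * (1 + eps),   eps ~ N(0, 1/SNR)

where E is the downwelling illumination spectrum, Kd the diffuse attenuation
of the water (1/m), h the imaging altitude of the line, and R_class the
class endmember reflectance. The factor 2 approximates the down-and-back
light path for bottom-reflected light with the board at the bottom. Class
endmembers are a flat baseline minus Gaussian absorption features (center,
width, depth) plus a linear red-edge rise beyond 690 nm — the feature model
behind the 670/700/580/605 nm derivative indices. Noise is multiplicative
Gaussian (shot-noise-like proportionality), seeded and reproducible.

The simulator does not attempt radiative-transfer realism: no surface glint,
no inter-pixel scattering or blur, no bidirectional reflectance, and noise
whose SNR does not fall with attenuation. Results on synthetic scenes bound
what the pipeline can do under its own assumptions, not field performance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .classify import UNLABELED, AnnotationSet, LabelMap
from .cube_io import SpectralCube
from .topography import SensorTrack

__all__ = [
    "ClassSpec", "SceneSpec", "Scene", "build_endmember", "generate_scene",
    "sparse_annotations", "reef11_spec", "elevated_variant",
    "default_illumination", "default_kd",
]

RED_EDGE_ONSET = 690.0  # nm


@dataclass(frozen=True)
class ClassSpec:
    """Endmember recipe: baseline reflectance, Gaussian absorption features
    [(center nm, width nm, depth)], and a red-edge slope (per nm beyond 690)."""

    name: str
    baseline: float
    features: tuple[tuple[float, float, float], ...] = ()
    red_edge_slope: float = 0.0

    def __post_init__(self) -> None:
        for center, width, depth in self.features:
            if width <= 0:
                raise ValueError(f"{self.name}: feature width must be > 0")
            if not (0.0 <= depth <= self.baseline):
                raise ValueError(f"{self.name}: feature depth must be in [0, baseline]")


def default_illumination(wavelengths: np.ndarray) -> np.ndarray:
    """Smooth daylight-like downwelling spectrum (arbitrary linear units)."""
    wl = np.asarray(wavelengths, dtype=float)
    return 0.6 + 0.8 * np.exp(-(((wl - 560.0) / 220.0) ** 2))

_KD_KNOTS_NM = np.array([400.0, 500.0, 600.0, 650.0, 700.0, 750.0, 800.0, 850.0, 900.0])
_KD_KNOTS = np.array([0.03, 0.05, 0.20, 0.30, 0.50, 0.80, 1.50, 2.00, 2.50])


def default_kd(wavelengths: np.ndarray) -> np.ndarray:
    """Clear-water-like diffuse attenuation Kd(lambda) in 1/m, rising from
    0.03 at 400 nm through 0.5 at 700 nm to 2.5 at 900 nm."""
    return np.interp(np.asarray(wavelengths, dtype=float), _KD_KNOTS_NM, _KD_KNOTS)


@dataclass
class SceneSpec:
    """Full parameterization of a synthetic transect scene.

    ``layout`` is either ``None`` (elliptical blobs placed by seeded
    rejection sampling: ``blobs_per_class`` ellipses per non-background,
    non-board class) or an explicit list of (vertices, class name) polygons.
    ``altitude`` is a scalar (m), a per-line array, or a callable of the
    line fraction in [0, 1]. ``snr`` is the multiplicative signal-to-noise
    ratio; ``np.inf`` disables noise. The seed is mandatory: scenes are
    deterministic functions of their spec.
    """

    classes: Sequence[ClassSpec]
    shape: tuple[int, int] = (200, 640)
    wavelengths: np.ndarray = field(
        default_factory=lambda: np.linspace(400.0, 900.0, 480)
    )
    background: str | None = None  # defaults to first class
    board_class: str = "Reference"
    board_albedo: float = 0.30
    board_rect: tuple[int, int, int, int] = (5, 40, 8, 45)  # (l0, l1, s0, s1) exclusive
    layout: list[tuple[np.ndarray, str]] | None = None
    blobs_per_class: int = 3
    blob_semiaxes: tuple[tuple[float, float], tuple[float, float]] = ((8.0, 16.0), (15.0, 35.0))
    illumination: Callable[[np.ndarray], np.ndarray] | np.ndarray = default_illumination
    kd: Callable[[np.ndarray], np.ndarray] | np.ndarray = default_kd
    altitude: float | np.ndarray | Callable[[np.ndarray], np.ndarray] = 1.0
    seafloor: Callable[[np.ndarray], np.ndarray] = field(
        default_factory=lambda: (lambda x: 3.0 + 0.3 * np.sin(2 * np.pi * x / 6.0))
    )
    transect_length: float = 12.5
    line_period: float = 0.175
    snr: float = 50.0
    seed: int = 0

    def class_names(self) -> list[str]:
        return [c.name for c in self.classes]


@dataclass
class Scene:
    """A generated scene: radiance cube, truth labels, sensor track, board."""

    cube: SpectralCube
    truth: LabelMap
    track: SensorTrack
    board_region: np.ndarray  # polygon vertices (line, sample)
    spec: SceneSpec


def build_endmember(cls: ClassSpec, wavelengths: np.ndarray) -> np.ndarray:
    """Endmember reflectance: baseline - sum of Gaussian dips + red edge.

    R(l) = baseline - sum_i depth_i * exp(-(l-center_i)^2 / (2 width_i^2))
           + slope * max(0, l - 690), clipped to >= 0.001.
    """
    wl = np.asarray(wavelengths, dtype=float)
    r = np.full(wl.shape, cls.baseline, dtype=float)
    for center, width, depth in cls.features:
        r -= depth * np.exp(-((wl - center) ** 2) / (2.0 * width**2))
    r += cls.red_edge_slope * np.maximum(0.0, wl - RED_EDGE_ONSET)
    return np.maximum(r, 1e-3)


def _altitude_per_line(spec: SceneSpec, n_lines: int) -> np.ndarray:
    frac = np.arange(n_lines) / max(n_lines - 1, 1)
    alt = spec.altitude
    if callable(alt):
        h = np.asarray(alt(frac), dtype=float)
    elif np.ndim(alt) == 0:
        h = np.full(n_lines, float(alt))
    else:
        h = np.asarray(alt, dtype=float)
        if h.size != n_lines:
            raise ValueError("altitude array length must equal line count")
    if np.any(h <= 0):
        raise ValueError("altitudes must be > 0")
    return h


def _spectral(fn_or_arr, wavelengths: np.ndarray) -> np.ndarray:
    arr = fn_or_arr(wavelengths) if callable(fn_or_arr) else np.asarray(fn_or_arr, dtype=float)
    if arr.shape != wavelengths.shape:
        raise ValueError("spectral curve length must match wavelength axis")
    return arr


def _build_truth(spec: SceneSpec, rng: np.random.Generator) -> LabelMap:
    names = spec.class_names()
    if len(names) != len(set(names)):
        raise ValueError("class names must be unique")
    background = spec.background or names[0]
    for required in (background,):
        if required not in names:
            raise ValueError(f"background class '{required}' not in class list")
    index_of = {n: i for i, n in enumerate(sorted(names))}
    L, S = spec.shape
    truth = np.full((L, S), index_of[background], dtype=np.int32)

    l0, l1, s0, s1 = spec.board_rect
    has_board = spec.board_class in names
    occupied = np.zeros((L, S), dtype=bool)
    if has_board:
        if (l1 - l0) * (s1 - s0) < 25:
            raise ValueError("board rect must cover >= 25 pixels")
        truth[l0:l1, s0:s1] = index_of[spec.board_class]
        occupied[l0:l1, s0:s1] = True

    if spec.layout is not None:
        from .classify import _rasterize_polygon

        for verts, name in spec.layout:
            mask = _rasterize_polygon(np.asarray(verts, dtype=float), (L, S))
            truth[mask & ~occupied] = index_of[name]
        return LabelMap(truth, {i: n for n, i in index_of.items()})

    gl, gs = np.mgrid[0:L, 0:S]
    blob_classes = [n for n in names if n not in (background, spec.board_class)]
    for name in blob_classes:
        placed = 0
        attempts = 0
        while placed < spec.blobs_per_class:
            attempts += 1
            if attempts > 200 * spec.blobs_per_class:
                raise ValueError(
                    f"could not place {spec.blobs_per_class} blobs for class "
                    f"'{name}'; scene too crowded for the requested layout"
                )
            (amin, amax), (bmin, bmax) = spec.blob_semiaxes
            a = rng.uniform(amin, amax)  # line semi-axis
            b = rng.uniform(bmin, bmax)  # sample semi-axis
            cl = rng.uniform(a + 1, L - a - 1)
            cs = rng.uniform(b + 1, S - b - 1)
            mask = ((gl - cl) / a) ** 2 + ((gs - cs) / b) ** 2 <= 1.0
            if np.any(mask & occupied):
                continue
            truth[mask] = index_of[name]
            occupied |= mask
            placed += 1
    return LabelMap(truth, {i: n for n, i in index_of.items()})


def _make_track(spec: SceneSpec, altitudes: np.ndarray, rng: np.random.Generator) -> SensorTrack:
    n_lines = spec.shape[0]
    duration = n_lines * spec.line_period
    t = np.arange(0.0, max(duration, 2.0) + 1e-9, 1.0)  # 1 Hz
    frac = np.clip(t / duration, 0.0, 1.0)
    x = spec.transect_length * frac
    altitude_t = np.interp(frac, np.arange(n_lines) / max(n_lines - 1, 1), altitudes)
    bottom = np.asarray(spec.seafloor(x), dtype=float)
    depth = np.maximum(bottom - altitude_t, 0.0)
    par = 1500.0 * np.exp(-0.15 * depth) * (1.0 + 0.01 * rng.standard_normal(t.size))
    o2 = 6.8 + 0.05 * np.sin(2 * np.pi * frac) + 0.01 * rng.standard_normal(t.size)
    ph = 8.10 + 0.02 * np.sin(2 * np.pi * frac + 1.0) + 0.002 * rng.standard_normal(t.size)
    return SensorTrack(t, depth, altitude_t, par=par, o2=o2, ph=ph)


def generate_scene(spec: SceneSpec) -> Scene:
    """Run the forward model: truth layout -> radiance cube + sensor track.

    Deterministic for a fixed spec (including its seed). Raises if the blob
    layout cannot be placed inside the scene.
    """
    truth = _build_truth(spec, np.random.default_rng(spec.seed))
    return _generate_with_truth(spec, truth)


def sparse_annotations(
    truth: LabelMap,
    per_class_fraction: float = 0.015,
    seed: int = 0,
    min_pixels_per_class: int = 40,
    board_class: str = "Reference",
) -> AnnotationSet:
    """Sparse rectangular annotations emulating a diver's sparse polygon effort.

    Seeded rejection sampling places small axis-aligned rectangles strictly
    inside each class's true region until the per-class quota is met; quotas
    are proportional to class abundance (with a floor) and total roughly
    ``per_class_fraction`` of the scene's pixels. Every class present in the
    truth map is represented. Raises if a class occupies < 50 pixels.
    """
    rng = np.random.default_rng(seed)
    L, S = truth.shape
    total = L * S
    regions: list[tuple[np.ndarray, str]] = []
    annotated = np.zeros((L, S), dtype=bool)

    for idx in sorted(truth.legend):
        name = truth.legend[idx]
        mask = truth.indices == idx
        count = int(mask.sum())
        if count == 0:
            continue
        if count < 50:
            raise ValueError(f"class '{name}' occupies only {count} pixels; need >= 50")
        quota = max(min_pixels_per_class, int(round(per_class_fraction * count)))
        quota = min(quota, count // 2)
        got = 0
        candidates = np.argwhere(mask)
        attempts = 0
        while got < quota:
            attempts += 1
            if attempts > 500 + 200 * quota:
                raise ValueError(f"could not annotate class '{name}' to quota")
            cl, cs = candidates[rng.integers(candidates.shape[0])]
            remaining = quota - got
            half = int(np.clip(np.sqrt(remaining) / 2 + 1, 1, 5))
            hl = int(rng.integers(1, half + 1))
            hs = int(rng.integers(1, half + 1))
            l0, l1 = cl - hl, cl + hl
            s0, s1 = cs - hs, cs + hs
            if l0 < 0 or s0 < 0 or l1 >= L or s1 >= S:
                continue
            patch = truth.indices[l0 : l1 + 1, s0 : s1 + 1]
            if not np.all(patch == idx):
                continue
            new = ~annotated[l0 : l1 + 1, s0 : s1 + 1]
            if new.sum() == 0:
                continue
            annotated[l0 : l1 + 1, s0 : s1 + 1] = True
            got += int(new.sum())
            regions.append(
                (
                    np.array(
                        [
                            [l0 - 0.45, s0 - 0.45],
                            [l0 - 0.45, s1 + 0.45],
                            [l1 + 0.45, s1 + 0.45],
                            [l1 + 0.45, s0 - 0.45],
                        ]
                    ),
                    name,
                )
            )
    return AnnotationSet(regions, image_id=f"synthetic-seed{seed}")


# ---------------------------------------------------------------------------
# reference fixtures

_REEF11_CLASSES: tuple[ClassSpec, ...] = (
    ClassSpec("Sediment", 0.40, ((605.0, 10.0, 0.06), (670.0, 10.0, 0.03)), 0.0010),
    ClassSpec("Acropora", 0.30, ((440.0, 15.0, 0.10), (670.0, 10.0, 0.12)), 0.0040),
    ClassSpec("Briareum", 0.22, ((500.0, 20.0, 0.05), (670.0, 10.0, 0.08)), 0.0030),
    ClassSpec("Echinopora", 0.28, ((580.0, 8.0, 0.06), (670.0, 10.0, 0.10)), 0.0035),
    ClassSpec("Goniopora", 0.26, ((620.0, 12.0, 0.04), (670.0, 10.0, 0.11)), 0.0030),
    ClassSpec("Isopora", 0.32, ((460.0, 18.0, 0.06), (670.0, 10.0, 0.09)), 0.0045),
    ClassSpec("Pocillopora", 0.27, ((580.0, 8.0, 0.08), (670.0, 10.0, 0.10)), 0.0040),
    ClassSpec("Porites", 0.35, ((580.0, 8.0, 0.05), (670.0, 10.0, 0.13)), 0.0050),
    ClassSpec("Reference", 0.30),
    ClassSpec("Seriatopora", 0.24, ((430.0, 15.0, 0.08), (670.0, 10.0, 0.07)), 0.0035),
    ClassSpec("Turf", 0.20, ((605.0, 10.0, 0.05), (670.0, 10.0, 0.10)), 0.0020),
)


def reef11_spec(seed: int = 0, snr: float = 50.0) -> SceneSpec:
    """The 11-class reference reef scene: 200 x 640 pixels, 480 bands over
    400-900 nm, gray board top-left, ~1 m imaging altitude with a gentle
    along-track swing, SNR 50."""
    return SceneSpec(
        classes=_REEF11_CLASSES,
        shape=(200, 640),
        background="Sediment",
        board_class="Reference",
        altitude=lambda frac: 1.0 + 0.2 * np.sin(2 * np.pi * 3.0 * frac),
        snr=snr,
        seed=seed,
    )


def elevated_variant(
    spec: SceneSpec,
    truth: LabelMap,
    altitude_factor: float = 2.0,
    swath_factor: float = 1.5,
    seed: int | None = None,
) -> tuple[SceneSpec, "Scene"]:
    """Re-scan of the same transect area from higher altitude.

    Doubling the altitude widens the swath, so the same layout occupies
    1/swath_factor of the sample axis (coarser lateral pixels, padded with
    the background class at the edges) and every line's water path doubles.
    Returns the new spec and the generated scene.
    """
    L, S = truth.shape
    new_w = int(round(S / swath_factor))
    pad = (S - new_w) // 2
    cols = np.clip((np.arange(new_w) * swath_factor).astype(int), 0, S - 1)
    shrunk = truth.indices[:, cols]
    names = sorted(n for n in spec.class_names())
    index_of = {n: i for i, n in enumerate(names)}
    background_idx = index_of[spec.background or spec.classes[0].name]
    new_truth = np.full((L, S), background_idx, dtype=np.int32)
    new_truth[:, pad : pad + new_w] = shrunk

    base_alt = spec.altitude
    if callable(base_alt):
        new_alt = lambda frac, _b=base_alt, _f=altitude_factor: _f * np.asarray(_b(frac))
    elif np.ndim(base_alt) == 0:
        new_alt = altitude_factor * float(base_alt)
    else:
        new_alt = altitude_factor * np.asarray(base_alt, dtype=float)

    # locate the (shrunk, shifted) board rectangle in the new frame
    l0, l1, s0, s1 = spec.board_rect
    s0n = pad + int(np.searchsorted(cols, s0))
    s1n = pad + int(np.searchsorted(cols, s1 - 1)) + 1
    new_spec = SceneSpec(
        classes=spec.classes,
        shape=spec.shape,
        wavelengths=np.asarray(spec.wavelengths, dtype=float).copy(),
        background=spec.background,
        board_class=spec.board_class,
        board_albedo=spec.board_albedo,
        board_rect=(l0, l1, s0n, s1n),
        layout=[],  # truth supplied explicitly below
        illumination=spec.illumination,
        kd=spec.kd,
        altitude=new_alt,
        seafloor=spec.seafloor,
        transect_length=spec.transect_length,
        line_period=spec.line_period,
        snr=spec.snr,
        seed=spec.seed + 1 if seed is None else seed,
    )
    scene = _generate_with_truth(new_spec, LabelMap(new_truth, {i: n for n, i in index_of.items()}))
    return new_spec, scene


def _generate_with_truth(spec: SceneSpec, truth: LabelMap) -> Scene:
    """Forward model on an explicit truth map (bypasses layout generation)."""
    rng = np.random.default_rng((spec.seed, 1))
    wl = np.asarray(spec.wavelengths, dtype=float)
    index_to_spec = {c.name: c for c in spec.classes}
    endmembers = np.zeros((len(spec.classes), wl.size))
    for idx, name in truth.legend.items():
        if name == spec.board_class:
            endmembers[idx] = spec.board_albedo
        else:
            endmembers[idx] = build_endmember(index_to_spec[name], wl)
    E = _spectral(spec.illumination, wl)
    kd = _spectral(spec.kd, wl)
    if np.any(E <= 0):
        raise ValueError("illumination must be positive")
    if np.any(kd < 0):
        raise ValueError("Kd must be >= 0")
    altitudes = _altitude_per_line(spec, spec.shape[0])
    att = E[None, :] * np.exp(-2.0 * np.outer(altitudes, kd))
    values = endmembers[truth.indices] * att[:, None, :]
    if np.isfinite(spec.snr):
        noise = rng.standard_normal(values.shape)
        values *= 1.0 + noise / spec.snr
        np.maximum(values, 1e-8, out=values)
    cube = SpectralCube(values, wl, line_period=spec.line_period,
                        meta={"description": "synthetic transect scene", "seed": spec.seed})
    track = _make_track(spec, altitudes, rng)
    l0, l1, s0, s1 = spec.board_rect
    board_poly = np.array(
        [[l0 - 0.45, s0 - 0.45], [l0 - 0.45, s1 - 0.55], [l1 - 0.55, s1 - 0.55], [l1 - 0.55, s0 - 0.45]]
    )
    return Scene(cube=cube, truth=truth, track=track, board_region=board_poly, spec=spec)
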