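import numpy as np
import pytest

from benthoscan.synthetic_scene import ClassSpec, SceneSpec, generate_scene


def quad_classes() -> tuple[ClassSpec, ...]:
    """Four benthic classes + gray board: sand background, a red-edged coral,
    a chromoprotein-bearing coral, and turf algae."""
    return (
        ClassSpec("Sand", 0.40, ((605.0, 10.0, 0.05),), 0.001),
        ClassSpec("Coral", 0.30, ((670.0, 10.0, 0.12),), 0.004),
        ClassSpec("Chromo", 0.28, ((580.0, 8.0, 0.08), (670.0, 10.0, 0.10)), 0.003),
        ClassSpec("Algae", 0.20, ((670.0, 10.0, 0.10),), 0.0015),
        ClassSpec("Reference", 0.30),
    )


def small_spec(snr=np.inf, altitude=1.0, seed=7, shape=(40, 100)) -> SceneSpec:
    return SceneSpec(
        classes=quad_classes(),
        shape=shape,
        background="Sand",
        board_rect=(2, 12, 2, 12),
        blobs_per_class=2,
        blob_semiaxes=((4.0, 7.0), (6.0, 12.0)),
        altitude=altitude,
        snr=snr,
        seed=seed,
    )


@pytest.fixture(scope="session")
def noiseless_scene():
    """Noise-free, constant-altitude 4-class scene: the exact-recovery oracle."""
    return generate_scene(small_spec())


@pytest.fixture(scope="session")
def noisy_scene():
    """SNR-50 scene with an altitude swing along the track (realistic case)."""
    return generate_scene(
        small_spec(snr=50.0, altitude=lambda f: 1.0 + 0.2 * np.sin(2 * np.pi * f), seed=7)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
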