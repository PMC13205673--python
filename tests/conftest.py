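"""Shared fixtures: small, fast phantoms generated at test time."""

import numpy as np
import pytest

from stemsim import PhantomConfig, build_stem_frame, generate_phantom

#: Desk-scale phantom used by most unit tests: axis-aligned stem so that
#: integer shifts are exact in the image grid.
SMALL_CONFIG = PhantomConfig(
    shape=(64, 64, 96),
    spacing_mm=(0.7812, 0.7812, 0.45),
    stem_length_mm=18.0,
    stem_radius_mm=4.0,
    head_radius_mm=3.5,
    neck_length_mm=5.5,
    stem_tilt_deg=0.0,
)


@pytest.fixture(scope="session")
def small_phantom():
    """Noise-free axis-aligned right-sided phantom (ct, labels, landmarks)."""
    return generate_phantom(SMALL_CONFIG)


@pytest.fixture(scope="session")
def small_frame(small_phantom):
    _, _, landmarks = small_phantom
    return build_stem_frame(landmarks, "right")


@pytest.fixture(scope="session")
def tilted_phantom():
    """Noise-free phantom with the default 10-degree stem tilt."""
    cfg = PhantomConfig(
        shape=(64, 64, 96),
        spacing_mm=(0.7812, 0.7812, 0.45),
        stem_length_mm=18.0,
        stem_radius_mm=4.0,
        head_radius_mm=3.5,
        neck_length_mm=5.5,
        stem_tilt_deg=10.0,
    )
    return generate_phantom(cfg), cfg


@pytest.fixture(scope="session")
def left_phantom():
    cfg = PhantomConfig(
        shape=(64, 64, 96),
        spacing_mm=(0.7812, 0.7812, 0.45),
        stem_length_mm=18.0,
        stem_radius_mm=4.0,
        head_radius_mm=3.5,
        neck_length_mm=5.5,
        stem_tilt_deg=0.0,
        side="left",
    )
    return generate_phantom(cfg)


def rng(seed: int = 0) -> np.random.Generator:
    return np.random.default_rng(seed)
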