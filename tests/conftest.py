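"""Shared fixtures: small synthetic slides and stain mixes, all seeded."""
from __future__ import annotations

import numpy as np
import pytest

from hemlabel.normalization import od_to_rgb
from hemlabel.separation import RUIFROK_HED
from hemlabel.synthetic import SyntheticSpec, generate_pair


@pytest.fixture(scope="session")
def aligned_pair():
    """256-px synthetic pair with no misalignment (masks line up exactly)."""
    spec = SyntheticSpec(
        seed=3,
        image_shape=(256, 256),
        smooth_px=40.0,
        rotation_deg=0.0,
        translation_px=(0.0, 0.0),
    )
    return generate_pair(spec)


@pytest.fixture(scope="session")
def misaligned_pair():
    """256-px pair with a known rigid misalignment."""
    spec = SyntheticSpec(
        seed=9,
        image_shape=(256, 256),
        smooth_px=40.0,
        rotation_deg=4.0,
        translation_px=(10.0, -5.0),
    )
    return generate_pair(spec)


@pytest.fixture(scope="session")
def separated_mix():
    """Well-separated H&E mix with known stain matrix and concentrations.

    One third of pixels are hematoxylin-dominated, one third
    eosin-dominated, one third mixed — the regime in which stain-vector
    estimators are identifiable.
    """
    rng = np.random.default_rng(0)
    S = RUIFROK_HED[:2]
    n = 40000
    mode = rng.integers(0, 3, n)
    c_h = np.where(
        mode == 0,
        rng.uniform(0.5, 1.2, n),
        np.where(mode == 1, rng.uniform(0.0, 0.1, n), rng.uniform(0.2, 0.8, n)),
    )
    c_e = np.where(
        mode == 1,
        rng.uniform(0.5, 1.2, n),
        np.where(mode == 0, rng.uniform(0.0, 0.1, n), rng.uniform(0.2, 0.8, n)),
    )
    C = np.stack([c_h, c_e], axis=1)
    od = (C @ S).reshape(200, 200, 3)
    return {"S": S, "C": C, "od": od, "img": od_to_rgb(od)}


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
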