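"""Shared fixtures: all test data is generated programmatically and seeded."""

from __future__ import annotations

import numpy as np
import pytest

from aslsubvol.core_io import ImageVolume, Mask
from aslsubvol.phantom import SubjectSpec, generate_subject


@pytest.fixture(scope="session")
def canonical_subject():
    """One deterministic default subject (full-size lattice), shared read-only."""
    return generate_subject(SubjectSpec(seed=42))


@pytest.fixture(scope="session")
def small_subject():
    """A small, fast subject for geometry-light tests."""
    spec = SubjectSpec(
        grid_shape=(40, 40, 30),
        spacing_mm=(3.0, 3.0, 3.0),
        gtv_volume_cm3=60.0,
        high_perfusion_fraction=0.4,
        seed=7,
    )
    return generate_subject(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def textured_volume_region():
    """A random textured volume with an ellipsoidal region (~900 voxels)."""
    gen = np.random.default_rng(99)
    shape = (24, 24, 18)
    vol = ImageVolume(gen.normal(100.0, 20.0, shape), spacing=(1.0, 1.0, 2.0))
    x, y, z = np.indices(shape)
    r = ((x - 12) / 8.0) ** 2 + ((y - 12) / 7.0) ** 2 + ((z - 9) / 6.0) ** 2
    region = Mask.like(vol, r < 1.0)
    return vol, region
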