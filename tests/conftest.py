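"""Shared fixtures: small synthetic discs and count datasets.

Everything is generated programmatically and seeded; no data files.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from phasequant.synthetic import (
    CountSimSpec,
    DiscSpec,
    MarkerSpec,
    PhaseProfile,
    generate_disc,
)


def small_disc_spec(**overrides) -> DiscSpec:
    """A quick ~100-nucleus disc for unit tests (two 100x80 compartments)."""
    defaults = dict(
        image_shape=(220, 160),
        n_nuclei=100,
        pouch_polygon=((20.0, 20.0), (140.0, 20.0), (140.0, 100.0), (20.0, 100.0)),
        hinge_polygon=((20.0, 120.0), (140.0, 120.0), (140.0, 200.0), (20.0, 200.0)),
        seed=0,
    )
    defaults.update(overrides)
    return DiscSpec(**defaults)


@pytest.fixture(scope="session")
def noisefree_disc():
    """A noise-free default-geometry disc with an EdU channel marking S phase."""
    spec = dataclasses.replace(
        DiscSpec(seed=11),
        noise_sd=0.0,
        markers={
            "H3K27ac": MarkerSpec(),
            "EdU": MarkerSpec(
                profile=PhaseProfile(1e-3, 1.0, 1.0, 1e-3), base_intensity=18.0
            ),
        },
    )
    return generate_disc(spec)


@pytest.fixture(scope="session")
def small_noisy_disc():
    return generate_disc(small_disc_spec(seed=4, noise_sd=4.5))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def count_spec(**overrides) -> CountSimSpec:
    defaults = dict(seed=0)
    defaults.update(overrides)
    return CountSimSpec(**defaults)
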