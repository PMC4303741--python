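"""Shared fixtures: phantoms and atlas sets are generated once per session."""

from __future__ import annotations

import dataclasses

import pytest

from clinmri.phantom import (
    AtlasJitter,
    PhantomSpec,
    Pose,
    generate_atlas_set,
    generate_phantom,
)


@pytest.fixture(scope="session")
def default_spec() -> PhantomSpec:
    return PhantomSpec(seed=1)


@pytest.fixture(scope="session")
def default_phantom(default_spec):
    return generate_phantom(default_spec)


@pytest.fixture(scope="session")
def noise_free_spec() -> PhantomSpec:
    return PhantomSpec(seed=2, class_noise_sd=0.0)


@pytest.fixture(scope="session")
def noise_free_phantom(noise_free_spec):
    return generate_phantom(noise_free_spec)


@pytest.fixture(scope="session")
def atlas_set6():
    """The standard six-atlas set used by registration-heavy tests."""
    return generate_atlas_set(PhantomSpec(), n=6, seed=7)


@pytest.fixture(scope="session")
def posed_subject():
    """A subject phantom with a known non-trivial pose and mild bias."""
    spec = dataclasses.replace(
        PhantomSpec(),
        seed=11,
        bias_amplitude=0.1,
        pose=Pose((4.0, -3.0, 2.0), (5.0, -4.0, 3.0), 1.02),
    )
    return spec, generate_phantom(spec)
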