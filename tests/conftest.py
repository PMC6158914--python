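"""Shared fixtures: small deterministic grids and scaled-down phantoms."""

import dataclasses

import numpy as np
import pytest

from cupseg.image_io import BinaryMask, GrayImage
from cupseg.phantom import PhantomSpec


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_spec():
    """A 192x192 phantom with the same proportions as the default one;
    fast enough for per-test pipeline runs."""
    return PhantomSpec(
        height=192,
        width=192,
        disc_center=(96.0, 96.0),
        disc_axes=(44.0, 50.0),
        cup_axes=(22.0, 25.0),
        rim_softness=4.0,
        n_vessels=3,
        vessel_width=2.0,
        seed=11,
    )


@pytest.fixture
def clean_small_spec(small_spec):
    return dataclasses.replace(small_spec, n_vessels=0, noise_sigma=0.0)


def gray(arr, stage="green"):
    return GrayImage(np.asarray(arr, dtype=float), stage=stage)


def mask(arr, role="vessel"):
    return BinaryMask(np.asarray(arr, dtype=bool), role=role)
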