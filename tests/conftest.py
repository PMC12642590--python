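"""Shared fixtures: one small synthetic world reused across the suite."""

import numpy as np
import pytest

import biovep as bv


@pytest.fixture(scope="session")
def world():
    return bv.generate_world(L=30, seed=11)


@pytest.fixture(scope="session")
def dms(world):
    return bv.generate_dms(world, n_variants=400, read_depth=200_000, seed=11)


@pytest.fixture(scope="session")
def resources(world):
    return bv.fit_feature_resources(
        world.reference, world.aaindex_properties, world.energy_table, world.rmsf
    )


@pytest.fixture(scope="session")
def resources_plain(world):
    """Resources without the biophysics inputs (sequence-only encoding)."""
    return bv.fit_feature_resources(world.reference, world.aaindex_properties)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
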