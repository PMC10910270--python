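"""Shared fixtures: a small head, arrays and bases reused across modules.

Everything is generated programmatically and deterministically; the
session-scoped bases keep the order-9 spheroidal evaluation from being
repeated in every test.
"""

import warnings

import numpy as np
import pytest

import ammeg as am


@pytest.fixture(scope="session")
def head() -> am.ReferenceSpheroid:
    return am.default_head()


@pytest.fixture(scope="session")
def triaxial_array(head) -> am.SensorArray:
    # ~45 sensors / ~135 channels: enough for the 99+8 column model
    return am.generate_scalp_array(head, spacing=0.035, offset=0.0065, axes=3, seed=11)


@pytest.fixture(scope="session")
def radial_array(head) -> am.SensorArray:
    return am.generate_scalp_array(head, spacing=0.021, offset=0.0065, axes=1, seed=11)


@pytest.fixture(scope="session")
def triaxial_basis(triaxial_array, head) -> am.HarmonicBasis:
    return am.build_basis(triaxial_array, head, family="spheroidal", L_in=9, L_out=2)


@pytest.fixture(scope="session")
def radial_basis(radial_array, head) -> am.HarmonicBasis:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return am.build_basis(radial_array, head, family="spheroidal", L_in=9, L_out=2)


@pytest.fixture(scope="session")
def low_order_basis(triaxial_array, head) -> am.HarmonicBasis:
    return am.build_basis(triaxial_array, head, family="spheroidal", L_in=4, L_out=2)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240301)
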