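"""Shared fixtures: small synthetic templates and architectures.

Everything is generated programmatically; payload bead counts are kept small
where clash realism is not the point, so the suite stays fast.
"""

import numpy as np
import pytest

from trimerbody import (
    LinkerSpec,
    make_architecture,
    make_ideal_core,
    make_point_payload,
    make_sphere_payload,
)


@pytest.fixture(scope="session")
def core():
    return make_ideal_core(seed=0)


@pytest.fixture(scope="session")
def sphere_payload():
    return make_sphere_payload(radius=14.0, n_beads=60, seed=1)


@pytest.fixture(scope="session")
def point_payload():
    return make_point_payload()


@pytest.fixture(scope="session")
def multi_arch(core, sphere_payload):
    return make_architecture(
        "multi_chain", core, [sphere_payload] * 3, [LinkerSpec(7)] * 3
    )


@pytest.fixture(scope="session")
def tandem_arch(core, sphere_payload):
    return make_architecture(
        "tandem", core, [sphere_payload] * 3, [LinkerSpec(7)] * 3,
        [LinkerSpec(17)] * 2,
    )


@pytest.fixture(scope="session")
def point_multi_arch(core, point_payload):
    return make_architecture(
        "multi_chain", core, [point_payload] * 3, [LinkerSpec(7)] * 3
    )


@pytest.fixture(scope="session")
def point_tandem_arch(core, point_payload):
    return make_architecture(
        "tandem", core, [point_payload] * 3, [LinkerSpec(7)] * 3,
        [LinkerSpec(17)] * 2,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)
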