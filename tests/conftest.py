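import pytest

from weedspray import (DropletSpec, LeafGeometry, LeafMaterial, NozzleSpec)


@pytest.fixture
def leaf():
    """Bottom-leaf geometry of the measured weed template."""
    return LeafGeometry(length=0.035, width=0.015, thickness=4.0e-4,
                        beta_deg=33.22)


@pytest.fixture
def material():
    return LeafMaterial(elastic_modulus=272.5e6, density=700.0)


@pytest.fixture
def nozzle_spec():
    return NozzleSpec()


@pytest.fixture
def droplet():
    return DropletSpec(radius=1.0e-3)
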