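import numpy as np
import pytest

from sprgamma.optics import LayerStack, OpticalLayer, simulate_scan
from sprgamma.presets import EPS_PRISM_DEFAULT, default_chip

#: Reference operating point used across the suite.
EPS_BULK_REF = 1.8489
EPS_INTERF_REF = 2.1070


@pytest.fixture(scope="session")
def angle_grid():
    """Instrument-like grid: 0.01 deg steps spanning both features."""
    return np.arange(45.0, 70.0, 0.01)


@pytest.fixture(scope="session")
def ref_chip():
    """Calibrated reference gold chip with the index-matched bulk."""
    return default_chip(eps_bulk=EPS_BULK_REF)


@pytest.fixture(scope="session")
def dielectric_pair():
    """Prism/bulk stack whose analytic critical angle is 49.53 deg."""
    return LayerStack(
        (
            OpticalLayer("prism", EPS_PRISM_DEFAULT),
            OpticalLayer("bulk", EPS_BULK_REF),
        )
    )


@pytest.fixture(scope="session")
def clean_scan(ref_chip, angle_grid):
    """Noise-free scan of the layer-free reference chip."""
    return simulate_scan(ref_chip, angle_grid)


@pytest.fixture(scope="session")
def layered_scan(ref_chip, angle_grid):
    """Noise-free scan with the 1 nm enriched interfacial layer."""
    return simulate_scan(
        ref_chip.with_interfacial_layer(EPS_INTERF_REF, 1.0), angle_grid
    )
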