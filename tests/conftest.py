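import numpy as np
import pytest

from elastrack import DeformationSpec, GridGeometry, simulate_pair

#: default acquisition geometry used by small test fixtures (40 MHz
#: sampling, 1540 m/s, 0.21 mm pitch)
AXIAL_DX = 1540.0 / (2 * 40e6) * 1e3
LATERAL_DX = 0.21


def make_geometry(m: int, n: int) -> GridGeometry:
    return GridGeometry(
        n_axial=m, n_lateral=n,
        axial_spacing_mm=AXIAL_DX, lateral_spacing_mm=LATERAL_DX,
    )


@pytest.fixture(scope="session")
def rigid_pair():
    """Small speckle pair with a (0.3, 0.2)-sample rigid shift."""
    geometry = make_geometry(400, 48)
    spec = DeformationSpec(
        mode="rigid_shift", shift_samples=(0.3, 0.2), applied_strain=0.0
    )
    pre, post, truth = simulate_pair(geometry, spec, seed=7)
    return pre, post, truth, geometry


@pytest.fixture
def speckle_frame():
    """One modest noiseless speckle frame for IO/display tests."""
    geometry = make_geometry(256, 32)
    spec = DeformationSpec(mode="rigid_shift", applied_strain=0.0)
    pre, _, _ = simulate_pair(geometry, spec, seed=3)
    return pre
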