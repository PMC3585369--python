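import numpy as np
import pytest

from tacsim.geometry import (ShellModel, default_eeg_shells, default_field_shells,
                             dipole_layer, generate_cortical_mesh, parcellate,
                             standard_electrode_positions)

SCALP_R = 0.092


@pytest.fixture(scope="session")
def icosphere3():
    """Unperturbed subdivision-3 icosphere (1280 triangles)."""
    return generate_cortical_mesh(3, 0.08, 0.0, seed=0)


@pytest.fixture(scope="session")
def small_mesh():
    """Perturbed subdivision-2 mesh used by fast tests."""
    return generate_cortical_mesh(2, 0.077, 0.0015, seed=1)


@pytest.fixture(scope="session")
def small_parcellation(small_mesh):
    return parcellate(small_mesh, 8, seed=2)


@pytest.fixture(scope="session")
def layout1010():
    return standard_electrode_positions("10-10", SCALP_R)


@pytest.fixture(scope="session")
def layout1020():
    return standard_electrode_positions("10-20", SCALP_R)


@pytest.fixture(scope="session")
def small_dipoles(small_mesh):
    return dipole_layer(small_mesh, 1e-6)


@pytest.fixture(scope="session")
def field_shells():
    return default_field_shells()


@pytest.fixture(scope="session")
def eeg_shells():
    return default_eeg_shells()


@pytest.fixture(scope="session")
def homogeneous_shells():
    return ShellModel(radii=(0.082, SCALP_R), conductivities=(0.33, 0.33))
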