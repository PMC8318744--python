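import numpy as np
import pytest

from kalmix import (
    SensitivityMatrix,
    Spectrum,
    align_to_grid,
    build_sensitivity_matrix,
    component_spectrum,
    study_presets,
)


@pytest.fixture(scope="session")
def presets():
    """HCT-like and LSP-like band models plus the 81-point study grid."""
    return study_presets()


@pytest.fixture(scope="session")
def preset_sensitivity(presets):
    """Sensitivity matrix from noiseless 5 / 20 µg/mL preset standards."""
    hct, lsp, grid = presets
    standards = align_to_grid(
        [
            component_spectrum(hct, 5.0, grid),
            component_spectrum(lsp, 20.0, grid),
        ]
    )
    return build_sensitivity_matrix(
        standards, {standards[0].label: 5.0, standards[1].label: 20.0}
    )


@pytest.fixture
def hand_system():
    """3-wavelength, 2-component system with an exactly known solution."""
    grid = np.array([230.0, 250.0, 270.0])
    H = SensitivityMatrix(
        grid, ("x", "y"), np.array([[1.0, 0.5], [0.2, 1.0], [0.3, 0.8]])
    )
    c_true = np.array([2.0, 3.0])
    sample = Spectrum(grid, H.values @ c_true, "mix")
    return H, sample, c_true
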