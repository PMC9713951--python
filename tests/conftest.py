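import numpy as np
import pytest

from lambpress.dispersion import CharacteristicContext, forward_dispersion_curve
from lambpress.mechanics import CompartmentGeometry, FluidModel, MaterialModel
from lambpress.units import ml_to_m3, mmhg_to_pa


@pytest.fixture(scope="session")
def default_geometry() -> CompartmentGeometry:
    """260 ml compartment at 1.3x its 200 ml reference volume, 2.75 mm
    undeformed half-thickness."""
    V0 = ml_to_m3(200.0)
    return CompartmentGeometry(V=1.3 * V0, V0=V0, h0=2.75e-3)


@pytest.fixture(scope="session")
def fluid() -> FluidModel:
    return FluidModel()


@pytest.fixture(scope="session")
def soft_material() -> MaterialModel:
    return MaterialModel(mu0=5e3, b_stiff=5.0)


@pytest.fixture(scope="session")
def fit_band_freqs() -> np.ndarray:
    return np.arange(150.0, 501.0, 10.0)


@pytest.fixture(scope="session")
def reference_curve(default_geometry, fit_band_freqs):
    """Noiseless forward curve at 15 mmHg on the default geometry."""
    ctx = CharacteristicContext(P=mmhg_to_pa(15.0), geometry=default_geometry,
                                b_stiff=5.0)
    return forward_dispersion_curve(fit_band_freqs, ctx)
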