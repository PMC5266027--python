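import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from bolusim import (
    EnhancementCalibration,
    InjectionProtocol,
    PatientProfile,
    build_model,
    compute_body_parameters,
    concentration_to_hu,
    load_default_config,
    simulate,
)


@pytest.fixture(scope="session")
def config():
    return load_default_config()


@pytest.fixture(scope="session")
def reference_profile():
    """The worked-example adult: male, 170 cm, 75 kg."""
    return PatientProfile(sex="male", height_cm=170.0, weight_kg=75.0, id="ref")


@pytest.fixture(scope="session")
def protocol(config):
    return InjectionProtocol.from_config(config)


@pytest.fixture(scope="session")
def calibration(config):
    return EnhancementCalibration.from_config(config)


@pytest.fixture(scope="session")
def reference_model(reference_profile, config):
    body = compute_body_parameters(reference_profile, config)
    return build_model(body, config, recirculation=False)


@pytest.fixture(scope="session")
def reference_curve(reference_model, protocol):
    """Default-adult, default-protocol simulation reused across tests."""
    return simulate(reference_model, protocol, t_end_s=90.0, dt_out_s=0.1)


@pytest.fixture(scope="session")
def reference_tdc(reference_curve, calibration, protocol):
    return concentration_to_hu(reference_curve, calibration, protocol.tube_voltage_kv)


@pytest.fixture()
def smooth_curve():
    """A synthetic gamma-variate-like arterial curve with known peak."""
    t = np.linspace(0.0, 60.0, 601)
    shape = np.where(t > 8.0, (t - 8.0) ** 3 * np.exp(-(t - 8.0) / 4.0), 0.0)
    att = 50.0 + 450.0 * shape / shape.max()
    return t, att
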