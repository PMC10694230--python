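import numpy as np
import pytest

from bolusco import (
    CalibrationConstant,
    InjectionProtocol,
    PatientProfile,
    TimeDensityCurve,
    body_composition,
    build_default_model,
    simulate,
)


@pytest.fixture(scope="session")
def ref_profile():
    return PatientProfile(height_cm=180.0, weight_kg=80.0, sex="male",
                          pulse_bpm=60.0, id="ref")


@pytest.fixture(scope="session")
def ref_body(ref_profile):
    return body_composition(ref_profile)


@pytest.fixture(scope="session")
def injection():
    return InjectionProtocol()


@pytest.fixture(scope="session")
def calib():
    return CalibrationConstant()


@pytest.fixture(scope="session")
def ref_model(ref_profile, ref_body):
    return build_default_model(ref_profile, ref_body, 5.0)


@pytest.fixture(scope="session")
def ref_sim(ref_model, injection, calib):
    """Forward simulation at CO = 5 L/min, 45 s, default step."""
    return simulate(ref_model, injection, calib, duration_s=45.0)


@pytest.fixture(scope="session")
def ref_tdc(ref_sim):
    """The reference simulation resampled on a clinical 2-s grid, noiseless."""
    grid = np.arange(0.0, 40.0 + 1e-9, 2.0)
    return TimeDensityCurve(times=grid,
                            hu=np.interp(grid, ref_sim.times, ref_sim.hu))


def gamma_variate_samples(times, t0=8.0, t_max=18.0, y_max=200.0, alpha=3.0,
                          baseline=40.0):
    """Noise-free gamma-variate enhancement on a grid, plus baseline."""
    times = np.asarray(times, dtype=float)
    u = np.clip((times - t0) / (t_max - t0), 0.0, None)
    y = np.where(u > 0, y_max * u ** alpha * np.exp(alpha * (1.0 - u)), 0.0)
    return baseline + y
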