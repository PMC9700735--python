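import numpy as np
import pytest

from nucleoforce import synth
from nucleoforce.fractions import ArrheniusFit

# the fitted two-state parameters for the two headline conditions
FIT_WITHOUT = ArrheniusFit(f_half=10.6, delta_x=5.7)
FIT_WITH = ArrheniusFit(f_half=5.5, delta_x=4.4)


@pytest.fixture(scope="session")
def noiseless_staircase():
    """Clean three-level staircase trace (0/26/52 nm, 100 s dwells)."""
    from nucleoforce.stepfit import ForceClampTrace

    t = np.arange(0, 300, 0.02)
    d = np.zeros_like(t)
    d[t >= 100] += 26.0
    d[t >= 200] += 26.0
    return ForceClampTrace(time=t, distance=d, force_setpoint=10.0)


@pytest.fixture(scope="session")
def monomer_psf_calibration():
    """Calibrated PSF from 60 synthetic single-monomer profiles."""
    from nucleoforce import kymo

    profiles = []
    for i in range(60):
        km, _ = synth.simulate_kymograph(
            [(5000.0, 1)], n_lines=60, photons_per_monomer_per_line=100.0,
            seed=1000 + i,
        )
        profiles.append(kymo.intensity_profile(km, window=6.0))
    return kymo.calibrate_psf(profiles, n_molecules=6)
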