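import numpy as np
import pytest

import teraspec as ts

#: The instrument band over which peak positions and optical constants
#: are reported; estimator-recovery checks are evaluated here.
INSTRUMENT_BAND = (0.3, 2.6)


@pytest.fixture(scope="session")
def clean_pulse():
    """Noise-free default reference pulse."""
    return ts.generate_reference_pulse(snr=float("inf"), seed=None)


@pytest.fixture(scope="session")
def mannitol_artifacts():
    """Full solid pipeline on the six-oscillator mannitol tablet preset."""
    return ts.run_pipeline(ts.RunConfig(preset="mannitol_solid"), mode="solid")


@pytest.fixture(scope="session")
def erythritol_artifacts():
    return ts.run_pipeline(ts.RunConfig(preset="erythritol_solid"), mode="solid")


@pytest.fixture(scope="session")
def mannitol_solution_artifacts():
    cfg = ts.RunConfig(preset="mannitol_solution", snr=1e4)
    return ts.run_pipeline(cfg, mode="solution")


def model_alpha_cm(model, nu):
    """Analytic power absorption coefficient of a material model, cm^-1."""
    ncplx = ts.refractive_index_model(model, nu)
    return 2.0 * (2.0 * np.pi * nu * 1e12) * ncplx.imag / 2.99792458e10


def in_instrument_band(oc):
    """Mask: inside both the validity band and the instrument band."""
    lo, hi = INSTRUMENT_BAND
    return oc.in_band & (oc.nu >= lo) & (oc.nu <= hi)
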