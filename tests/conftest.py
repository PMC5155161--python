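import numpy as np
import pytest

import spaint


@pytest.fixture(scope="session")
def calib_stack():
    """Small sparse calibration-bead stack shared across tests."""
    return spaint.simulate_calibration_stack(
        12, n_frames=10, spatial_size_px=(256, 256), seed=42
    )


@pytest.fixture(scope="session")
def calib_pipeline(calib_stack):
    """Localizations + fitted calibration from the shared stack."""
    from spaint import calibration as cal, localization as loc
    from spaint.instrument import linear_dispersion_from_optics

    table = loc.localize_stack(calib_stack)
    base = linear_dispersion_from_optics(calib_stack.geometry, calib_stack.camera)
    est = tuple(float(base.distance(w)) for w in cal.CALIBRATION_WAVELENGTHS_NM)
    model, obs = cal.calibrate_stack(calib_stack, table, est)
    return table, model, obs


@pytest.fixture(scope="session")
def luv_stack():
    """Small LUV field acquisition (16 vesicles, 300 frames)."""
    sample = spaint.luv_field(16, binding_rate_per_luv=2.5)
    return spaint.simulate_spaint_stack(sample, n_frames=300, seed=7)


@pytest.fixture(scope="session")
def luv_localizations(luv_stack):
    from spaint import localization as loc

    return loc.localize_stack(luv_stack)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
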