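import numpy as np
import pytest

import fpmrecon as fp


@pytest.fixture(scope="session")
def toy_optics() -> fp.OpticalConfig:
    """8x8 HR / 4x4 LR toy with a 1.5 px pupil (9 pass pixels)."""
    return fp.OpticalConfig(
        na_objective=0.3, wavelength_um=0.8, pixel_size_lr_um=1.0, n_hr=8, n_lr=4
    )


@pytest.fixture(scope="session")
def toy_pupil(toy_optics) -> fp.Pupil:
    return fp.pupil_mask(toy_optics)


@pytest.fixture(scope="session")
def toy_wavevectors(toy_optics) -> np.ndarray:
    """Five captures at hand-picked integer frequency-pixel shifts."""
    shifts = np.array([[0, 0], [1, 0], [0, 1], [-1, -1], [2, -2]], dtype=float)
    return shifts * toy_optics.delta_f


@pytest.fixture(scope="session")
def toy_spectrum(toy_optics) -> np.ndarray:
    rng = np.random.default_rng(7)
    n = toy_optics.n_hr
    return rng.standard_normal((n, n)) + 1j * rng.standard_normal((n, n))


@pytest.fixture(scope="session")
def toy_stack(toy_spectrum, toy_wavevectors, toy_pupil, toy_optics) -> fp.CaptureStack:
    return fp.forward_capture(toy_spectrum, toy_wavevectors, toy_pupil, toy_optics)


@pytest.fixture(scope="session")
def default_fixture() -> fp.FixtureSet:
    """The standard noiseless 64-HR acquisition shared across recovery tests."""
    return fp.make_fixture(seed=0)
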