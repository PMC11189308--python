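"""Shared fixtures: session-scoped synthetic models and stacks.

Everything is generated programmatically and deterministically; the
expensive objects (long filament models, 512-px spectra) are built once
per session.
"""

import numpy as np
import pytest

from vifhelix import layerline_spectra as lls
from vifhelix import synthetic_data as sd
from vifhelix.helix_core import params_from_units


@pytest.fixture(scope="session")
def default_model():
    """Straight 5-protofibril filament, measured symmetry, 60 tetramers."""
    return sd.build_filament_model(n_tetramers=60)


@pytest.fixture(scope="session")
def long_model():
    """Long filament for 512-px spectral segment stacks."""
    return sd.build_filament_model(n_tetramers=85)


@pytest.fixture(scope="session")
def fivefold_model():
    """Exact 5-fold control: twist 72 deg, rise 37 Å."""
    return sd.build_filament_model(n_tetramers=85,
                                   params=params_from_units(5.0, 37.0))


@pytest.fixture(scope="session")
def noiseless_stack_512(long_model):
    imaging = sd.ImagingParams(seed=11, noise_sigma=0.0, box=512)
    return sd.project_segments(long_model, imaging, n_segments=30,
                               spacing=60.0, max_shift_px=6)


@pytest.fixture(scope="session")
def noiseless_ps_512(noiseless_stack_512):
    return lls.average_power_spectrum(noiseless_stack_512)


@pytest.fixture(scope="session")
def small_stack(default_model):
    """Cheap noisy 110-px stack for I/O and bookkeeping tests."""
    imaging = sd.ImagingParams(seed=5, noise_sigma=0.5)
    return sd.project_segments(default_model, imaging, n_segments=10,
                               spacing=100.0)
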