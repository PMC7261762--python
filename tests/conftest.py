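import numpy as np
import pytest

import dbsidnn as dd


@pytest.fixture(scope="session")
def scheme():
    """Default 99-direction, 5-shell, b_max 1500 scheme (K = 100)."""
    return dd.make_default_scheme()


@pytest.fixture(scope="session")
def grid():
    return dd.default_grid()


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small but complete cohort: 5 classes x 5 lesions, shrunken sizes."""
    return dd.generate_cohort(
        composition={c: 5 for c in dd.CLASSES},
        snr=30.0,
        seed=42,
        size_scale=0.15,
    )


def make_params(grid, orientations=(), lambda_par=(), lambda_perp=(), fractions=(),
                spikes=()):
    """Build model parameters with the isotropic spectrum given as
    (diffusivity, fraction) spikes placed on the nearest grid node."""
    spectrum = np.zeros(grid.n)
    for d, f in spikes:
        j = int(np.argmin(np.abs(grid.d_values - d)))
        spectrum[j] += f / grid.weights[j]
    return dd.DbsiModelParams(
        orientations=np.array(orientations, dtype=float).reshape(-1, 3),
        lambda_par=list(lambda_par),
        lambda_perp=list(lambda_perp),
        fractions=list(fractions),
        iso_spectrum=spectrum,
        grid=grid,
    )


@pytest.fixture(scope="session")
def params_factory():
    return make_params
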